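"""Readers and writers for the user-facing tabular schemas.

All tables are comma-delimited UTF-8 with a header row and '.' decimals.

``bins.csv``     : county_id, state_id, age_group, sex, race, poverty, count
``contexts.csv`` : one row per county with every CountyContext field
``results.csv``  : BinRiskResult flattened (bin columns, p_ever_smoking,
                   one probability and one concentration column per house
                   type, expected_concentration, lifetime_risk)

Writing then reading a results table reproduces values to full precision
(17 significant digits).
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import pandas as pd

from . import vocab
from .exceptions import SchemaError, ValidationError
from .types import BinRiskResult, CountyContext, DemographicBin

_BIN_COLS = ["county_id", "state_id", "age_group", "sex", "race", "poverty",
             "count"]
_CONTEXT_COLS = [f.name for f in dc_fields(CountyContext)]


def _read_csv(path, required_cols) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return df


def read_bins(path) -> list[DemographicBin]:
    """Read a demographic-bin table into validated records."""
    df = _read_csv(path, _BIN_COLS)
    return bins_from_frame(df)


def bins_from_frame(df: pd.DataFrame) -> list[DemographicBin]:
    bins = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            bins.append(DemographicBin(
                county_id=str(row.county_id), state_id=str(row.state_id),
                age_group=str(row.age_group), sex=str(row.sex),
                race=str(row.race), poverty=str(row.poverty),
                count=int(row.count),
            ))
        except ValidationError as exc:
            raise ValidationError(f"bin row {i}: {exc}") from exc
    return bins


def bins_to_frame(bins) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(b, c) for c in _BIN_COLS} for b in bins])


def read_contexts(path) -> dict[str, CountyContext]:
    """Read a county-context table into a map county_id -> CountyContext."""
    df = _read_csv(path, _CONTEXT_COLS)
    return contexts_from_frame(df)


def contexts_from_frame(df: pd.DataFrame) -> dict[str, CountyContext]:
    out: dict[str, CountyContext] = {}
    for i, row in df.iterrows():
        kwargs = {c: row[c] for c in _CONTEXT_COLS}
        kwargs["county_id"] = str(kwargs["county_id"])
        kwargs["state_id"] = str(kwargs["state_id"])
        for flag in ("indoor_restriction_flag", "cbsa_poverty_above_median",
                     "cbsa_nonmetropolitan"):
            kwargs[flag] = int(kwargs[flag])
        try:
            ctx = CountyContext(**kwargs)
        except ValidationError as exc:
            raise ValidationError(f"context row {i}: {exc}") from exc
        if ctx.county_id in out:
            raise ValidationError(f"duplicate county_id {ctx.county_id!r}")
        out[ctx.county_id] = ctx
    return out


def contexts_to_frame(contexts) -> pd.DataFrame:
    vals = contexts.values() if isinstance(contexts, dict) else contexts
    return pd.DataFrame([{c: getattr(ctx, c) for c in _CONTEXT_COLS}
                         for ctx in vals])


def write_contexts(contexts, path) -> None:
    contexts_to_frame(contexts).to_csv(path, index=False)


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {c: getattr(r.bin, c) for c in _BIN_COLS}
        row["p_ever_smoking"] = r.p_ever_smoking
        for ht in vocab.HOUSE_TYPES:
            row[f"p_{ht}"] = r.housetype_probs[ht]
            row[f"conc_{ht}"] = r.concentration_by_type[ht]
        row["expected_concentration"] = r.expected_concentration
        row["lifetime_risk"] = r.lifetime_risk
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results, path) -> None:
    """Write flattened per-bin risk results; round-trip stable."""
    results_to_frame(results).to_csv(path, index=False)


def read_results(path) -> list[BinRiskResult]:
    cols = _BIN_COLS + ["p_ever_smoking", "expected_concentration",
                        "lifetime_risk"]
    df = _read_csv(path, cols)
    out = []
    for row in df.itertuples(index=False):
        b = DemographicBin(
            county_id=str(row.county_id), state_id=str(row.state_id),
            age_group=str(row.age_group), sex=str(row.sex),
            race=str(row.race), poverty=str(row.poverty), count=int(row.count),
        )
        probs = {ht: getattr(row, f"p_{ht}") for ht in vocab.HOUSE_TYPES}
        concs = {ht: getattr(row, f"conc_{ht}") for ht in vocab.HOUSE_TYPES}
        out.append(BinRiskResult(
            bin=b, p_ever_smoking=row.p_ever_smoking, housetype_probs=probs,
            concentration_by_type=concs,
            expected_concentration=row.expected_concentration,
            lifetime_risk=row.lifetime_risk,
        ))
    return out
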