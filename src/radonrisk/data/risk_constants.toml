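# Physical and epidemiological constants of the lifetime radon risk algorithm.
#
# The derived exposure rate is
#   wl_per_pci * wlm_per_wl_year * occupancy_fraction = 0.144 WLM/yr per pCi/L.
# equilibrium_fraction (radon progeny / radon gas activity ratio) is recorded
# for documentation: it is already embodied in wl_per_pci (1 pCi/L at 40%
# equilibrium corresponds to 0.004 WL) and enters no further computation.

[exposure]
wl_per_pci = 0.004            # working levels per pCi/L of radon gas
wlm_per_wl_year = 51.6        # working level months per WL-year
occupancy_fraction = 0.70     # fraction of time spent indoors at home
equilibrium_fraction = 0.40   # documentation only, see note above
exposure_duration_years = 75  # residential exposure duration

# Lifetime excess probability of fatal lung cancer per WLM, by sex and
# ever/never smoking status.  general_population is used only for
# calibration checks against the published national benchmark.
[unit_risk]
male_ever = 0.00106
female_ever = 0.000851
male_never = 0.000174
female_never = 0.000161
general_population = 0.00054
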