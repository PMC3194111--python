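# Fit the multilevel logistic ever-smoking model by Laplace approximation.
#
# Usage: Rscript fit_smoking_glmer.R <design.csv> <out.json>
#
# The design CSV is produced by radonrisk.smoking.EverSmokingModel: the
# outcome column `y`, pre-built numeric covariate columns, a `black`
# indicator for the state-level random slope, and integer grouping columns
# `state`, `cbsa`, `household`.  Random structure: correlated state
# intercept and black-race slope, CBSA intercept, household intercept.

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 2) stop("usage: fit_smoking_glmer.R <design.csv> <out.json>")

suppressMessages({
  library(lme4)
  library(jsonlite)
})

d <- read.csv(args[1])
fixed <- setdiff(colnames(d), c("y", "state", "cbsa", "household"))
f <- as.formula(paste(
  "y ~", paste(fixed, collapse = " + "),
  "+ (1 + black | state) + (1 | cbsa) + (1 | household)"))

m <- glmer(f, data = d, family = binomial, nAGQ = 1,
           control = glmerControl(calc.derivs = FALSE,
                                  optimizer = "nloptwrap",
                                  check.nobs.vs.nlev = "ignore",
                                  check.nobs.vs.nRE = "ignore"))

sm <- summary(m)
fe <- sm$coefficients
vc <- VarCorr(m)
st <- vc$state
out <- list(
  converged = length(m@optinfo$conv$lme4$messages) == 0,
  messages = unlist(m@optinfo$conv$lme4$messages),
  loglik = as.numeric(logLik(m)),
  fixed = list(
    names = rownames(fe),
    estimate = unname(fe[, "Estimate"]),
    se = unname(fe[, "Std. Error"])
  ),
  random = list(
    var_state = unname(st["(Intercept)", "(Intercept)"]),
    var_state_black_slope = unname(st["black", "black"]),
    cov_state_blackslope = unname(st["(Intercept)", "black"]),
    var_cbsa = unname(vc$cbsa[1, 1]),
    var_household = unname(vc$household[1, 1])
  )
)
write(toJSON(out, digits = 12, auto_unbox = TRUE), args[2])
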