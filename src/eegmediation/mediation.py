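"""Quasi-Bayesian counterfactual mediation and simulation-based power.

The dose -> cognition effect is decomposed, from the two fitted
random-intercept models, into the component transmitted through the
qEEG latent mediator (ACME, the product of the dose->mediator and
mediator->outcome coefficients times the dose contrast) and the direct
component (ADE, the dose coefficient of the outcome model).  Parameter
uncertainty is propagated by drawing fixed-effect vectors from the
Gaussian approximation N(beta_hat, vcov_beta) of each model
independently ("quasi-Bayesian" draws, random effects integrated out);
percentile intervals and Monte-Carlo p-values summarize the draws.

Power for a given coefficient is estimated by parametric simulation
from the fitted model: responses are regenerated (new subject
intercepts and residuals), the model is refit, and the rejection rate
at level alpha is reported with an exact Clopper-Pearson binomial
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lmm import LMMFit, ModelSpec, fit_random_intercept


@dataclass
class EffectSummary:
    point: float
    ci_low: float
    ci_high: float
    p_value: float
    p_floored: bool = False           # True -> report as "< 2/n_sims"

    def p_label(self, n_sims: int) -> str:
        return f"< {2 / n_sims:g}" if self.p_floored else f"{self.p_value:g}"


@dataclass
class MediationResult:
    acme: EffectSummary
    ade: EffectSummary
    total: EffectSummary
    prop_mediated: EffectSummary
    prop_ratio_of_means: float        # diagnostic: mean(acme)/mean(total)
    n_sims: int
    seed: int | None
    treat: tuple[float, float]
    n_excluded_draws: int = 0
    draws: dict = field(default_factory=dict, repr=False)


def _summarize(draws: np.ndarray, n_sims: int) -> EffectSummary:
    point = float(np.mean(draws))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    frac_pos = np.mean(draws > 0)
    frac_neg = np.mean(draws < 0)
    p = 2.0 * min(frac_pos, frac_neg)
    floored = p < 2.0 / n_sims
    return EffectSummary(point=point, ci_low=float(lo), ci_high=float(hi),
                         p_value=float(max(p, 2.0 / n_sims)),
                         p_floored=bool(floored))


def quasi_bayesian_mediation(mediator_fit: LMMFit, outcome_fit: LMMFit,
                             treat: tuple[float, float] = (0.0, 1.0),
                             n_sims: int = 1000,
                             seed: int | None = None,
                             dose_term: str = "dose",
                             mediator_term: str | None = None
                             ) -> MediationResult:
    """Decompose the dose effect via Monte-Carlo parameter draws.

    Per draw: acme = a*b*delta, ade = c'*delta, total = acme + ade with
    delta the treated-minus-control dose contrast; linearity makes the
    additivity acme + ade = total exact in every draw.
    """
    if mediator_term is None:
        mediator_term = mediator_fit.spec.response
    if mediator_term not in outcome_fit.term_names:
        raise ValueError(
            f"outcome fit has no term '{mediator_term}' (the mediator); "
            f"terms are {outcome_fit.term_names}")
    for fit, label in ((mediator_fit, "mediator"), (outcome_fit, "outcome")):
        if dose_term not in fit.term_names:
            raise ValueError(f"{label} fit has no term '{dose_term}'")
    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} < 100; Monte-Carlo summaries will be "
                      "unstable", stacklevel=2)

    rng = np.random.default_rng(seed)
    dm = rng.multivariate_normal(mediator_fit.beta.to_numpy(),
                                 mediator_fit.vcov_beta.to_numpy(),
                                 size=n_sims)
    dy = rng.multivariate_normal(outcome_fit.beta.to_numpy(),
                                 outcome_fit.vcov_beta.to_numpy(),
                                 size=n_sims)
    delta = treat[1] - treat[0]
    a = dm[:, mediator_fit.term_names.index(dose_term)]
    b = dy[:, outcome_fit.term_names.index(mediator_term)]
    c = dy[:, outcome_fit.term_names.index(dose_term)]

    acme = a * b * delta
    ade = c * delta
    total = acme + ade
    ok = total != 0
    n_excluded = int(np.sum(~ok))
    prop = acme[ok] / total[ok]

    result = MediationResult(
        acme=_summarize(acme, n_sims), ade=_summarize(ade, n_sims),
        total=_summarize(total, n_sims),
        prop_mediated=_summarize(prop, n_sims),
        prop_ratio_of_means=float(np.mean(acme) / np.mean(total)),
        n_sims=n_sims, seed=seed, treat=treat,
        n_excluded_draws=n_excluded,
        draws={"acme": acme, "ade": ade, "total": total, "prop": prop})
    return result


def proportion_mediated(result: MediationResult) -> tuple[float, float]:
    """Point estimate (mean of per-draw ratios) and ratio-of-means diagnostic.

    Warns when the total-effect CI includes zero, in which case the
    ratio is numerically unstable.
    """
    if result.total.ci_low <= 0.0 <= result.total.ci_high:
        warnings.warn("total-effect CI includes 0; the proportion mediated "
                      "is unstable", stacklevel=2)
    return result.prop_mediated.point, result.prop_ratio_of_means


def clopper_pearson(successes: int, trials: int,
                    level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI on the percentage scale (beta-quantile bounds)."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return 100.0 * lo, 100.0 * hi


@dataclass
class PowerResult:
    successes: int
    trials: int
    power: float                      # percent
    ci: tuple[float, float]           # percent, exact binomial
    alpha: float
    coefficient: str
    seed: int | None
    n_failed: int = 0


def simulate_power(fit: LMMFit, coefficient: str, alpha: float = 0.05,
                   n_sims: int = 100, seed: int | None = None,
                   data_template=None) -> PowerResult:
    """Simulation-based power for one fixed-effect coefficient.

    Responses are regenerated unconditionally from the fitted model
    (fixed effects plus fresh subject intercepts and residuals), the
    model is refit by ML, and a success is a Wald p-value below alpha.
    Refit failures are counted separately and excluded from the trials.
    """
    if coefficient not in fit.term_names:
        raise ValueError(f"no coefficient '{coefficient}' in the fit; terms "
                         f"are {fit.term_names}")
    rng = np.random.default_rng(seed)
    X, codes = fit.X, fit.group_codes
    n_groups = codes.max() + 1
    mu = X @ fit.beta.to_numpy()
    sd_u = np.sqrt(max(fit.sigma2_subject, 0.0))
    sd_e = np.sqrt(max(fit.sigma2_resid, 0.0))
    refit_spec = ModelSpec(response=fit.spec.response,
                           fixed_effects=fit.spec.fixed_effects,
                           groups=fit.spec.groups, method="ML",
                           p_value_mode="wald-z")
    import pandas as pd
    base = pd.DataFrame(X[:, 1:], columns=list(fit.spec.fixed_effects))
    base[fit.spec.groups] = codes

    successes = trials = failed = 0
    idx = fit.term_names.index(coefficient)
    for _ in range(n_sims):
        u = rng.normal(0.0, sd_u, n_groups)
        ysim = mu + u[codes] + rng.normal(0.0, sd_e, len(mu))
        base[fit.spec.response] = ysim
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = fit_random_intercept(refit_spec, base)
            if not refit.converged:
                raise RuntimeError("refit did not converge")
        except Exception:
            failed += 1
            continue
        trials += 1
        if refit.p_values.iloc[idx] < alpha:
            successes += 1
    if trials == 0:
        raise RuntimeError("all power-simulation refits failed")
    return PowerResult(successes=successes, trials=trials,
                       power=100.0 * successes / trials,
                       ci=clopper_pearson(successes, trials),
                       alpha=alpha, coefficient=coefficient, seed=seed,
                       n_failed=failed)
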