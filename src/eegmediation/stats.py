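"""Baseline group comparisons and cognitive-variable screening.

Pearson chi-square (no continuity correction by default, which
reproduces the trial's printed categorical p-values), Welch t-tests
from raw samples or printed summaries, the Benjamini-Hochberg step-up
FDR rule, and the paired-t screening that reduces a full
neuropsychological battery to the variables showing a significant
within-group change between visits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    observed: np.ndarray
    chi2: float
    df: int
    p_value: float
    continuity: bool


def chi_square_2x2(table, continuity: bool = False) -> ContingencyResult:
    """Pearson chi-square test on a 2x2 contingency table (1 df)."""
    obs = np.asarray(table)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    obs = obs.astype(int)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be > 0")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=continuity)
    return ContingencyResult(observed=obs, chi2=float(chi2), df=int(df),
                             p_value=float(p), continuity=continuity)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test; accepts raw samples or (mean, sd, n).

    Summary mode uses the closed-form Welch statistic and Satterthwaite
    degrees of freedom and agrees exactly with raw-sample mode on
    matching data.
    Returns (t, df, two-sided p).
    """
    def as_summary(v):
        if isinstance(v, tuple) and len(v) == 3:
            m, s, n = v
        else:
            arr = np.asarray(v, dtype=float)
            if arr.size < 2:
                raise ValueError("need n >= 2 observations per group")
            m, s, n = arr.mean(), arr.std(ddof=1), arr.size
        if n < 2:
            raise ValueError("need n >= 2 per group")
        if s <= 0:
            raise ValueError("sd must be > 0")
        return float(m), float(s), int(n)

    m1, s1, n1 = as_summary(x)
    m2, s2, n2 = as_summary(y)
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up selection at FDR level q.

    Returns (boolean mask, largest rejected p-value; NaN if none).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if q <= 0:
        return np.zeros(p.size, dtype=bool), float("nan")
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    threshold = float(p[mask].max()) if mask.any() else float("nan")
    return mask, threshold


@dataclass
class ScreeningResult:
    table: pd.DataFrame        # variable, t/p per group, selected flag
    threshold: float
    rule: str
    q: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "variable"].tolist()


def screen_cognitive_variables(cohort: pd.DataFrame,
                               score_columns: list[str],
                               q: float = 0.05,
                               rule: str = "treated",
                               group_column: str = "group",
                               treated_label: str = "treated") -> ScreeningResult:
    """Screen battery variables by paired change between visits.

    Per variable and group, a paired t-test of (follow-up - baseline);
    BH-FDR across variables at level ``q``.  ``rule`` decides selection:
    ``treated`` (default) keeps variables passing FDR in the treated
    group, ``either`` in either group, ``treated_not_control`` in the
    treated but not the control group.  Subjects missing a visit are
    excluded with a log entry.
    """
    if rule not in ("treated", "either", "treated_not_control"):
        raise ValueError(f"unknown screening rule {rule!r}")
    counts = cohort.groupby("subject_id")["visit"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        log.warning("excluding subjects with a missing visit: %s", incomplete)
        cohort = cohort[~cohort["subject_id"].isin(incomplete)]

    rows = []
    for var in score_columns:
        wide = cohort.pivot_table(index=["subject_id", group_column],
                                  columns="visit", values=var,
                                  aggfunc="first").reset_index()
        rec = {"variable": var}
        for glabel, tag in ((treated_label, "treated"), (None, "control")):
            sub = (wide[wide[group_column] == glabel] if glabel is not None
                   else wide[wide[group_column] != treated_label])
            diff = (sub["month6"] - sub["baseline"]).to_numpy(dtype=float)
            if len(diff) < 2 or diff.std(ddof=1) == 0:
                # degenerate paired test: no change -> p=1, constant
                # nonzero change -> unbounded evidence of change
                changed = len(diff) > 0 and diff.mean() != 0
                t = float(np.sign(diff.mean()) * np.inf) if changed else 0.0
                p = 0.0 if changed else 1.0
            else:
                t, p = sps.ttest_rel(sub["month6"], sub["baseline"])
            rec[f"t_{tag}"], rec[f"p_{tag}"] = float(t), float(p)
        rows.append(rec)
    table = pd.DataFrame(rows)

    sel_treated, thr = bh_fdr(table["p_treated"].to_numpy(), q)
    sel_control, _ = bh_fdr(table["p_control"].to_numpy(), q)
    if rule == "treated":
        selected = sel_treated
    elif rule == "either":
        selected = sel_treated | sel_control
    else:
        selected = sel_treated & ~sel_control
    table["selected"] = selected
    return ScreeningResult(table=table, threshold=thr, rule=rule, q=q)


def baseline_table(cohort: pd.DataFrame,
                   group_column: str = "group",
                   treated_label: str = "treated") -> pd.DataFrame:
    """Group summaries and p-values for the baseline characteristics.

    Continuous rows use Welch t-tests; the binary severity row uses the
    Pearson chi-square without continuity correction.
    """
    base = cohort[cohort["visit"] == "baseline"]
    g1 = base[base[group_column] == treated_label]
    g2 = base[base[group_column] != treated_label]
    rows = []
    for var in ("age_trial", "education"):
        t, df, p = welch_t(g1[var].to_numpy(), g2[var].to_numpy())
        rows.append({
            "variable": var, "test": "welch_t",
            "treated": f"{g1[var].mean():.1f} ± {g1[var].std(ddof=1):.1f}",
            "placebo": f"{g2[var].mean():.1f} ± {g2[var].std(ddof=1):.1f}",
            "p_value": p})
    tab = np.array([[int((g1["severity"] == 1).sum()), int((g2["severity"] == 1).sum())],
                    [int((g1["severity"] == 2).sum()), int((g2["severity"] == 2).sum())]])
    if np.all(tab.sum(axis=0) > 0) and np.all(tab.sum(axis=1) > 0):
        res = chi_square_2x2(tab)
        rows.append({"variable": "severity", "test": "chi2",
                     "treated": f"I: {tab[0, 0]}, II: {tab[1, 0]}",
                     "placebo": f"I: {tab[0, 1]}, II: {tab[1, 1]}",
                     "p_value": res.p_value})
    return pd.DataFrame(rows)
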