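"""ROC classification, survival modeling with cutoff optimization, and the drug screen.

The signature is evaluated three ways: as a classifier (rank-based AUC with
a DeLong confidence interval and a Wilcoxon group-difference test), as a
prognostic factor (Kaplan-Meier / log-rank and univariate or multivariate
Cox proportional hazards, with an optional survival-optimized cutoff scan in
the style of CutoffFinder), and as a predictor of compound sensitivity
(per-compound Spearman correlation of signature score with viability
log-fold change, BH-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import SurvivalCohort


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p: float  # two-sided Wilcoxon comparing the two score groups
    n_pos: int
    n_neg: int


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values (handles ties as 1/2)."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores: pd.Series, labels: pd.Series) -> ROCResult:
    """AUC of scores for binary labels, DeLong 95% CI, and Wilcoxon group p.

    Labels are coerced to {0, 1}; the AUC is the Mann-Whitney probability
    that a positive outranks a negative (ties count 1/2).
    """
    y = np.asarray(labels.loc[scores.index]).astype(int)
    x = scores.to_numpy(dtype=float)
    pos, neg = x[y == 1], x[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one sample in each class")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    auc = float(u.statistic / (len(pos) * len(neg)))
    var = _delong_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(var)
    return ROCResult(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0, 1)),
        ci_high=float(np.clip(auc + half, 0, 1)),
        p=float(u.pvalue),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def km_logrank(cohort: SurvivalCohort, labels: pd.Series) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier curves per label group and the two-group log-rank p."""
    tab = cohort.table.loc[labels.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 label groups, got {list(groups)}")
    curves = []
    for grp in sorted(groups):
        sub = tab[labels == grp]
        if sub["event"].sum() == 0:
            warnings.warn(f"group {grp!r} has zero events", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(grp))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = grp
        sf["n"] = len(sub)
        curves.append(sf)
    g0, g1 = sorted(groups)
    res = logrank_test(
        tab.loc[labels == g0, "time"],
        tab.loc[labels == g1, "time"],
        event_observed_A=tab.loc[labels == g0, "event"],
        event_observed_B=tab.loc[labels == g1, "event"],
    )
    return pd.concat(curves, ignore_index=True), float(res.p_value)


def cox_model(cohort: SurvivalCohort, terms: list[str], data: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per term with HR, 95% CI and p.

    ``data`` supplies term columns not already in the cohort table (e.g. a
    score or a high/low indicator).  Univariate use passes a single term;
    multivariate passes the score plus clinicopathological covariates.
    """
    df = cohort.table.copy()
    if data is not None:
        df = df.join(data, how="inner")
    missing = [t for t in terms if t not in df.columns]
    if missing:
        raise ValueError(f"terms not found: {missing}")
    df = df[["time", "event", *terms]].dropna()
    n_events = int(df["event"].sum())
    if n_events < 10 * len(terms):
        warnings.warn(
            f"only {n_events} events for {len(terms)} terms; estimates may be unstable",
            stacklevel=2,
        )
    df = pd.get_dummies(df, columns=[t for t in terms if df[t].dtype == object], drop_first=True)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    out.index.name = "term"
    return out


def survival_cutoff_optimize(
    scores: pd.Series, cohort: SurvivalCohort, min_group_frac: float = 0.1
) -> tuple[float, pd.DataFrame]:
    """Scan observed score values for the cutoff minimizing the log-rank p.

    Every observed score that leaves at least ``min_group_frac`` of samples
    on each side is a candidate split (score > cutoff -> high).  Returns the
    minimizing cutoff and the full (cutoff, p) profile.  The optimized p is
    descriptive only: the scan over cutoffs makes it optimistically biased.
    """
    shared = scores.index.intersection(cohort.table.index)
    if len(shared) < 30:
        raise ValueError(f"need >= 30 samples, got {len(shared)}")
    x = scores.loc[shared].to_numpy(dtype=float)
    tab = cohort.table.loc[shared]
    time = tab["time"].to_numpy()
    event = tab["event"].to_numpy()
    n = len(x)
    min_n = int(np.ceil(min_group_frac * n))
    candidates = np.unique(x)
    profile = []
    for c in candidates:
        high = x > c
        if high.sum() < min_n or (~high).sum() < min_n:
            continue
        res = logrank_test(time[high], time[~high], event_observed_A=event[high], event_observed_B=event[~high])
        profile.append((float(c), float(res.p_value), int(high.sum())))
    if not profile:
        raise ValueError("no admissible cutoff under the group-size constraint")
    prof = pd.DataFrame(profile, columns=["cutoff", "logrank_p", "n_high"])
    best = prof.loc[prof["logrank_p"].idxmin()]
    return float(best["cutoff"]), prof


def drug_screen(
    score_by_line: pd.Series, lfc: pd.DataFrame, min_lines: int = 10, fdr: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of signature score with per-compound viability LFC.

    ``lfc`` is cell lines x compounds, NaN for missing readouts.  Compounds
    observed in fewer than ``min_lines`` scored lines are dropped with a
    warning.  Negative rho flags sensitivity (lower viability at higher
    score).  BH across compounds.
    """
    shared = score_by_line.index.intersection(lfc.index)
    rows = []
    dropped = []
    for compound in lfc.columns:
        y = lfc.loc[shared, compound]
        ok = y.notna()
        if ok.sum() < min_lines:
            dropped.append(compound)
            continue
        rho, p = stats.spearmanr(score_by_line.loc[shared[ok]], y[ok])
        rows.append((compound, float(rho), float(p), int(ok.sum())))
    if dropped:
        warnings.warn(f"{len(dropped)} compounds dropped (< {min_lines} lines)", stacklevel=2)
    if not rows:
        raise ValueError("no compound with enough scored lines")
    out = pd.DataFrame(rows, columns=["compound", "rho", "p", "n"]).set_index("compound")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["sensitizing"] = (out["rho"] < 0) & (out["q"] <= fdr)
    return out.sort_values("p")


__all__ = [
    "ROCResult",
    "roc_auc",
    "km_logrank",
    "cox_model",
    "survival_cutoff_optimize",
    "drug_screen",
]
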