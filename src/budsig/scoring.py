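"""Signature scoring (TBS, pEMT), bimodal cutoff estimation, and classification.

A signature score is the mean log2 expression of the signature genes in a
sample: for Q3-normalized or bulk matrices the values are log2-transformed
(with a pseudocount) first, while single-cell log-normalized matrices are
averaged as-is.  Cutoffs for high/low classification come either from the
intersection of a two-component Gaussian mixture fit to a bimodal score
distribution, or (for survival) from a log-rank scan in :mod:`budsig.evaluate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .containers import ExpressionMatrix, SignatureDef

#: pseudocount for log2 of normalized (linear-scale) expression values
LOG2_PSEUDOCOUNT = 1.0

#: the 15-gene partial-EMT program of Puram et al. (top pEMT genes)
PEMT_GENES = (
    "SERPINE1", "TGFBI", "MMP10", "LAMC2", "P4HA2", "PDPN", "ITGA5", "LAMA3",
    "CDH13", "TNC", "MMP2", "EMP3", "INHBA", "LAMB3", "VIM",
)


def score_signature(
    matrix: ExpressionMatrix,
    signature: SignatureDef,
    missing_policy: str = "drop",
    pseudocount: float = LOG2_PSEUDOCOUNT,
    statistic: str = "mean",
) -> pd.Series:
    """Per-sample signature score: mean log2 expression over the signature genes.

    Matrices tagged ``lognorm_sc`` or ``log2`` are already on log scale and
    averaged directly; ``raw``/``q3`` values go through
    ``log2(value + pseudocount)`` first.  Missing signature genes are dropped
    (the mean renormalizes over the present ones) under the default policy,
    or raise under ``missing_policy="error"``.  ``statistic="sum"`` gives the
    un-averaged total for completeness.
    """
    present = [g for g in signature.genes if g in matrix.genes]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} present in matrix")
    missing = [g for g in signature.genes if g not in matrix.genes]
    if missing and missing_policy == "error":
        raise ValueError(f"signature genes missing from matrix: {missing[:5]}")
    # contiguity pins the reduction order, keeping scores bit-reproducible
    # whether the matrix came from memory or from a TSV round-trip
    vals = np.ascontiguousarray(matrix.values[present].to_numpy(dtype=float))
    if matrix.norm in ("lognorm_sc", "log2"):
        logvals = vals
    else:
        logvals = np.log2(vals + pseudocount)
    agg = logvals.sum(axis=1) if statistic == "sum" else logvals.mean(axis=1)
    return pd.Series(agg, index=matrix.samples, name=signature.name)


def score_pemt(matrix: ExpressionMatrix, **kwargs) -> pd.Series:
    """The fixed 15-gene pEMT score (mean log2 expression of the pEMT program)."""
    sig = SignatureDef(name="pEMT", genes=list(PEMT_GENES))
    return score_signature(matrix, sig, **kwargs)


@dataclass
class MixtureCutoff:
    """Two-component Gaussian mixture fit and the density-intersection cutoff."""

    mu1: float
    mu2: float
    sd1: float
    sd2: float
    w1: float
    w2: float
    cutoff: float
    converged: bool


def fit_bimodal_cutoff(
    scores: pd.Series | np.ndarray,
    seed: int = 0,
    n_restarts: int = 10,
    min_separation_sd: float = 0.5,
) -> MixtureCutoff:
    """Fit a two-component Gaussian mixture and find where the weighted densities cross.

    The cutoff is the root of ``w1 N(x|mu1,sd1) = w2 N(x|mu2,sd2)`` between the
    two component means.  ``converged`` is False when the data do not support
    a bimodal split: either the two-component fit loses the BIC comparison
    against a single Gaussian, or the components are closer than
    ``min_separation_sd`` pooled standard deviations.
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if x.shape[0] < 50:
        raise ValueError(f"need >= 50 scores to fit a bimodal cutoff, got {x.shape[0]}")
    gm = GaussianMixture(n_components=2, n_init=n_restarts, random_state=seed)
    gm.fit(x)
    if not gm.converged_:
        raise RuntimeError(f"EM failed to converge after {n_restarts} restarts (lower bound {gm.lower_bound_:.3g})")
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    order = np.argsort(gm.means_.ravel())
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.ravel()[order])
    w = gm.weights_.ravel()[order]

    def mixture_pdf(t):
        return w[0] * stats.norm.pdf(t, mu[0], sd[0]) + w[1] * stats.norm.pdf(t, mu[1], sd[1])

    # bimodal iff the fitted mixture density actually dips between the means
    grid = np.linspace(mu[0], mu[1], 256)
    dens = mixture_pdf(grid)
    has_dip = dens.min() < 0.999 * min(dens[0], dens[-1])
    pooled_sd = float(np.sqrt(np.mean(sd**2)))
    separable = bool(
        gm.bic(x) < gm1.bic(x)
        and (mu[1] - mu[0]) > min_separation_sd * pooled_sd
        and has_dip
    )

    def diff(t: float) -> float:
        return w[0] * stats.norm.pdf(t, mu[0], sd[0]) - w[1] * stats.norm.pdf(t, mu[1], sd[1])

    cutoff = float((mu[0] + mu[1]) / 2)
    if separable and mu[1] - mu[0] > 1e-12:
        lo, hi = mu[0], mu[1]
        if np.sign(diff(lo)) != np.sign(diff(hi)):
            cutoff = float(optimize.brentq(diff, lo, hi))
    return MixtureCutoff(
        mu1=float(mu[0]), mu2=float(mu[1]), sd1=float(sd[0]), sd2=float(sd[1]),
        w1=float(w[0]), w2=float(w[1]), cutoff=cutoff, converged=bool(separable),
    )


def classify(scores: pd.Series, cutoff: float) -> pd.Series:
    """Label samples "high" when score > cutoff, else "low" (boundary goes low)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return pd.Series(np.where(scores.to_numpy() > cutoff, "high", "low"), index=scores.index, name="label")


def correlate_scores(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Spearman correlation (rho, two-sided p) of two score sets on shared samples."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    rho, p = stats.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho), float(p)


def classify_budding_bulk(tb_counts: pd.Series) -> pd.DataFrame:
    """Two- and three-way budding classes from histological tumor-bud counts.

    TB = 0 is "non-budding"; TB > 0 is "budding", split into "low_budding"
    (0 < TB < 6) and "high_budding" (TB >= 6).
    """
    tb = tb_counts.astype(float)
    if (tb < 0).any():
        raise ValueError("negative tumor-bud counts")
    binary = np.where(tb == 0, "non_budding", "budding")
    three = np.where(tb == 0, "non_budding", np.where(tb < 6, "low_budding", "high_budding"))
    return pd.DataFrame({"budding": binary, "budding_class": three}, index=tb_counts.index)


__all__ = [
    "PEMT_GENES",
    "LOG2_PSEUDOCOUNT",
    "MixtureCutoff",
    "score_signature",
    "score_pemt",
    "fit_bimodal_cutoff",
    "classify",
    "correlate_scores",
    "classify_budding_bulk",
]
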