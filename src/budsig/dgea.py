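"""Differential expression by Wilcoxon contrasts and intersection-based signature derivation.

Each contrast compares case-level mean expression between two
(segment type, compartment) groups: signed-rank when the groups come from
the same cases (within-tumor) and rank-sum when they do not (between-tumor).
P-values are Benjamini-Hochberg adjusted within a contrast and a gene is
differentially expressed when q <= 0.05 and its absolute fold change exceeds
1.5.  The bud signature is the intersection of the up-regulated DEG sets
from the six bud-versus-everything contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import SignatureDef

#: pseudocount added to group means before the fold-change ratio
FC_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison on case-level matrices.

    ``group_a`` / ``group_b`` are (segment_type, compartment) keys into the
    dict produced by case-level aggregation.  For paired contrasts the pairing
    unit is the case: only cases present in both groups contribute.
    """

    name: str
    group_a: tuple[str, str]
    group_b: tuple[str, str]
    paired: bool
    fc_threshold: float = 1.5
    fdr: float = 0.05


def _wilcoxon_paired(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    d = d[d != 0]  # zero differences dropped, standard signed-rank convention
    if d.size == 0:
        return 1.0
    exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    res = stats.wilcoxon(d, alternative="two-sided", method="exact" if exact else "approx", correction=True)
    return float(res.pvalue)


def _wilcoxon_unpaired(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def run_contrast(
    case_matrices: dict[tuple[str, str], pd.DataFrame], contrast: ContrastSpec
) -> pd.DataFrame:
    """Per-gene Wilcoxon test of group A vs group B on case-level values.

    Returns a DataFrame indexed by gene with ``mean_a``, ``mean_b``,
    ``log2_fc`` (ratio of pseudocounted group means), ``p``, ``q`` (BH within
    the contrast) and ``direction`` in {up, down, ns}.  Direction "up" means
    higher in group A.
    """
    for key in (contrast.group_a, contrast.group_b):
        if key not in case_matrices:
            raise ValueError(f"contrast {contrast.name}: group {key} not in case matrices")
    mat_a = case_matrices[contrast.group_a]
    mat_b = case_matrices[contrast.group_b]
    genes = mat_a.columns.intersection(mat_b.columns)
    if contrast.paired:
        cases = mat_a.index.intersection(mat_b.index)
        if len(cases) < 3:
            raise ValueError(f"contrast {contrast.name}: need >= 3 complete pairs, got {len(cases)}")
        a = mat_a.loc[cases, genes].to_numpy(dtype=float)
        b = mat_b.loc[cases, genes].to_numpy(dtype=float)
        pvals = np.array([_wilcoxon_paired(a[:, j], b[:, j]) for j in range(len(genes))])
    else:
        if len(mat_a) < 3 or len(mat_b) < 3:
            raise ValueError(f"contrast {contrast.name}: need >= 3 cases per group")
        a = mat_a[genes].to_numpy(dtype=float)
        b = mat_b[genes].to_numpy(dtype=float)
        pvals = np.array([_wilcoxon_unpaired(a[:, j], b[:, j]) for j in range(len(genes))])

    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    log2_fc = np.log2((mean_a + FC_PSEUDOCOUNT) / (mean_b + FC_PSEUDOCOUNT))
    q = multipletests(pvals, method="fdr_bh")[1]
    # DEG call: q at FDR and a strict |FC| > threshold on the ratio scale
    sig = (q <= contrast.fdr) & (np.abs(log2_fc) > np.log2(contrast.fc_threshold))
    direction = np.where(~sig, "ns", np.where(log2_fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "p": pvals,
            "q": q,
            "direction": direction,
        },
        index=pd.Index(genes, name="gene"),
    )


def derive_signature(
    tables: dict[str, pd.DataFrame], name: str = "TBS"
) -> tuple[SignatureDef | None, SignatureDef | None]:
    """Intersect DEG calls across contrasts into up- and down-signatures.

    A gene enters the up-signature only if it is called "up" in *every*
    contrast (analogously for down).  Gene order is lexicographic.  Returns
    ``None`` for an empty direction.
    """
    if len(tables) < 2:
        raise ValueError("signature derivation needs at least two contrasts")
    up_sets = [set(t.index[t["direction"] == "up"]) for t in tables.values()]
    down_sets = [set(t.index[t["direction"] == "down"]) for t in tables.values()]
    provenance = sorted(tables)
    up = sorted(set.intersection(*up_sets))
    down = sorted(set.intersection(*down_sets))
    sig_up = SignatureDef(name=name, genes=up, direction="up", provenance=provenance) if up else None
    sig_down = (
        SignatureDef(name=f"{name}_down", genes=down, direction="down", provenance=provenance)
        if down
        else None
    )
    return sig_up, sig_down


def overlap_test(
    genes_a, genes_b, universe, exclude=()
) -> tuple[int, float]:
    """Fisher exact test (two-sided) for the overlap of two gene lists.

    ``exclude`` genes (e.g. the signature genes themselves) are removed from
    the universe and both lists before building the 2x2 table.
    """
    universe = set(universe) - set(exclude)
    if not universe:
        raise ValueError("empty gene universe")
    a = set(genes_a) & universe
    b = set(genes_b) & universe
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return n11, float(p)


#: The six bud-versus-everything contrasts used for signature derivation,
#: in terms of (segment_type, compartment) group keys.
def default_signature_contrasts() -> list[ContrastSpec]:
    bud = ("bud", "tumor")
    return [
        ContrastSpec("bud_vs_bud_stroma", bud, ("bud", "stroma"), paired=True),
        ContrastSpec("bud_vs_bulk_budding", bud, ("bulk_budding", "tumor"), paired=True),
        ContrastSpec("bud_vs_bulk_budding_stroma", bud, ("bulk_budding", "stroma"), paired=True),
        ContrastSpec("bud_vs_bulk_nonbudding", bud, ("bulk_nonbudding", "tumor"), paired=False),
        ContrastSpec("bud_vs_bulk_nonbudding_stroma", bud, ("bulk_nonbudding", "stroma"), paired=False),
        ContrastSpec("bud_vs_immune", bud, ("immune", "immune"), paired=False),
    ]


__all__ = [
    "ContrastSpec",
    "run_contrast",
    "derive_signature",
    "overlap_test",
    "default_signature_contrasts",
    "FC_PSEUDOCOUNT",
]
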