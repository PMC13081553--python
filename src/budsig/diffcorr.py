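"""Differential gene-gene correlation between two conditions with a permutation null.

Case-level Spearman correlations are computed for all gene pairs of a
compartment pairing (tumor-tumor, stroma-stroma, or tumor-stroma) separately
in two conditions (e.g. tumor buds + adjacent stroma versus budding bulk +
adjacent stroma).  Pairs that correlate strongly (|rho| > 0.8 at FDR 1%) in
at least one condition are candidates; for each candidate the difference of
Fisher-Z transformed correlations, dz = atanh(rho_A) - atanh(rho_B), is
compared against a null built by shuffling case profiles between the two
conditions.  Differential edges additionally require |dz| >= 1.4 and are
assembled into an annotated network keyed by (gene, compartment).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: |rho| is clamped below 1 by this margin before atanh
ATANH_EPS = 1e-6


@dataclass
class CompartmentPairing:
    """Matched case-level matrices for one compartment combination in two conditions.

    ``a_x``/``a_y`` are the condition-A matrices of the two compartments
    (identical objects for a within-compartment pairing), with rows (cases)
    aligned; likewise ``b_x``/``b_y`` for condition B.  Cross-compartment
    pairings correlate every gene of x with every gene of y; within-compartment
    pairings use unordered gene pairs excluding self-pairs.
    """

    kind: str  # "tumor-tumor", "stroma-stroma", "tumor-stroma"
    a_x: pd.DataFrame
    a_y: pd.DataFrame
    b_x: pd.DataFrame
    b_y: pd.DataFrame

    @property
    def within(self) -> bool:
        return self.a_x.columns.equals(self.a_y.columns) and self.a_x is self.a_y or self.kind in (
            "tumor-tumor",
            "stroma-stroma",
        )

    def __post_init__(self) -> None:
        if not self.a_x.index.equals(self.a_y.index):
            raise ValueError("condition A cases not aligned across compartments")
        if not self.b_x.index.equals(self.b_y.index):
            raise ValueError("condition B cases not aligned across compartments")


def _rank_standardize(x: np.ndarray) -> np.ndarray:
    """Column-wise rank transform, centered and scaled; constant columns -> NaN."""
    r = stats.rankdata(x, axis=0)
    r = r - r.mean(axis=0)
    sd = r.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, r / sd, np.nan)
    return out


def spearman_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every column pair of x vs y.

    Uses the rank-then-Pearson identity with a t approximation for p
    (n >= 5 in practice here).  Constant columns yield NaN.
    """
    n = x.shape[0]
    rx = _rank_standardize(x)
    ry = _rank_standardize(y)
    rho = rx.T @ ry / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def condition_correlations(
    pairing: CompartmentPairing, condition: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full Spearman rho and p matrices for one condition of a pairing."""
    if condition == "A":
        mx, my = pairing.a_x, pairing.a_y
    elif condition == "B":
        mx, my = pairing.b_x, pairing.b_y
    else:
        raise ValueError("condition must be 'A' or 'B'")
    if len(mx) < 5:
        raise ValueError(f"condition {condition}: need >= 5 aligned cases, got {len(mx)}")
    rho, p = spearman_matrix(mx.to_numpy(dtype=float), my.to_numpy(dtype=float))
    return (
        pd.DataFrame(rho, index=mx.columns, columns=my.columns),
        pd.DataFrame(p, index=mx.columns, columns=my.columns),
    )


def _pair_index(pairing: CompartmentPairing) -> list[tuple[str, str]]:
    gx = list(pairing.a_x.columns)
    gy = list(pairing.a_y.columns)
    if pairing.within:
        return [(gx[i], gy[j]) for i in range(len(gx)) for j in range(i + 1, len(gy))]
    return [(a, b) for a in gx for b in gy]


def candidate_pairs(
    pairing: CompartmentPairing, rho_min: float = 0.8, fdr: float = 0.01
) -> pd.DataFrame:
    """Pairs with |rho| > rho_min and BH q <= fdr in at least one condition.

    BH is applied within each condition across all (non-degenerate) pairs of
    the pairing.  Returns a DataFrame with gene_x, gene_y, rho_a, rho_b.
    """
    rho_a, p_a = condition_correlations(pairing, "A")
    rho_b, p_b = condition_correlations(pairing, "B")
    pairs = _pair_index(pairing)
    ix = {g: i for i, g in enumerate(rho_a.index)}
    iy = {g: i for i, g in enumerate(rho_a.columns)}
    rows = np.array([ix[a] for a, _ in pairs])
    cols = np.array([iy[b] for _, b in pairs])

    out_rows = []
    ra = rho_a.to_numpy()[rows, cols]
    rb = rho_b.to_numpy()[rows, cols]
    pa = p_a.to_numpy()[rows, cols]
    pb = p_b.to_numpy()[rows, cols]
    valid = ~(np.isnan(ra) | np.isnan(rb))
    qa = np.full(len(pairs), np.nan)
    qb = np.full(len(pairs), np.nan)
    if valid.any():
        qa[valid] = multipletests(pa[valid], method="fdr_bh")[1]
        qb[valid] = multipletests(pb[valid], method="fdr_bh")[1]
    keep = valid & (
        ((np.abs(ra) > rho_min) & (qa <= fdr)) | ((np.abs(rb) > rho_min) & (qb <= fdr))
    )
    for k in np.flatnonzero(keep):
        out_rows.append((pairs[k][0], pairs[k][1], ra[k], rb[k]))
    return pd.DataFrame(out_rows, columns=["gene_x", "gene_y", "rho_a", "rho_b"])


def fisher_z(rho: np.ndarray | float) -> np.ndarray | float:
    """atanh with |rho| clamped at 1 - 1e-6 to keep dz finite."""
    return np.arctanh(np.clip(rho, -1 + ATANH_EPS, 1 - ATANH_EPS))


def _pair_spearman(x: np.ndarray, y: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Spearman rho for selected column pairs (i of x, j of y)."""
    n = x.shape[0]
    rx = _rank_standardize(x)
    ry = _rank_standardize(y)
    return np.clip(np.einsum("nk,nk->k", rx[:, i], ry[:, j]) / n, -1.0, 1.0)


def permutation_test(
    pairing: CompartmentPairing,
    candidates: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical p-values for the Fisher-Z difference of each candidate pair.

    Case profiles (the joint x/y rows of a case) are shuffled between the two
    conditions, preserving group sizes; each candidate's |dz| is compared with
    its own permutation distribution:
    ``p_emp = (1 + #{|dz_perm| >= |dz_obs|}) / (n_perm + 1)``.
    """
    if candidates.empty:
        raise ValueError("no candidate pairs to test")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_a, n_b = len(pairing.a_x), len(pairing.b_x)
    if min(n_a, n_b) < 4:
        raise ValueError("need >= 4 cases per condition for permutation")

    # restrict to the genes actually involved, for speed
    gx = sorted(set(candidates["gene_x"]))
    gy = sorted(set(candidates["gene_y"]))
    ax, ay = pairing.a_x[gx].to_numpy(float), pairing.a_y[gy].to_numpy(float)
    bx, by = pairing.b_x[gx].to_numpy(float), pairing.b_y[gy].to_numpy(float)
    i = np.array([gx.index(g) for g in candidates["gene_x"]])
    j = np.array([gy.index(g) for g in candidates["gene_y"]])

    rho_a = _pair_spearman(ax, ay, i, j)
    rho_b = _pair_spearman(bx, by, i, j)
    dz_obs = fisher_z(rho_a) - fisher_z(rho_b)

    pool_x = np.vstack([ax, bx])
    pool_y = np.vstack([ay, by])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(candidates), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_a + n_b)
        pa, pb = perm[:n_a], perm[n_a:]
        dz = fisher_z(_pair_spearman(pool_x[pa], pool_y[pa], i, j)) - fisher_z(
            _pair_spearman(pool_x[pb], pool_y[pb], i, j)
        )
        exceed += np.abs(dz) >= np.abs(dz_obs)
    p_emp = (1 + exceed) / (n_perm + 1)

    edges = candidates.copy()
    edges["z_a"] = fisher_z(rho_a)
    edges["z_b"] = fisher_z(rho_b)
    edges["dz"] = dz_obs
    edges["p_emp"] = p_emp
    edges["q"] = multipletests(p_emp, method="fdr_bh")[1]
    return edges


def select_differential(
    edges: pd.DataFrame, fdr: float = 0.01, min_abs_dz: float = 1.4
) -> pd.DataFrame:
    """Keep edges with q <= fdr and |dz| >= min_abs_dz (inclusive); label the change.

    An edge is "gained" when the correlation is stronger (in absolute value)
    in condition A, "lost" otherwise; sign flips are labelled toward the
    condition with the larger |rho| and flagged in ``sign_flip``.
    """
    keep = (edges["q"] <= fdr) & (edges["dz"].abs() >= min_abs_dz)
    out = edges.loc[keep].copy()
    out["change"] = np.where(out["rho_a"].abs() >= out["rho_b"].abs(), "gained", "lost")
    out["sign_flip"] = np.sign(out["rho_a"]) * np.sign(out["rho_b"]) < 0
    return out


@dataclass
class NetworkAnnotation:
    """Optional gene-symbol annotation sources for the differential network."""

    tfs: set[str] | None = None
    ligands: set[str] | None = None
    receptors: set[str] | None = None
    deg_status: dict[str, str] | None = None  # gene -> up/down/ns
    known_interactions: set[frozenset[str]] | None = None

    @staticmethod
    def _norm(genes) -> set[str]:
        return {g.upper() for g in genes}


def build_network(
    edges: pd.DataFrame,
    comp_x: str,
    comp_y: str,
    annotations: NetworkAnnotation | None = None,
) -> tuple[nx.Graph, list[set]]:
    """Assemble differential edges into a graph keyed by (gene, compartment).

    Returns the annotated graph and its connected components sorted by
    decreasing size.  Component size classes (large > 8 members, medium 3-8,
    pair = 2) are stored on the graph under ``G.graph['size_class']``.
    """
    ann = annotations or NetworkAnnotation()
    tfs = NetworkAnnotation._norm(ann.tfs) if ann.tfs else set()
    ligands = NetworkAnnotation._norm(ann.ligands) if ann.ligands else set()
    receptors = NetworkAnnotation._norm(ann.receptors) if ann.receptors else set()
    deg = {k.upper(): v for k, v in (ann.deg_status or {}).items()}
    known = ann.known_interactions or set()

    g = nx.Graph()
    for _, row in edges.iterrows():
        u = (row["gene_x"], comp_x)
        v = (row["gene_y"], comp_y)
        for node in (u, v):
            sym = node[0].upper()
            g.add_node(
                node,
                gene=node[0],
                compartment=node[1],
                is_tf=sym in tfs,
                is_ligand=sym in ligands,
                is_receptor=sym in receptors,
                deg_status=deg.get(sym, "ns"),
            )
        g.add_edge(
            u,
            v,
            rho_a=row["rho_a"],
            rho_b=row["rho_b"],
            dz=row["dz"],
            q=row["q"],
            change=row["change"],
            known_interaction=frozenset((row["gene_x"].upper(), row["gene_y"].upper())) in known,
        )
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    g.graph["size_class"] = {
        "large": sum(1 for c in components if len(c) > 8),
        "medium": sum(1 for c in components if 3 <= len(c) <= 8),
        "pair": sum(1 for c in components if len(c) == 2),
    }
    return g, components


__all__ = [
    "CompartmentPairing",
    "NetworkAnnotation",
    "spearman_matrix",
    "condition_correlations",
    "candidate_pairs",
    "fisher_z",
    "permutation_test",
    "select_differential",
    "build_network",
    "ATANH_EPS",
]
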