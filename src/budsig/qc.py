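"""Segment-level QC, LOQ filtering, Q3 normalization and single-cell preprocessing.

GeoMx-style digital spatial profiling yields one expression profile per
*segment* (an ROI/AOI combination).  Every segment carries a handful of
negative-control probes whose counts estimate the non-specific background.
The limit of quantification (LOQ) of a segment is defined from the geometric
statistics of those negatives::

    LOQ = max(2, NegGeoMean * NegGeoSD**2)

i.e. two (geometric) standard deviations above the negative-control mean,
clamped at 2 counts.  Sequencing-level filters (raw reads, stitching,
alignment, saturation, no-template-control counts) remove failed segments
before any expression filtering; LOQ-based filters then remove segments with
almost no signal and genes that are essentially never detected.  Surviving
raw counts are upper-quartile (Q3) normalized and averaged per case within
each (segment type, compartment) group.

Single-cell matrices follow the standard UMI route instead: cell filters on
detected genes and mitochondrial fraction, a sparse-gene filter, and
log-normalization ``log(1 + count / total * 10_000)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SegmentCountMatrix

#: pseudocount added to negative-probe counts before taking logs, so that
#: geometric statistics are defined in the presence of zero counts.
NEG_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class QCThresholds:
    """Segment- and matrix-level QC thresholds.

    Defaults are the conventional GeoMx whole-transcriptome settings:
    at least 40,000 deduplicated reads per segment, 80% stitched, 70%
    aligned, 50% sequencing saturation, at most 1,000 counts in the
    no-template control, and the 5% / 10% LOQ detection-rate filters.
    All comparisons are inclusive at the boundary.
    """

    min_reads: int = 40_000
    min_stitched: float = 0.80
    min_aligned: float = 0.70
    min_saturation: float = 0.50
    max_ntc: int = 1_000
    min_gene_detect_frac_per_segment: float = 0.05
    min_segment_detect_frac_per_gene: float = 0.10

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")


@dataclass
class LOQRecord:
    """Per-segment negative-probe geometric statistics and derived LOQ."""

    segment_id: str
    neg_geo_mean: float
    neg_geo_sd: float
    loq: float


def compute_loq(neg_counts: np.ndarray | pd.Series, segment_id: str = "<segment>") -> LOQRecord:
    """Compute the limit of quantification of one segment from its negative probes.

    The geometric SD is the exponential of the standard deviation (ddof=1) of
    the natural-log counts, so a zero-variance negative set gives
    ``neg_geo_sd == 1`` and the clamp at 2 takes over.  Zero counts are
    replaced by a 0.5 pseudocount before the log (positive counts are left
    untouched, so e.g. all-equal negatives give loq == that count).
    """
    x = np.asarray(neg_counts, dtype=float)
    if x.size < 2:
        raise ValueError(f"segment {segment_id}: need >= 2 negative probes, got {x.size}")
    if (x < 0).any():
        raise ValueError(f"segment {segment_id}: negative probe counts must be >= 0")
    logs = np.log(np.where(x == 0, NEG_PSEUDOCOUNT, x))
    gmean = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1)))
    return LOQRecord(segment_id=segment_id, neg_geo_mean=gmean, neg_geo_sd=gsd, loq=max(2.0, gmean * gsd**2))


def compute_loq_table(matrix: SegmentCountMatrix) -> pd.DataFrame:
    """LOQ records for every segment, as a DataFrame indexed by segment id."""
    neg = matrix.counts[matrix.negative_probes]
    if neg.shape[1] < 2:
        raise ValueError("need >= 2 negative-control probes to compute LOQ")
    recs = [compute_loq(neg.loc[s].to_numpy(), s) for s in neg.index]
    return pd.DataFrame(
        {
            "neg_geo_mean": [r.neg_geo_mean for r in recs],
            "neg_geo_sd": [r.neg_geo_sd for r in recs],
            "loq": [r.loq for r in recs],
        },
        index=neg.index,
    )


#: (metric column, threshold attribute, direction) for the sequencing filters
_SEGMENT_CRITERIA = (
    ("raw_reads", "min_reads", "ge"),
    ("stitched_frac", "min_stitched", "ge"),
    ("aligned_frac", "min_aligned", "ge"),
    ("saturation_frac", "min_saturation", "ge"),
    ("ntc_count", "max_ntc", "le"),
)


def filter_segments(
    matrix: SegmentCountMatrix, thresholds: QCThresholds | None = None
) -> tuple[SegmentCountMatrix, pd.DataFrame]:
    """Apply sequencing-level segment filters; return kept matrix and a QC report.

    The report has one boolean column per criterion plus ``pass`` and a
    ``fail_reasons`` string; a missing metric raises rather than silently
    passing the segment.
    """
    thresholds = thresholds or QCThresholds()
    meta = matrix.meta
    report = pd.DataFrame(index=meta.index)
    for col, attr, op in _SEGMENT_CRITERIA:
        if col not in meta.columns:
            raise ValueError(f"metadata missing QC metric {col!r}")
        vals = meta[col]
        if vals.isna().any():
            bad = vals.index[vals.isna()][0]
            raise ValueError(f"segment {bad}: missing QC metric {col!r}")
        bound = getattr(thresholds, attr)
        report[attr] = vals >= bound if op == "ge" else vals <= bound
    report["pass"] = report.all(axis=1)
    crit_cols = [a for _, a, _ in _SEGMENT_CRITERIA]
    report["fail_reasons"] = report[crit_cols].apply(
        lambda row: ";".join(c for c in crit_cols if not row[c]), axis=1
    )
    kept = matrix.subset(segments=report.index[report["pass"]])
    return kept, report


def filter_by_loq(
    matrix: SegmentCountMatrix,
    loq_table: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> SegmentCountMatrix:
    """Drop low-signal segments, then rarely detected genes, by the LOQ rule.

    Detection means count >= segment LOQ (inclusive).  Segments detecting
    fewer than 5% of genes above their own LOQ go first; genes detected in
    fewer than 10% of the remaining segments go second.  Negative probes are
    excluded from the gene universe (and from the output).
    """
    thresholds = thresholds or QCThresholds()
    if loq_table is None:
        loq_table = compute_loq_table(matrix)
    missing = set(matrix.counts.index) - set(loq_table.index)
    if missing:
        raise ValueError(f"no LOQ record for segments: {sorted(missing)[:5]}")
    genes = matrix.gene_probes
    counts = matrix.counts[genes]
    loq = loq_table.loc[counts.index, "loq"].to_numpy()[:, None]
    detected = counts.to_numpy() >= loq

    seg_frac = detected.mean(axis=1)
    keep_seg = seg_frac >= thresholds.min_gene_detect_frac_per_segment
    if not keep_seg.any():
        raise ValueError("segment LOQ filter removed every segment")
    detected = detected[keep_seg]
    gene_frac = detected.mean(axis=0)
    keep_gene = gene_frac >= thresholds.min_segment_detect_frac_per_gene
    if not keep_gene.any():
        raise ValueError("gene LOQ filter removed every gene")
    return matrix.subset(segments=counts.index[keep_seg], probes=genes[keep_gene])


def q3_percentile(values: np.ndarray) -> float:
    """75th percentile with linear interpolation between order statistics."""
    return float(np.percentile(values, 75, method="linear"))


def q3_normalize(matrix: SegmentCountMatrix | pd.DataFrame) -> ExpressionMatrix:
    """Upper-quartile normalize counts so every segment has the same Q3.

    Each segment is rescaled so its 75th-percentile gene count equals the
    geometric mean of all segments' raw 75th percentiles — the scale is data
    driven, which makes the operation idempotent.
    """
    counts = matrix.counts[matrix.gene_probes] if isinstance(matrix, SegmentCountMatrix) else matrix
    q3 = np.apply_along_axis(q3_percentile, 1, counts.to_numpy(dtype=float))
    if (q3 <= 0).any():
        bad = counts.index[q3 <= 0][0]
        raise ValueError(f"segment {bad}: zero upper quartile, cannot normalize")
    target = float(np.exp(np.mean(np.log(q3))))
    values = counts.to_numpy(dtype=float) * (target / q3)[:, None]
    return ExpressionMatrix(values=pd.DataFrame(values, index=counts.index, columns=counts.columns), norm="q3")


def aggregate_case_level(
    norm: ExpressionMatrix, meta: pd.DataFrame
) -> dict[tuple[str, str], pd.DataFrame]:
    """Average normalized segment profiles per case within each (segment_type, compartment).

    Returns one case x gene matrix per group; a case missing from a group is
    simply absent from that group's matrix.
    """
    meta = meta.loc[norm.samples]
    out: dict[tuple[str, str], pd.DataFrame] = {}
    grouping = [meta["segment_type"], meta["compartment"], meta["case_id"]]
    means = norm.values.groupby(grouping).mean()
    for (seg_type, comp), block in means.groupby(level=[0, 1]):
        mat = block.droplevel([0, 1]).sort_index()
        mat.index.name = "case_id"
        out[(seg_type, comp)] = mat
    return out


@dataclass
class SCFilterReport:
    """Counts of cells/genes removed at each single-cell preprocessing step."""

    n_cells_in: int = 0
    n_low_genes: int = 0
    n_high_genes: int = 0
    n_high_mito: int = 0
    n_cells_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    mito_filter_applied: bool = True
    notes: list[str] = field(default_factory=list)


def sc_preprocess(
    umi: pd.DataFrame,
    mito_prefixes: tuple[str, ...] = ("MT-",),
    min_genes: int = 200,
    max_genes: int = 8_000,
    max_mito_frac: float = 0.10,
    min_cell_frac_per_gene: float = 0.001,
    scale_factor: float = 10_000.0,
) -> tuple[ExpressionMatrix, SCFilterReport]:
    """Standard UMI preprocessing: cell filters, sparse-gene filter, log-normalize.

    Cells with fewer than ``min_genes`` or more than ``max_genes`` detected
    genes, or with more than ``max_mito_frac`` of UMIs from mitochondrial
    genes, are excluded; genes expressed in fewer than 0.1% of the remaining
    cells are dropped; values become ``log(1 + count / cell_total * 10,000)``.
    """
    report = SCFilterReport(n_cells_in=umi.shape[0], n_genes_in=umi.shape[1])
    x = umi.to_numpy(dtype=float)
    n_detected = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)

    mito_cols = np.array(
        [any(g.upper().startswith(p.upper()) for p in mito_prefixes) for g in umi.columns]
    )
    if mito_cols.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, x[:, mito_cols].sum(axis=1) / np.maximum(totals, 1), 1.0)
        mito_ok = mito_frac <= max_mito_frac
    else:
        warnings.warn("no mitochondrial genes found; mito filter skipped", stacklevel=2)
        report.mito_filter_applied = False
        report.notes.append("mito filter skipped: no genes matched prefixes")
        mito_ok = np.ones(umi.shape[0], dtype=bool)

    low = n_detected < min_genes
    high = n_detected > max_genes
    keep_cell = ~low & ~high & mito_ok
    report.n_low_genes = int(low.sum())
    report.n_high_genes = int(high.sum())
    report.n_high_mito = int((~mito_ok & ~low & ~high).sum())
    report.n_cells_out = int(keep_cell.sum())
    if not keep_cell.any():
        raise ValueError("cell filters removed every cell")

    x = x[keep_cell]
    expressed_frac = (x > 0).mean(axis=0)
    keep_gene = expressed_frac >= min_cell_frac_per_gene
    report.n_genes_out = int(keep_gene.sum())
    x = x[:, keep_gene]
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("cell with zero total UMIs after gene filtering")
    values = np.log1p(x / totals * scale_factor)
    return (
        ExpressionMatrix(
            values=pd.DataFrame(
                values, index=umi.index[keep_cell], columns=umi.columns[keep_gene]
            ),
            norm="lognorm_sc",
        ),
        report,
    )


__all__ = [
    "QCThresholds",
    "LOQRecord",
    "SCFilterReport",
    "compute_loq",
    "compute_loq_table",
    "filter_segments",
    "filter_by_loq",
    "q3_normalize",
    "q3_percentile",
    "aggregate_case_level",
    "sc_preprocess",
]
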