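"""Core in-memory containers shared across the pipeline.

Everything is a thin, validated wrapper around :class:`pandas.DataFrame`
so that each stage can be inspected, sliced and written to TSV without
ceremony.  The containers encode the two structural facts the pipeline
relies on everywhere: a count matrix is *segments x probes* with the
negative-control probes flagged, and an expression matrix is
*samples x genes* with an explicit normalization tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Normalization states an ExpressionMatrix can be in.
NORM_TAGS = ("raw", "q3", "lognorm_sc", "log2")


@dataclass
class SegmentCountMatrix:
    """Raw integer counts (segments x probes) plus probe and segment annotation.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per segment, one column per probe.
    probes
        Indexed by probe id, with columns ``gene_symbol`` and
        ``is_negative_control``.  Gene-targeting probes map 1:1 to genes here;
        negative-control probes carry no biological signal and are only used
        to estimate the per-segment background (LOQ).
    meta
        Indexed by segment id; carries ``case_id``, ``segment_type``,
        ``compartment`` and the sequencing QC metrics.
    """

    counts: pd.DataFrame
    probes: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate segment ids in count matrix")
        if self.probes.index.duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        if not self.counts.columns.equals(self.probes.index):
            # allow any order but require the same probe universe
            missing = set(self.counts.columns) ^ set(self.probes.index)
            if missing:
                raise ValueError(f"probe annotation does not match counts: {sorted(missing)[:5]}")
            self.probes = self.probes.loc[self.counts.columns]
        extra = set(self.counts.index) - set(self.meta.index)
        if extra:
            raise ValueError(f"segments without metadata: {sorted(extra)[:5]}")
        self.meta = self.meta.loc[self.counts.index]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def negative_probes(self) -> pd.Index:
        return self.probes.index[self.probes["is_negative_control"].astype(bool)]

    @property
    def gene_probes(self) -> pd.Index:
        return self.probes.index[~self.probes["is_negative_control"].astype(bool)]

    def subset(self, segments=None, probes=None) -> "SegmentCountMatrix":
        counts = self.counts
        if segments is not None:
            counts = counts.loc[segments]
        if probes is not None:
            counts = counts[probes]
        return SegmentCountMatrix(
            counts=counts, probes=self.probes.loc[counts.columns], meta=self.meta.loc[counts.index]
        )

    def write(self, outdir: str | Path, prefix: str = "segments") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / f"{prefix}_counts.tsv", sep="\t")
        self.probes.to_csv(outdir / f"{prefix}_probes.tsv", sep="\t")
        self.meta.to_csv(outdir / f"{prefix}_meta.tsv", sep="\t")

    @classmethod
    def read(cls, counts_path, probes_path, meta_path) -> "SegmentCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        probes = pd.read_csv(probes_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts=counts, probes=probes, meta=meta)


@dataclass
class ExpressionMatrix:
    """Normalized expression values, samples x genes, with a provenance tag."""

    values: pd.DataFrame
    norm: str = "raw"

    def __post_init__(self) -> None:
        if self.norm not in NORM_TAGS:
            raise ValueError(f"unknown normalization tag {self.norm!r}; expected one of {NORM_TAGS}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def write(self, path: str | Path) -> None:
        # %.17g round-trips IEEE doubles exactly through text
        self.values.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read(cls, path, norm: str = "raw") -> "ExpressionMatrix":
        return cls(values=pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip"), norm=norm)


@dataclass
class SignatureDef:
    """A named gene list with a direction (up/down) and its derivation provenance."""

    name: str
    genes: list[str]
    direction: str = "up"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.genes) + "\n")

    @classmethod
    def read(cls, path, name: str | None = None, direction: str = "up") -> "SignatureDef":
        genes = [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]
        return cls(name=name or Path(path).stem, genes=genes, direction=direction)


@dataclass
class SurvivalCohort:
    """Per-sample follow-up: time (months), event indicator, optional covariates."""

    table: pd.DataFrame  # index sample_id; columns time, event, covariates...

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if self.table[["time", "event"]].isna().any().any():
            raise ValueError("missing time/event values")
        if (self.table["time"] <= 0).any():
            raise ValueError("non-positive survival times")
        if not self.table["event"].isin((0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "SurvivalCohort":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


__all__ = [
    "SegmentCountMatrix",
    "ExpressionMatrix",
    "SignatureDef",
    "SurvivalCohort",
    "NORM_TAGS",
]
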