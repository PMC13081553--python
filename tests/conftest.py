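import numpy as np
import pandas as pd
import pytest

from budsig import qc
from budsig.containers import SegmentCountMatrix
from budsig.simulate import SpatialSimConfig, generate_spatial


@pytest.fixture(scope="session")
def planted_spatial():
    """Spatial dataset with 28 genes overexpressed 2.5x in buds (cohort-sized)."""
    planted = {f"G{i + 1:03d}": 2.5 for i in range(28)}
    cfg = SpatialSimConfig(seed=11, planted_signature=planted)
    return cfg, generate_spatial(cfg)


@pytest.fixture(scope="session")
def case_matrices(planted_spatial):
    """Case-level Q3-normalized matrices derived from the planted dataset."""
    _, matrix = planted_spatial
    kept, _ = qc.filter_segments(matrix)
    filtered = qc.filter_by_loq(kept, qc.compute_loq_table(kept))
    norm = qc.q3_normalize(filtered)
    return qc.aggregate_case_level(norm, filtered.meta), filtered


def make_matrix(counts: np.ndarray, n_neg: int = 0, meta: pd.DataFrame | None = None):
    """Small SegmentCountMatrix from a raw array; last n_neg probes are negatives."""
    n_seg, n_probe = counts.shape
    segs = [f"S{i}" for i in range(n_seg)]
    probes = [f"P{i}" for i in range(n_probe)]
    if meta is None:
        meta = pd.DataFrame(
            {
                "case_id": [f"C{i}" for i in range(n_seg)],
                "segment_type": "bud",
                "compartment": "tumor",
                "raw_reads": 100_000,
                "stitched_frac": 0.95,
                "aligned_frac": 0.9,
                "saturation_frac": 0.8,
                "ntc_count": 50,
            },
            index=pd.Index(segs, name="segment_id"),
        )
    ann = pd.DataFrame(
        {
            "gene_symbol": probes,
            "is_negative_control": [False] * (n_probe - n_neg) + [True] * n_neg,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return SegmentCountMatrix(
        counts=pd.DataFrame(counts, index=segs, columns=probes), probes=ann, meta=meta
    )
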