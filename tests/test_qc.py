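"""Segment QC, LOQ, Q3 normalization and single-cell preprocessing."""

import numpy as np
import pandas as pd
import pytest

from budsig import qc
from budsig.containers import ExpressionMatrix

from conftest import make_matrix


class TestComputeLOQ:
    def test_zero_variance_clamps_at_two(self):
        rec = qc.compute_loq(np.array([2, 2, 2]))
        assert rec.neg_geo_sd == pytest.approx(1.0)
        assert rec.loq == 2.0

    @pytest.mark.parametrize("c", [3, 5, 17])
    def test_equal_counts_give_loq_equal_count(self, c):
        # zero geometric SD: the LOQ collapses onto the (pseudocounted) mean
        rec = qc.compute_loq(np.array([c, c, c, c]))
        assert rec.loq == pytest.approx(max(2, c))

    def test_matches_literal_formula(self):
        # independent re-implementation of geomean * geosd^2 on [1, 9]
        counts = np.array([1.0, 9.0])
        logs = np.log(counts)
        gmean = np.exp(np.mean(logs))
        gsd = np.exp(np.std(logs, ddof=1))
        rec = qc.compute_loq(counts)
        assert rec.neg_geo_mean == pytest.approx(gmean)
        assert rec.neg_geo_sd == pytest.approx(gsd)
        assert rec.loq == pytest.approx(max(2.0, gmean * gsd**2))

    def test_random_instances_match_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 40, size=rng.integers(2, 12)).astype(float)
            logs = np.log(np.where(counts == 0, 0.5, counts))
            expected = max(2.0, np.exp(logs.mean()) * np.exp(logs.std(ddof=1)) ** 2)
            assert qc.compute_loq(counts).loq == pytest.approx(expected)

    def test_requires_two_probes(self):
        with pytest.raises(ValueError, match="S7"):
            qc.compute_loq(np.array([3.0]), segment_id="S7")


class TestFilterSegments:
    def _matrix(self, **overrides):
        counts = np.full((1, 4), 10)
        m = make_matrix(counts)
        for k, v in overrides.items():
            m.meta.loc["S0", k] = v
        return m

    @pytest.mark.parametrize(
        "metric,value,reason",
        [
            ("raw_reads", 39_999, "min_reads"),
            ("stitched_frac", 0.79, "min_stitched"),
            ("aligned_frac", 0.69, "min_aligned"),
            ("saturation_frac", 0.49, "min_saturation"),
            ("ntc_count", 1_001, "max_ntc"),
        ],
    )
    def test_each_criterion_fails_below_threshold(self, metric, value, reason):
        kept, report = qc.filter_segments(self._matrix(**{metric: value}))
        assert kept.counts.shape[0] == 0
        assert report.loc["S0", "fail_reasons"] == reason

    def test_exact_boundary_passes(self):
        m = self._matrix(
            raw_reads=40_000, stitched_frac=0.80, aligned_frac=0.70,
            saturation_frac=0.50, ntc_count=1_000,
        )
        kept, report = qc.filter_segments(m)
        assert kept.counts.shape[0] == 1
        assert report.loc["S0", "pass"]

    def test_missing_metric_raises(self):
        m = self._matrix()
        m.meta.loc["S0", "ntc_count"] = np.nan
        with pytest.raises(ValueError, match="ntc_count"):
            qc.filter_segments(m)

    def test_raising_threshold_never_enlarges_kept_set(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(30, 5))
        m = make_matrix(counts)
        m.meta["raw_reads"] = rng.integers(10_000, 90_000, 30)
        base, _ = qc.filter_segments(m, qc.QCThresholds(min_reads=30_000))
        tighter, _ = qc.filter_segments(m, qc.QCThresholds(min_reads=60_000))
        assert set(tighter.counts.index) <= set(base.counts.index)


class TestFilterByLOQ:
    def test_zero_count_segment_dropped(self):
        counts = np.vstack([np.zeros(12), np.full(12, 50)]).astype(int)
        counts[:, -2:] = 3  # negative probes
        m = make_matrix(counts, n_neg=2)
        out = qc.filter_by_loq(m)
        assert list(out.counts.index) == ["S1"]

    def test_gene_at_exactly_ten_percent_kept(self):
        # 10 segments; gene detected (>= LOQ) in exactly 1 of 10 -> kept
        n_seg, n_gene = 10, 30
        counts = np.full((n_seg, n_gene + 2), 50)
        counts[:, -2:] = 3
        counts[1:, 0] = 0  # gene 0 detected only in segment 0
        m = make_matrix(counts, n_neg=2)
        out = qc.filter_by_loq(m)
        assert "P0" in out.counts.columns

    def test_background_genes_removed_matches_loop_recount(self):
        rng = np.random.default_rng(5)
        n_seg, n_gene, n_neg = 25, 100, 10
        counts = rng.poisson(60, size=(n_seg, n_gene + n_neg))
        counts[:, [4, 40, 77]] = rng.poisson(1.0, size=(n_seg, 3))  # background genes
        counts[:, -n_neg:] = rng.poisson(3.0, size=(n_seg, n_neg))
        m = make_matrix(counts, n_neg=n_neg)
        loq = qc.compute_loq_table(m)
        out = qc.filter_by_loq(m, loq)
        # independent loop-based recount of the two-stage filter
        keep_seg = []
        for s in m.counts.index:
            det = (m.counts.loc[s, m.gene_probes] >= loq.loc[s, "loq"]).mean()
            if det >= 0.05:
                keep_seg.append(s)
        keep_gene = []
        for g in m.gene_probes:
            det = np.mean([m.counts.loc[s, g] >= loq.loc[s, "loq"] for s in keep_seg])
            if det >= 0.10:
                keep_gene.append(g)
        assert list(out.counts.index) == keep_seg
        assert list(out.counts.columns) == keep_gene
        assert {"P4", "P40", "P77"}.isdisjoint(out.counts.columns)

    def test_negative_probes_excluded_from_output(self):
        counts = np.full((5, 8), 50)
        counts[:, -3:] = 3
        out = qc.filter_by_loq(make_matrix(counts, n_neg=3))
        assert not set(out.counts.columns) & {"P5", "P6", "P7"}


class TestQ3Normalize:
    def test_single_segment_identity(self):
        counts = np.array([[1, 5, 9, 20]])
        out = qc.q3_normalize(make_matrix(counts))
        np.testing.assert_allclose(out.values.to_numpy(), counts)

    def test_scaled_segments_become_identical(self):
        base = np.array([3.0, 10.0, 40.0, 7.0, 1.0])
        counts = np.vstack([base, 2 * base]).astype(int)
        out = qc.q3_normalize(make_matrix(counts))
        np.testing.assert_allclose(out.values.iloc[0], out.values.iloc[1])

    def test_post_normalization_q3_all_equal(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 500, size=(10, 50))
        out = qc.q3_normalize(make_matrix(counts))
        q3s = np.percentile(out.values.to_numpy(), 75, axis=1)
        assert np.ptp(q3s) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 300, size=(8, 40))
        once = qc.q3_normalize(make_matrix(counts))
        again = qc.q3_normalize(once.values)  # re-normalize the normalized values
        np.testing.assert_allclose(again.values.to_numpy(), once.values.to_numpy(), rtol=1e-12)

    def test_zero_q3_segment_raises(self):
        counts = np.zeros((2, 4), dtype=int)
        counts[1] = 10
        with pytest.raises(ValueError, match="zero upper quartile"):
            qc.q3_normalize(make_matrix(counts))


class TestAggregateCaseLevel:
    def _norm(self, values, meta):
        return ExpressionMatrix(values=values, norm="q3")

    def test_single_segment_groups_identity_and_mean(self):
        vals = pd.DataFrame(
            [[2.0, 4.0], [6.0, 12.0], [10.0, 20.0]],
            index=["S0", "S1", "S2"], columns=["g1", "g2"],
        )
        meta = pd.DataFrame(
            {
                "case_id": ["C1", "C1", "C2"],
                "segment_type": ["bud", "bud", "bud"],
                "compartment": ["tumor"] * 3,
            },
            index=vals.index,
        )
        out = qc.aggregate_case_level(self._norm(vals, meta), meta)
        mat = out[("bud", "tumor")]
        np.testing.assert_allclose(mat.loc["C1"], [4.0, 8.0])  # mean of v and 3v = 2v
        np.testing.assert_allclose(mat.loc["C2"], [10.0, 20.0])  # identity

    def test_randomized_grouping_matches_loop_means(self):
        rng = np.random.default_rng(9)
        n = 40
        vals = pd.DataFrame(
            rng.uniform(0, 100, size=(n, 6)),
            index=[f"S{i}" for i in range(n)],
            columns=[f"g{j}" for j in range(6)],
        )
        meta = pd.DataFrame(
            {
                "case_id": rng.choice(["C1", "C2", "C3"], n),
                "segment_type": rng.choice(["bud", "bulk_budding"], n),
                "compartment": rng.choice(["tumor", "stroma"], n),
            },
            index=vals.index,
        )
        out = qc.aggregate_case_level(self._norm(vals, meta), meta)
        for (st, comp), mat in out.items():
            for case in mat.index:
                segs = meta.index[
                    (meta["case_id"] == case)
                    & (meta["segment_type"] == st)
                    & (meta["compartment"] == comp)
                ]
                np.testing.assert_allclose(mat.loc[case], vals.loc[segs].mean(axis=0))


class TestSCPreprocess:
    def _umi(self, counts, genes):
        return pd.DataFrame(counts, index=[f"c{i}" for i in range(len(counts))], columns=genes)

    def test_cell_with_199_detected_genes_excluded(self):
        genes = [f"g{i}" for i in range(250)]
        a = np.zeros(250, dtype=int); a[:199] = 1
        b = np.zeros(250, dtype=int); b[:200] = 1
        norm, rep = qc.sc_preprocess(self._umi(np.vstack([a, b]), genes))
        assert list(norm.samples) == ["c1"]
        assert rep.n_low_genes == 1

    def test_single_gene_closed_form(self):
        # one cell with its whole 10,000-count library in one gene
        genes = [f"g{i}" for i in range(300)]
        a = np.ones(300, dtype=int)
        a[0] = 10_000 - 299  # total exactly 10,000
        norm, _ = qc.sc_preprocess(self._umi(np.vstack([a, np.ones(300, int) * 2]), genes))
        v = norm.values.loc["c0", "g0"]
        assert v == pytest.approx(np.log(1 + (10_000 - 299) / 10_000 * 10_000))

    def test_filters_match_loop_recount(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(280)] + ["MT-1", "MT-2"]
        counts = rng.poisson(1.5, size=(120, 282))
        counts[:5] = 0  # empty cells
        counts[6, -2:] = 500  # high-mito cell
        umi = self._umi(counts, genes)
        norm, rep = qc.sc_preprocess(umi, min_genes=100)
        detected = (counts > 0).sum(axis=1)
        totals = counts.sum(axis=1)
        mito = counts[:, -2:].sum(axis=1) / np.maximum(totals, 1)
        keep = (detected >= 100) & (detected <= 8000) & (np.where(totals > 0, mito, 1.0) <= 0.10)
        assert rep.n_cells_out == int(keep.sum())
        expressed = (counts[keep] > 0).mean(axis=0)
        assert rep.n_genes_out == int((expressed >= 0.001).sum())

    def test_no_mito_genes_warns_and_skips(self):
        genes = [f"g{i}" for i in range(250)]
        counts = np.ones((60, 250), dtype=int)
        with pytest.warns(UserWarning, match="mito"):
            _, rep = qc.sc_preprocess(self._umi(counts, genes), min_genes=10)
        assert not rep.mito_filter_applied
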