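"""Slope model, positional correlation, matched subsampling, GSEA, region compare."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metachrom import coverage as cov
from metachrom import position_stats as ps
from metachrom.annotations import Anchor, ExonRecord
from metachrom.profiles import ProfileMatrix


def make_matrix(values, offsets=None):
    values = np.asarray(values, dtype=float)
    offsets = np.arange(values.shape[1]) if offsets is None else np.asarray(offsets)
    anchors = [Anchor("intron_exon", "c", 0, "+", f"g{i:03d}", 1)
               for i in range(values.shape[0])]
    return ProfileMatrix(values, offsets, anchors)


class TestSlopeProfile:
    def test_analytically_forced_slope_recovered_exactly(self):
        """Ratio built as 0.5 + 0.3*log2(TPM+1) gives slope 0.3, zero residual."""
        tpm = np.array([0.0, 1.0, 3.0, 7.0, 15.0, 31.0])
        eps = ps.DEFAULT_PSEUDOCOUNT
        target = 0.5 + 0.3 * np.log2(tpm + 1)
        chip = make_matrix(np.tile((target - eps)[:, None], (1, 60)))
        inp = make_matrix(np.full((6, 60), 1.0 - eps))
        res = ps.slope_profile(chip, inp, tpm)
        np.testing.assert_allclose(res["slope"], 0.3, atol=1e-12)
        np.testing.assert_allclose(res["stderr"], 0.0, atol=1e-6)

    def test_expression_independent_ratio_gives_zero_slope(self):
        tpm = np.array([1.0, 2.0, 4.0, 8.0])
        chip = make_matrix(np.full((4, 40), 1.0))
        inp = make_matrix(np.full((4, 40), 1.0))
        res = ps.slope_profile(chip, inp, tpm)
        np.testing.assert_allclose(res["slope"], 0.0, atol=1e-12)

    def test_matches_statsmodels_ols_oracle(self):
        """Per-offset fit agrees with an independent OLS on the same ratios."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        tpm = rng.lognormal(2, 1, 50)
        chip = make_matrix(rng.gamma(5, 1, size=(50, 30)))
        inp = make_matrix(rng.gamma(5, 1, size=(50, 30)))
        res = ps.slope_profile(chip, inp, tpm, window=20)
        cw = ps.sliding_window_means(chip.values, 20)
        iw = ps.sliding_window_means(inp.values, 20)
        r = (cw + 0.1) / (iw + 0.1)
        x = sm.add_constant(np.log2(tpm + 1))
        for j in (0, 13, 29):
            fit = sm.OLS(r[:, j], x).fit()
            assert res["slope"][j] == pytest.approx(fit.params[1], rel=1e-10)
            assert res["stderr"][j] == pytest.approx(fit.bse[1], rel=1e-10)

    def test_expression_scaling_equivariance(self):
        """Multiplying all TPM by a constant shifts log-expression, not the slope."""
        rng = np.random.default_rng(3)
        # the shift-absorption argument is exact for pure log; with the
        # log2(TPM+1) transform it holds in the TPM >> 1 regime
        tpm = rng.lognormal(5, 0.5, 30) * 100
        chip = make_matrix(rng.random((30, 25)))
        inp = make_matrix(rng.random((30, 25)) + 0.5)
        a = ps.slope_profile(chip, inp, tpm)
        b = ps.slope_profile(chip, inp, tpm * 8)
        np.testing.assert_allclose(a["slope"], b["slope"], rtol=1e-3)

    def test_too_few_anchors_rejected(self):
        tpm = np.array([1.0, 2.0])
        m = make_matrix(np.ones((2, 10)))
        with pytest.raises(ValueError, match="3 anchors"):
            ps.slope_profile(m, m, tpm)

    def test_constant_expression_rejected(self):
        tpm = np.full(5, 2.0)
        m = make_matrix(np.ones((5, 10)))
        with pytest.raises(ValueError, match="variance"):
            ps.slope_profile(m, m, tpm)

    def test_window_truncated_at_matrix_edges(self):
        values = np.tile(np.arange(30.0), (5, 1))
        w = ps.sliding_window_means(values, 20)
        # column 0 window is [0, 10): mean 4.5, not padded
        assert w[0, 0] == pytest.approx(np.mean(np.arange(10)))
        assert w[0, 15] == pytest.approx(np.mean(np.arange(5, 25)))


class TestPositionalCorrelation:
    def test_identical_tracks_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        a = make_matrix(rng.random((100, 150)), offsets=np.arange(-50, 100))
        res = ps.positional_correlation(a, a, window=50)
        np.testing.assert_allclose(res["r"], 1.0)
        assert list(res["offset"]) == [-25, 25, 75]

    def test_independent_tracks_near_zero(self):
        rng = np.random.default_rng(8)
        a = make_matrix(rng.lognormal(1, 0.5, (500, 400)))
        b = make_matrix(rng.lognormal(1, 0.5, (500, 400)))
        res = ps.positional_correlation(a, b, window=50)
        assert (res["r"].abs() < 0.1).mean() >= 0.95

    def test_constant_window_is_missing(self):
        a = make_matrix(np.ones((10, 50)))
        b = make_matrix(np.random.default_rng(0).random((10, 50)))
        res = ps.positional_correlation(a, b, window=50)
        assert np.isnan(res["r"]).all()

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        a = make_matrix(rng.lognormal(0, 1, (80, 100)))
        b = make_matrix(rng.lognormal(0, 1, (80, 100)))
        ab = ps.positional_correlation(a, b, window=50)
        ba = ps.positional_correlation(b, a, window=50)
        np.testing.assert_allclose(ab["r"], ba["r"])
        a3 = make_matrix(a.values * 3.0)
        # a positive rescale is an additive shift after log: r barely moves
        # (exactly invariant in the zero-pseudocount limit)
        scaled = ps.positional_correlation(a3, b, window=50, pseudocount=1e-9)
        base = ps.positional_correlation(a, b, window=50, pseudocount=1e-9)
        np.testing.assert_allclose(scaled["r"], base["r"], atol=1e-6)


def exon_records(tpms, cls="constitutive"):
    return [
        ExonRecord(f"g{i:04d}", "c", 100 * i, 100 * i + 50, "+", cls,
                   inclusion=0.5 if cls == "cassette" else None, expression=t)
        for i, t in enumerate(tpms)
    ]


class TestMatchedSubsample:
    def test_identical_distributions_match_bin_counts(self):
        vals = np.linspace(1, 100, 60)
        target = exon_records(vals, "cassette")
        pool = exon_records(np.concatenate([vals, vals]))
        subset = ps.matched_subsample(pool, target, seed=0)
        assert len(subset) == len(target)

        def bin_counts(values):
            lv = np.log2(np.asarray(values) + 1)
            inner = np.quantile(np.log2(vals + 1), np.linspace(0, 1, 21))[1:-1]
            return np.bincount(np.searchsorted(inner, lv, side="left"), minlength=20)

        np.testing.assert_array_equal(
            bin_counts([r.expression for r in subset]), bin_counts(vals)
        )

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        target = exon_records(rng.lognormal(1, 1, 100), "cassette")
        pool = exon_records(rng.lognormal(2, 1, 800))
        s1 = ps.matched_subsample(pool, target, seed=5)
        s2 = ps.matched_subsample(pool, target, seed=5)
        s3 = ps.matched_subsample(pool, target, seed=6)
        assert s1 == s2
        assert s1 != s3

    def test_subset_is_duplicate_free_and_from_pool(self):
        rng = np.random.default_rng(2)
        target = exon_records(rng.lognormal(1, 1, 50), "cassette")
        pool = exon_records(rng.lognormal(1.5, 1, 400))
        subset = ps.matched_subsample(pool, target, seed=0)
        assert len(subset) == len(set(id(r) for r in subset)) == 50
        pool_ids = {id(r) for r in pool}
        assert all(id(r) in pool_ids for r in subset)

    def test_pool_smaller_than_target_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            ps.matched_subsample(exon_records([1, 2]), exon_records([1, 2, 3], "cassette"))

    def test_skewed_pool_is_corrected(self):
        """KS distance between subset and target log-expression is small."""
        rng = np.random.default_rng(7)
        target = exon_records(rng.lognormal(1.0, 1.0, 500), "cassette")
        pool = exon_records(rng.lognormal(2.5, 1.2, 4000))
        subset = ps.matched_subsample(pool, target, seed=0)
        ks_before = stats.ks_2samp(
            np.log2([r.expression + 1 for r in pool]),
            np.log2([r.expression + 1 for r in target]),
        ).statistic
        ks_after = stats.ks_2samp(
            np.log2([r.expression + 1 for r in subset]),
            np.log2([r.expression + 1 for r in target]),
        ).statistic
        assert ks_after < 0.1 < ks_before


class TestWindowMeanCompare:
    def _track_with_region_means(self, means_a, means_b):
        n = len(means_a) + len(means_b)
        arr = np.zeros(n * 20)
        regions_a, regions_b = [], []
        for i, v in enumerate(means_a):
            arr[i * 20: i * 20 + 10] = v
            regions_a.append(("c", i * 20, i * 20 + 10))
        off = len(means_a)
        for i, v in enumerate(means_b):
            arr[(off + i) * 20: (off + i) * 20 + 10] = v
            regions_b.append(("c", (off + i) * 20, (off + i) * 20 + 10))
        return cov.CoverageTrack({"c": arr}, 1, normalized=True), regions_a, regions_b

    def test_identical_sets_no_difference(self):
        track, ra, _ = self._track_with_region_means([1, 2, 3], [])
        mean_a, mean_b, p = ps.window_mean_compare(track, ra, ra)
        assert mean_a == mean_b
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        track, ra, rb = self._track_with_region_means(
            rng.normal(20, 2, 200), rng.normal(13, 2, 200)
        )
        mean_a, mean_b, p = ps.window_mean_compare(track, ra, rb)
        assert mean_a > mean_b
        assert p < 1e-3

    def test_single_region_rejected(self):
        track, ra, rb = self._track_with_region_means([5.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="2 usable regions"):
            ps.window_mean_compare(track, ra, rb)

    def test_wilcoxon_alternative_available(self):
        rng = np.random.default_rng(1)
        track, ra, rb = self._track_with_region_means(
            rng.normal(20, 2, 50), rng.normal(13, 2, 50)
        )
        _, _, p = ps.window_mean_compare(track, ra, rb, test="wilcoxon")
        assert p < 1e-3


class TestPositionalGsea:
    def _matrix(self, scores_by_window, n_genes=60):
        """Matrix whose per-window means equal the given score columns."""
        n_windows = scores_by_window.shape[1]
        values = np.repeat(scores_by_window, 50, axis=1)
        return make_matrix(values, offsets=np.arange(-50 * n_windows // 2,
                                                     50 * n_windows - 50 * n_windows // 2))

    def test_top_ranked_set_achieves_minimal_p(self):
        rng = np.random.default_rng(0)
        scores = rng.random((60, 1))
        m = self._matrix(scores)
        top = [m.anchors[i].gene_id for i in np.argsort(scores[:, 0])[-10:]]
        res = ps.positional_gsea(m, {"top": top}, window=50, step=50)
        n_in, n_out = 10, 50
        minimal = stats.mannwhitneyu(
            np.arange(n_out, n_out + n_in), np.arange(n_out), alternative="greater"
        ).pvalue
        assert res["p"].iloc[0] == pytest.approx(minimal)

    def test_random_set_p_values_are_uniform(self):
        """Under the null, p over 200 independent windows is ~U(0,1)."""
        rng = np.random.default_rng(12)
        scores = rng.random((60, 200))
        m = self._matrix(scores)
        members = [f"g{i:03d}" for i in rng.choice(60, 15, replace=False)]
        res = ps.positional_gsea(m, {"rand": members}, window=50, step=50)
        assert len(res) == 200
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01
        assert (res["q"] >= res["p"] - 1e-15).all()

    def test_small_set_skipped_with_warning(self):
        m = self._matrix(np.random.default_rng(0).random((60, 2)))
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError, match="enough joined"):
                ps.positional_gsea(m, {"tiny": ["g000", "g001"]})

    def test_empty_gene_sets_rejected(self):
        m = self._matrix(np.random.default_rng(0).random((60, 2)))
        with pytest.raises(ValueError, match="gene set"):
            ps.positional_gsea(m, {})


class TestReadGeneSets:
    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text("termA\tg1\ntermA\tg2\ntermB\tg3\n")
        sets = ps.read_gene_sets(p)
        assert sets == {"termA": ["g1", "g2"], "termB": ["g3"]}

    def test_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("termA\tdesc\tg1\tg2\ntermB\tdesc\tg3\tg4\tg5\n")
        sets = ps.read_gene_sets(p)
        assert sets["termA"] == ["g1", "g2"] and len(sets["termB"]) == 3

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="no gene sets"):
            ps.read_gene_sets(p)
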