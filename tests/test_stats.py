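"""Statistical primitives and sex-stratified comparisons.

scipy.stats and statsmodels serve as independent oracles for the
hand-implemented Wilcoxon / KS / BH primitives.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st_h
from statsmodels.stats.multitest import multipletests

from cytomodules import (benjamini_hochberg, compare_correlation_distributions,
                         compare_module_scores, correlation_matrix,
                         ks_two_sample, stratified_correlations,
                         wilcoxon_rank_sum)
from cytomodules.modules import ModuleAssignment
from cytomodules.stats import bootstrap_correlation_difference


class TestBenjaminiHochberg:
    def test_worked_triple(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert benjamini_hochberg([0.2])[0] == 0.2
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(st_h.lists(st_h.floats(min_value=0.0, max_value=1.0), min_size=1,
                      max_size=30))
    def test_matches_statsmodels_and_dominates_raw(self, pvals):
        ours = benjamini_hochberg(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-15).all()


class TestWilcoxon:
    def test_identical_samples_exact_p_one(self):
        r = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0
        assert r.note == "exact"

    def test_two_vs_two_enumeration(self):
        # 6 rank splits; only {1,2} gives W <= 3 -> one-tail 1/6, two-sided 1/3
        r = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert r.p_value == pytest.approx(1.0 / 3.0)

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            r = wilcoxon_rank_sum([2.0] * 4, [2.0] * 6)
        assert r.p_value == 1.0

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 60)
        y = rng.normal(4.0, 1.0, 60)
        assert wilcoxon_rank_sum(x, y).p_value < 1e-6

    def test_group_relabel_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=25), rng.normal(0.5, 1.0, 30)
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            wilcoxon_rank_sum(y, x).p_value, rel=1e-9)

    @pytest.mark.parametrize("n1,n2,seed", [(4, 5, 0), (7, 7, 1), (10, 9, 2)])
    def test_exact_path_matches_scipy(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n1), rng.normal(size=n2)  # ties a.s. absent
        ours = wilcoxon_rank_sum(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.normal(size=40), 1)     # heavy ties
        y = np.round(rng.normal(0.3, 1.0, 50), 1)
        ours = wilcoxon_rank_sum(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        assert ours.note == "normal approximation"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        assert ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).statistic == 0.0

    def test_disjoint_supports(self):
        r = ks_two_sample([1.0, 2.0], [10.0, 11.0])
        assert r.statistic == 1.0

    def test_interleaved_quartets(self):
        # hand ECDF: max gap 0.25 just after each x point
        r = ks_two_sample([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 4.5])
        assert r.statistic == pytest.approx(0.25)

    def test_matches_asymptotic_series_and_scipy_statistic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=45)
        y = rng.normal(0.4, 1.2, 40)
        ours = ks_two_sample(x, y)
        ref = scipy.stats.ks_2samp(x, y, method="asymp")
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        # independent oracle: limiting Kolmogorov tail 2*sum (-1)^(k-1) e^(-2k^2 z^2)
        z = np.sqrt(45 * 40 / 85) * ours.statistic
        series = 2 * sum((-1) ** (k - 1) * np.exp(-2 * k * k * z * z)
                         for k in range(1, 101))
        assert ours.p_value == pytest.approx(series, rel=1e-8)
        # same scale as scipy's finite-n asymptotic variant
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.2)


def _two_group_fm(n_per_group=30, n_feat=6, f_factor=1.0, m_factor=1.0,
                  seed=0):
    """Feature matrix with a sex-specific shared-factor strength."""
    rng = np.random.default_rng(seed)
    rows, donors, sexes = [], [], []
    for g, (label, w) in enumerate((("F", f_factor), ("M", m_factor))):
        for i in range(n_per_group):
            factor = rng.normal()
            rows.append(w * factor + 0.3 * rng.normal(size=n_feat))
            donors.append(f"{label}{i}")
            sexes.append(label)
    data = pd.DataFrame(rows, index=donors,
                        columns=[f"f{i}" for i in range(n_feat)])
    metadata = pd.DataFrame({"sex": sexes}, index=donors)
    return data, metadata


class TestStratified:
    def test_identical_groups_identical_matrices(self):
        data, metadata = _two_group_fm()
        meta_same = metadata.copy()
        meta_same["sex"] = "F"
        meta_same.iloc[: len(meta_same) // 2,
                       meta_same.columns.get_loc("sex")] = "M"
        # use the same donors for both labels by duplicating the frame
        dup = pd.concat([data, data])
        dup.index = [f"a{i}" for i in range(len(data))] + \
                    [f"b{i}" for i in range(len(data))]
        md = pd.DataFrame({"sex": ["F"] * len(data) + ["M"] * len(data)},
                          index=dup.index)
        strat = stratified_correlations(dup, md)
        np.testing.assert_allclose(strat.groups["F"].R, strat.groups["M"].R)

    def test_group_size_floor(self):
        data, metadata = _two_group_fm(n_per_group=30)
        metadata.iloc[:58, 0] = "F"              # leaves 2 M donors
        with pytest.raises(ValueError, match="below the floor"):
            stratified_correlations(data, metadata)

    def test_sampling_noise_shrinks_with_n(self):
        gaps = {}
        for n in (40, 400):
            data, metadata = _two_group_fm(n_per_group=n, seed=5)
            strat = stratified_correlations(data, metadata)
            diff = (strat.groups["F"].R - strat.groups["M"].R).abs()
            gaps[n] = np.nanmean(diff.to_numpy())
        assert gaps[400] < gaps[40]

    def test_planted_coordination_detected(self):
        """Perfectly coordinated F block vs uncorrelated M features."""
        data, metadata = _two_group_fm(f_factor=2.0, m_factor=0.0, seed=6)
        strat = stratified_correlations(data, metadata)
        asg = ModuleAssignment(
            pd.Series("1", index=data.columns, dtype=object), 2, 0.5)
        glob, per = compare_correlation_distributions(strat, asg)
        assert glob.summary_x > glob.summary_y          # F median R higher
        assert per[0].p_value < 0.05
        assert per[0].direction == "x_higher"

    def test_bootstrap_alternative_rejects_planted_difference(self):
        data, metadata = _two_group_fm(f_factor=2.0, m_factor=0.0, seed=8)
        r = bootstrap_correlation_difference(data, metadata, n_boot=100,
                                             seed=0)
        assert r.statistic > 0.3
        assert r.p_value <= 0.02


class TestModuleScoreComparison:
    def test_constant_scores_p_one(self):
        scores = pd.DataFrame({"1": [1.0] * 12}, index=[f"d{i}" for i in
                                                        range(12)])
        metadata = pd.DataFrame({"sex": ["F"] * 6 + ["M"] * 6},
                                index=scores.index)
        res = compare_module_scores(scores, metadata)
        assert res[0].statistic == 0.0
        assert res[0].p_value == 1.0

    def test_planted_shift_flagged_with_direction(self):
        rng = np.random.default_rng(9)
        n = 40
        scores = pd.DataFrame({
            "1": np.r_[rng.normal(1.5, 1.0, n), rng.normal(0.0, 1.0, n)],
            "2": rng.normal(size=2 * n),
        }, index=[f"d{i}" for i in range(2 * n)])
        metadata = pd.DataFrame({"sex": ["M"] * n + ["F"] * n},
                                index=scores.index)
        res = {t.name: t for t in compare_module_scores(scores, metadata)}
        assert res["module 1"].adjusted_p < 0.05
        assert res["module 1"].direction == "M_higher"
        assert res["module 2"].adjusted_p > 0.05

    def test_adjusted_p_dominates_raw(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(rng.normal(size=(30, 5)),
                              columns=list("abcde"),
                              index=[f"d{i}" for i in range(30)])
        metadata = pd.DataFrame({"sex": ["F"] * 15 + ["M"] * 15},
                                index=scores.index)
        for t in compare_module_scores(scores, metadata):
            assert t.adjusted_p >= t.p_value - 1e-15
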