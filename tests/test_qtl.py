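"""Interval mapping: normalisation, scan, thresholds, peaks, effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from epihybrid import qtl
from epihybrid._rng import substream
from epihybrid.simulate import MarkerMapSpec, haldane, simulate_epiril_pedigree, simulate_marker_map

from _oracles import marker_regression_lod


@pytest.fixture(scope="module")
def grid(epimap):
    return qtl.genotype_probabilities(epimap, step_cm=2.0)


class TestOrqNormalize:
    def test_three_values_symmetric(self):
        out = qtl.orq_normalize([1.0, 2.0, 3.0])
        assert out[1] == pytest.approx(0.0)
        assert out[0] == pytest.approx(-out[2])

    def test_rank_invariance_under_monotone_transform(self):
        x = np.random.default_rng(0).gamma(2, 1, 100)
        np.testing.assert_allclose(
            qtl.orq_normalize(x), qtl.orq_normalize(np.exp(x)), atol=1e-12
        )

    def test_ties_map_to_equal_outputs(self):
        out = qtl.orq_normalize([1.0, 2.0, 2.0, 3.0])
        assert out[1] == out[2]

    def test_large_sample_close_to_normal(self):
        from scipy import stats

        x = np.random.default_rng(1).exponential(size=2000)
        d, _ = stats.kstest(qtl.orq_normalize(x), "norm")
        assert d < 0.02

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            qtl.orq_normalize([1.0, 1.0, 1.0])


class TestGenotypeProbabilities:
    def test_marker_positions_reproduce_genotypes(self, epimap, grid):
        codes = epimap.codes()
        markers = epimap.markers
        at_markers = grid.positions[grid.positions["is_marker"]]
        for idx, row in at_markers.iloc[:: max(1, len(at_markers) // 20)].iterrows():
            j = markers[
                (markers["chrom"] == row["chrom"]) & (markers["cM"] == row["cM"])
            ].index[0]
            np.testing.assert_array_equal(
                grid.prob_uu[:, grid.positions.index.get_loc(idx)], codes[:, j]
            )

    def test_midpoint_between_opposite_flanks_is_half(self):
        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(20.0,), spacing_cm=20.0)
        m = simulate_epiril_pedigree(simulate_marker_map(spec), 200, seed=3)
        grid = qtl.genotype_probabilities(m, step_cm=10.0)
        mid = grid.positions["cM"] == 10.0
        codes = m.codes()
        opposite = codes[:, 0] != codes[:, 1]
        probs = grid.prob_uu[:, mid.to_numpy().nonzero()[0][0]]
        np.testing.assert_allclose(probs[opposite], 0.5)

    def test_flanking_uu_uu_closed_form(self):
        """Midpoint of a 10-cM UU/UU bracket: two-point closed form
        (1-r)^2 / ((1-r)^2 + r^2) with r = Haldane(5 cM) ~ 0.9976."""
        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(10.0,), spacing_cm=10.0)
        m = simulate_epiril_pedigree(simulate_marker_map(spec), 400, seed=4)
        grid = qtl.genotype_probabilities(m, step_cm=5.0)
        codes = m.codes()
        both_uu = (codes[:, 0] == 1) & (codes[:, 1] == 1)
        mid_col = grid.positions["cM"].eq(5.0).to_numpy().nonzero()[0][0]
        r = float(haldane(5.0))
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert expected == pytest.approx(0.9976, abs=2e-4)
        np.testing.assert_allclose(grid.prob_uu[both_uu, mid_col], expected)

    def test_bad_step_rejected(self, epimap):
        with pytest.raises(ValueError):
            qtl.genotype_probabilities(epimap, step_cm=0.0)


class TestHkScan:
    def test_marker_lod_matches_bruteforce_regression(self, epimap, grid):
        rng = substream(21, "trait")
        codes = epimap.codes()
        y = codes[:, 40] + rng.normal(0, 1, codes.shape[0])
        scan = qtl.hk_scan(grid, y)
        oracle = marker_regression_lod(codes, y)
        is_marker = grid.positions["is_marker"].to_numpy()
        np.testing.assert_allclose(
            scan.grid.loc[is_marker, "lod"].to_numpy(), oracle, atol=1e-9
        )

    def test_null_trait_low_lod(self, grid):
        y = substream(22, "null").normal(size=len(grid.line_ids))
        scan = qtl.hk_scan(grid, y)
        assert scan.grid["lod"].max() < 5

    def test_perfect_fit_capped_at_sentinel(self, epimap, grid):
        y = epimap.codes()[:, 10]
        scan = qtl.hk_scan(grid, y)
        assert scan.grid["lod"].max() == pytest.approx(qtl.LOD_MAX)

    def test_zero_variance_trait_rejected(self, grid):
        with pytest.raises(ValueError):
            qtl.hk_scan(grid, np.ones(len(grid.line_ids)))

    def test_too_few_lines_rejected(self, grid):
        y = np.full(len(grid.line_ids), np.nan)
        y[:5] = [1, 2, 3, 4, 5]
        with pytest.raises(ValueError):
            qtl.hk_scan(grid, y)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, grid):
        y = substream(23, "a").normal(size=len(grid.line_ids))
        thr_min = qtl.permutation_threshold(grid, y, n_perm=100, alpha=1.0, seed=1)
        thr_95 = qtl.permutation_threshold(grid, y, n_perm=100, alpha=0.05, seed=1)
        assert thr_min < thr_95

    def test_deterministic_given_seed(self, grid):
        y = substream(24, "b").normal(size=len(grid.line_ids))
        t1 = qtl.permutation_threshold(grid, y, n_perm=200, seed=7)
        t2 = qtl.permutation_threshold(grid, y, n_perm=200, seed=7)
        assert t1 == t2

    def test_stable_under_more_permutations(self, grid):
        y = substream(25, "c").normal(size=len(grid.line_ids))
        t1 = qtl.permutation_threshold(grid, y, n_perm=1000, seed=8)
        t2 = qtl.permutation_threshold(grid, y, n_perm=2000, seed=9)
        assert abs(t1 - t2) < 0.4

    def test_minimum_permutations_enforced(self, grid):
        with pytest.raises(ValueError):
            qtl.permutation_threshold(
                grid, np.zeros(len(grid.line_ids)), n_perm=50
            )


def _toy_scan(lods_by_chrom):
    rows = []
    for chrom, lods in lods_by_chrom.items():
        for i, lod in enumerate(lods):
            rows.append(
                {"chrom": chrom, "cM": 2.0 * i, "bp": 2e5 * 2 * i,
                 "is_marker": True, "lod": lod}
            )
    return qtl.QTLScanResult("t", pd.DataFrame(rows), np.nan, pd.DataFrame())


class TestPeaksAndCi:
    def test_flat_curve_no_peaks(self):
        scan = _toy_scan({"c1": [0.5, 0.4, 0.6]})
        assert qtl.peaks_and_ci(scan, threshold=3.0).empty

    def test_triangular_peak_ci_spans_drop(self):
        scan = _toy_scan({"c1": [0, 2, 4, 6, 4, 2, 0]})
        peaks = qtl.peaks_and_ci(scan, threshold=3.0, drop=2.0)
        assert len(peaks) == 1
        p = peaks.iloc[0]
        assert p["peak_cM"] == 6.0  # index 3
        assert (p["ci_lo_cM"], p["ci_hi_cM"]) == (4.0, 8.0)  # LOD >= 4 region

    def test_one_peak_per_chromosome(self):
        scan = _toy_scan({"c1": [0, 5, 0], "c2": [0, 0, 6]})
        peaks = qtl.peaks_and_ci(scan, threshold=3.0)
        assert list(peaks["chrom"]) == ["c1", "c2"]

    def test_leftmost_wins_lod_tie(self):
        scan = _toy_scan({"c1": [0, 5, 5, 0]})
        peaks = qtl.peaks_and_ci(scan, threshold=3.0)
        assert peaks.iloc[0]["peak_cM"] == 2.0


class TestCisTrans:
    peak = pd.Series(
        {"chrom": "c1", "ci_lo_bp": 1000.0, "ci_hi_bp": 5000.0}
    )

    def test_other_chromosome_is_trans(self):
        assert qtl.cis_trans_call(self.peak, "c2", 2000, 2200) == "trans"

    def test_contained_target_is_cis(self):
        assert qtl.cis_trans_call(self.peak, "c1", 2000, 2200) == "cis"

    def test_straddling_target_is_trans(self):
        assert qtl.cis_trans_call(self.peak, "c1", 4900, 5100) == "trans"


class TestQtlEffect:
    def test_flat_trait_zero_r2(self):
        r2, sign, slope = qtl.qtl_effect([1, 1, 1, 1], [0, 0, 1, 1])
        assert r2 == 0 and sign == 0

    def test_deterministic_effect(self):
        r2, sign, slope = qtl.qtl_effect([0, 0, 2, 2], [0, 0, 1, 1])
        assert r2 == pytest.approx(1.0) and sign == 1 and slope == pytest.approx(2.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            qtl.qtl_effect([1, 2, 3], [1, 1, 1])


class TestByAdjust:
    def test_single_p_unchanged(self):
        assert qtl.by_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            qtl.by_adjust([0.01, 0.02, 0.03]), [0.055, 0.055, 0.055]
        )

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_dominates_raw(self, ps):
        ours = qtl.by_adjust(ps)
        ref = multipletests(ps, method="fdr_by")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert (ours >= np.asarray(ps) - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qtl.by_adjust([1.5])


class TestRunNadQtl:
    def test_planted_distal_qtl_recovered_trans(self, epimap, regions, trio_states):
        from epihybrid.regions import divergence_matrix

        trios, planted = trio_states
        q = planted[0]
        marker = epimap.marker_row(q.marker_id)
        distal = [
            r for r in q.target_region_ids
            if regions.set_index("region_id").loc[r, "chrom"] != marker["chrom"]
        ]
        div = divergence_matrix(trios.mscol, trios.epiril, trios.hybrid)
        traits = div.loc[distal[:2]]
        targets = regions.set_index("region_id")[["chrom", "start", "end"]]
        table = qtl.run_nad_qtl(
            epimap, traits, targets=targets, n_perm=200, seed=5
        )
        assert not table.empty
        for rid in traits.index:
            hits = table[table["trait_id"] == rid]
            assert (hits["chrom"] == marker["chrom"]).any()
            best = hits.loc[hits["lod"].idxmax()]
            assert best["cis_trans"] == "trans"
            assert abs(best["peak_cM"] - marker["cM"]) <= 15
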