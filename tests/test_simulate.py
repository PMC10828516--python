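"""Synthetic-data generator: pedigree, methylomes, phenotypes, counts."""

import numpy as np
import pandas as pd
import pytest

from epihybrid.simulate import (
    MarkerMapSpec,
    PlantedQtl,
    simulate_counts,
    simulate_epiril_pedigree,
    simulate_marker_map,
    simulate_phenotypes,
    simulate_regions,
    simulate_trio_methylomes,
    state_multipliers,
)

from _oracles import two_locus_summary

ONE_LOCUS = MarkerMapSpec(chrom_names=("chr1",), lengths_cm=(0.0,))
_NO_COVARIATES = {
    "experiment": [0.0],
    "block": [0.0],
    "germination_date": [0.0],
}


class TestMarkerMap:
    def test_default_layout(self, skeleton):
        assert len(skeleton.markers) == 144
        assert skeleton.markers["chrom"].nunique() == 5

    def test_bp_monotone_with_cm(self, skeleton):
        for _, sub in skeleton.markers.groupby("chrom"):
            assert sub["cM"].is_monotonic_increasing
            assert sub["bp"].is_monotonic_increasing

    def test_degenerate_zero_span_gives_single_marker(self):
        assert len(simulate_marker_map(ONE_LOCUS).markers) == 1

    def test_grid_arithmetic(self):
        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(100.0,), spacing_cm=5.0)
        assert len(simulate_marker_map(spec).markers) == 21

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            MarkerMapSpec(spacing_cm=0.0)


class TestPedigree:
    def test_uu_frequency_near_quarter(self):
        m = simulate_epiril_pedigree(simulate_marker_map(ONE_LOCUS), 20000, seed=5)
        freq = m.codes().mean()
        se = np.sqrt(0.25 * 0.75 / 20000)
        assert abs(freq - 0.25) < 3 * se

    def test_zero_distance_markers_identical(self):
        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(0.0,))
        # two markers at the same cM: emulate by a tiny-spacing map
        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(1e-9,), spacing_cm=1e-9)
        m = simulate_epiril_pedigree(simulate_marker_map(spec), 300, seed=6)
        cols = m.genotypes
        assert cols.shape[1] == 2
        assert (cols.iloc[:, 0] == cols.iloc[:, 1]).all()

    def test_same_seed_bit_identical(self, skeleton):
        a = simulate_epiril_pedigree(skeleton, 50, seed=9)
        b = simulate_epiril_pedigree(skeleton, 50, seed=9)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    def test_n_lines_validated(self, skeleton):
        with pytest.raises(ValueError):
            simulate_epiril_pedigree(skeleton, 0, seed=0)

    @pytest.mark.parametrize("d_cm", [5.0, 30.0])
    def test_two_locus_distribution_matches_exact_pedigree_oracle(self, d_cm):
        """Terminal genotype correlation between linked markers agrees with
        the exact generation-by-generation two-locus enumeration."""
        oracle = two_locus_summary(d_cm)
        assert abs(oracle["p_uu"][0] - 0.25) < 1e-12  # sanity of the oracle
        assert abs(oracle["p_het"][0] - 1 / 128) < 1e-12
        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(d_cm,), spacing_cm=d_cm)
        m = simulate_epiril_pedigree(simulate_marker_map(spec), 20000, seed=7)
        codes = m.codes()
        sim_corr = np.corrcoef(codes[:, 0], codes[:, 1])[0, 1]
        assert abs(sim_corr - oracle["corr_uu"]) < 0.03

    def test_correlation_decays_with_distance(self):
        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(100.0,), spacing_cm=10.0)
        m = simulate_epiril_pedigree(simulate_marker_map(spec), 8000, seed=8)
        codes = m.codes()
        near = np.corrcoef(codes[:, 0], codes[:, 1])[0, 1]
        far = np.corrcoef(codes[:, 0], codes[:, -1])[0, 1]
        assert near > 0.5
        assert abs(far) < near / 2


class TestTrioMethylomes:
    def test_zero_penetrance_fully_additive(self, epimap, regions):
        planted = (
            PlantedQtl("MM010", tuple(regions["region_id"].iloc[:4]), 1, 0.0),
        )
        trios = simulate_trio_methylomes(
            epimap, regions, planted, state_noise=0.0, hybrid_noise=0.0, seed=3
        )
        mpv = (trios.mscol.to_numpy()[:, None] + trios.epiril.to_numpy()) / 2
        assert np.array_equal(trios.hybrid.to_numpy(), mpv)
        assert trios.events.empty

    def test_full_penetrance_targets_uu_families(self, epimap, trio_states):
        """Positive-effect QTL at penetrance 1 forces TCM in exactly the
        UU-parent families (wherever a methylation gain is possible)."""
        trios, planted = trio_states
        q = next(p for p in planted if p.effect_sign > 0)
        uu_lines = epimap.genotypes.index[epimap.genotypes[q.marker_id] == "UU"]
        for rid in q.target_region_ids:
            mpv = (trios.mscol.loc[rid] + trios.epiril.loc[rid]) / 2.0
            hd = trios.hybrid.loc[rid] - mpv
            gain_possible = mpv.loc[uu_lines] < 1.0
            assert (hd.loc[uu_lines][gain_possible] > 0).all()
            mm_lines = [l for l in trios.hybrid.columns if l not in set(uu_lines)]
            assert (hd.loc[mm_lines] <= 0).all()

    def test_penetrance_binomial_recovery(self, epimap, regions):
        """Observed remodeling frequency at targets matches the configured
        penetrance within the binomial 99% CI."""
        unmeth = regions[(~regions["segregating"]) & (regions["base_state"] == 0)]
        rid = unmeth["region_id"].iloc[0]
        planted = (PlantedQtl("MM010", (rid,), 1, 0.6),)
        trios = simulate_trio_methylomes(
            epimap, regions, planted, state_noise=0.0, hybrid_noise=0.0, seed=4
        )
        # only UU lines can gain at an unmethylated SMR (MPV = 0)
        n_uu = int((epimap.genotypes["MM010"] == "UU").sum())
        fired = int((trios.events["kind"] == "TCM").sum())
        ci = 2.58 * np.sqrt(n_uu * 0.6 * 0.4)
        assert abs(fired - 0.6 * n_uu) <= ci

    def test_unknown_marker_and_region_rejected(self, epimap, regions):
        with pytest.raises(KeyError):
            simulate_trio_methylomes(
                epimap, regions, (PlantedQtl("nope", ("R00001",), 1, 1.0),)
            )
        with pytest.raises(KeyError):
            simulate_trio_methylomes(
                epimap, regions, (PlantedQtl("MM001", ("nope",), 1, 1.0),)
            )


class TestPhenotypes:
    def test_all_effects_zero_gives_grand_mean(self, epimap):
        df = simulate_phenotypes(
            epimap, (), n_sibs=3, family_var=0.0, residual_var=0.0,
            parent_divergence_sd=0.0, covariate_effects=_NO_COVARIATES, seed=1,
        )
        assert np.allclose(df["value"], 100.0)

    def test_planted_qtl_contrast(self, epimap):
        from epihybrid.simulate import PhenoQtl

        df = simulate_phenotypes(
            epimap, (PhenoQtl("MM050", 10.0),), n_sibs=8, family_var=0.0,
            residual_var=1.0, parent_divergence_sd=0.0,
            covariate_effects=_NO_COVARIATES, seed=2,
        )
        means = df[df["group"] == "F1"].groupby("family_id")["value"].mean()
        mpv = 100.0
        mph = (means - mpv) / mpv * 100.0
        mm = epimap.genotypes["MM050"] == "MM"
        contrast = mph[mm.values].mean() - mph[~mm.values].mean()
        assert abs(contrast - 10.0) < 1.0

    def test_n_sibs_validated(self, epimap):
        with pytest.raises(ValueError):
            simulate_phenotypes(epimap, n_sibs=0)


class TestCounts:
    def test_unit_multipliers_flat_means(self):
        states = pd.DataFrame(
            np.random.default_rng(0).choice([0.0, 1.0], size=(5000, 2)),
            columns=["a", "b"],
        )
        counts = simulate_counts(states, {0.0: 1.0, 0.5: 1.0, 1.0: 1.0},
                                 base_mean=30, dispersion=0.05, seed=5)
        m_u = counts.to_numpy()[states.to_numpy() == 0].mean()
        m_m = counts.to_numpy()[states.to_numpy() == 1].mean()
        assert abs(m_u / m_m - 1.0) < 0.05

    def test_multiplier_ratio_recovered(self):
        states = pd.DataFrame({"s": [0.0] * 10000 + [1.0] * 10000})
        counts = simulate_counts(states, state_multipliers(4.0, 1),
                                 base_mean=50, dispersion=0.1, seed=6)
        ratio = counts["s"][10000:].mean() / counts["s"][:10000].mean()
        assert abs(ratio - 4.0) < 0.2

    def test_zero_mean_gives_zero_counts(self):
        states = pd.DataFrame({"s": [0.0] * 100})
        counts = simulate_counts(states, {0.0: 0.0, 0.5: 1.0, 1.0: 1.0},
                                 base_mean=50, dispersion=0.1, seed=7)
        assert (counts["s"] == 0).all()

    def test_bad_dispersion_rejected(self):
        states = pd.DataFrame({"s": [0.0]})
        with pytest.raises(ValueError):
            simulate_counts(states, {0.0: 1.0}, dispersion=0.0)
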