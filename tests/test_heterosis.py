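"""Heterosis: MPH, transgression, variance components, conditional EWAS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epihybrid.heterosis import (
    adjust_environment,
    classify_transgression,
    compute_mph,
    conditional_ewas,
    marker_ld,
    variance_components,
)
from epihybrid._rng import substream


def _plants(families, value_fn, n=8, groups=("msCol", "epiRIL", "F1")):
    rows = []
    for fam in families:
        for grp in groups:
            for s in range(n):
                rows.append(
                    {
                        "plant_id": f"{fam}_{grp}_{s}",
                        "family_id": fam,
                        "group": grp,
                        "value": value_fn(fam, grp, s),
                        "experiment": f"E{s % 3}",
                        "block": f"B{s % 4}",
                        "germination_date": "G1",
                    }
                )
    return pd.DataFrame(rows)


class TestAdjustEnvironment:
    def test_planted_block_effect_removed(self):
        rng = substream(31, "env")

        def value(fam, grp, s):
            return 100.0 + (10.0 if s % 4 == 0 else 0.0) + rng.normal(0, 1)

        df = _plants([f"f{i}" for i in range(30)], value)
        adj = adjust_environment(df)
        by_block = adj.groupby("block")["value"].mean()
        assert by_block.max() - by_block.min() < 1.0

    def test_outliers_removed(self):
        def value(fam, grp, s):
            return 1000.0 if (fam, grp, s) == ("f0", "F1", 0) else 100.0 + s * 0.01

        df = _plants(["f0", "f1", "f2"], value)
        adj = adjust_environment(df)
        assert len(adj) == len(df) - 1

    def test_no_covariate_effect_recenters_only(self):
        def value(fam, grp, s):
            return 100.0 + (1.0 if fam == "f1" else 0.0)

        df = _plants(["f0", "f1"], value)
        adj = adjust_environment(df)
        # family contrast preserved
        means = adj.groupby("family_id")["value"].mean()
        assert means["f1"] - means["f0"] == pytest.approx(1.0, abs=1e-9)


class TestComputeMph:
    def _simple(self, ms, ep, f1, n=6):
        means = {"msCol": ms, "epiRIL": ep, "F1": f1}
        return _plants(["fam"], lambda fam, grp, s: means[grp], n=n)

    def test_f1_at_mpv_gives_zero(self):
        out = compute_mph(self._simple(100, 140, 120))
        assert out["MPH"].iloc[0] == pytest.approx(0.0)

    def test_arithmetic(self):
        out = compute_mph(self._simple(100, 140, 150))
        assert out["MPH"].iloc[0] == pytest.approx(25.0)
        assert out["MPV"].iloc[0] == pytest.approx(120.0)

    def test_best_parent_value(self):
        out = compute_mph(self._simple(100, 140, 140))
        assert out["MPH"].iloc[0] == pytest.approx(100 * 20 / 120)

    def test_small_families_excluded(self):
        out = compute_mph(self._simple(100, 140, 150, n=4))
        assert out.empty
        assert out.attrs["excluded"][0][1].startswith("fewer than")

    def test_missing_group_excluded(self):
        df = _plants(["fam"], lambda f, g, s: 100.0, groups=("msCol", "F1"))
        out = compute_mph(df)
        assert out.empty and out.attrs["excluded"][0][1] == "missing group"

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        base = self._simple(100, 140, 150)
        scaled = base.assign(value=base["value"] * c)
        assert compute_mph(scaled)["MPH"].iloc[0] == pytest.approx(25.0)


class TestTransgression:
    def _family(self, f1_mean, noise_sd=1.0, n=18, seed=0):
        rng = substream(seed, "trans")

        def value(fam, grp, s):
            mean = {"msCol": 100.0, "epiRIL": 110.0, "F1": f1_mean}[grp]
            return mean + rng.normal(0, noise_sd)

        return _plants(["fam"], value, n=n)

    def test_f1_at_mpv_is_additive(self):
        label, aic = classify_transgression(self._family(105.0))
        assert label == "additive"

    def test_far_above_best_parent_is_high(self):
        label, _ = classify_transgression(self._family(125.0))
        assert label == "high_parent"

    def test_far_below_worst_parent_is_low(self):
        label, _ = classify_transgression(self._family(85.0))
        assert label == "low_parent"

    def test_too_few_f1_undetermined(self):
        fam = self._family(105.0, n=2)
        label, aic = classify_transgression(fam)
        assert label == "undetermined" and aic == {}

    def test_recovery_at_two_sd_effect(self):
        """High-parent truth at a 2-SD offset above the better parent is
        recovered in at least 90% of replicates at 18 siblings."""
        hits = 0
        for k in range(30):
            label, _ = classify_transgression(
                self._family(112.0, noise_sd=1.0, n=18, seed=100 + k)
            )
            hits += label == "high_parent"
        assert hits >= 27

    def test_additive_truth_mislabel_rate(self):
        """Under additive truth the classifier mislabels at most ~10%."""
        wrong = 0
        for k in range(40):
            label, _ = classify_transgression(
                self._family(105.0, noise_sd=2.0, n=18, seed=500 + k)
            )
            wrong += label != "additive"
        assert wrong / 40 <= 0.10 + 0.05


class TestVarianceComponents:
    def test_equal_family_means_zero_fraction(self):
        df = pd.DataFrame(
            {"family_id": np.repeat(list("abcd"), 5),
             "MPH": np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 4)}
        )
        frac, s_b, s_w, trunc = variance_components(df)
        assert frac == 0.0 and trunc

    def test_single_replicate_rejected(self):
        df = pd.DataFrame({"family_id": list("abcd"), "MPH": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            variance_components(df)

    def test_thirty_seventy_split_recovered(self):
        rng = substream(33, "vc")
        fams = 400
        fam_eff = rng.normal(0, np.sqrt(30.0), fams)
        rows = []
        for i in range(fams):
            for _ in range(10):
                rows.append({"family_id": f"f{i}",
                             "MPH": fam_eff[i] + rng.normal(0, np.sqrt(70.0))})
        frac, *_ = variance_components(pd.DataFrame(rows))
        assert abs(frac - 0.30) < 0.03


class TestMarkerLd:
    def test_identical_markers(self):
        g = np.array([0, 1, 0, 1, 1])
        assert marker_ld(g, g) == pytest.approx(1.0)

    def test_independent_markers_near_zero(self):
        rng = substream(34, "ld")
        a = (rng.random(5000) < 0.25).astype(float)
        b = (rng.random(5000) < 0.25).astype(float)
        assert marker_ld(a, b) < 0.01

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            marker_ld([1, 1, 1], [0, 1, 0])

    def test_linked_markers_match_pedigree_oracle(self):
        """r^2 between markers 10 cM apart matches the exact two-locus
        pedigree enumeration."""
        from epihybrid.simulate import (
            MarkerMapSpec, simulate_epiril_pedigree, simulate_marker_map
        )
        from _oracles import two_locus_summary

        spec = MarkerMapSpec(chrom_names=("c",), lengths_cm=(10.0,), spacing_cm=10.0)
        m = simulate_epiril_pedigree(simulate_marker_map(spec), 20000, seed=35)
        codes = m.codes()
        expected = two_locus_summary(10.0)["corr_uu"] ** 2
        assert abs(marker_ld(codes[:, 0], codes[:, 1]) - expected) < 0.03


class TestConditionalEwas:
    def _setup(self, n_fam=160, seed=36, planted_clusters=0, cluster_w=0.0):
        rng = substream(seed, "ewas")
        fams = [f"f{i}" for i in range(n_fam)]
        core = pd.DataFrame(
            (rng.random((n_fam, 3)) < 0.25).astype(float),
            index=fams, columns=["m1", "m2", "m3"],
        )
        mph = core.to_numpy() @ np.array([3.0, -2.0, 2.5]) + rng.normal(0, 2, n_fam)
        nad_cols = {}
        factors = rng.normal(0, 1, (n_fam, max(planted_clusters, 1)))
        for c in range(planted_clusters):
            for j in range(8):
                nad_cols[f"c{c}_n{j}"] = factors[:, c] + rng.normal(0, 0.2, n_fam)
            mph = mph + cluster_w * factors[:, c]
        for j in range(10):  # unrelated NADs
            nad_cols[f"null_{j}"] = rng.normal(0, 1, n_fam)
        nad = pd.DataFrame(nad_cols, index=fams)
        return core, nad, pd.Series(mph, index=fams)

    def test_null_nads_add_no_variance(self):
        core, nad, mph = self._setup(planted_clusters=0)
        res = conditional_ewas(core, nad, mph)
        assert res["r2_denovo"] < 0.05
        assert len(res["proxies"]) <= 1

    def test_saturating_nad_reaches_full_r2(self):
        core, nad, mph = self._setup(planted_clusters=0)
        resid = mph - mph.mean()
        nad["perfect"] = resid  # contains the full residual signal
        res = conditional_ewas(core, nad, mph)
        assert res["r2_full"] > 0.999
        assert "perfect" in res["proxies"]

    def test_planted_four_cluster_structure_recovered(self):
        core, nad, mph = self._setup(planted_clusters=4, cluster_w=3.0)
        res = conditional_ewas(core, nad, mph)
        assert res["n_clusters"] == 4
        assert len(res["proxies"]) == 4
        # each proxy comes from a distinct planted cluster
        origins = {p.split("_")[0] for p in res["proxies"]}
        assert origins == {"c0", "c1", "c2", "c3"}
        assert res["r2_denovo"] > 0.2
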