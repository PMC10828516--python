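"""Pipeline configuration.

A single YAML document with sections mirroring the analysis modules.
Every published analysis constant is a named key with its published
default: 200-bp regions on a 50-bp step with >= 10 cytosines, sharing
filters (>= 2 families for shared NADs, >= 10 for correlations, >= 50%
for QTL traits), the 2-cM scan step, 1,000 permutations, the 2-LOD (and
1-LOD) drop, p < 0.05, FDR < 0.05, the 1-kb gene-linking window, and the
CPM >= 1 in >= 2 samples count filter.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["default_config", "load_config", "dump_config"]

_DEFAULTS = {
    "simulate": {
        "n_lines": 169,
        "n_sibs": 18,
        "n_trios_omics": 36,
        "marker_spacing_cm": 5.0,
        "state_noise": 0.01,
        "hybrid_noise": 0.02,
        "planted_penetrance": 0.8,
        "family_var": 30.0,
        "residual_var": 70.0,
        "pheno_qtl_effect_mph": 2.7,
        "srna_mult_m": 4.0,
        "expr_mult_u": 2.0,
        "nb_dispersion": 0.1,
        "count_base_mean": 50.0,
    },
    "region_model": {
        "region_bp": 200,
        "step_bp": 50,
        "min_cytosines": 10,
        "t_low": 0.2,
        "t_high": 0.8,
        "min_shared_families": 2,
        "n_boot_enrichment": 1000,
        "window_bp": 10000,
        "window_step_bp": 10000,
    },
    "co_remodeling": {
        "min_families": 10,
        "alpha": 0.05,
        "majority_fraction": 0.5,
        "adjust": None,
    },
    "epiqtl": {
        "trait_share_fraction": 0.5,
        "step_cm": 2.0,
        "n_perm": 1000,
        "alpha": 0.05,
        "fdr": 0.05,
        "lod_drop": 2.0,
        "pheno_lod_drop_compare": 1.0,
    },
    "heterosis": {
        "min_plants": 5,
        "outlier_sd": 3.0,
        "anova_alpha": 0.05,
        "ewas_fdr": 0.05,
        "max_clusters": 10,
    },
    "omics": {
        "min_cpm": 1.0,
        "min_samples": 2,
        "gene_link_bp": 1000,
        "alpha": 0.05,
    },
    "causal": {
        "n_boot": 1000,
    },
    "pipeline": {
        "stages": [
            "simulate",
            "classify",
            "correlate",
            "mapqtl",
            "heterosis",
            "omics",
            "causal",
        ],
        # desk-scale caps so the full demo run stays interactive
        "max_correlation_regions": 60,
        "max_qtl_traits": 60,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def load_config(path=None) -> dict:
    """Defaults, deep-merged with an optional YAML overlay."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            overlay = yaml.safe_load(fh) or {}
        _merge(cfg, overlay)
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _merge(base: dict, overlay: dict) -> None:
    for key, val in overlay.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _merge(base[key], val)
        else:
            base[key] = val
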