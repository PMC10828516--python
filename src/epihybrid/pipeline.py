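"""End-to-end pipeline orchestrator.

Runs simulate -> classify -> correlate -> mapqtl -> heterosis -> omics ->
causal on a configuration, writing each stage's tables under an output
directory and a run manifest (config snapshot, seeds, file checksums,
stage timings) as JSON.  Re-running with the same seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import causal as causal_mod
from . import coremodeling, heterosis, io, omics, qtl, regions as region_mod
from ._rng import substream
from .config import default_config
from .simulate import (
    MarkerMapSpec,
    RegionSpec,
    default_pheno_qtl,
    default_planted_qtl,
    pericentromere_intervals,
    simulate_counts,
    simulate_epiril_pedigree,
    simulate_marker_map,
    simulate_phenotypes,
    simulate_regions,
    simulate_trio_methylomes,
    state_multipliers,
)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    def __init__(self, manifest, name):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest["stage_timings_s"][self.name] = round(
            time.perf_counter() - self.t0, 3
        )
        if exc_type is not None:
            self.manifest["failed_stage"] = self.name
        return False


def _synthetic_gff3(regions: pd.DataFrame, path: Path, rng) -> None:
    """Synthetic gene annotation: one gene near a subset of region blocks.

    Purely generated plumbing for the gene-linking stage (there is no
    reference annotation in a simulated genome)."""
    lines = ["##gff-version 3"]
    gid = 0
    block = regions.groupby("chrom").cumcount() // 8
    for (chrom, _b), sub in regions.groupby(["chrom", block], sort=False):
        if rng.random() < 0.6:
            gid += 1
            start = int(sub["start"].min()) + int(rng.integers(0, 600))
            end = start + int(rng.integers(400, 2000))
            lines.append(
                "\t".join(
                    [
                        chrom if isinstance(chrom, str) else chrom[0],
                        "epihybrid_sim",
                        "gene",
                        str(start + 1),
                        str(end),
                        ".",
                        "+" if rng.random() < 0.5 else "-",
                        ".",
                        f"ID=G{gid:05d}",
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: dict | None = None, outdir="epihybrid_run",
                 seed: int = 0) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg = config or default_config()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["pipeline"]["stages"]
    manifest = {
        "tool_version": __version__,
        "seed": int(seed),
        "config": cfg,
        "stages_run": [],
        "stage_timings_s": {},
        "outputs": {},
        "summary": {},
    }

    def save(name, df, writer=io.write_table, **kw):
        path = out / name
        writer(df, path, **kw) if writer is not io.write_bed else writer(df, path)
        manifest["outputs"][name] = _sha256(path)
        return path

    sim = cfg["simulate"]
    reg_cfg = cfg["region_model"]
    map_spec = MarkerMapSpec(spacing_cm=sim["marker_spacing_cm"])
    region_spec = RegionSpec(region_bp=reg_cfg["region_bp"], step_bp=reg_cfg["step_bp"])

    # ---- simulate -------------------------------------------------------
    with _Stage(manifest, "simulate"):
        skeleton = simulate_marker_map(map_spec)
        epimap = simulate_epiril_pedigree(skeleton, sim["n_lines"], seed)
        regions = simulate_regions(skeleton, region_spec, map_spec, seed=seed)
        planted = default_planted_qtl(epimap, regions, penetrance=sim["planted_penetrance"])
        trios = simulate_trio_methylomes(
            epimap, regions, planted, state_noise=sim["state_noise"],
            hybrid_noise=sim["hybrid_noise"], seed=seed,
        )
        pheno_qtl = default_pheno_qtl(epimap, effect_mph=sim["pheno_qtl_effect_mph"])
        phenos = simulate_phenotypes(
            epimap, pheno_qtl, n_sibs=sim["n_sibs"], family_var=sim["family_var"],
            residual_var=sim["residual_var"], seed=seed,
        )
        peri = pericentromere_intervals(map_spec, region_spec)
        if "simulate" in stages:
            save("marker_map.csv", epimap, writer=io.write_marker_map, seed=seed)
            states = pd.concat(
                [trios.mscol.to_frame(),
                 trios.epiril.add_prefix("epiRIL_"),
                 trios.hybrid.add_prefix("F1_")],
                axis=1,
            )
            save("state_matrix.tsv", (trios.regions, states),
                 writer=lambda t, p, **kw: io.write_state_matrix(t[0], t[1], p, **kw),
                 seed=seed)
            save("regions.bed", trios.regions, writer=io.write_bed)
            save("pericentromeres.bed", peri, writer=io.write_bed)
            save("phenotypes.tsv", phenos, seed=seed)
            rng = substream(seed, "gff3")
            gff_path = out / "genes.gff3"
            _synthetic_gff3(regions, gff_path, rng)
            manifest["outputs"]["genes.gff3"] = _sha256(gff_path)
            manifest["stages_run"].append("simulate")

    # ---- classify -------------------------------------------------------
    scen_table = region_mod.classify_trios(trios.mscol, trios.epiril, trios.hybrid)
    div = region_mod.divergence_matrix(trios.mscol, trios.epiril, trios.hybrid)
    hd_wide = scen_table.pivot(index="region_id", columns="family_id", values="HD")
    hd_wide = hd_wide.loc[trios.epiril.index, trios.epiril.columns]
    nad_ind = (hd_wide != 0).astype(int)
    if "classify" in stages:
        with _Stage(manifest, "classify"):
            save("scenario_table.tsv", scen_table)
            labels = region_mod.shared_private_labels(
                nad_ind, min_shared=reg_cfg["min_shared_families"]
            )
            save("region_labels.tsv", labels.reset_index())
            nad_any = nad_ind.sum(axis=1) > 0
            is_dmr_by_family = scen_table.assign(is_dmr=scen_table["PD"] != 0)
            nad_rows = is_dmr_by_family[is_dmr_by_family["HD"] != 0]
            p_enrich, obs, _ = region_mod.enrichment_bootstrap(
                nad_rows["is_dmr"].to_numpy(),
                is_dmr_by_family["is_dmr"].to_numpy(),
                n_boot=reg_cfg["n_boot_enrichment"],
                seed=seed,
            )
            dens = region_mod.window_density(
                trios.regions, labels[labels == "shared"].index,
                window_bp=reg_cfg["window_bp"], step_bp=reg_cfg["window_step_bp"],
            )
            save("shared_nad_density.tsv", dens)
            manifest["summary"]["nad_frequency"] = float(
                (scen_table["HD"] != 0).mean()
            )
            manifest["summary"]["dmr_enrichment_p"] = float(p_enrich)
            manifest["summary"]["dmr_freq_in_nads"] = float(obs)
            manifest["stages_run"].append("classify")

    # shared NADs and their divergence traits
    n_fam = nad_ind.shape[1]
    shared_counts = nad_ind.sum(axis=1)

    if "correlate" in stages:
        with _Stage(manifest, "correlate"):
            cor_cfg = cfg["co_remodeling"]
            shared_ids = shared_counts[
                shared_counts >= cor_cfg["min_families"]
            ].index
            cap = cfg["pipeline"]["max_correlation_regions"]
            shared_ids = shared_ids[:cap]
            div_nad = div.loc[shared_ids].where(nad_ind.loc[shared_ids] == 1)
            cors = coremodeling.pairwise_nad_correlations(
                div_nad, min_families=cor_cfg["min_families"],
                alpha=cor_cfg["alpha"],
                majority_fraction=cor_cfg["majority_fraction"],
                adjust=cor_cfg["adjust"],
            )
            meta = trios.regions.set_index("region_id")
            if not cors.empty:
                cats = [
                    coremodeling.compartment_categorize(
                        meta.loc[a], meta.loc[b], peri
                    )
                    for a, b in zip(cors["region_a"], cors["region_b"])
                ]
                cors["category"] = [c[0] for c in cats]
                cors["chromosomal"] = [c[1] for c in cats]
            save("nad_correlations.tsv", cors)
            fam0 = trios.epiril.columns[0]
            fam_table = scen_table[scen_table["family_id"] == fam0].merge(
                trios.regions[["region_id", "chrom", "start", "end"]], on="region_id"
            )
            prox = coremodeling.proximity_to_dmr_events(fam_table)
            save("smr_dmr_distances.tsv", prox["distances"])
            manifest["summary"]["n_significant_correlations"] = int(len(cors))
            manifest["stages_run"].append("correlate")

    qtl_table = pd.DataFrame()
    if "mapqtl" in stages:
        with _Stage(manifest, "mapqtl"):
            q_cfg = cfg["epiqtl"]
            trait_ids = shared_counts[
                shared_counts >= q_cfg["trait_share_fraction"] * n_fam
            ].index[: cfg["pipeline"]["max_qtl_traits"]]
            traits = div.loc[trait_ids]
            targets = trios.regions.set_index("region_id")[["chrom", "start", "end"]]
            scen_major = (
                scen_table[scen_table["HD"] != 0]
                .assign(kind=lambda d: np.where(d["HD"] > 0, "TCM", "TCdM"))
                .groupby("region_id")["kind"]
                .agg(lambda s: s.mode().iloc[0])
            )
            qtl_table = qtl.run_nad_qtl(
                epimap, traits, targets=targets, scenario_majority=scen_major,
                step_cm=q_cfg["step_cm"], n_perm=q_cfg["n_perm"],
                alpha=q_cfg["alpha"], fdr=q_cfg["fdr"],
                lod_drop=q_cfg["lod_drop"], seed=seed,
            )
            save("nad_qtl.tsv", qtl_table)
            if not qtl_table.empty:
                manifest["summary"]["frac_trans"] = float(
                    (qtl_table["cis_trans"] == "trans").mean()
                )
            manifest["summary"]["n_qtl_traits"] = int(len(traits))
            manifest["summary"]["n_qtl_associations"] = int(len(qtl_table))
            manifest["stages_run"].append("mapqtl")

    mph_table = pd.DataFrame()
    if "heterosis" in stages:
        with _Stage(manifest, "heterosis"):
            h_cfg = cfg["heterosis"]
            adjusted = heterosis.adjust_environment(phenos, sd_cutoff=h_cfg["outlier_sd"])
            mph_table = heterosis.compute_mph(adjusted, min_plants=h_cfg["min_plants"])
            classes = []
            for fam, sub in adjusted.groupby("family_id", sort=False):
                label, _aic = heterosis.classify_transgression(sub)
                classes.append({"family_id": fam, "transgression": label})
            mph_table = mph_table.merge(pd.DataFrame(classes), on="family_id")
            save("heterosis.tsv", mph_table)
            # plant-level MPH replicates for the variance decomposition
            fam_mpv = mph_table.set_index("family_id")["MPV"]
            f1 = adjusted[adjusted["group"] == "F1"].copy()
            f1 = f1[f1["family_id"].isin(fam_mpv.index)]
            f1["MPH"] = (
                (f1["value"] - f1["family_id"].map(fam_mpv))
                / f1["family_id"].map(fam_mpv) * 100.0
            )
            frac, s_b, s_w, _trunc = heterosis.variance_components(f1)
            manifest["summary"]["between_family_mph_fraction"] = float(frac)
            family_mph = mph_table.set_index("family_id")["MPH"].reindex(
                epimap.line_ids
            )
            pheno_peaks = heterosis.pheno_qtl_scan(
                epimap, family_mph, step_cm=cfg["epiqtl"]["step_cm"],
                n_perm=cfg["epiqtl"]["n_perm"], alpha=cfg["epiqtl"]["alpha"],
                anova_alpha=h_cfg["anova_alpha"], lod_drop=cfg["epiqtl"]["lod_drop"],
                seed=seed,
            )
            save("pheno_qtl.tsv", pheno_peaks)
            manifest["summary"]["n_pheno_qtl"] = int(len(pheno_peaks))
            # conditional EWAS on de novo NADs (no QTL association)
            core_markers = (
                pheno_peaks["marker_id"].tolist()
                if not pheno_peaks.empty
                else [q.marker_id for q in default_pheno_qtl(epimap)]
            )
            core_geno = pd.DataFrame(
                {m: (epimap.genotypes[m] == "UU").astype(float) for m in core_markers}
            )
            qtl_assoc = set(qtl_table["trait_id"]) if not qtl_table.empty else set()
            denovo_ids = [
                r for r in shared_counts[shared_counts >= 2].index
                if r not in qtl_assoc
            ][:60]
            ok_fam = family_mph.dropna().index
            ewas = heterosis.conditional_ewas(
                core_geno.loc[ok_fam],
                div.loc[denovo_ids, ok_fam].T,
                family_mph.loc[ok_fam],
                fdr=h_cfg["ewas_fdr"], max_clusters=h_cfg["max_clusters"],
                seed=seed,
            )
            save("ewas.tsv", ewas["table"])
            manifest["summary"]["ewas_r2_core"] = ewas["r2_core"]
            manifest["summary"]["ewas_r2_denovo"] = ewas["r2_denovo"]
            manifest["summary"]["ewas_n_clusters"] = ewas["n_clusters"]
            manifest["stages_run"].append("heterosis")

    expr_div = meth_div36 = None
    gene_regions = pd.DataFrame()
    if "omics" in stages:
        with _Stage(manifest, "omics"):
            o_cfg = cfg["omics"]
            n36 = min(sim["n_trios_omics"], len(epimap.line_ids))
            trio_lines = epimap.line_ids[:n36]
            genes = io.read_gff3_genes(out / "genes.gff3") if (
                out / "genes.gff3"
            ).exists() else pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
            gene_regions = omics.link_regions_to_genes(
                trios.regions, genes, max_distance=o_cfg["gene_link_bp"]
            )
            save("region_gene_links.tsv", gene_regions)
            # expression counts: genes follow the state of a linked region
            linked = gene_regions.drop_duplicates("gene_id").set_index("gene_id")
            cols = {}
            for line in trio_lines:
                cols[f"msCol_{line}"] = trios.mscol.loc[linked["region_id"]].to_numpy()
                cols[f"epiRIL_{line}"] = trios.epiril.loc[
                    linked["region_id"], line
                ].to_numpy()
                cols[f"F1_{line}"] = trios.hybrid.loc[
                    linked["region_id"], line
                ].to_numpy()
            gene_states = pd.DataFrame(cols, index=linked.index)
            expr_counts = simulate_counts(
                gene_states, state_multipliers(sim["expr_mult_u"], direction=-1),
                base_mean=sim["count_base_mean"], dispersion=sim["nb_dispersion"],
                seed=substream(seed, "expr").integers(2**31),
            )
            srna_states = pd.DataFrame(
                {
                    **{f"msCol_{line}": trios.mscol for line in trio_lines},
                    **{f"epiRIL_{line}": trios.epiril[line] for line in trio_lines},
                    **{f"F1_{line}": trios.hybrid[line] for line in trio_lines},
                }
            )
            srna_counts = simulate_counts(
                srna_states, state_multipliers(sim["srna_mult_m"], direction=1),
                base_mean=sim["count_base_mean"], dispersion=sim["nb_dispersion"],
                seed=substream(seed, "srna").integers(2**31),
            )
            save("expression_counts.tsv", expr_counts.reset_index(names="feature_id"))
            save("srna_counts.tsv", srna_counts.reset_index(names="feature_id"))
            expr_norm, _f = omics.filter_and_normalize_counts(
                expr_counts, min_cpm=o_cfg["min_cpm"], min_samples=o_cfg["min_samples"]
            )
            design = pd.DataFrame(
                {
                    "family_id": trio_lines,
                    "msCol": [f"msCol_{l}" for l in trio_lines],
                    "epiRIL": [f"epiRIL_{l}" for l in trio_lines],
                    "F1": [f"F1_{l}" for l in trio_lines],
                }
            )
            expr_div = omics.omics_divergence(expr_norm, design)
            meth_div36 = div[trio_lines]
            pairs = gene_regions.rename(
                columns={"region_id": "feature_a", "gene_id": "feature_b"}
            )[["feature_a", "feature_b"]]
            cors = omics.divergence_correlation(
                meth_div36, expr_div, pairs, alpha=o_cfg["alpha"]
            )
            save("meth_expression_correlations.tsv", cors)
            manifest["summary"]["n_gene_links"] = int(len(gene_regions))
            manifest["summary"]["frac_sig_meth_expr"] = (
                float(cors["significant"].mean()) if len(cors) else float("nan")
            )
            manifest["stages_run"].append("omics")

    if "causal" in stages:
        with _Stage(manifest, "causal"):
            rows = []
            if (
                not qtl_table.empty
                and expr_div is not None
                and not gene_regions.empty
            ):
                assoc = qtl_table.drop_duplicates("trait_id").set_index("trait_id")
                linked = gene_regions[gene_regions["region_id"].isin(assoc.index)]
                linked = linked.drop_duplicates("region_id").drop_duplicates("gene_id")
                for _, lk in linked.head(5).iterrows():
                    rid, gid = lk["region_id"], lk["gene_id"]
                    if gid not in expr_div.index:
                        continue
                    marker = assoc.loc[rid, "peak_marker"]
                    fams = [f for f in meth_div36.columns]
                    Qv = (epimap.genotypes.loc[fams, marker] == "UU").astype(float)
                    Mv = meth_div36.loc[rid, fams].astype(float)
                    Ev = expr_div.loc[gid, fams].astype(float)
                    ok = np.isfinite(Mv) & np.isfinite(Ev)
                    if ok.sum() < 10 or Qv[ok].std() == 0:
                        continue
                    try:
                        sel = causal_mod.bootstrap_select(
                            Qv[ok], Mv[ok], Ev[ok],
                            n_boot=max(100, cfg["causal"]["n_boot"] // 4),
                            seed=substream(seed, "causal", gid).integers(2**31),
                        )
                    except (ValueError, RuntimeError):
                        continue
                    rows.append(
                        {
                            "gene_id": gid,
                            "region_id": rid,
                            "marker_id": marker,
                            "selected_model": sel["selected"],
                            "support": sel["support"],
                            **{f"freq_{m}": v
                               for m, v in sel["frequencies"].items()},
                        }
                    )
            causal_table = pd.DataFrame(rows)
            save("causal_models.tsv", causal_table)
            manifest["summary"]["n_causal_genes"] = int(len(causal_table))
            manifest["stages_run"].append("causal")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
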