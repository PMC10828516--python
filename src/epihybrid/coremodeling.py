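"""Genome-wide co-occurrence of methylome remodeling.

Pairwise Pearson correlations of mid-parent methylation divergence between
shared non-additive regions across families, categorisation of correlated
pairs by chromosome compartment (arm vs pericentromere) and chromosome
(intra vs inter), and proximity of remodeling events within similarly
methylated regions to remodeled parental DMRs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pairwise_nad_correlations",
    "compartment_categorize",
    "proximity_to_dmr_events",
]


def _pearson_p(r, n):
    """Two-sided p for a Pearson correlation via the exact t reference."""
    r = np.clip(r, -1.0, 1.0)
    t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-12))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def pairwise_nad_correlations(
    divergence: pd.DataFrame,
    min_families: int = 10,
    alpha: float = 0.05,
    majority_fraction: float = 0.5,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Pearson correlations between all region pairs across families.

    ``divergence`` is regions x families %MPDiv with NaN where a family
    is not remodeled at the region; rows should already be restricted to
    NADs shared by at least ``min_families`` families.  Pairs with fewer
    than 3 jointly non-missing families are skipped.  Raw p-values are
    kept at ``p < alpha`` (the published procedure); ``adjust="BY"``
    optionally applies Benjamini-Yekutieli before filtering.  The
    ``majority_pair`` flag records whether both regions are remodeled in
    at least ``majority_fraction`` of families.
    """
    if min_families < 2:
        raise ValueError("min_families must be >= 2")
    mat = divergence.to_numpy(dtype=float)
    present = np.isfinite(mat)
    n_fam = mat.shape[1]
    keep = present.sum(axis=1) >= min_families
    mat, present = mat[keep], present[keep]
    ids = divergence.index.to_numpy()[keep]
    majority = present.sum(axis=1) >= majority_fraction * n_fam
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            both = present[a] & present[b]
            n = int(both.sum())
            if n < 3:
                continue
            xa, xb = mat[a, both], mat[b, both]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            p = float(_pearson_p(r, n))
            rows.append(
                {
                    "region_a": ids[a],
                    "region_b": ids[b],
                    "pearson_r": r,
                    "p_value": p,
                    "n_families": n,
                    "sign": int(np.sign(r)),
                    "majority_pair": bool(majority[a] and majority[b]),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["region_a", "region_b", "pearson_r", "p_value", "n_families",
                 "sign", "majority_pair"],
    )
    if out.empty:
        return out
    if adjust == "BY":
        from .qtl import by_adjust

        out["p_value"] = by_adjust(out["p_value"].to_numpy())
    return out[out["p_value"] < alpha].reset_index(drop=True)


def _is_peri(chrom, midpoint, peri: pd.DataFrame) -> bool:
    sub = peri[peri["chrom"] == chrom]
    if sub.empty:
        raise KeyError(f"chromosome {chrom!r} absent from pericentromere BED")
    return bool(((sub["start"] <= midpoint) & (midpoint < sub["end"])).any())


def compartment_categorize(region_a: pd.Series, region_b: pd.Series,
                           pericentromeres: pd.DataFrame):
    """Compartment category and chromosomal relation of a region pair.

    A region is pericentromeric iff its midpoint falls inside a
    pericentromere interval (half-open).  Returns ``(category,
    chromosomal)`` with category in {arm-arm, arm-peri, peri-peri} (the
    pair is unordered) and chromosomal in {intra, inter}.
    """
    mids = []
    for reg in (region_a, region_b):
        mid = (int(reg["start"]) + int(reg["end"])) // 2
        mids.append(_is_peri(reg["chrom"], mid, pericentromeres))
    n_peri = sum(mids)
    category = ("arm-arm", "arm-peri", "peri-peri")[n_peri]
    chromosomal = "intra" if region_a["chrom"] == region_b["chrom"] else "inter"
    return category, chromosomal


def _nearest_gap(queries: pd.DataFrame, targets: pd.DataFrame) -> pd.Series:
    """Edge-to-edge bp distance from each query interval to the nearest
    target interval on the same chromosome (0 when overlapping, NaN when
    the chromosome has no target)."""
    out = pd.Series(np.nan, index=queries.index, dtype=float)
    for chrom, qsub in queries.groupby("chrom", sort=False):
        tsub = targets[targets["chrom"] == chrom]
        if tsub.empty:
            continue
        ts = tsub["start"].to_numpy()
        te = tsub["end"].to_numpy()
        for i, q in qsub.iterrows():
            gap = np.maximum(ts - q["end"], q["start"] - te)
            out.loc[i] = max(0, int(gap.min()))
    return out


def proximity_to_dmr_events(scenario_table: pd.DataFrame) -> dict:
    """Distances from SMR remodeling events to the nearest DMR event.

    ``scenario_table`` is one family's classified regions with columns
    ``region_id, chrom, start, end, scenario``.  Computes edge-to-edge
    distances for the four published query/target pairings (gain events
    versus gain events, loss versus loss, and the additive-SMR baselines)
    and their per-group medians.

    Returns ``{"distances": long frame, "medians": {group: median}}``.
    """
    groups = {
        "SMR_TCM_to_DMR_TCM": ("TCM_SMR", "TCM_DMR"),
        "SMR_ADD_to_DMR_TCM": ("ADD_SMR", "TCM_DMR"),
        "SMR_TCdM_to_DMR_TCdM": ("TCdM_SMR", "TCdM_DMR"),
        "SMR_ADD_to_DMR_TCdM": ("ADD_SMR", "TCdM_DMR"),
    }
    tab = scenario_table
    is_smr_add = (tab["scenario"] == "ADD") & (tab.get("PD", 0) == 0)
    frames = []
    medians = {}
    for name, (q_scen, t_scen) in groups.items():
        if q_scen == "ADD_SMR":
            queries = tab[is_smr_add]
        else:
            queries = tab[tab["scenario"] == q_scen]
        targets = tab[tab["scenario"] == t_scen]
        d = _nearest_gap(queries, targets)
        frames.append(
            pd.DataFrame(
                {"region_id": queries["region_id"], "group": name, "distance_bp": d}
            )
        )
        medians[name] = float(np.nanmedian(d)) if d.notna().any() else np.nan
    distances = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["region_id", "group", "distance_bp"])
    )
    return {"distances": distances, "medians": medians}
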