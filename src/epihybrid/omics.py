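"""Count-based omics layers: expression and small-RNA matrices.

Counts are filtered on counts-per-million, normalised with the trimmed
mean of M-values (TMM) method, converted to per-feature mid-parent
divergence across trios, and linked to nearby genes for the
candidate-gene filtering chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cpm",
    "tmm_factors",
    "filter_and_normalize_counts",
    "omics_divergence",
    "link_regions_to_genes",
    "annotation_overlap_fractions",
    "divergence_correlation",
]


def cpm(counts: pd.DataFrame, lib_sizes=None) -> pd.DataFrame:
    """Counts per million on (optionally effective) library sizes."""
    libs = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    if (np.asarray(libs) <= 0).any():
        raise ValueError("library with zero total counts")
    return counts / libs * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    ref_column=None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    For each library against the reference (by default the library whose
    upper quartile of scaled counts is closest to the mean upper
    quartile), log ratios (M) and average log intensities (A) are
    computed over features expressed in both; the most extreme
    ``m_trim`` (by M) and ``a_trim`` (by A) fractions are trimmed
    two-sided, and the factor is 2 to the precision-weighted mean of the
    remaining M values.  Factors are rescaled so their geometric mean
    is 1.
    """
    mat = counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("library with zero total counts")
    if ref_column is None:
        uq = np.array(
            [np.quantile(col[col > 0] / n, 0.75) if (col > 0).any() else 0.0
             for col, n in zip(mat.T, libs)]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_column)
    ref = mat[:, ref_idx]
    n_ref = libs[ref_idx]
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        obs = mat[:, j]
        n_obs = libs[j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            continue
        p_obs, p_ref = obs[keep] / n_obs, ref[keep] / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic inverse variance of M (delta method)
        w = 1.0 / (
            (n_obs - obs[keep]) / (n_obs * obs[keep])
            + (n_ref - ref[keep]) / (n_ref * ref[keep])
        )
        finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
        m, a, w = m[finite], a[finite], w[finite]
        if m.size == 0:
            continue
        m_lo, m_hi = np.quantile(m, [m_trim, 1 - m_trim])
        a_lo, a_hi = np.quantile(a, [a_trim, 1 - a_trim])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not sel.any():
            sel = np.ones(m.size, dtype=bool)
        factors[j] = 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def filter_and_normalize_counts(
    raw: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> tuple:
    """CPM filter followed by TMM normalisation.

    Features with CPM >= ``min_cpm`` in at least ``min_samples`` samples
    are kept; TMM factors are computed on the filtered matrix and CPM are
    returned on the effective (factor-scaled) library sizes.

    Returns ``(normalized_cpm, tmm_factors)``.
    """
    raw_cpm = cpm(raw)
    keep = (raw_cpm >= min_cpm).sum(axis=1) >= min_samples
    filtered = raw[keep]
    factors = tmm_factors(filtered)
    eff_libs = filtered.sum(axis=0) * factors
    return cpm(filtered, eff_libs), factors


def omics_divergence(normalized: pd.DataFrame, trio_design: pd.DataFrame) -> pd.DataFrame:
    """Per-feature percent mid-parent divergence for every trio.

    ``trio_design`` has columns ``family_id, msCol, epiRIL, F1`` naming
    the sample columns of each trio.  Divergence is (F1 - MPV)/MPV x 100;
    trios with MPV = 0 for a feature are set missing (NaN).
    """
    out = {}
    for _, trio in trio_design.iterrows():
        mpv = (normalized[trio["msCol"]] + normalized[trio["epiRIL"]]) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            div = (normalized[trio["F1"]] - mpv) / mpv * 100.0
        out[trio["family_id"]] = div.where(mpv != 0)
    return pd.DataFrame(out, index=normalized.index)


def link_regions_to_genes(
    regions: pd.DataFrame, genes: pd.DataFrame, max_distance: int = 1000
) -> pd.DataFrame:
    """Region-gene pairs within an edge-to-edge distance cutoff.

    ``genes`` uses internal 0-based half-open coordinates (``gene_id,
    chrom, start, end``).  A pair is linked iff the bp gap between the
    region interval and the gene interval is <= ``max_distance``
    (0 when overlapping); strand is ignored.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    rows = []
    for chrom, rsub in regions.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        gs = gsub["start"].to_numpy()
        ge = gsub["end"].to_numpy()
        gid = gsub["gene_id"].to_numpy()
        for _, reg in rsub.iterrows():
            gap = np.maximum(
                np.maximum(gs - int(reg["end"]), int(reg["start"]) - ge), 0
            )
            hits = np.flatnonzero(gap <= max_distance)
            for h in hits:
                rows.append(
                    {
                        "region_id": reg["region_id"],
                        "gene_id": gid[h],
                        "distance_bp": int(gap[h]),
                    }
                )
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "distance_bp"])


def annotation_overlap_fractions(
    scenario_table: pd.DataFrame,
    regions: pd.DataFrame,
    annotations: dict,
) -> pd.DataFrame:
    """Fraction of regions per remodeling category overlapping annotations.

    ``annotations`` maps a label (e.g. "gene", "TE") to an interval frame
    with ``chrom, start, end``.  Overlap means a strictly positive
    intersection (edge-to-edge distance 0 with the half-open convention).
    """
    meta = regions.set_index("region_id")
    rows = []
    for scen, sub in scenario_table.groupby("scenario", sort=False):
        ids = sub["region_id"].unique()
        rmeta = meta.loc[ids]
        rec = {"scenario": scen, "n_regions": len(ids)}
        for label, ann in annotations.items():
            hits = 0
            for chrom, asub in ann.groupby("chrom", sort=False):
                rsub = rmeta[rmeta["chrom"] == chrom]
                if rsub.empty:
                    continue
                a_s = asub["start"].to_numpy()
                a_e = asub["end"].to_numpy()
                for _, reg in rsub.iterrows():
                    if np.any((a_s < reg["end"]) & (reg["start"] < a_e)):
                        hits += 1
            rec[f"frac_{label}"] = hits / len(ids) if len(ids) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def divergence_correlation(
    div_a: pd.DataFrame,
    div_b: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of two divergence layers over matched trios.

    ``pairs`` has columns ``feature_a, feature_b`` indexing rows of
    ``div_a`` and ``div_b`` (trio columns are aligned by name).  Pairs
    with fewer than 3 jointly finite trios are skipped; the
    ``significant`` column applies ``p < alpha``.
    """
    common = [c for c in div_a.columns if c in set(div_b.columns)]
    rows = []
    for _, pair in pairs.iterrows():
        fa, fb = pair["feature_a"], pair["feature_b"]
        if fa not in div_a.index or fb not in div_b.index:
            continue
        x = div_a.loc[fa, common].to_numpy(dtype=float)
        y = div_b.loc[fb, common].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        if x[ok].std() == 0 or y[ok].std() == 0:
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append(
            {
                "feature_a": fa,
                "feature_b": fb,
                "pearson_r": float(r),
                "p_value": float(p),
                "n": int(ok.sum()),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_a", "feature_b", "pearson_r", "p_value", "n", "significant"],
    )
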