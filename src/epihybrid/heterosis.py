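"""Mid-parent heterosis analysis of the epihybrid panel.

Covers environmental adjustment of the raw phenotypes, per-family
mid-parent heterosis (MPH), a likelihood-based transgression
classification, the one-way variance decomposition of MPH into between-
and within-family components, the phenotypic QTL scan on the
epihaplotype map, and the conditional epigenome-wide association study
(EWAS) that asks whether "de novo" non-additive methylation regions
explain heterotic variance beyond the mapped QTL.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import qtl as _qtl

__all__ = [
    "adjust_environment",
    "compute_mph",
    "classify_transgression",
    "variance_components",
    "pheno_qtl_scan",
    "conditional_ewas",
    "marker_ld",
]


def adjust_environment(
    phenotypes: pd.DataFrame,
    covariates: tuple = ("experiment", "block", "germination_date"),
    value_col: str = "value",
    sd_cutoff: float = 3.0,
) -> pd.DataFrame:
    """Remove fixed environmental effects by least squares.

    Outliers beyond ``sd_cutoff`` standard deviations of the raw values
    are dropped first.  The phenotype is regressed on the categorical
    covariates (fixed effects only) and the residuals, with the grand
    mean re-added, replace the raw values in the returned copy.
    Rank-deficient designs are handled by the pseudoinverse (aliased
    levels absorb into the fit).
    """
    df = phenotypes.copy()
    v = df[value_col].to_numpy(dtype=float)
    mu, sd = v.mean(), v.std()
    if sd > 0:
        df = df[np.abs(v - mu) <= sd_cutoff * sd].copy()
    y = df[value_col].to_numpy(dtype=float)
    X = pd.get_dummies(df[list(covariates)].astype(str), drop_first=True)
    X = np.column_stack([np.ones(len(df)), X.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df[value_col] = resid + y.mean()
    return df


def compute_mph(
    phenotypes: pd.DataFrame,
    value_col: str = "value",
    min_plants: int = 5,
    mpv_tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-family mid-parent heterosis table.

    Expects columns ``family_id, group, value`` with group in
    {msCol, epiRIL, F1}.  MPH = (F1 mean - MPV) / MPV x 100 with
    MPV = (msCol mean + epiRIL mean) / 2.  Families missing a group, with
    fewer than ``min_plants`` plants in any group, or with |MPV| below
    ``mpv_tol`` are excluded (the latter flagged in the ``excluded``
    companion attribute ``.attrs['excluded']``).
    """
    rows, excluded = [], []
    for fam, sub in phenotypes.groupby("family_id", sort=False):
        means, counts = {}, {}
        for grp in ("msCol", "epiRIL", "F1"):
            vals = sub.loc[sub["group"] == grp, value_col]
            means[grp] = vals.mean()
            counts[grp] = len(vals)
        if any(counts[g] == 0 for g in counts):
            excluded.append((fam, "missing group"))
            continue
        if any(counts[g] < min_plants for g in counts):
            excluded.append((fam, "fewer than %d plants" % min_plants))
            continue
        mpv = (means["msCol"] + means["epiRIL"]) / 2.0
        if abs(mpv) < mpv_tol:
            excluded.append((fam, "mid-parent value ~ 0"))
            continue
        rows.append(
            {
                "family_id": fam,
                "mean_msCol": means["msCol"],
                "mean_epiRIL": means["epiRIL"],
                "mean_F1": means["F1"],
                "MPV": mpv,
                "MPH": (means["F1"] - mpv) / mpv * 100.0,
                "n_msCol": counts["msCol"],
                "n_epiRIL": counts["epiRIL"],
                "n_F1": counts["F1"],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def _gauss_loglik(x, mean, var):
    n = x.size
    return -0.5 * n * (np.log(2 * np.pi * var) + 1) if var > 0 else np.inf


def classify_transgression(family_plants: pd.DataFrame, value_col: str = "value"):
    """Likelihood (AIC) classification of a family's heterosis mode.

    Compares Gaussian models for the three plant groups: (a) *additive* -
    the F1 mean is constrained to the mid-parent value; (b) *free* - the
    F1 mean is unconstrained.  If the free model wins on AIC and the
    fitted F1 mean exceeds the better parent the family is
    ``high_parent``; below the worse parent it is ``low_parent``; an F1
    mean within the parental range keeps the ``additive`` call.

    Returns ``(label, {"additive": aic, "free": aic})``; fewer than 3 F1
    replicates yield ``("undetermined", {})``.
    """
    groups = {
        g: family_plants.loc[family_plants["group"] == g, value_col].to_numpy(float)
        for g in ("msCol", "epiRIL", "F1")
    }
    if groups["F1"].size < 3 or groups["msCol"].size < 1 or groups["epiRIL"].size < 1:
        return "undetermined", {}
    m_ms, m_ep = groups["msCol"].mean(), groups["epiRIL"].mean()
    mpv = (m_ms + m_ep) / 2.0
    f1 = groups["F1"]
    # additive: F1 mean pinned at MPV; free: F1 mean at its MLE
    var_add = np.mean((f1 - mpv) ** 2)
    var_free = np.mean((f1 - f1.mean()) ** 2)
    ll_add = _gauss_loglik(f1, mpv, var_add)
    ll_free = _gauss_loglik(f1, f1.mean(), var_free)
    aic = {"additive": -2 * ll_add + 2 * 1, "free": -2 * ll_free + 2 * 2}
    label = "additive"
    if aic["free"] < aic["additive"]:
        if f1.mean() > max(m_ms, m_ep):
            label = "high_parent"
        elif f1.mean() < min(m_ms, m_ep):
            label = "low_parent"
    return label, aic


def variance_components(mph_replicates: pd.DataFrame, value_col: str = "MPH"):
    """Between-family fraction of MPH variance (one-way random effects).

    ``mph_replicates`` has columns ``family_id`` and the MPH replicate
    value (e.g. one per sibling).  Method-of-moments on the one-way
    ANOVA mean squares; a negative between-family moment estimate is
    truncated at zero and flagged.

    Returns ``(fraction, sigma2_family, sigma2_residual, truncated)``.
    """
    sizes = mph_replicates.groupby("family_id")[value_col].count()
    if (sizes < 2).all() or len(sizes) < 2:
        raise ValueError("need >= 2 families with >= 2 replicates each")
    g = mph_replicates.groupby("family_id")[value_col]
    n_i = g.count().to_numpy(dtype=float)
    means = g.mean().to_numpy()
    grand = mph_replicates[value_col].mean()
    N, a = n_i.sum(), len(n_i)
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(
        np.sum((mph_replicates[value_col] - g.transform("mean")) ** 2)
    )
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    n0 = (N - np.sum(n_i**2) / N) / (a - 1)
    sigma_b = (msb - msw) / n0
    truncated = sigma_b < 0
    sigma_b = max(sigma_b, 0.0)
    frac = sigma_b / (sigma_b + msw) if (sigma_b + msw) > 0 else 0.0
    return frac, sigma_b, msw, truncated


def pheno_qtl_scan(
    epihap_map,
    family_mph: pd.Series,
    step_cm: float = 2.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    anova_alpha: float = 0.05,
    lod_drop: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genome-wide phenotypic QTL scan for family-level MPH.

    Haley-Knott scan with a per-trait permutation threshold, exactly as
    in the methylation QTL analysis; peak markers are additionally tested
    by one-way ANOVA (MM vs UU) and retained at ``p < anova_alpha``.  The
    returned table carries the per-peak effect data (group means) used
    for effect plots.
    """
    y = family_mph.reindex(epihap_map.line_ids).to_numpy(dtype=float)
    grid = _qtl.genotype_probabilities(epihap_map, step_cm=step_cm)
    scan = _qtl.hk_scan(grid, y, trait_id="MPH")
    thr = _qtl.permutation_threshold(grid, y, n_perm=n_perm, alpha=alpha, seed=seed)
    peaks = _qtl.peaks_and_ci(scan, thr, drop=lod_drop)
    rows = []
    markers = epihap_map.markers
    codes = epihap_map.codes()
    for _, peak in peaks.iterrows():
        msub = markers[markers["chrom"] == peak["chrom"]]
        jm = (msub["cM"] - peak["peak_cM"]).abs().to_numpy().argmin()
        marker = msub.iloc[jm]
        g = codes[:, markers.index.get_loc(marker.name)]
        ok = np.isfinite(y)
        mm, uu = y[ok][g[ok] == 0], y[ok][g[ok] == 1]
        if mm.size == 0 or uu.size == 0:
            continue
        f_stat, p_anova = stats.f_oneway(mm, uu)
        if p_anova >= anova_alpha:
            continue
        rows.append(
            {
                "marker_id": marker["marker_id"],
                "chrom": peak["chrom"],
                "peak_cM": peak["peak_cM"],
                "peak_bp": peak["peak_bp"],
                "lod": peak["lod"],
                "threshold": thr,
                "p_anova": float(p_anova),
                "mean_MPH_MM": float(mm.mean()),
                "mean_MPH_UU": float(uu.mean()),
                "n_MM": int(mm.size),
                "n_UU": int(uu.size),
                "ci_lo_bp": peak["ci_lo_bp"],
                "ci_hi_bp": peak["ci_hi_bp"],
            }
        )
    return pd.DataFrame(rows)


def _ols_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def conditional_ewas(
    core_genotypes: pd.DataFrame,
    nad_divergence: pd.DataFrame,
    family_mph: pd.Series,
    fdr: float = 0.05,
    max_clusters: int = 10,
    seed: int = 0,
) -> dict:
    """Conditional EWAS of de novo NADs on MPH, beyond the core QTL model.

    The *core model* regresses family MPH on the epigenotype codes of the
    mapped QTL markers (``core_genotypes``: families x markers).  For each
    candidate NAD (a column-aligned families x regions %MPDiv frame whose
    regions showed no QTL association), a nested model adds that NAD's
    divergence; the improvement is a 1-df likelihood-ratio test, adjusted
    across NADs by Benjamini-Yekutieli.  Significant NADs are grouped by
    PCA + Ward hierarchical clustering (cluster count by maximal average
    silhouette over 2..``max_clusters``) and the NAD with the largest
    added R-squared represents each cluster in the final model.

    Returns a dict with the per-NAD LRT table, proxy region ids, and the
    core / de novo R-squared decomposition.
    """
    fams = family_mph.index
    y = family_mph.to_numpy(dtype=float)
    Xc = np.column_stack(
        [np.ones(len(fams)), core_genotypes.reindex(fams).to_numpy(dtype=float)]
    )
    n = len(y)
    rss_core = _ols_rss(Xc, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2_core = 1.0 - rss_core / tss

    nad = nad_divergence.reindex(fams)
    records = []
    for rid in nad.columns:
        x = nad[rid].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < Xc.shape[1] + 2:
            continue
        Xn = np.column_stack([Xc[ok], x[ok]])
        rss0 = _ols_rss(Xc[ok], y[ok])
        rss1 = _ols_rss(Xn, y[ok])
        if rss1 <= 0:
            lrt = np.inf
        else:
            lrt = ok.sum() * np.log(rss0 / rss1)
        p = float(stats.chi2.sf(lrt, df=1))
        records.append(
            {"region_id": rid, "lrt": float(lrt), "p_value": p,
             "added_r2": 1.0 - rss1 / max(rss0, np.finfo(float).tiny)}
        )
    table = pd.DataFrame(records)
    if table.empty:
        return {"table": table, "proxies": [], "r2_core": r2_core,
                "r2_denovo": 0.0, "r2_full": r2_core, "n_clusters": 0}
    table["q_value"] = _qtl.by_adjust(table["p_value"].to_numpy())
    sig = table[table["q_value"] < fdr].copy()

    proxies: list = []
    n_clusters = 0
    if len(sig) == 1:
        proxies = [sig["region_id"].iloc[0]]
        n_clusters = 1
    elif len(sig) > 1:
        profiles = nad[sig["region_id"]].T.to_numpy(dtype=float)
        profiles = np.nan_to_num(profiles - np.nanmean(profiles, axis=1, keepdims=True))
        n_comp = int(min(5, profiles.shape[0], profiles.shape[1]))
        pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(profiles)
        link = linkage(pcs, method="ward")
        best_k, best_score = 1, -np.inf
        for k in range(2, min(max_clusters, len(sig) - 1) + 1):
            lab = fcluster(link, k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(pcs, lab)
            if score > best_score:
                best_k, best_score = k, score
        labels = (
            fcluster(link, best_k, criterion="maxclust")
            if best_k > 1
            else np.ones(len(sig), dtype=int)
        )
        n_clusters = int(len(np.unique(labels)))
        sig = sig.reset_index(drop=True)
        for c in np.unique(labels):
            members = sig[labels == c]
            proxies.append(members.loc[members["added_r2"].idxmax(), "region_id"])

    r2_full = r2_core
    if proxies:
        P = nad[proxies].to_numpy(dtype=float)
        ok = np.all(np.isfinite(P), axis=1)
        # drop collinear proxies (rank-deficient addition)
        Xf = np.column_stack([Xc[ok], P[ok]])
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            keep, cols = [], [Xc[ok]]
            for j, rid in enumerate(proxies):
                trial = np.column_stack(cols + [P[ok][:, j]])
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    keep.append(rid)
                    cols.append(P[ok][:, j : j + 1])
            proxies = keep
            Xf = np.column_stack(cols)
        rss_full = _ols_rss(Xf, y[ok])
        tss_ok = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        rss_core_ok = _ols_rss(Xc[ok], y[ok])
        r2_full = 1.0 - rss_full / tss_ok
        r2_core = 1.0 - rss_core_ok / tss_ok
    return {
        "table": table,
        "proxies": list(proxies),
        "r2_core": float(r2_core),
        "r2_denovo": float(max(r2_full - r2_core, 0.0)),
        "r2_full": float(r2_full),
        "n_clusters": n_clusters,
    }


def marker_ld(genotype_a, genotype_b) -> float:
    """Linkage disequilibrium between two markers as squared Pearson r
    of their epigenotype codes over the same lines."""
    a = np.asarray(genotype_a, dtype=float)
    b = np.asarray(genotype_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("monomorphic marker")
    return float(np.corrcoef(a, b)[0, 1] ** 2)
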