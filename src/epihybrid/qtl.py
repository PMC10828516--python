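"""Epigenetic QTL interval mapping on the epihaplotype marker map.

Traits (ordered-quantile-normalised mid-parent methylation divergence of
shared non-additive regions, or family-level heterosis) are regressed on
the expected epigenotype at a grid of pseudomarkers (Haley-Knott
regression).  Significance is assessed per trait by permutation of the
trait values across lines (genome-wide 5% false-positive rate), peaks are
localised with a LOD-drop confidence interval, cis/trans status is called
by containment of the target region in the interval, and effect size and
direction come from a single-marker regression at the peak.  Multiple
testing across traits uses the Benjamini-Yekutieli correction.

Epigenotypes are two-class and fully epihomozygous: MM (wild-type
methylated) coded 0 and UU (ddm1-hypomethylated) coded 1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .simulate import EpihaplotypeMap, haldane

__all__ = [
    "LOD_MAX",
    "ScanGrid",
    "QTLScanResult",
    "orq_normalize",
    "genotype_probabilities",
    "hk_scan",
    "permutation_threshold",
    "peaks_and_ci",
    "cis_trans_call",
    "qtl_effect",
    "by_adjust",
    "lod_to_p",
    "run_nad_qtl",
]

#: sentinel LOD for numerically perfect fits (RSS of the full model ~ 0)
LOD_MAX = 50.0


def orq_normalize(values) -> np.ndarray:
    """Ordered Quantile normalisation (rank-to-normal-quantile transform).

    Maps values onto standard-normal quantiles at probability points
    (rank - 0.5) / n with average ranks for ties, so the output is a
    strictly monotone function of the input ranks and invariant to any
    strictly monotone transformation of the input.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values")
    xs = x[finite]
    if np.all(xs == xs[0]):
        raise ValueError("constant input has no rank spread")
    ranks = stats.rankdata(xs, method="average")
    out = np.full(x.shape, np.nan)
    out[finite] = stats.norm.ppf((ranks - 0.5) / xs.size)
    return out


@dataclass
class ScanGrid:
    """Pseudomarker grid with expected-genotype design matrix.

    ``positions`` has columns ``chrom, cM, bp, is_marker``; ``prob_uu`` is
    lines x positions with P(UU | flanking marker genotypes).
    """

    positions: pd.DataFrame
    prob_uu: np.ndarray
    line_ids: list


@dataclass
class QTLScanResult:
    """LOD curve with its permutation threshold and called peaks."""

    trait_id: str
    grid: pd.DataFrame  # chrom, cM, bp, is_marker, lod
    threshold: float
    peaks: pd.DataFrame


def _interval_prob(g_left, g_right, r_left, r_right):
    """P(UU at an interior point | flanking genotypes), Haldane, no interference.

    For a two-class fully homozygous population the line's genome is
    treated as a single recombinant haplotype: with a = P(observed left
    flank | U at the point) and b likewise on the right,
    P(UU | flanks) = ab / (ab + (1-a)(1-b)).
    """
    a = np.where(g_left == 1, 1.0 - r_left, r_left)
    b = np.where(g_right == 1, 1.0 - r_right, r_right)
    denom = a * b + (1.0 - a) * (1.0 - b)
    return a * b / denom


def genotype_probabilities(epihap_map: EpihaplotypeMap, step_cm: float = 2.0) -> ScanGrid:
    """Expected genotype at a cM grid of pseudomarkers.

    The grid contains every marker position plus points every ``step_cm``
    between them.  At marker positions the probability equals the observed
    genotype (0 or 1); between markers it follows Haldane recombination
    fractions to both flanks; outside the terminal markers positions are
    clipped onto the terminal marker.
    """
    if step_cm <= 0:
        raise ValueError("step_cm must be positive")
    markers = epihap_map.markers
    codes = epihap_map.codes()  # lines x markers, UU = 1
    col_of = {m: j for j, m in enumerate(markers["marker_id"])}
    pos_rows = []
    prob_cols = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        cm = sub["cM"].to_numpy()
        bp = sub["bp"].to_numpy()
        idx = [col_of[m] for m in sub["marker_id"]]
        g = codes[:, idx]  # lines x chrom markers
        grid = np.unique(
            np.concatenate([cm, np.arange(cm[0], cm[-1] + 1e-9, step_cm)])
        )
        for p in grid:
            j = int(np.searchsorted(cm, p, side="right")) - 1
            j = min(max(j, 0), len(cm) - 1)
            at_marker = np.isclose(p, cm).any()
            if at_marker:
                jm = int(np.argmin(np.abs(cm - p)))
                prob = g[:, jm].astype(float)
            else:
                jr = min(j + 1, len(cm) - 1)
                r_l = float(haldane(p - cm[j]))
                r_r = float(haldane(cm[jr] - p))
                prob = _interval_prob(g[:, j], g[:, jr], r_l, r_r)
            pos_rows.append(
                {
                    "chrom": chrom,
                    "cM": float(p),
                    "bp": float(np.interp(p, cm, bp)),
                    "is_marker": bool(at_marker),
                }
            )
            prob_cols.append(prob)
    return ScanGrid(
        positions=pd.DataFrame(pos_rows),
        prob_uu=np.column_stack(prob_cols),
        line_ids=epihap_map.line_ids,
    )


def _lod_from_r2(r2: np.ndarray, n: int) -> np.ndarray:
    """LOD = (n/2) log10(RSS0 / RSS1) = -(n/2) log10(1 - R^2), capped."""
    r2 = np.clip(r2, 0.0, 1.0)
    floor = 10.0 ** (-2.0 * LOD_MAX / n)
    return -(n / 2.0) * np.log10(np.maximum(1.0 - r2, floor))


def hk_scan(grid: ScanGrid, trait, trait_id: str = "trait") -> QTLScanResult:
    """Haley-Knott regression scan of one trait over the pseudomarker grid.

    At each grid position the trait is regressed on the expected
    epigenotype; LOD compares against the intercept-only model.  A
    numerically perfect fit is capped at the ``LOD_MAX`` sentinel.
    """
    y = np.asarray(trait, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("need >= 10 non-missing lines")
    y = y[ok]
    X = grid.prob_uu[ok]
    n = y.size
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y == 0:
        raise ValueError("trait has zero variance")
    Xc = X - X.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    sxy = yc @ Xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_x > 0, sxy**2 / (ss_x * ss_y), 0.0)
    lod = _lod_from_r2(r2, n)
    out = grid.positions.copy()
    out["lod"] = lod
    return QTLScanResult(trait_id=trait_id, grid=out, threshold=np.nan,
                         peaks=pd.DataFrame())


def permutation_threshold(grid: ScanGrid, trait, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Genome-wide LOD threshold from trait permutations.

    Permutes trait values across lines, rescans, and returns the
    (1 - alpha) quantile of the genome-wide maximum LOD.  ``alpha = 1``
    degenerates to the minimum of the null maxima.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(trait, dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    X = grid.prob_uu[ok]
    n = y.size
    rng = substream(seed, "permutation_threshold")
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = y[perms].T  # n x n_perm
    Yc = Y - Y.mean(axis=0)
    ss_y = np.einsum("ij,ij->j", Yc, Yc)
    Xc = X - X.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    sxy = Xc.T @ Yc  # positions x n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / np.outer(ss_x, ss_y)
    r2[~np.isfinite(r2)] = 0.0
    max_lod = _lod_from_r2(r2, n).max(axis=0)
    if alpha >= 1.0:
        return float(max_lod.min())
    return float(np.quantile(max_lod, 1.0 - alpha))


def peaks_and_ci(scan: QTLScanResult, threshold: float, drop: float = 2.0) -> pd.DataFrame:
    """Per-chromosome peaks above threshold with LOD-drop confidence intervals.

    The highest pseudomarker per chromosome is a peak if its LOD passes
    the threshold (leftmost wins ties); the CI extends contiguously around
    the peak while LOD >= peak - drop.  Returns an empty frame when
    nothing passes.
    """
    if drop <= 0:
        raise ValueError("drop must be positive")
    rows = []
    for chrom, sub in scan.grid.groupby("chrom", sort=False):
        lod = sub["lod"].to_numpy()
        j = int(np.argmax(lod))  # argmax returns the first (leftmost) maximum
        if lod[j] < threshold:
            continue
        lo = j
        while lo > 0 and lod[lo - 1] >= lod[j] - drop:
            lo -= 1
        hi = j
        while hi < len(lod) - 1 and lod[hi + 1] >= lod[j] - drop:
            hi += 1
        rows.append(
            {
                "trait_id": scan.trait_id,
                "chrom": chrom,
                "peak_cM": sub["cM"].iloc[j],
                "peak_bp": sub["bp"].iloc[j],
                "lod": lod[j],
                "ci_lo_cM": sub["cM"].iloc[lo],
                "ci_hi_cM": sub["cM"].iloc[hi],
                "ci_lo_bp": sub["bp"].iloc[lo],
                "ci_hi_bp": sub["bp"].iloc[hi],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["trait_id", "chrom", "peak_cM", "peak_bp", "lod",
                 "ci_lo_cM", "ci_hi_cM", "ci_lo_bp", "ci_hi_bp"],
    )


def cis_trans_call(peak: pd.Series, target_chrom: str, target_start: int,
                   target_end: int) -> str:
    """cis iff the target region's body lies within the confidence interval.

    Containment is required: a target straddling the CI boundary, or on
    another chromosome, is trans.
    """
    if peak["chrom"] != target_chrom:
        return "trans"
    if peak["ci_lo_bp"] <= target_start and target_end <= peak["ci_hi_bp"]:
        return "cis"
    return "trans"


def qtl_effect(trait, genotype_codes):
    """Effect size and direction at the peak marker.

    Ordinary regression of the trait on the epigenotype code (MM = 0,
    UU = 1).  Returns ``(r_squared, sign, slope)``; a positive sign means
    UU-parent families have the larger trait value.
    """
    y = np.asarray(trait, dtype=float)
    g = np.asarray(genotype_codes, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    if np.unique(g).size < 2:
        raise ValueError("both epigenotype classes must be present")
    if np.ptp(y) == 0:
        return 0.0, 0, 0.0
    slope, intercept, r, p, se = stats.linregress(g, y)
    sign = int(np.sign(slope)) if slope != 0 else 0
    return float(r**2), sign, float(slope)


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment.

    adj_(i) = min_{j >= i} ( p_(j) * m * c(m) / j ) with the harmonic
    factor c(m) = sum_{k<=m} 1/k; monotone in the raw p-values and capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def lod_to_p(lod, df: int = 1) -> np.ndarray:
    """Point-wise p-value for a LOD score via the chi-square approximation.

    2 ln(10) LOD ~ chi-square(df) under the null of no linkage.
    """
    return stats.chi2.sf(2.0 * np.log(10.0) * np.asarray(lod, dtype=float), df)


def run_nad_qtl(
    epihap_map: EpihaplotypeMap,
    nad_traits: pd.DataFrame,
    targets: pd.DataFrame | None = None,
    scenario_majority: pd.Series | None = None,
    step_cm: float = 2.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    fdr: float = 0.05,
    lod_drop: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Full NAD-QTL association scan across traits.

    ``nad_traits`` is traits (rows, indexed by region id) x lines; each
    trait is ORQ-normalised, scanned, thresholded by its own permutation
    null, and its best peak converted to a p-value for Benjamini-Yekutieli
    adjustment across traits.  Traits passing both their genome-wide
    threshold and FDR < ``fdr`` are reported with LOD-drop confidence
    intervals, cis/trans status (against ``targets``: region coordinates
    indexed by region id), effect size/direction at the peak position, and
    the region's predominant remodeling scenario if supplied.
    """
    grid = genotype_probabilities(epihap_map, step_cm=step_cm)
    records = []
    kept = []
    for trait_id, row in nad_traits.iterrows():
        try:
            y = orq_normalize(row.to_numpy())
            scan = hk_scan(grid, y, trait_id=str(trait_id))
            thr = permutation_threshold(grid, y, n_perm=n_perm, alpha=alpha,
                                        seed=substream(seed, "perm", trait_id).integers(2**31))
        except ValueError:
            continue
        peaks = peaks_and_ci(scan, thr, drop=lod_drop)
        if peaks.empty:
            continue
        best = peaks.iloc[int(peaks["lod"].to_numpy().argmax())]
        kept.append((trait_id, y, thr, peaks, float(best["lod"])))
    if not kept:
        return pd.DataFrame()
    p_best = lod_to_p([k[4] for k in kept])
    p_by = by_adjust(p_best)
    codes = epihap_map.codes()
    markers = epihap_map.markers
    for (trait_id, y, thr, peaks, _), p_raw, p_adj in zip(kept, p_best, p_by):
        if p_adj >= fdr:
            continue
        for _, peak in peaks.iterrows():
            msub = markers[markers["chrom"] == peak["chrom"]]
            jm = (msub["cM"] - peak["peak_cM"]).abs().to_numpy().argmin()
            marker = msub.iloc[jm]
            g = codes[:, markers.index.get_loc(marker.name)]
            try:
                r2, sign, slope = qtl_effect(y, g)
            except ValueError:
                r2, sign, slope = np.nan, 0, np.nan
            rec = {
                "trait_id": trait_id,
                "chrom": peak["chrom"],
                "peak_cM": peak["peak_cM"],
                "peak_bp": peak["peak_bp"],
                "peak_marker": marker["marker_id"],
                "lod": peak["lod"],
                "threshold": thr,
                "p_raw": p_raw,
                "p_BY": p_adj,
                "ci_lo_bp": peak["ci_lo_bp"],
                "ci_hi_bp": peak["ci_hi_bp"],
                "R2": r2,
                "sign": sign,
            }
            if targets is not None and trait_id in targets.index:
                t = targets.loc[trait_id]
                rec["cis_trans"] = cis_trans_call(
                    peak, t["chrom"], int(t["start"]), int(t["end"])
                )
            else:
                rec["cis_trans"] = ""
            rec["predominant_scenario"] = (
                scenario_majority.get(trait_id, "")
                if scenario_majority is not None
                else ""
            )
            records.append(rec)
    return pd.DataFrame(records)
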