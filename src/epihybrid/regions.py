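"""Trio-based methylome remodeling classification.

Every 200-bp region of every (maternal, paternal, hybrid) trio is placed
into one of five categories by comparing the hybrid's region-level
methylation state call with those of its two parents:

* parental divergence      PD  = msCol - epiRIL
* mid-parent value         MPV = (msCol + epiRIL) / 2
* hybrid divergence        HD  = hybrid - MPV

Parents are called binary (0 unmethylated, 1 methylated); hybrids may be
intermediate (0.5).  A region is a DMR when PD != 0 and an SMR otherwise;
it is non-additive (NAD) when HD != 0, with methylation gain (HD > 0)
termed trans-chromosomal methylation (TCM) and loss (HD < 0)
trans-chromosomal demethylation (TCdM).  The five labels are ADD,
TCM_DMR, TCdM_DMR, TCM_SMR and TCdM_SMR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "SCENARIOS",
    "call_region_states",
    "classify_trio",
    "classify_trios",
    "midparent_divergence",
    "divergence_matrix",
    "enrichment_bootstrap",
    "shared_private_labels",
    "window_density",
]

SCENARIOS = ("ADD", "TCM_DMR", "TCdM_DMR", "TCM_SMR", "TCdM_SMR")

_PARENT_STATES = (0.0, 1.0)
_HYBRID_STATES = (0.0, 0.5, 1.0)


def call_region_states(levels, t_low: float = 0.2, t_high: float = 0.8,
                       is_parent: bool = False):
    """Discretise continuous methylation levels into region state calls.

    Levels <= ``t_low`` become 0 and >= ``t_high`` become 1.  The middle
    band is the intermediate state 0.5 for hybrids; parents are binary by
    definition, so their middle-band levels are resolved to the nearer
    threshold (ties to methylated) and flagged as ambiguous.

    Returns ``(states, ambiguous)`` as arrays of the input shape.
    """
    if not t_low < t_high:
        raise ValueError("t_low must be < t_high")
    x = np.asarray(levels, dtype=float)
    if np.any((x < 0) | (x > 1) | ~np.isfinite(x)):
        raise ValueError("methylation levels must lie in [0, 1]")
    states = np.full(x.shape, 0.5)
    states[x <= t_low] = 0.0
    states[x >= t_high] = 1.0
    ambiguous = np.zeros(x.shape, dtype=bool)
    if is_parent:
        middle = (x > t_low) & (x < t_high)
        ambiguous = middle
        nearer_high = (t_high - x) <= (x - t_low)
        states[middle] = np.where(nearer_high[middle], 1.0, 0.0)
    return states, ambiguous


def classify_trio(mscol_state: float, epiril_state: float, hybrid_state: float):
    """Classify one region of one trio.

    Returns ``(scenario, PD, MPV, HD)``.  Deterministic and total over the
    12 valid state combinations.
    """
    if mscol_state not in _PARENT_STATES or epiril_state not in _PARENT_STATES:
        raise ValueError("parent states must be binary (0 or 1)")
    if hybrid_state not in _HYBRID_STATES:
        raise ValueError("hybrid state must be one of 0, 0.5, 1")
    pd_ = mscol_state - epiril_state
    mpv = (mscol_state + epiril_state) / 2.0
    hd = hybrid_state - mpv
    if hd == 0:
        scenario = "ADD"
    elif hd > 0:
        scenario = "TCM_DMR" if pd_ != 0 else "TCM_SMR"
    else:
        scenario = "TCdM_DMR" if pd_ != 0 else "TCdM_SMR"
    return scenario, pd_, mpv, hd


def classify_trios(mscol, epiril: pd.DataFrame, hybrid: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification over a full regions x families panel.

    ``mscol`` is a per-region Series (the shared maternal parent);
    ``epiril``/``hybrid`` are regions x families frames.  Returns a long
    table with one row per region x family and columns ``region_id,
    family_id, PD, MPV, HD, scenario, pct_mpdiv``.
    """
    ms = np.asarray(mscol, dtype=float)[:, None]
    ep = epiril.to_numpy(dtype=float)
    hy = hybrid.to_numpy(dtype=float)
    if not np.isin(ms, _PARENT_STATES).all() or not np.isin(ep, _PARENT_STATES).all():
        raise ValueError("parent states must be binary (0 or 1)")
    pd_ = ms - ep
    mpv = (ms + ep) / 2.0
    hd = hy - mpv
    scen = np.where(
        hd == 0,
        "ADD",
        np.where(
            hd > 0,
            np.where(pd_ != 0, "TCM_DMR", "TCM_SMR"),
            np.where(pd_ != 0, "TCdM_DMR", "TCdM_SMR"),
        ),
    )
    pct, _ = midparent_divergence(hy, ms, ep, mode="ratio")
    n_reg, n_fam = hy.shape
    out = pd.DataFrame(
        {
            "region_id": np.repeat(epiril.index.to_numpy(), n_fam),
            "family_id": np.tile(epiril.columns.to_numpy(), n_reg),
            "PD": pd_.ravel(),
            "MPV": mpv.ravel(),
            "HD": hd.ravel(),
            "scenario": scen.ravel(),
            "pct_mpdiv": pct.ravel(),
        }
    )
    return out


def midparent_divergence(hybrid_value, mscol_value, epiril_value, mode: str = "ratio"):
    """Percent mid-parent divergence, (H - MPV) / MPV x 100.

    ``mode="ratio"`` is the published formula; where MPV = 0 it is
    undefined and falls back to the difference form (H - MPV) x 100 with
    the record flagged.  ``mode="difference"`` always uses the difference
    form.  Returns ``(percent, fallback_flag)`` broadcast over the inputs.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    h = np.asarray(hybrid_value, dtype=float)
    ms = np.asarray(mscol_value, dtype=float)
    ep = np.asarray(epiril_value, dtype=float)
    mpv = (ms + ep) / 2.0
    h, mpv = np.broadcast_arrays(h, mpv)
    diff = (h - mpv) * 100.0
    if mode == "difference":
        return diff, np.zeros(h.shape, dtype=bool)
    zero = mpv == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (h - mpv) / mpv * 100.0
    return np.where(zero, diff, ratio), zero


def divergence_matrix(mscol, epiril: pd.DataFrame, hybrid: pd.DataFrame,
                      mode: str = "ratio") -> pd.DataFrame:
    """Regions x families %MPDiv frame (ratio mode with difference fallback)."""
    pct, _ = midparent_divergence(
        hybrid.to_numpy(dtype=float),
        np.asarray(mscol, dtype=float)[:, None],
        epiril.to_numpy(dtype=float),
        mode=mode,
    )
    return pd.DataFrame(pct, index=hybrid.index, columns=hybrid.columns)


def enrichment_bootstrap(nad_is_dmr, universe_is_dmr, n_boot: int = 1000,
                         seed: int = 0):
    """Bootstrap test for DMR enrichment among non-additive regions.

    ``nad_is_dmr`` indicates, for each NAD region, whether it is a
    parental DMR; ``universe_is_dmr`` does the same for every region in
    the genome-wide universe.  ``n_boot`` random draws of the NAD set's
    size from the universe give a null distribution of DMR frequencies;
    the empirical p-value is (1 + #{null >= observed}) / (n_boot + 1).

    Returns ``(p_value, observed_freq, null_freqs)``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    nad = np.asarray(nad_is_dmr, dtype=bool)
    uni = np.asarray(universe_is_dmr, dtype=bool)
    if nad.size == 0:
        raise ValueError("NAD set is empty")
    if uni.size == 0:
        raise ValueError("region universe is empty")
    rng = substream(seed, "enrichment_bootstrap")
    observed = nad.mean()
    draws = rng.choice(uni.size, size=(n_boot, nad.size), replace=True)
    null = uni[draws].mean(axis=1)
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_boot + 1.0)
    return p, observed, null


def shared_private_labels(nad_indicator: pd.DataFrame, min_shared: int = 2) -> pd.Series:
    """Label each region shared / private / none by how many families remodel it.

    A region is *private* when remodeled in exactly one family and
    *shared* when remodeled in at least ``min_shared`` families.
    """
    if min_shared < 2:
        raise ValueError("min_shared must be >= 2")
    mat = nad_indicator.to_numpy()
    if not np.isin(mat, (0, 1, True, False)).all():
        raise ValueError("indicator matrix must be binary")
    counts = mat.astype(bool).sum(axis=1)
    labels = np.where(counts >= min_shared, "shared",
                      np.where(counts == 1, "private", "none"))
    return pd.Series(labels, index=nad_indicator.index, name="label")


def window_density(regions: pd.DataFrame, labeled_ids, window_bp: int = 10_000,
                   step_bp: int = 10_000, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Count labeled regions per sliding genomic window.

    A region belongs to the half-open window that contains its midpoint
    (integer floor of (start + end) / 2).  Returns ``chrom, start, end,
    count`` for every window up to the last labeled midpoint (or the
    supplied chromosome sizes).
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window and step must be positive")
    labeled = regions[regions["region_id"].isin(set(labeled_ids))]
    rows = []
    chroms = chrom_sizes.keys() if chrom_sizes else regions["chrom"].unique()
    for chrom in chroms:
        sub = labeled[labeled["chrom"] == chrom]
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        if chrom_sizes:
            size = chrom_sizes[chrom]
        else:
            allc = regions[regions["chrom"] == chrom]
            size = int(allc["end"].max()) if len(allc) else 0
        n_win = (-(-max(size - window_bp, 0) // step_bp) + 1) if size else 0
        for w in range(n_win):
            lo = w * step_bp
            hi = lo + window_bp
            count = int(np.count_nonzero((mids >= lo) & (mids < hi)))
            rows.append({"chrom": chrom, "start": lo, "end": hi, "count": count})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
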