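"""Synthetic data generator for the epiHybrid cross design.

Emulates a panel of F1 epihybrids obtained by crossing a recurrent,
male-sterile wild-type maternal line (msCol) to a set of paternal epiRILs.
The epiRILs derive from a ddm1 x wild-type founder cross: the F1 was
backcrossed to the wild type and propagated for six generations of
single-seed descent, so each line is an epihomozygous mosaic of
wild-type-methylated (MM) and ddm1-hypomethylated (UU) epihaplotypes.

The generator produces every input the analysis pipeline consumes:

* an epihaplotype marker map with per-line MM/UU calls,
* region-level methylation state matrices for parents and hybrids
  (200-bp regions on a 50-bp step), with planted local and distal
  remodeling effects controlled by marker epigenotypes,
* per-plant phenotypes with family-level mid-parent heterosis driven by
  marker epigenotypes, and
* negative-binomial expression / small-RNA count matrices coupled to the
  methylation states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "MarkerMapSpec",
    "RegionSpec",
    "PlantedQtl",
    "PhenoQtl",
    "SimConfig",
    "EpihaplotypeMap",
    "TrioStates",
    "haldane",
    "simulate_marker_map",
    "simulate_epiril_pedigree",
    "simulate_regions",
    "simulate_trio_methylomes",
    "simulate_phenotypes",
    "simulate_counts",
    "default_planted_qtl",
    "default_pheno_qtl",
]

#: number of single-seed-descent generations after the backcross
N_SSD_GENERATIONS = 6


def haldane(d_cm):
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMapSpec:
    """Chromosome layout of the epihaplotype marker map.

    Defaults give five chromosomes whose 5-cM marker grid carries 144
    markers in total, the size of the published epiRIL recombination map.
    """

    chrom_names: tuple = ("chr1", "chr2", "chr3", "chr4", "chr5")
    lengths_cm: tuple = (180.0, 115.0, 135.0, 105.0, 160.0)
    spacing_cm: float = 5.0
    bp_per_cm: float = 200_000.0

    def __post_init__(self):
        if len(self.chrom_names) != len(self.lengths_cm):
            raise ValueError("chrom_names and lengths_cm must align")
        if self.spacing_cm <= 0:
            raise ValueError("marker spacing must be positive")
        if self.bp_per_cm <= 0:
            raise ValueError("bp_per_cm must be positive")
        if any(l < 0 for l in self.lengths_cm):
            raise ValueError("chromosome lengths must be >= 0 cM")


@dataclass(frozen=True)
class RegionSpec:
    """Layout of the 200-bp methylation regions on the synthetic genome.

    Regions are laid out in blocks of consecutive 50-bp-step windows,
    spread evenly along each chromosome so that both chromosome arms and
    the pericentromere (by default the middle 40% of each chromosome)
    are represented.
    """

    region_bp: int = 200
    step_bp: int = 50
    blocks_per_chrom: int = 25
    regions_per_block: int = 8
    peri_fraction: float = 0.4  # centred fraction of each chromosome
    contexts: tuple = ("CG", "CHG", "CHH")
    context_probs: tuple = (0.3, 0.3, 0.4)
    # probability that a block segregates with its nearest marker
    seg_prob_peri: float = 0.30
    seg_prob_arm: float = 0.08
    # P(methylated) for non-segregating background regions
    meth_prob_peri: float = 0.8
    meth_prob_arm: float = 0.3

    def __post_init__(self):
        if self.region_bp % self.step_bp:
            raise ValueError("step_bp must divide region_bp")
        if not 0 < self.peri_fraction < 1:
            raise ValueError("peri_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PlantedQtl:
    """A marker that remodels methylation at target regions in the hybrids.

    With ``effect_sign=+1`` hybrids from UU-parent families gain methylation
    (TCM) at the targets and MM-parent families lose it (TCdM); with
    ``effect_sign=-1`` the direction is reversed.  Each event fires with
    probability ``penetrance`` per family.
    """

    marker_id: str
    target_region_ids: tuple
    effect_sign: int = 1
    penetrance: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect_sign must be +1 or -1")


@dataclass(frozen=True)
class PhenoQtl:
    """A marker with an additive effect on family mid-parent heterosis.

    ``effect_mph`` is the expected MPH difference (percentage points)
    between MM-parent and UU-parent families; positive values reproduce
    the wild-type-epihaplotype-positive pattern seen in the mapped loci.
    """

    marker_id: str
    effect_mph: float


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic epiHybrid panel.

    Defaults are the published design: 169 methylome trios, 18 phenotyped
    siblings per family, a 144-marker map, a 30:70 split of between-family
    versus residual MPH variance, and phenotype QTL jointly explaining a
    modest share (~12%) of between-family MPH variance.
    """

    n_lines: int = 169
    n_sibs: int = 18
    marker_map_spec: MarkerMapSpec = field(default_factory=MarkerMapSpec)
    region_spec: RegionSpec = field(default_factory=RegionSpec)
    planted_qtl: tuple = ()  # tuple[PlantedQtl]; see default_planted_qtl
    pheno_qtl: tuple = ()  # tuple[PhenoQtl]; see default_pheno_qtl
    family_var: float = 30.0  # between-family MPH variance (%^2)
    residual_var: float = 70.0  # plant-level residual MPH variance (%^2)
    grand_mean: float = 100.0  # leaf-area-like scale (arbitrary units)
    parent_divergence_sd: float = 5.0  # epiRIL family mean shift, % of mean
    state_noise: float = 0.01  # epiRIL state call flip probability
    hybrid_noise: float = 0.02  # background non-additivity probability
    srna_mult_m: float = 4.0  # 24-nt sRNA mean multiplier, M vs U
    expr_mult_u: float = 2.0  # expression mean multiplier, U vs M
    nb_dispersion: float = 0.1
    count_base_mean: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.family_var < 0 or self.residual_var < 0:
            raise ValueError("variance components must be >= 0")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EpihaplotypeMap:
    """Marker map plus per-line MM/UU epigenotype calls.

    ``markers`` has columns ``marker_id, chrom, cM, bp``; ``genotypes`` is
    lines x markers with values ``"MM"``/``"UU"`` (empty before the
    pedigree has been simulated).
    """

    markers: pd.DataFrame
    genotypes: pd.DataFrame

    @property
    def line_ids(self):
        return list(self.genotypes.index)

    def codes(self) -> np.ndarray:
        """Genotypes coded numerically: MM = 0, UU = 1 (lines x markers)."""
        return (self.genotypes.to_numpy() == "UU").astype(float)

    def marker_row(self, marker_id: str) -> pd.Series:
        rows = self.markers[self.markers["marker_id"] == marker_id]
        if rows.empty:
            raise KeyError(f"unknown marker {marker_id!r}")
        return rows.iloc[0]


@dataclass
class TrioStates:
    """Region-level methylation state calls for every trio.

    ``regions`` carries region metadata (including the ``segregating``
    flag and nearest marker); ``mscol`` is the shared maternal state per
    region; ``epiril`` and ``hybrid`` are regions x lines matrices.
    ``events`` records planted remodeling events that actually fired
    (generator ground truth, used by recovery tests).
    """

    regions: pd.DataFrame
    mscol: pd.Series
    epiril: pd.DataFrame
    hybrid: pd.DataFrame
    events: pd.DataFrame


# ---------------------------------------------------------------------------
# marker map and pedigree
# ---------------------------------------------------------------------------


def simulate_marker_map(spec: MarkerMapSpec | None = None) -> EpihaplotypeMap:
    """Lay out the marker grid (no genotypes yet).

    Markers sit on a regular cM grid per chromosome; bp positions are a
    linear function of cM, hence monotone.  The default spec yields 144
    markers on 5 chromosomes.
    """
    spec = spec or MarkerMapSpec()
    rows = []
    idx = 1
    for chrom, length in zip(spec.chrom_names, spec.lengths_cm):
        n_mark = int(np.floor(length / spec.spacing_cm + 1e-9)) + 1
        for j in range(n_mark):
            cm = j * spec.spacing_cm
            rows.append(
                {
                    "marker_id": f"MM{idx:03d}",
                    "chrom": chrom,
                    "cM": cm,
                    "bp": int(round(cm * spec.bp_per_cm)),
                }
            )
            idx += 1
    markers = pd.DataFrame(rows)
    return EpihaplotypeMap(markers=markers, genotypes=pd.DataFrame())


def _gametes(h1: np.ndarray, h2: np.ndarray, rec: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One meiotic gamete per line from diplotype (h1, h2).

    ``h1, h2``: (n_lines, n_markers) boolean haplotypes; ``rec``: per-interval
    recombination fractions (n_markers - 1).  Crossovers are independent
    across intervals (Haldane, no interference).
    """
    n, k = h1.shape
    start = rng.random(n) < 0.5
    if k > 1:
        xo = rng.random((n, k - 1)) < rec[None, :]
        chooser = np.empty((n, k), dtype=bool)
        chooser[:, 0] = start
        np.logical_xor.accumulate(
            np.concatenate([start[:, None], xo], axis=1), axis=1, out=chooser
        )
    else:
        chooser = start[:, None]
    return np.where(chooser, h1, h2)


def simulate_epiril_pedigree(
    map_skeleton: EpihaplotypeMap, n_lines: int, seed: int
) -> EpihaplotypeMap:
    """Simulate epiRIL epigenotypes through the actual pedigree.

    Founders are UU (ddm1 parent) and MM (wild type) at every marker.  The
    F1 is backcrossed as a female to the wild type, then propagated for six
    generations of single-seed descent; recombination at each meiosis
    follows the Haldane map function on the marker cM distances.  Residual
    heterozygotes after the six generations (about 0.8% of line x locus
    calls) are resolved to a random homozygote, so the output map is fully
    epihomozygous; the expected UU frequency per marker is exactly 25%.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    markers = map_skeleton.markers
    rng = substream(seed, "pedigree")
    geno_cols = {}
    order = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        cm = sub["cM"].to_numpy()
        rec = haldane(np.diff(cm)) if len(cm) > 1 else np.empty(0)
        k = len(cm)
        # F1: one full ddm1 (U) haplotype, one full wild-type (M) haplotype
        h_u = np.ones((n_lines, k), dtype=bool)
        h_m = np.zeros((n_lines, k), dtype=bool)
        # BC1 = gamete(F1) x wild-type gamete
        ha = _gametes(h_u, h_m, rec, rng)
        hb = np.zeros((n_lines, k), dtype=bool)
        for _ in range(N_SSD_GENERATIONS):
            ha, hb = (
                _gametes(ha, hb, rec, rng),
                _gametes(ha, hb, rec, rng),
            )
        # residual heterozygous segments fix to one haplotype (as under
        # continued propagation): resolve with one further gamete draw so
        # that linked het loci resolve coherently
        het = ha != hb
        resolve = _gametes(ha, hb, rec, rng)
        uu = np.where(het, resolve, ha & hb)
        for j, mid in enumerate(sub["marker_id"]):
            geno_cols[mid] = np.where(uu[:, j], "UU", "MM")
            order.append(mid)
    line_ids = [f"line{i + 1:04d}" for i in range(n_lines)]
    genotypes = pd.DataFrame(geno_cols, index=line_ids)[order]
    return EpihaplotypeMap(markers=markers.copy(), genotypes=genotypes)


# ---------------------------------------------------------------------------
# regions and trio methylomes
# ---------------------------------------------------------------------------


def pericentromere_intervals(
    spec: MarkerMapSpec, region_spec: RegionSpec | None = None
) -> pd.DataFrame:
    """Default pericentromere BED: the centred fraction of each chromosome."""
    frac = (region_spec or RegionSpec()).peri_fraction
    rows = []
    for chrom, length in zip(spec.chrom_names, spec.lengths_cm):
        total_bp = int(round(length * spec.bp_per_cm))
        half = (1.0 - frac) / 2.0
        rows.append(
            {
                "chrom": chrom,
                "start": int(round(total_bp * half)),
                "end": int(round(total_bp * (1.0 - half))),
            }
        )
    return pd.DataFrame(rows)


def simulate_regions(
    map_skeleton: EpihaplotypeMap,
    region_spec: RegionSpec | None = None,
    map_spec: MarkerMapSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Place 200-bp regions along the genome and assign their roles.

    Returns a frame with columns ``region_id, chrom, start, end, context,
    peri, nearest_marker, segregating, base_state``.  ``segregating``
    regions are parental DMR candidates: the maternal line is methylated
    there while a paternal epiRIL is unmethylated iff it is UU at the
    nearest marker.
    """
    region_spec = region_spec or RegionSpec()
    map_spec = map_spec or MarkerMapSpec()
    rng = substream(seed, "regions")
    peri = pericentromere_intervals(map_spec, region_spec)
    markers = map_skeleton.markers
    rows = []
    rid = 0
    for chrom, length in zip(map_spec.chrom_names, map_spec.lengths_cm):
        total_bp = int(round(length * map_spec.bp_per_cm))
        msub = markers[markers["chrom"] == chrom]
        mpos = msub["bp"].to_numpy()
        mids = msub["marker_id"].to_numpy()
        p_lo, p_hi = peri.loc[peri["chrom"] == chrom, ["start", "end"]].iloc[0]
        span = region_spec.regions_per_block * region_spec.step_bp + region_spec.region_bp
        for b in range(region_spec.blocks_per_chrom):
            center = int((b + 0.5) / region_spec.blocks_per_chrom * total_bp)
            block_start = max(0, center - span // 2)
            in_peri = p_lo <= center < p_hi
            seg_p = region_spec.seg_prob_peri if in_peri else region_spec.seg_prob_arm
            segregating = rng.random() < seg_p
            meth_p = region_spec.meth_prob_peri if in_peri else region_spec.meth_prob_arm
            base_state = 1 if segregating else int(rng.random() < meth_p)
            context = rng.choice(region_spec.contexts, p=region_spec.context_probs)
            nearest = mids[np.argmin(np.abs(mpos - center))] if len(mpos) else ""
            for j in range(region_spec.regions_per_block):
                start = block_start + j * region_spec.step_bp
                rid += 1
                rows.append(
                    {
                        "region_id": f"R{rid:05d}",
                        "chrom": chrom,
                        "start": start,
                        "end": start + region_spec.region_bp,
                        "context": context,
                        "peri": bool(in_peri),
                        "nearest_marker": nearest,
                        "segregating": bool(segregating),
                        "base_state": base_state,
                    }
                )
    return pd.DataFrame(rows)


def default_planted_qtl(
    epihap_map: EpihaplotypeMap,
    regions: pd.DataFrame,
    n_qtl: int = 3,
    targets_per_qtl: int = 8,
    penetrance: float = 0.8,
) -> tuple:
    """Choose pericentromeric controller markers and distal target regions.

    For each of ``n_qtl`` chromosomes, the marker closest to the chromosome
    midpoint (a pericentromeric DMR) controls ``targets_per_qtl`` regions:
    one local block near the marker and distal blocks, some on other
    chromosomes, mirroring the mapped local-plus-distal architecture.
    Deterministic given the map and region table.
    """
    markers = epihap_map.markers
    chroms = list(dict.fromkeys(markers["chrom"]))[:n_qtl]
    peri_regions = regions[regions["peri"]]
    used: set = set()
    planted = []
    for ci, chrom in enumerate(chroms):
        msub = markers[markers["chrom"] == chrom]
        mid_cm = msub["cM"].max() / 2.0
        marker = msub.iloc[(msub["cM"] - mid_cm).abs().argsort().iloc[0]]
        local = peri_regions[
            (peri_regions["chrom"] == chrom)
            & ~peri_regions["region_id"].isin(used)
        ]
        n_local = max(1, targets_per_qtl // 2)
        local_ids = list(local["region_id"].iloc[:n_local])
        distal = peri_regions[
            (peri_regions["chrom"] != chrom)
            & ~peri_regions["region_id"].isin(used | set(local_ids))
        ]
        distal_ids = list(distal["region_id"].iloc[: targets_per_qtl - n_local])
        sign = 1 if ci % 2 == 0 else -1
        targets = tuple(local_ids + distal_ids)
        used.update(targets)
        planted.append(
            PlantedQtl(
                marker_id=marker["marker_id"],
                target_region_ids=targets,
                effect_sign=sign,
                penetrance=penetrance,
            )
        )
    return tuple(planted)


def simulate_trio_methylomes(
    epihap_map: EpihaplotypeMap,
    regions: pd.DataFrame,
    planted_qtl: tuple = (),
    state_noise: float = 0.01,
    hybrid_noise: float = 0.0,
    seed: int = 0,
) -> TrioStates:
    """Generate parent and hybrid state calls for every region x family.

    Maternal (msCol) states are fixed per region.  Paternal epiRIL states
    follow the line's epigenotype at the nearest marker in segregating
    regions (U iff UU), plus a small call-noise flip rate.  Hybrid states
    default to the additive expectation (the mid-parent value mapped onto
    {U, I, M}); at planted target regions a TCM or TCdM event fires with
    probability ``penetrance``, with the direction set by the controlling
    marker's epigenotype and the configured effect sign.  ``hybrid_noise``
    adds background non-additive events at random regions.
    """
    known = set(regions["region_id"])
    for q in planted_qtl:
        epihap_map.marker_row(q.marker_id)  # raises on unknown marker
        unknown = set(q.target_region_ids) - known
        if unknown:
            raise KeyError(f"unknown target region ids: {sorted(unknown)[:3]}")

    rng = substream(seed, "trios")
    lines = epihap_map.line_ids
    n_reg, n_lin = len(regions), len(lines)
    region_ids = regions["region_id"].to_numpy()
    mscol = regions["base_state"].to_numpy(dtype=float)

    # paternal states: segregating regions track the nearest marker
    epi = np.tile(mscol[:, None], (1, n_lin))
    seg_mask = regions["segregating"].to_numpy()
    geno = epihap_map.genotypes
    for i in np.flatnonzero(seg_mask):
        uu = (geno[regions["nearest_marker"].iat[i]] == "UU").to_numpy()
        epi[i, uu] = 0.0
    if state_noise > 0:
        flips = rng.random((n_reg, n_lin)) < state_noise
        epi = np.where(flips, 1.0 - epi, epi)

    mpv = (mscol[:, None] + epi) / 2.0
    hybrid = mpv.copy()  # additive expectation; states {0, 0.5, 1} directly

    events = []
    row_of = {r: i for i, r in enumerate(region_ids)}
    for q in planted_qtl:
        uu = (geno[q.marker_id] == "UU").to_numpy()
        fire = rng.random((len(q.target_region_ids), n_lin)) < q.penetrance
        for t, rid in enumerate(q.target_region_ids):
            i = row_of[rid]
            # positive sign: TCM in UU-parent families, TCdM in MM families
            gain = uu if q.effect_sign > 0 else ~uu
            for j in np.flatnonzero(fire[t]):
                delta = 0.5 if gain[j] else -0.5
                new = hybrid[i, j] + delta
                if 0.0 <= new <= 1.0:
                    hybrid[i, j] = new
                    events.append(
                        {
                            "region_id": rid,
                            "line": lines[j],
                            "marker_id": q.marker_id,
                            "kind": "TCM" if delta > 0 else "TCdM",
                        }
                    )
    if hybrid_noise > 0:
        noise = rng.random((n_reg, n_lin)) < hybrid_noise
        delta = np.where(rng.random((n_reg, n_lin)) < 0.5, 0.5, -0.5)
        cand = hybrid + delta
        ok = noise & (cand >= 0.0) & (cand <= 1.0)
        hybrid = np.where(ok, cand, hybrid)

    return TrioStates(
        regions=regions.reset_index(drop=True),
        mscol=pd.Series(mscol, index=region_ids, name="msCol"),
        epiril=pd.DataFrame(epi, index=region_ids, columns=lines),
        hybrid=pd.DataFrame(hybrid, index=region_ids, columns=lines),
        events=pd.DataFrame(events, columns=["region_id", "line", "marker_id", "kind"]),
    )


# ---------------------------------------------------------------------------
# phenotypes and counts
# ---------------------------------------------------------------------------


def default_pheno_qtl(epihap_map: EpihaplotypeMap, n_qtl: int = 3,
                      effect_mph: float = 2.7) -> tuple:
    """Phenotype QTL at the same mid-chromosome markers as the planted
    methylation QTL, each adding ``effect_mph`` points of MPH to MM-parent
    families.  Three such loci jointly explain roughly 12% of the
    between-family MPH variance under the default variance components."""
    markers = epihap_map.markers
    chroms = list(dict.fromkeys(markers["chrom"]))[:n_qtl]
    out = []
    for chrom in chroms:
        msub = markers[markers["chrom"] == chrom]
        mid_cm = msub["cM"].max() / 2.0
        marker = msub.iloc[(msub["cM"] - mid_cm).abs().argsort().iloc[0]]
        out.append(PhenoQtl(marker_id=marker["marker_id"], effect_mph=effect_mph))
    return tuple(out)


def simulate_phenotypes(
    epihap_map: EpihaplotypeMap,
    pheno_qtl: tuple = (),
    n_sibs: int = 18,
    family_var: float = 30.0,
    residual_var: float = 70.0,
    grand_mean: float = 100.0,
    parent_divergence_sd: float = 5.0,
    covariate_effects: dict | None = None,
    n_experiments: int = 3,
    n_blocks: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plant phenotype table for parents and hybrids of every family.

    A plant's value is grand mean + fixed covariate effects (experiment,
    block, germination date) + group mean + residual.  The F1 group mean is
    the family mid-parent value scaled by ``1 + MPH/100``, where the
    family's expected MPH is the sum of marker effects (``effect_mph`` for
    MM-parent families) and a Gaussian family effect with variance
    ``family_var``.  Plant residuals are scaled so that plant-level MPH
    replicates have variance ``residual_var``; the between-family share of
    MPH variance is therefore family_var / (family_var + residual_var)
    before marker effects.
    """
    if n_sibs < 1:
        raise ValueError("n_sibs must be >= 1")
    if family_var < 0 or residual_var < 0:
        raise ValueError("variance components must be >= 0")
    rng = substream(seed, "phenotypes")
    lines = epihap_map.line_ids
    n_fam = len(lines)
    geno = epihap_map.genotypes

    cov_eff = covariate_effects or {
        "experiment": [0.0, 1.5, -1.5],
        "block": [0.0] * n_blocks,
        "germination_date": [0.0, 1.0, -1.0, 0.5, -0.5],
    }
    exp_eff = np.asarray(cov_eff["experiment"], dtype=float)
    blk_eff = np.asarray(cov_eff["block"], dtype=float)
    germ_eff = np.asarray(cov_eff["germination_date"], dtype=float)

    mscol_mean = grand_mean
    epi_shift = rng.normal(0.0, parent_divergence_sd, n_fam)  # % of grand mean
    epi_mean = grand_mean * (1.0 + epi_shift / 100.0)
    mpv = (mscol_mean + epi_mean) / 2.0

    mph = rng.normal(0.0, np.sqrt(family_var), n_fam)
    for q in pheno_qtl:
        mm = (geno[q.marker_id] == "MM").to_numpy()
        mph = mph + q.effect_mph * mm.astype(float)
    f1_mean = mpv * (1.0 + mph / 100.0)

    resid_sd = grand_mean * np.sqrt(residual_var) / 100.0
    rows = []
    pid = 0
    for f, line in enumerate(lines):
        for group, mean in (("msCol", mscol_mean), ("epiRIL", epi_mean[f]),
                            ("F1", f1_mean[f])):
            for s in range(n_sibs):
                pid += 1
                exp = int(rng.integers(len(exp_eff)))
                blk = int(rng.integers(len(blk_eff)))
                germ = int(rng.integers(len(germ_eff)))
                value = (
                    mean
                    + exp_eff[exp]
                    + blk_eff[blk]
                    + germ_eff[germ]
                    + rng.normal(0.0, resid_sd)
                )
                rows.append(
                    {
                        "plant_id": f"P{pid:06d}",
                        "family_id": line,
                        "group": group,
                        "value": value,
                        "experiment": f"E{exp + 1}",
                        "block": f"B{blk + 1}",
                        "germination_date": f"G{germ + 1}",
                    }
                )
    return pd.DataFrame(rows)


def _nb_draw(rng, mean, dispersion):
    """Negative-binomial draw with mean ``mean`` and NB2 dispersion.

    var = mean + dispersion * mean^2; zero mean yields zero counts.
    """
    mean = np.asarray(mean, dtype=float)
    size = 1.0 / dispersion
    p = np.where(mean > 0, size / (size + mean), 1.0)
    return rng.negative_binomial(size, p)


def simulate_counts(
    states: pd.DataFrame,
    multipliers: dict,
    base_mean: float = 50.0,
    dispersion: float = 0.1,
    library_factors: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count matrix coupled to methylation states.

    ``states`` is features x samples with values in {0, 0.5, 1};
    ``multipliers`` maps state -> mean multiplier (e.g. ``{0: 1, 0.5: 2,
    1: 4}`` for 24-nt sRNA that scales with methylation; invert the
    mapping for expression repressed by methylation).  ``library_factors``
    optionally scales per-sample sequencing depth.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if any(m < 0 for m in multipliers.values()):
        raise ValueError("multipliers must be >= 0")
    rng = substream(seed, "counts")
    mult = np.vectorize(lambda s: multipliers[float(s)])(states.to_numpy())
    mean = base_mean * mult
    if library_factors is not None:
        mean = mean * library_factors.reindex(states.columns).to_numpy()[None, :]
    counts = _nb_draw(rng, mean, dispersion)
    return pd.DataFrame(counts, index=states.index, columns=states.columns)


def state_multipliers(mult_m: float, direction: int = 1) -> dict:
    """Multiplier table for the three states, geometric in the state.

    ``direction=+1`` makes methylated features high (sRNA coupling);
    ``direction=-1`` makes unmethylated features high (expression
    silenced by methylation)."""
    if mult_m <= 0:
        raise ValueError("multiplier must be positive")
    m = mult_m if direction > 0 else 1.0 / mult_m
    return {0.0: 1.0, 0.5: float(np.sqrt(m)), 1.0: float(m)}
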