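"""Quantitative (epi)genetic decomposition of the epihybrid QTL contrast.

In the asymmetrical cross design (every epiRIL crossed to the same
recurrent wild-type parent, phenotype defined as divergence from the
mid-parent value) the QTL contrast at a focal locus l,

    QTL_F1,l = E(z | l = MM) - E(z | l = UU),

mixes the locus's dominance effect with aggregate epistatic interactions
between the locus and the epigenomic background.  After integrating out
the unknown background MM frequency p and collapsing N-scaled background
effects into single aggregate coefficients, the contrast is

    QTL_F1,l = 2 b_D - 1/2 b_AxA + 2 b_AxD - 2 b_DxA,

where b_D is the focal dominance effect and b_AxA, b_AxD, b_DxA are the
aggregate additive x additive, additive x dominance and dominance x
additive background interactions (the dominance x dominance term drops
out of the integrated form).  The module provides the closed form, the
quadrature utility used to integrate over p, and a forward population
simulator that evaluates the contrast empirically from an explicit
genotype-phenotype map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from ._rng import substream

__all__ = [
    "QuantGenEffects",
    "EffectsMap",
    "qtl_contrast_closed_form",
    "integrate_over_p",
    "contrast_forward_sim",
]


@dataclass(frozen=True)
class QuantGenEffects:
    """Aggregate effect coefficients of the integrated QTL contrast."""

    beta_d: float = 0.0
    beta_axa: float = 0.0
    beta_axd: float = 0.0
    beta_dxa: float = 0.0
    beta_dxd: float = 0.0  # absent from the integrated contrast
    p: float = 0.5
    n_background: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n_background < 0:
            raise ValueError("N must be >= 0")


def qtl_contrast_closed_form(effects: QuantGenEffects) -> float:
    """The p-integrated QTL contrast.

    2 b_D - 1/2 b_AxA + 2 b_AxD - 2 b_DxA; linear in every coefficient,
    with no dominance x dominance term by construction.
    """
    return (
        2.0 * effects.beta_d
        - 0.5 * effects.beta_axa
        + 2.0 * effects.beta_axd
        - 2.0 * effects.beta_dxa
    )


def integrate_over_p(integrand, tol: float = 1e-12) -> float:
    """Numerical integral of ``integrand(p)`` over p in [0, 1].

    Gauss-Kronrod quadrature; exact to ``tol`` for the polynomial
    integrands that arise from the contrast."""
    value, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=tol, epsrel=tol)
    return value


@dataclass(frozen=True)
class EffectsMap:
    """Explicit genotype-phenotype map for the forward simulator.

    Loci are coded by M-allele count g in {0 (UU), 1 (MU), 2 (MM)} with
    additive score x_A = g - 1 and dominance indicator x_D = 1[g == 1].
    The phenotype is

        y = sum_l a_l x_A(l) + d_l x_D(l)
            + sum_j!=focal  aa x_A(f) x_A(j) + ad x_A(f) x_D(j)
                          + da x_D(f) x_A(j) + dd x_D(f) x_D(j),

    i.e. per-locus additive and dominance effects plus pairwise
    interactions between the focal locus and each background locus with
    shared coefficients (equal effect sizes across the background).
    """

    additive: tuple = ()  # a_l, focal first
    dominance: tuple = ()  # d_l, focal first
    aa: float = 0.0
    ad: float = 0.0
    da: float = 0.0
    dd: float = 0.0
    residual_sd: float = 0.0


def _phenotype(g: np.ndarray, eff: EffectsMap, rng=None) -> np.ndarray:
    """Evaluate the map on genotype matrix g (individuals x loci)."""
    x_a = g - 1.0
    x_d = (g == 1).astype(float)
    a = np.asarray(eff.additive, dtype=float)
    d = np.asarray(eff.dominance, dtype=float)
    y = x_a @ a + x_d @ d
    if g.shape[1] > 1:
        bg_a = x_a[:, 1:].sum(axis=1)
        bg_d = x_d[:, 1:].sum(axis=1)
        y = y + (
            eff.aa * x_a[:, 0] * bg_a
            + eff.ad * x_a[:, 0] * bg_d
            + eff.da * x_d[:, 0] * bg_a
            + eff.dd * x_d[:, 0] * bg_d
        )
    if eff.residual_sd > 0 and rng is not None:
        y = y + rng.normal(0.0, eff.residual_sd, y.shape[0])
    return y


def contrast_forward_sim(
    effects_map: EffectsMap, p: float, n_lines: int, seed: int = 0
) -> dict:
    """Empirical QTL contrast from a simulated epihybrid population.

    EpiRIL parents are epihomozygous: the focal locus is MM or UU with
    probability 1/2 each, background loci are MM with probability ``p``.
    F1s carry one M allele from the recurrent wild-type parent at every
    locus (so a UU parental locus becomes MU in the F1).  The heterosis
    value is z = y_F1 - mid with mid = (y_wt + y_epiRIL) / 2, and the
    contrast is the MM-vs-UU difference of the conditional means of z.

    Returns the contrast with its standard error, the conditional means
    of z and of mid, and the class sizes.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    n_loci = len(effects_map.additive)
    if n_loci < 1 or len(effects_map.dominance) != n_loci:
        raise ValueError("additive and dominance effect tuples must align")
    rng = substream(seed, "quantgen_forward")
    focal_mm = rng.random(n_lines) < 0.5
    if focal_mm.all() or not focal_mm.any():
        raise ValueError("n_lines too small: need both focal classes")
    g_epi = np.empty((n_lines, n_loci))
    g_epi[:, 0] = np.where(focal_mm, 2.0, 0.0)
    if n_loci > 1:
        g_epi[:, 1:] = np.where(rng.random((n_lines, n_loci - 1)) < p, 2.0, 0.0)
    g_wt = np.full_like(g_epi, 2.0)
    g_f1 = (g_epi + g_wt) / 2.0  # MM stays 2, UU becomes heterozygous (1)
    y_epi = _phenotype(g_epi, effects_map, rng)
    y_wt = _phenotype(g_wt, effects_map, rng)
    y_f1 = _phenotype(g_f1, effects_map, rng)
    mid = (y_wt + y_epi) / 2.0
    z = y_f1 - mid
    z_mm, z_uu = z[focal_mm], z[~focal_mm]
    contrast = float(z_mm.mean() - z_uu.mean())
    se = float(
        np.sqrt(z_mm.var(ddof=1) / z_mm.size + z_uu.var(ddof=1) / z_uu.size)
    )
    return {
        "contrast": contrast,
        "se": se,
        "mean_z_mm": float(z_mm.mean()),
        "mean_z_uu": float(z_uu.mean()),
        "mean_mid_mm": float(mid[focal_mm].mean()),
        "mean_mid_uu": float(mid[~focal_mm].mean()),
        "n_mm": int(z_mm.size),
        "n_uu": int(z_uu.size),
    }
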