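"""Independent oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: the
two-locus pedigree oracle enumerates the exact diplotype distribution
through the cross generation by generation, and the regression oracle
fits each marker by brute force.
"""

from itertools import product

import numpy as np

#: haplotypes over two loci; allele True = U (ddm1-derived)
_HAPS = [(a, b) for a in (True, False) for b in (True, False)]


def _gamete_dist(h1, h2, r):
    """P(gamete) from an ordered diplotype with recombination fraction r."""
    out = {}
    for start, other in ((h1, h2), (h2, h1)):
        for recomb, pr in ((False, 1 - r), (True, r)):
            g = (start[0], other[1]) if recomb else start
            out[g] = out.get(g, 0.0) + 0.5 * pr
    return out


def two_locus_pedigree_distribution(d_cm, n_ssd=6):
    """Exact terminal distribution of the epiRIL cross at two linked loci.

    F1 (one all-U, one all-M haplotype) is backcrossed to the all-M wild
    type, then selfed ``n_ssd`` times (each offspring = two independent
    gametes of its parent).  Returns a dict over ordered diplotypes
    ((hap1, hap2) pairs) before heterozygote resolution.
    """
    r = 0.5 * (1 - np.exp(-2 * d_cm / 100.0))
    f1 = ((True, True), (False, False))
    # backcross: gamete(F1) paired with the all-M wild-type gamete
    dist = {}
    for g, p in _gamete_dist(*f1, r).items():
        dist[(g, (False, False))] = dist.get((g, (False, False)), 0.0) + p
    for _ in range(n_ssd):
        nxt = {}
        for (h1, h2), p in dist.items():
            gd = _gamete_dist(h1, h2, r)
            for ga, pa in gd.items():
                for gb, pb in gd.items():
                    key = (ga, gb)
                    nxt[key] = nxt.get(key, 0.0) + p * pa * pb
        dist = nxt
    return dist


def two_locus_summary(d_cm, n_ssd=6):
    """Marginal UU probability, heterozygote fraction, and the correlation
    of the post-resolution UU indicators between the two loci."""
    dist = two_locus_pedigree_distribution(d_cm, n_ssd)
    r = 0.5 * (1 - np.exp(-2 * d_cm / 100.0))
    # heterozygous loci resolve along one further gamete draw, so linked
    # het loci resolve coherently
    p_uu = np.zeros(2)
    p_het = np.zeros(2)
    p_joint = 0.0
    for (h1, h2), p in dist.items():
        for locus in (0, 1):
            if h1[locus] != h2[locus]:
                p_het[locus] += p
        for g, pg in _gamete_dist(h1, h2, r).items():
            final = [
                h1[i] if h1[i] == h2[i] else g[i] for i in (0, 1)
            ]
            p_uu += p * pg * np.array(final, dtype=float)
            p_joint += p * pg * (final[0] and final[1])
    var = p_uu * (1 - p_uu)
    corr = (p_joint - p_uu[0] * p_uu[1]) / np.sqrt(var[0] * var[1])
    return {
        "p_uu": p_uu,
        "p_het": p_het,
        "corr_uu": float(corr),
    }


def marker_regression_lod(genotype_codes, trait):
    """Brute-force single-marker regression LOD for every marker column."""
    y = np.asarray(trait, dtype=float)
    n = y.size
    lods = []
    for j in range(genotype_codes.shape[1]):
        X = np.column_stack([np.ones(n), genotype_codes[:, j]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(np.sum((y - X @ beta) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        lods.append((n / 2.0) * np.log10(rss0 / rss1) if rss1 > 0 else np.inf)
    return np.array(lods)


def all_trio_state_combinations():
    """The 12 valid (msCol, epiRIL, hybrid) state combinations."""
    return [
        (ms, ep, hy)
        for ms, ep, hy in product((0.0, 1.0), (0.0, 1.0), (0.0, 0.5, 1.0))
    ]
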