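"""Causal model selection for QTL -> methylation -> expression triples.

For each candidate gene the epigenotype at the mapped QTL (Q, binary),
the mid-parent methylation divergence of the linked region (M) and the
gene's mid-parent expression divergence (E) are related through four
fixed Gaussian directed-acyclic-graph factorisations:

* i   saturated / no direction:  f(M | Q) f(E | Q, M)
* ii  independent effects:       f(M | Q) f(E | Q)
* iii expression-mediated:       f(E | Q) f(M | E)
* iv  methylation-mediated:      f(M | Q) f(E | M)

Each conditional is an ordinary least-squares Gaussian regression; the
model AIC is -2 log L + 2k over the summed conditionals.  The final call
is the modal minimum-AIC model over bootstrap resamples of the trios.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream

__all__ = ["MODELS", "fit_causal_models", "select_model", "bootstrap_select"]

MODELS = ("i", "ii", "iii", "iv")

#: regressor sets per model: (response, predictors) pairs
_STRUCTURES = {
    "i": (("M", ("Q",)), ("E", ("Q", "M"))),
    "ii": (("M", ("Q",)), ("E", ("Q",))),
    "iii": (("E", ("Q",)), ("M", ("E",))),
    "iv": (("M", ("Q",)), ("E", ("M",))),
}

#: tie-break preference: fewer parameters first, then fixed order
_TIE_ORDER = ("ii", "iii", "iv", "i")

#: default competition set: the three directed relationships; the
#: saturated no-direction model i is fitted and reported but nests the
#: others and is excluded from selection by default
DEFAULT_CANDIDATES = ("ii", "iii", "iv")


def _ols_loglik(y, X):
    """Gaussian OLS log-likelihood at the MLE and its parameter count."""
    Xd = np.column_stack([np.ones(y.size), X]) if X is not None else np.ones((y.size, 1))
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    s2 = float(resid @ resid) / y.size
    # absolute floor: a numerically perfect conditional contributes the
    # same (large) likelihood in every model instead of comparing noise
    s2 = max(s2, 1e-12)
    ll = -0.5 * y.size * (np.log(2 * np.pi * s2) + 1.0)
    return ll, Xd.shape[1] + 1  # coefficients + error variance


def fit_causal_models(Q, M, E) -> dict:
    """Log-likelihood, parameter count and AIC for each of the four models.

    Returns ``{model: {"loglik", "k", "aic"}}``.
    """
    Q = np.asarray(Q, dtype=float)
    M = np.asarray(M, dtype=float)
    E = np.asarray(E, dtype=float)
    if not (Q.size == M.size == E.size) or Q.size < 10:
        raise ValueError("Q, M, E must have equal length >= 10")
    if np.std(M) == 0 or np.std(E) == 0:
        raise ValueError("constant M or E")
    data = {"Q": Q, "M": M, "E": E}
    out = {}
    for model, parts in _STRUCTURES.items():
        ll_tot, k_tot = 0.0, 0
        for resp, preds in parts:
            X = np.column_stack([data[p] for p in preds])
            ll, k = _ols_loglik(data[resp], X)
            ll_tot += ll
            k_tot += k
        out[model] = {"loglik": ll_tot, "k": k_tot, "aic": -2.0 * ll_tot + 2.0 * k_tot}
    return out


def select_model(fits: dict, candidates=None, tol: float = 1e-9) -> str:
    """Minimum-AIC model among ``candidates`` (defaults to the keys of
    ``fits`` intersected with the directed models); ties within ``tol``
    go to the simpler model, then to the fixed order ii < iii < iv < i."""
    if candidates is None:
        candidates = [m for m in fits if m in DEFAULT_CANDIDATES] or list(fits)
    best_aic = min(fits[m]["aic"] for m in candidates)
    tied = [m for m in candidates if fits[m]["aic"] <= best_aic + tol]
    tied.sort(key=lambda m: (fits[m]["k"], _TIE_ORDER.index(m)))
    return tied[0]


def bootstrap_select(Q, M, E, n_boot: int = 1000, seed: int = 0,
                     candidates=DEFAULT_CANDIDATES, max_retries: int = 100) -> dict:
    """Modal minimum-AIC model over bootstrap resamples of the trios.

    Selection is restricted to ``candidates`` (by default the three
    directed relationships ii-iv).  Degenerate resamples (constant Q, M
    or E) are redrawn up to ``max_retries`` times each.  Returns the
    selected model, its support (modal frequency) and the full
    selection-frequency table (sums to 1).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    Q = np.asarray(Q, dtype=float)
    M = np.asarray(M, dtype=float)
    E = np.asarray(E, dtype=float)
    n = Q.size
    rng = substream(seed, "bootstrap_select")
    votes = {m: 0 for m in MODELS}
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            q, m_, e = Q[idx], M[idx], E[idx]
            if np.std(q) > 0 and np.std(m_) > 0 and np.std(e) > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        votes[select_model(fit_causal_models(q, m_, e), candidates)] += 1
    freqs = {m: votes[m] / n_boot for m in candidates}
    selected = max(
        candidates, key=lambda m: (freqs[m], -_TIE_ORDER.index(m))
    )
    return {"selected": selected, "support": freqs[selected], "frequencies": freqs}
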