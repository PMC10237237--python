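"""Supervised admixture: ancestry fractions by maximum likelihood.

Per-breed allele frequencies F are fixed from labelled purebred training
animals ("projection" mode: the frequencies are frozen, they are not
re-estimated from the animals being predicted).  Each animal's ancestry
vector q on the K-simplex then maximises the binomial likelihood

    LL(q) = sum_j [ g_j ln(sum_k q_k f_kj) + (2 - g_j) ln(sum_k q_k (1 - f_kj)) ]

which is concave in q for fixed F, so the EM iteration below converges to
the global optimum from the uniform start; the log-likelihood never
decreases.  Downstream, the same post-processing and assignment rules as
SNP-BLUP apply (zero < 0.05, rescale, assign at >= 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING
from .simdata import AlleleFrequencyTable

#: frequency clamp keeping the likelihood finite
EPS = 1e-6


@dataclass
class AdmixtureModel:
    """Frozen reference frequencies for K ancestral breeds."""

    freqs: np.ndarray  # (K, m), entries in [EPS, 1 - EPS]
    breeds: list[str]
    marker_ids: pd.Index

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape[0] != len(self.breeds):
            raise ValueError("one frequency row per breed required")
        if self.freqs.shape[1] != len(self.marker_ids):
            raise ValueError("one frequency column per marker required")
        self.freqs = np.clip(self.freqs, EPS, 1.0 - EPS)

    @property
    def K(self) -> int:
        return len(self.breeds)


@dataclass
class AncestryEstimate:
    q: np.ndarray  # (n, K) on the simplex
    loglik: np.ndarray  # (n,) final log-likelihood per animal
    iterations: np.ndarray  # (n,)
    converged: np.ndarray  # (n,) bool


def estimate_breed_frequencies(
    g: GenotypeMatrix, labels: pd.Series | None = None
) -> AdmixtureModel:
    """Observed allele frequencies of labelled purebreds, clamped to
    [EPS, 1 - EPS]; breeds ordered by first appearance."""
    if labels is None:
        labels = g.samples["breed"]
    labels = labels.astype(str)
    if (g.genotypes == MISSING).any():
        raise ValueError("missing genotypes: run qc_filter first")
    breeds = list(pd.unique(labels))
    rows = []
    for b in breeds:
        sub = g.genotypes[(labels == b).to_numpy()]
        if len(sub) == 0:
            raise ValueError(f"breed {b!r} has no animals")
        rows.append(sub.mean(axis=0) / 2.0)
    return AdmixtureModel(np.array(rows), breeds, g.marker_ids)


def admixture_loglik(
    g: np.ndarray, q: np.ndarray, model: AdmixtureModel
) -> np.ndarray:
    """Binomial log-likelihood of genotypes under mixture frequencies q'F.

    Accepts a single genotype/q vector or stacked rows; returns one value
    per animal.
    """
    single = np.asarray(g).ndim == 1
    G = np.atleast_2d(np.asarray(g, dtype=float))
    Q = np.atleast_2d(np.asarray(q, dtype=float))
    F = model.freqs
    a = Q @ F  # (n, m) mixture frequency of the counted allele
    ll = (G * np.log(a) + (2.0 - G) * np.log1p(-a)).sum(axis=1)
    return ll[0] if single else ll


def fit_admixture_em(
    g: np.ndarray,
    model: AdmixtureModel,
    tol: float = 1e-6,
    max_iter: int = 2000,
    check_monotone: bool = True,
) -> AncestryEstimate:
    """Estimate ancestry fractions for one or many animals by EM.

    Starts from the uniform q = (1/K, ..., 1/K); stops per animal once the
    log-likelihood improves by less than ``tol`` (or at ``max_iter``, with
    ``converged=False``).  ``check_monotone`` asserts the EM ascent property
    each iteration.
    """
    single = np.asarray(g).ndim == 1
    G = np.atleast_2d(np.asarray(g, dtype=float))
    n, m = G.shape
    F = model.freqs  # (K, m)
    K = model.K
    if m != F.shape[1]:
        raise ValueError("genotype length does not match model markers")

    Q = np.full((n, K), 1.0 / K)
    ll = admixture_loglik(G, Q, model)
    iters = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    active = np.arange(n)
    G2 = 2.0 - G

    for _ in range(max_iter):
        if active.size == 0:
            break
        Qa = Q[active]
        Ga, G2a = G[active], G2[active]
        A = Qa @ F  # (na, m)
        Bm = 1.0 - A
        # E-step responsibilities folded into the multiplicative update
        upd = (Ga / A) @ F.T + (G2a / Bm) @ (1.0 - F).T
        Qn = Qa * upd / (2.0 * m)
        Qn /= Qn.sum(axis=1, keepdims=True)  # guard simplex drift
        ll_new = admixture_loglik(Ga, Qn, model)
        if check_monotone and not np.all(ll_new >= ll[active] - 1e-8):
            raise AssertionError("EM log-likelihood decreased")
        Q[active] = Qn
        done = ll_new - ll[active] < tol
        ll[active] = ll_new
        iters[active] += 1
        converged[active[done]] = True
        active = active[~done]

    est = AncestryEstimate(Q, ll, iters, converged)
    if single:
        est = AncestryEstimate(Q[0], ll[:1], iters[:1], converged[:1])
    return est
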