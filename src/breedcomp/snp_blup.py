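"""SNP-BLUP breed-composition prediction.

Breed composition is predicted one breed at a time with a ridge-type mixed
model.  For the breed under investigation, its training animals get a
dependent variable y = 1 and an equal number of animals drawn as evenly as
possible from the other breeds get y = 0; every SNP is fitted as a random
effect with common variance.  With heritability h2 = 0.999 and the total
genetic variance split equally over the m SNPs, the ridge parameter is

    lambda = m (1 - h2) / h2

independent of the phenotypic variance p*q (p = fraction of coded animals
of the target breed), which cancels out of the mixed-model equations.
Predicted raw scores (intercept + allele counts times effects) are then
clamped at zero, small values (< 0.05) zeroed, and the rest rescaled to sum
to one; a purebred is *assigned* when one breed reaches 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"

#: breed proportions below this are zeroed before rescaling
MIN_PROPORTION = 0.05

#: purebred assignment threshold (inclusive)
ASSIGN_THRESHOLD = 0.90


class SizingError(ValueError):
    """Too few animals in some breed to build a balanced coding."""


@dataclass
class VarianceComponents:
    """Variance bookkeeping for one breed's fit.

    ``p`` is the fraction of coded animals that carry y = 1; the phenotypic
    variance of the 1/0 trait is p*q.  ``lambda_mode="per-snp"`` divides the
    genetic variance over the m SNPs (lambda = m(1-h2)/h2, the default);
    ``"total"`` puts the whole genetic variance on each SNP
    (lambda = (1-h2)/h2), which leaves the system nearly unregularised.
    """

    p: float
    m: int
    h2: float = 0.999
    lambda_mode: str = "per-snp"

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be strictly between 0 and 1")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be strictly between 0 and 1")
        if self.m < 1:
            raise ValueError("need at least one SNP")
        if self.lambda_mode not in ("per-snp", "total"):
            raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def var_phenotypic(self) -> float:
        return self.p * self.q

    @property
    def var_genetic(self) -> float:
        return self.h2 * self.var_phenotypic

    @property
    def var_residual(self) -> float:
        return (1.0 - self.h2) * self.var_phenotypic

    @property
    def ridge(self) -> float:
        lam = (1.0 - self.h2) / self.h2
        return lam * self.m if self.lambda_mode == "per-snp" else lam


@dataclass
class BreedCodingDesign:
    """Balanced 1/0 coding for one target breed."""

    target: str
    sample_ids: list[str]
    y: np.ndarray  # 1/0 per coded animal
    zero_set_counts: dict[str, int]  # non-target breed -> animals coded 0

    @property
    def n_ones(self) -> int:
        return int(self.y.sum())

    @property
    def n_zeros(self) -> int:
        return int((1 - self.y).sum())


@dataclass
class SNPEffects:
    target: str
    intercept: float
    effects: np.ndarray  # (m,)
    marker_ids: pd.Index


def build_breed_coding(
    labels: pd.Series, target: str, seed: int | None = None
) -> BreedCodingDesign:
    """Balanced per-breed coding of the training population.

    All n_t target-breed animals are coded 1; n_t animals coded 0 are drawn
    across the other B-1 breeds with per-breed counts differing by at most
    one (the breeds receiving the remainder are chosen at random, seeded).
    Animals outside the coding are simply excluded from the fit.
    """
    labels = labels.astype(str)
    breeds = list(pd.unique(labels))
    if target not in breeds:
        raise SizingError(f"no training animals for target breed {target!r}")
    others = [b for b in breeds if b != target]
    if not others:
        raise SizingError("need at least two breeds to build a coding")
    rng = np.random.default_rng(seed)

    ones = labels.index[labels == target].tolist()
    n_t = len(ones)
    base, rem = divmod(n_t, len(others))
    counts = {b: base for b in others}
    for b in rng.permutation(others)[:rem]:
        counts[b] += 1
    zeros: list[str] = []
    for b in others:
        pool = labels.index[labels == b].to_numpy()
        if len(pool) < counts[b]:
            raise SizingError(
                f"breed {b!r} has {len(pool)} training animals, "
                f"needs {counts[b]} for the zero set of {target!r}"
            )
        zeros += list(rng.choice(pool, size=counts[b], replace=False))
    y = np.concatenate([np.ones(n_t), np.zeros(len(zeros))])
    return BreedCodingDesign(target, ones + zeros, y, counts)


def fit_snp_blup(
    X: np.ndarray,
    y: np.ndarray,
    vc: VarianceComponents,
    target: str = "",
    marker_ids: pd.Index | None = None,
    force_form: str | None = None,
) -> SNPEffects:
    """Solve the mixed-model equations for the intercept and SNP effects.

    X is the raw 0/1/2 allele-count matrix of the coded animals (no
    centering or standardisation).  Eliminating the unpenalised intercept
    gives the ridge system (Xc' Xc + lambda I) g = Xc' yc on column-centered
    data; it is solved in its primal (m x m) form when m <= n and in the
    dual (n x n) kernel form otherwise — the two agree to ~1e-8 relative.
    A zero-contrast y (all equal) returns g = 0 with the intercept at the
    mean rather than failing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if m != vc.m:
        raise ValueError(f"X has {m} SNPs but variance components expect {vc.m}")
    ids = marker_ids if marker_ids is not None else pd.RangeIndex(m)
    if np.ptp(y) == 0:
        return SNPEffects(target, float(y.mean()), np.zeros(m), ids)
    lam = vc.ridge
    xbar = X.mean(axis=0)
    Xc = X - xbar
    yc = y - y.mean()
    form = force_form or ("primal" if m <= n else "dual")
    if form == "primal":
        A = Xc.T @ Xc
        A[np.diag_indices(m)] += lam
        g = np.linalg.solve(A, Xc.T @ yc)
    elif form == "dual":
        K = Xc @ Xc.T
        K[np.diag_indices(n)] += lam
        g = Xc.T @ np.linalg.solve(K, yc)
    else:
        raise ValueError(f"unknown solver form {form!r}")
    mu = float(y.mean() - xbar @ g)
    return SNPEffects(target, mu, g, ids)


def predict_raw_scores(
    effects: list[SNPEffects],
    X: np.ndarray,
    marker_ids: pd.Index,
    include_intercept: bool = False,
) -> np.ndarray:
    """Raw per-breed scores: SNP effects multiplied by allele counts.

    The effect vectors must be defined on a subset of the genotyped markers;
    genotypes are aligned to each effect's marker ids.  The default omits
    the fitted intercept — the score is literally the sum of allele counts
    times effects, which places off-target purebreds *below* zero on
    average so clamping and the 0.05 threshold silence them; with
    ``include_intercept=True`` purebred training-animal scores center on 1
    (target breed) and 0 (others) instead.
    """
    X = np.asarray(X, dtype=float)
    scores = np.empty((X.shape[0], len(effects)))
    for b, eff in enumerate(effects):
        if not eff.marker_ids.equals(marker_ids):
            cols = marker_ids.get_indexer(eff.marker_ids)
            if (cols < 0).any():
                raise KeyError(
                    f"effects for breed {eff.target!r} use markers absent from "
                    "the genotype matrix"
                )
            Xb = X[:, cols]
        else:
            Xb = X
        scores[:, b] = Xb @ eff.effects
        if include_intercept:
            scores[:, b] += eff.intercept
    return scores


def postprocess_composition(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp, zero small values, rescale to the simplex.

    Order: (1) negatives to 0; (2) values below 0.05 to 0; (3) divide by the
    row sum.  Rows whose sum after zeroing is 0 are flagged unassignable and
    left all-zero.  Returns ``(processed, unassignable_mask)``.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.isfinite(raw).all():
        raise ValueError("raw scores must be finite")
    out = np.clip(raw, 0.0, None)
    out[out < MIN_PROPORTION] = 0.0
    sums = out.sum(axis=1)
    unassignable = sums == 0
    ok = ~unassignable
    out[ok] = out[ok] / sums[ok, None]
    return out, unassignable


def assign_breed(
    processed: np.ndarray,
    breeds: list[str],
    threshold: float = ASSIGN_THRESHOLD,
    unassignable: np.ndarray | None = None,
) -> pd.Series | str:
    """Assigned breed per animal: argmax iff its proportion >= threshold
    (boundary inclusive), else ``"unassigned"``."""
    single = np.asarray(processed).ndim == 1
    proc = np.atleast_2d(processed)
    best = proc.argmax(axis=1)
    ok = proc[np.arange(len(proc)), best] >= threshold
    if unassignable is not None:
        ok &= ~unassignable
    labels = np.where(ok, np.asarray(breeds, dtype=object)[best], UNASSIGNED)
    if single:
        return labels[0]
    return pd.Series(labels)
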