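"""Low-density SNP panel design.

Panels of a target density are drawn from the full map with per-chromosome
counts proportional to chromosome length (largest-remainder rounding), so
every selection strategy sees the same per-chromosome allocation.  SNP
informativeness scores come from a dedicated SNP-selection population,
never from training or validation animals, to avoid selection bias:

* ``fst`` — per-SNP fixation index across all breeds;
* ``pca_weight`` — eigenvalue-weighted sum of squared SNP loadings over the
  leading components of the standardized-genotype covariance (B-1
  components by default: what separates B breed clusters);
* ``snpblup_sd`` — standard deviation, across breeds, of each SNP's
  per-breed SNP-BLUP effect estimate;
* ``rf_vim`` — random-forest mean-decrease-in-impurity importance of a
  13-class breed classifier;
* ``plsda_weight`` — largest absolute one-vs-rest PLS regression
  coefficient across breeds (+1/-1 class coding).

Position-based tiling uses k-medoids on basepair positions; because the
positions are one-dimensional, optimal k-medoids clusters are contiguous
runs, and the implementation solves that restricted problem exactly by
dynamic programming (globally optimal, deterministic) rather than by a
build-and-swap local search.  No LD threshold or minimum spacing between
selected SNPs is imposed, deliberately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier

from ._utils import largest_remainder, spawn_rngs
from .genotype_io import GenotypeMatrix
from .snp_blup import VarianceComponents, build_breed_coding, fit_snp_blup

#: the panel densities evaluated in the emulated study design
DEFAULT_DENSITIES: list[int] = [100, 500, 1000, 2000, 3000, 5000, 7500]

#: the seven selection strategies compared head-to-head
DEFAULT_STRATEGIES: list[str] = [
    "random",
    "pam_medoid",
    "fst_highest",
    "pca_highest",
    "snpblup_sd_highest",
    "rf_highest",
    "plsda_highest",
]

SCORE_METHODS = ("fst", "pca_weight", "snpblup_sd", "rf_vim", "plsda_weight")

_STRATEGY_SCORE = {
    "fst": "fst",
    "pca": "pca_weight",
    "snpblup_sd": "snpblup_sd",
    "rf": "rf_vim",
    "plsda": "plsda_weight",
}


class SizingError(ValueError):
    pass


@dataclass
class PanelSpec:
    """An ordered SNP subset with its provenance."""

    strategy: str
    density: int
    marker_ids: list[str]
    per_chromosome: dict[int, int]

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("panel contains duplicate SNPs")
        if sum(self.per_chromosome.values()) != self.density:
            raise ValueError("per-chromosome counts do not sum to the density")


def allocate_per_chromosome(density: int, chrom_lengths) -> np.ndarray:
    """Per-chromosome SNP counts proportional to chromosome length.

    Largest-remainder rounding: floors first, then +1 to the largest
    fractional remainders (ties to the earlier chromosome).  Sums to
    ``density`` exactly.  Densities below the chromosome count leave some
    chromosomes empty (warned).
    """
    lengths = np.asarray(chrom_lengths, dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("total chromosome length must be positive")
    counts = largest_remainder(density, lengths)
    if (counts == 0).any() and density > 0:
        warnings.warn("density below chromosome count: some chromosomes get 0 SNPs")
    return counts


# ---------------------------------------------------------------------------
# 1-D k-medoids (exact, contiguous-interval DP)
# ---------------------------------------------------------------------------


def _kmedoids_1d(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact k-medoids on sorted 1-D data.

    Returns ``(labels, medoid_indices)``.  Clusters are contiguous; each
    cluster's medoid is its lower median (ties resolve to the lower
    position).  Globally minimises the summed absolute deviation.
    """
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])

    def cost(a: int, b: int) -> float:
        mid = (a + b) >> 1
        xm = x[mid]
        return (
            xm * (mid - a + 1)
            - (S[mid + 1] - S[a])
            + (S[b + 1] - S[mid])
            - xm * (b - mid + 1)
        )

    prev = np.array([cost(0, i) for i in range(n)])
    # args[j][i]: start index of the last cluster in the optimal (j+1)-cluster
    # partition of x[0..i]
    args = np.zeros((k, n), dtype=np.int64)
    for j in range(1, k):
        cur = np.full(n, np.inf)
        arg = np.zeros(n, dtype=np.int64)
        # divide & conquer over i using argmin monotonicity
        stack = [(j, n - 1, j, n - 1)]
        while stack:
            ilo, ihi, tlo, thi = stack.pop()
            if ilo > ihi:
                continue
            i = (ilo + ihi) >> 1
            best, bt = np.inf, tlo
            for t in range(tlo, min(thi, i) + 1):
                v = prev[t - 1] + cost(t, i)
                if v < best:
                    best, bt = v, t
            cur[i], arg[i] = best, bt
            stack.append((ilo, i - 1, tlo, bt))
            stack.append((i + 1, ihi, bt, thi))
        prev, args[j] = cur, arg

    labels = np.empty(n, dtype=np.int64)
    medoids = np.empty(k, dtype=np.int64)
    end = n - 1
    for j in range(k - 1, -1, -1):
        start = int(args[j][end]) if j > 0 else 0
        labels[start : end + 1] = j
        medoids[j] = (start + end) >> 1
        end = start - 1
    return labels, medoids


def pam_position_clusters(
    positions, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster one chromosome's SNP basepair positions into k groups.

    Returns ``(labels, medoid_indices)`` in the order of the supplied
    positions (which must be sorted ascending).  The medoid SNP sits in the
    middle of its cluster; LD plays no role.
    """
    x = np.asarray(positions, dtype=float)
    n = len(x)
    if k < 1 or k > n:
        raise SizingError(f"k={k} clusters for {n} positions")
    if (np.diff(x) < 0).any():
        raise ValueError("positions must be sorted ascending")
    return _kmedoids_1d(x, k)


# ---------------------------------------------------------------------------
# SNP scoring
# ---------------------------------------------------------------------------


def score_snps(
    method: str,
    g: GenotypeMatrix,
    labels: pd.Series | None = None,
    seed: int | None = None,
    n_components: int | None = None,
    n_trees: int = 500,
    pls_components: int = 10,
) -> np.ndarray:
    """One informativeness score per SNP from the SNP-selection population."""
    if method not in SCORE_METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    labels = (labels if labels is not None else g.samples["breed"]).astype(str)
    breeds = list(pd.unique(labels))
    X = g.genotypes.astype(float)
    lab = labels.to_numpy()

    if method == "fst":
        from .divergence import fst_per_snp

        freqs = np.array([X[lab == b].mean(axis=0) / 2.0 for b in breeds])
        return fst_per_snp(freqs).per_snp

    if method == "pca_weight":
        sd = X.std(axis=0)
        poly = sd > 0
        ncomp = n_components if n_components is not None else len(breeds) - 1
        ncomp = min(ncomp, int(poly.sum()) - 1, X.shape[0] - 1)
        Z = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
        v0 = np.full(min(Z.shape), 1.0 / np.sqrt(min(Z.shape)))  # deterministic
        _, s, Vt = svds(Z, k=ncomp, v0=v0)
        eigvals = s**2 / (X.shape[0] - 1)
        w = np.zeros(g.n_markers)
        w[poly] = (eigvals[:, None] * Vt**2).sum(axis=0)
        return w

    if method == "snpblup_sd":
        rngs = spawn_rngs(0 if seed is None else seed, len(breeds))
        eff = np.empty((len(breeds), g.n_markers))
        for b, breed in enumerate(breeds):
            design = build_breed_coding(
                labels, breed, seed=int(rngs[b].integers(2**31))
            )
            rows = g.sample_ids.get_indexer(design.sample_ids)
            vc = VarianceComponents(p=design.n_ones / len(design.y), m=g.n_markers)
            eff[b] = fit_snp_blup(X[rows], design.y, vc, target=breed).effects
        return eff.std(axis=0)

    if method == "rf_vim":
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=0 if seed is None else seed,
            n_jobs=1,
        )
        rf.fit(X, lab)
        return rf.feature_importances_

    # plsda_weight
    sd = X.std(axis=0)
    poly = sd > 0
    w = np.zeros(g.n_markers)
    Xp = X[:, poly]
    for breed in breeds:
        y = np.where(lab == breed, 1.0, -1.0)
        ncomp = min(pls_components, Xp.shape[0] - 1, int(poly.sum()))
        pls = PLSRegression(n_components=ncomp, scale=True)
        pls.fit(Xp, y)
        w[poly] = np.maximum(w[poly], np.abs(pls.coef_.ravel()))
    return w


def score_table(
    g: GenotypeMatrix,
    labels: pd.Series | None = None,
    methods=SCORE_METHODS,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Score table (one row per SNP, one column per method) plus chrom/pos."""
    tab = g.markers[["chrom", "pos"]].copy()
    for method in methods:
        tab[method] = score_snps(method, g, labels=labels, seed=seed, **kwargs)
    return tab


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


def _resolve_counts(density: int, markers: pd.DataFrame, chrom_lengths=None):
    chroms = list(pd.unique(markers["chrom"]))
    n_per = markers["chrom"].value_counts()
    if chrom_lengths is None:
        lengths = [markers.loc[markers["chrom"] == c, "pos"].max() for c in chroms]
    else:
        lengths = [chrom_lengths[c] for c in chroms]
    counts = allocate_per_chromosome(density, lengths)
    # cap chromosomes with too few SNPs and push the excess elsewhere
    counts = dict(zip(chroms, counts))
    while True:
        over = {c: counts[c] - n_per[c] for c in chroms if counts[c] > n_per[c]}
        if not over:
            break
        warnings.warn("panel density exceeds SNPs on some chromosome; reallocating")
        excess = sum(over.values())
        for c in over:
            counts[c] = int(n_per[c])
        spare = [c for c in chroms if counts[c] < n_per[c]]
        if not spare:
            raise SizingError("panel density exceeds the total SNP count")
        add = largest_remainder(
            excess, [lengths[chroms.index(c)] for c in spare]
        )
        for c, a in zip(spare, add):
            counts[c] += int(a)
    return counts


def select_panel(
    strategy: str,
    density: int,
    markers: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    chrom_lengths: dict[int, float] | None = None,
    seed: int | None = None,
) -> PanelSpec:
    """Build one panel by one strategy.

    Strategies: ``random``, ``pam_medoid``, and ``<score>_block`` /
    ``<score>_pam`` / ``<score>_highest`` for score in {fst, pca,
    snpblup_sd, rf, plsda}.  Blocks are contiguous equal-count runs of SNPs
    in map order (remainder SNPs go to the last blocks), one max-score SNP
    per block; the pam variant takes the max-score SNP per position
    cluster; highest takes the top-n per chromosome irrespective of
    position.  Score ties break to the lower basepair; random is seeded.
    """
    if density > len(markers):
        raise SizingError(f"density {density} exceeds {len(markers)} SNPs")
    score_col = None
    if strategy not in ("random", "pam_medoid"):
        stem, _, mode = strategy.rpartition("_")
        if mode not in ("block", "pam", "highest") or stem not in _STRATEGY_SCORE:
            raise ValueError(f"unknown strategy {strategy!r}")
        score_col = _STRATEGY_SCORE[stem]
        if scores is None or score_col not in scores:
            raise ValueError(f"strategy {strategy!r} needs a {score_col!r} score")
    counts = _resolve_counts(density, markers, chrom_lengths)
    rng = np.random.default_rng(seed)

    chosen: list[str] = []
    for c, cnt in counts.items():
        if cnt == 0:
            continue
        sub = markers[markers["chrom"] == c]
        ids = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if score_col is not None:
            sc = scores.loc[sub.index, score_col].to_numpy(dtype=float)

        if strategy == "random":
            chosen += list(ids[np.sort(rng.choice(len(ids), cnt, replace=False))])
        elif strategy == "pam_medoid":
            _, med = pam_position_clusters(pos, cnt)
            chosen += list(ids[med])
        else:
            mode = strategy.rpartition("_")[2]
            if mode == "highest":
                order = np.lexsort((pos, -sc))[:cnt]
                chosen += list(ids[np.sort(order)])
            elif mode == "block":
                q, r = divmod(len(ids), cnt)
                sizes = [q] * (cnt - r) + [q + 1] * r  # remainder to last blocks
                start = 0
                for size in sizes:
                    blk = slice(start, start + size)
                    chosen.append(ids[start + int(np.argmax(sc[blk]))])
                    start += size
            else:  # pam
                lab, _ = pam_position_clusters(pos, cnt)
                for cl in range(cnt):
                    members = np.flatnonzero(lab == cl)
                    chosen.append(ids[members[int(np.argmax(sc[members]))]])
    return PanelSpec(strategy, density, chosen, {c: int(v) for c, v in counts.items()})


def build_all_panels(
    g_selection: GenotypeMatrix,
    labels: pd.Series | None = None,
    densities=None,
    strategies=None,
    seed: int | None = None,
    chrom_lengths: dict[int, float] | None = None,
    scores: pd.DataFrame | None = None,
) -> list[PanelSpec]:
    """Panels for every strategy x density from the SNP-selection population.

    Scores are computed once (on the selection population only); the
    per-chromosome allocation at a given density is identical across
    strategies by construction.
    """
    densities = DEFAULT_DENSITIES if densities is None else densities
    strategies = DEFAULT_STRATEGIES if strategies is None else strategies
    needed = {
        _STRATEGY_SCORE[s.rpartition("_")[0]]
        for s in strategies
        if s not in ("random", "pam_medoid")
    }
    if needed and scores is None:
        scores = score_table(g_selection, labels=labels, methods=sorted(needed), seed=seed)
    panels = []
    for strategy in strategies:
        for density in densities:
            panels.append(
                select_panel(
                    strategy,
                    density,
                    g_selection.markers,
                    scores=scores,
                    chrom_lengths=chrom_lengths,
                    seed=seed,
                )
            )
    return panels
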