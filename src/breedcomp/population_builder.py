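"""Population construction: LD pruning, GRM PCA, purebred verification,
IBS-cluster training selection and crossbred validation assembly.

These reproduce the machinery used to establish clean study populations
from a raw genotype database: prune SNPs in strong LD before structure
analyses, verify recorded purebreds against a GRM-based PCA and an
ancestry threshold, spread training picks across identity-by-state
clusters so each breed's training set captures its diversity, and select
crossbred validation animals whose estimated compositions fall in defined
two- and three-way bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .genotype_io import GenotypeMatrix

#: default two-way composition bands (low1, high1, low2, high2) on the top
#: two breed fractions: 45-55:45-55, 20-30:70-80 and 70-80:20-30 collapse to
#: two unordered bands once fractions are sorted.
TWO_WAY_BANDS: list[tuple[float, float, float, float]] = [
    (0.45, 0.55, 0.45, 0.55),
    (0.70, 0.80, 0.20, 0.30),
]


@dataclass
class GRM:
    """Genomic relationship matrix (VanRaden method 1, observed frequencies)."""

    matrix: np.ndarray
    sample_ids: pd.Index
    n_snps_used: int


@dataclass
class IBSClustering:
    breed: str
    cluster_of: pd.Series  # sample id -> cluster index (1..k)
    representatives: list[str]  # one sample id per cluster


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.5, window: int = 50, step: int = 10
) -> pd.Index:
    """Sliding-window LD pruning; returns the retained marker ids.

    Within each 50-SNP window (sliding by 10, per chromosome), every pair of
    retained SNPs with squared Pearson correlation of allele counts above
    ``r2_max`` loses its higher-index member.  Monomorphic SNPs carry no LD
    signal and are never pruned here.
    """
    keep = np.ones(g.n_markers, dtype=bool)
    X = g.genotypes.astype(float)
    chrom = g.markers["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for start in range(0, len(idx), step):
            win = idx[start : start + window]
            if len(win) < 2:
                continue
            act = win[keep[win]]
            if len(act) < 2:
                continue
            sub = X[:, act]
            sd = sub.std(axis=0)
            ok = sd > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(sub[:, ok], rowvar=False)
            cols = act[ok]
            r2 = r**2
            for a in range(len(cols)):
                if not keep[cols[a]]:
                    continue
                for b in range(a + 1, len(cols)):
                    if keep[cols[b]] and r2[a, b] > r2_max:
                        keep[cols[b]] = False  # lower index retained
            if start + window >= len(idx):
                break
    return g.marker_ids[keep]


def compute_grm(g: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM with observed allele frequencies.

    G = Z Z' / m with z_ij = (g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j));
    monomorphic SNPs are skipped.  On HWE data the diagonal averages ~1.
    """
    if g.n_samples < 2:
        raise ValueError("GRM needs at least two samples")
    X = g.genotypes.astype(float)
    if (X < 0).any():
        raise ValueError("missing genotypes: impute before computing a GRM")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; GRM is degenerate")
    Xp, pp = X[:, poly], p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    m = int(poly.sum())
    return GRM(Z @ Z.T / m, g.sample_ids, m)


def pca_from_grm(grm: GRM, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the GRM: (scores, variance-explained).

    Scores are eigenvectors scaled by the square root of their eigenvalue;
    variance explained is eigenvalue over trace.  Eigenvalues come out
    non-increasing.
    """
    A = grm.matrix
    if not np.isfinite(A).all():
        raise ValueError("GRM contains non-finite entries")
    if n_pcs >= A.shape[0]:
        raise ValueError("n_pcs must be smaller than the number of samples")
    vals, vecs = np.linalg.eigh(A)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    top = np.clip(vals[:n_pcs], 0.0, None)
    scores = vecs[:, :n_pcs] * np.sqrt(top)
    var_explained = vals[:n_pcs] / np.trace(A)
    return scores, var_explained


def flag_pca_outliers(
    scores: np.ndarray, labels: pd.Series, n_sd: float = 4.0
) -> pd.Series:
    """Flag animals whose PC scores sit far from their breed centroid.

    An animal is flagged when its distance (in the supplied PCs, typically
    the first three) from its recorded breed's centroid exceeds ``n_sd``
    times the within-breed root-mean-square distance.  The multiplier is a
    configuration knob, not a calibrated constant.
    """
    labels = labels.astype(str)
    flagged = pd.Series(False, index=labels.index)
    for b in pd.unique(labels):
        mask = (labels == b).to_numpy()
        sub = scores[mask]
        centroid = sub.mean(axis=0)
        dist = np.linalg.norm(sub - centroid, axis=1)
        rms = np.sqrt((dist**2).mean())
        if rms > 0:
            flagged.iloc[np.flatnonzero(mask)[dist > n_sd * rms]] = True
    return flagged


def ibs_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise IBS distance on {0,1,2} vectors.

    d(x, y) = 1 - (mean shared alleles per locus)/2 = mean |x - y| / 2 —
    identical genotypes are at 0, opposite homozygotes at 1.  A metric
    (scaled Manhattan distance).
    """
    X = np.asarray(X, dtype=float)
    return squareform(pdist(X, metric="cityblock") / (2.0 * X.shape[1]))


def select_training_by_ibs(
    g: GenotypeMatrix,
    breed_labels: pd.Series | None = None,
    k: int = 500,
    n_pick_per_cluster: int = 1,
    seed: int | None = None,
) -> tuple[list[str], dict[str, IBSClustering]]:
    """Per-breed IBS clustering; one random animal per cluster.

    Average-linkage hierarchical clustering on the IBS distance, cut at k
    clusters per breed, spreads the training picks across each breed's
    genomic diversity.  If a breed has fewer than k animals, k drops to n
    with a warning.  Returns (selected sample ids, per-breed clustering).
    """
    labels = (
        breed_labels if breed_labels is not None else g.samples["breed"]
    ).astype(str)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    clusterings: dict[str, IBSClustering] = {}
    for b in pd.unique(labels):
        ids = labels.index[labels == b]
        if len(ids) == 0:
            raise ValueError(f"breed {b!r} has no animals")
        kb = k
        if len(ids) < k:
            warnings.warn(
                f"breed {b!r}: only {len(ids)} animals for {k} clusters; "
                f"using k={len(ids)}"
            )
            kb = len(ids)
        rows = g.sample_ids.get_indexer(ids)
        X = g.genotypes[rows].astype(float)
        if kb == len(ids):
            assign = np.arange(1, len(ids) + 1)
        else:
            D = pdist(X, metric="cityblock") / (2.0 * X.shape[1])
            Zl = linkage(D, method="average")
            assign = fcluster(Zl, t=kb, criterion="maxclust")
        reps = []
        for c in range(1, assign.max() + 1):
            members = np.asarray(ids)[assign == c]
            picks = rng.choice(
                members, size=min(n_pick_per_cluster, len(members)), replace=False
            )
            reps += list(picks)
        chosen += reps
        clusterings[b] = IBSClustering(
            b, pd.Series(assign, index=ids), sorted(reps)
        )
    return chosen, clusterings


def build_validation_sets(
    compositions: pd.DataFrame,
    purity_min: float = 0.90,
    two_way_bands: list[tuple[float, float, float, float]] | None = None,
    three_way_min: float = 0.20,
    fourth_breed_max: float = 0.025,
    minor_breed_max: float = 0.05,
) -> pd.DataFrame:
    """Classify animals into purebred-verified / two-way / three-way sets.

    * purebred-verified: any single breed proportion >= ``purity_min``;
    * two-way: the top-two fractions fall in one of the bands
      (45-55:45-55 or 70-80:20-30, either order) and every other breed is
      below ``minor_breed_max``;
    * three-way: three breeds each >= ``three_way_min`` and any fourth
      breed below ``fourth_breed_max``.

    Returns a frame with ``category`` in {purebred, two_way, three_way,
    none} and ``main_breed``.
    """
    bands = TWO_WAY_BANDS if two_way_bands is None else two_way_bands
    # normalise bands so the first interval is the larger fraction's
    bands = [b if b[0] >= b[2] else (b[2], b[3], b[0], b[1]) for b in bands]
    Q = compositions.to_numpy(dtype=float)
    breeds = np.asarray(compositions.columns, dtype=object)
    order = np.argsort(-Q, axis=1)
    sortedq = -np.sort(-Q, axis=1)
    cat = np.full(len(Q), "none", dtype=object)

    pure = sortedq[:, 0] >= purity_min
    cat[pure] = "purebred"

    f1, f2 = sortedq[:, 0], sortedq[:, 1]
    rest_max = sortedq[:, 2] if Q.shape[1] > 2 else np.zeros(len(Q))
    in_band = np.zeros(len(Q), dtype=bool)
    for lo1, hi1, lo2, hi2 in bands:
        in_band |= (f1 >= lo1) & (f1 <= hi1) & (f2 >= lo2) & (f2 <= hi2)
    two = ~pure & in_band & (rest_max < minor_breed_max)
    cat[two] = "two_way"

    if Q.shape[1] >= 3:
        f3 = sortedq[:, 2]
        f4 = sortedq[:, 3] if Q.shape[1] > 3 else np.zeros(len(Q))
        three = ~pure & ~two & (f3 >= three_way_min) & (f4 < fourth_breed_max)
        cat[three] = "three_way"

    return pd.DataFrame(
        {"category": cat, "main_breed": breeds[order[:, 0]]},
        index=compositions.index,
    )
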