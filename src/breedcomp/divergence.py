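"""Breed divergence: per-SNP and pairwise Fst, and a neighbor-joining tree.

Fst follows Wright's fixation index, Fst = s^2 / (p_bar (1 - p_bar)), with
s^2 the *population* (divide-by-B) variance of the allele frequency among
breeds and p_bar the unweighted mean frequency.  Under this convention a
fixed difference between two breeds gives Fst = 1 exactly and per-SNP Fst
never exceeds 1.  No sample-size correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import AlleleFrequencyTable


@dataclass
class FstResult:
    per_snp: np.ndarray  # (m,)
    global_fst: float
    p_bar: np.ndarray  # (m,) mean allele frequency across breeds
    s2: np.ndarray  # (m,) among-breed variance of allele frequency


def _fst_arrays(freqs: np.ndarray, global_mode: str) -> FstResult:
    if freqs.shape[0] < 2:
        raise ValueError("Fst needs at least two breeds")
    p_bar = freqs.mean(axis=0)
    s2 = freqs.var(axis=0)  # population variance (ddof=0)
    denom = p_bar * (1.0 - p_bar)
    per_snp = np.zeros_like(p_bar)
    ok = denom > 0
    per_snp[ok] = s2[ok] / denom[ok]  # monomorphic across breeds -> 0
    if global_mode == "mean_of_ratios":
        global_fst = float(per_snp.mean())
    elif global_mode == "ratio_of_means":
        global_fst = float(s2[ok].sum() / denom[ok].sum()) if ok.any() else 0.0
    else:
        raise ValueError(f"unknown global_mode {global_mode!r}")
    return FstResult(per_snp, global_fst, p_bar, s2)


def fst_per_snp(
    freqs: AlleleFrequencyTable | np.ndarray, global_mode: str = "mean_of_ratios"
) -> FstResult:
    """Per-SNP Fst across all breeds plus the genome-average.

    The genome-wide value is the unweighted mean of per-SNP ratios by
    default; ``global_mode="ratio_of_means"`` pools numerators and
    denominators instead.
    """
    f = freqs.freqs if isinstance(freqs, AlleleFrequencyTable) else np.asarray(freqs)
    return _fst_arrays(f, global_mode)


def pairwise_fst(
    freqs: AlleleFrequencyTable | np.ndarray, global_mode: str = "mean_of_ratios"
) -> np.ndarray:
    """Symmetric B x B matrix of two-breed genome-average Fst (zero diagonal)."""
    f = freqs.freqs if isinstance(freqs, AlleleFrequencyTable) else np.asarray(freqs)
    B = f.shape[0]
    out = np.zeros((B, B))
    for a in range(B):
        for b in range(a + 1, B):
            out[a, b] = out[b, a] = _fst_arrays(f[[a, b]], global_mode).global_fst
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _fmt(length: float) -> str:
    return f"{length:.10g}"


def neighbor_joining_tree(d, labels) -> str:
    """Saitou–Nei neighbor joining on a distance matrix; returns Newick.

    Negative branch lengths are clamped to zero with the deficit moved onto
    the sibling branch (path lengths through the joined pair are conserved).
    Pair selection ties break toward the lexicographically first index pair.
    Two taxa collapse to a single split edge.
    """
    d = np.asarray(d, dtype=float).copy()
    labels = [str(x) for x in labels]
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (np.diag(d) != 0).any():
        raise ValueError("distance matrix must have a zero diagonal")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        h = d[0, 1] / 2.0
        return f"({labels[0]}:{_fmt(h)},{labels[1]}:{_fmt(h)});"

    nodes = list(labels)  # Newick fragment per active node
    active = list(range(n))
    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (na - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        ai, aj = active[i], active[j]
        merged = f"({nodes[ai]}:{_fmt(li)},{nodes[aj]}:{_fmt(lj)})"
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        rest = [a for a in active if a not in (ai, aj)]
        du = 0.5 * (d[ai, rest] + d[aj, rest] - dij)
        nodes[ai] = merged
        d[ai, rest] = du
        d[rest, ai] = du
        active = [ai] + rest

    a, b, c = active
    # final unrooted star: closed-form leaf branches
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({nodes[a]}:{_fmt(la)},{nodes[b]}:{_fmt(lb)},{nodes[c]}:{_fmt(lc)});"
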