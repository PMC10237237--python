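"""Genotype containers, PLINK 1 binary I/O and SNP quality control.

The pipeline's universal currency is :class:`GenotypeMatrix`: a samples x
markers matrix of reference-allele counts in {0, 1, 2} with ``-1`` as the
missing sentinel, a sample table and a marker map.  On disk, genotypes are
exchanged as PLINK 1 .bed/.bim/.fam triplets (SNP-major .bed); allele counts
count the A1 allele of the .bim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])  # magic + SNP-major flag

#: number of cattle autosomes; chromosomes outside 1..29 are non-autosomal
N_AUTOSOMES = 29


class FormatError(ValueError):
    """Malformed PLINK file (bad magic bytes, dimension mismatch, ...)."""


class EmptyPanelError(ValueError):
    """A filter removed every SNP (or every sample)."""


def _check_marker_map(markers: pd.DataFrame) -> None:
    if not {"chrom", "pos"}.issubset(markers.columns):
        raise ValueError("marker map needs 'chrom' and 'pos' columns")
    if markers.index.has_duplicates:
        raise ValueError("marker ids must be unique")


@dataclass
class GenotypeMatrix:
    """Allele-count matrix with its sample table and marker map.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_markers)`` integer array of A1-allele counts in
        {0, 1, 2}; missing genotypes are ``MISSING`` (-1).
    samples
        Indexed by sample id.  Optional columns used downstream: ``breed``
        (purebred label), ``population`` (training/validation/... tag) and
        per-breed true-fraction columns for simulated crossbreds.
    markers
        Indexed by SNP id; columns ``chrom`` (int), ``pos`` (1-based bp) and
        optionally ``a1``/``a2`` allele codes.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x markers)")
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        _check_marker_map(self.markers)
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"invalid genotype codes: {bad}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    def subset(self, samples=None, markers=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/marker ids (order kept)."""
        g, s, m = self.genotypes, self.samples, self.markers
        if samples is not None:
            rows = s.index.get_indexer(pd.Index(samples))
            if (rows < 0).any():
                missing = pd.Index(samples)[rows < 0]
                raise KeyError(f"unknown sample ids: {list(missing[:5])}")
            g, s = g[rows], s.iloc[rows]
        if markers is not None:
            cols = m.index.get_indexer(pd.Index(markers))
            if (cols < 0).any():
                missing = pd.Index(markers)[cols < 0]
                raise KeyError(f"unknown marker ids: {list(missing[:5])}")
            g, m = g[:, cols], m.iloc[cols]
        return GenotypeMatrix(g.copy(), s.copy(), m.copy())

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP A1 frequency over non-missing genotypes (nan if all missing)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        return np.ma.filled(g.mean(axis=0) / 2.0, np.nan)


# ---------------------------------------------------------------------------
# PLINK 1 binary codec
# ---------------------------------------------------------------------------
# Two-bit codes, within-byte order: sample (i % 4) occupies bits 2*(i%4).
#   00 -> homozygous A1 (count 2)     01 -> missing
#   10 -> heterozygous (count 1)      11 -> homozygous A2 (count 0)
_CODE_OF_COUNT = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_COUNT_OF_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a SNP-major PLINK 1 ``.bed``/``.bim``/``.fam`` triplet.

    The .bim columns are chrom, id, 0 cM, bp, A1, A2 (A1/A2 default to
    ``A``/``B`` when the marker map carries no allele codes); the .fam uses
    the ``population`` column (or 0) as family id.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n_samples, g.n_markers

    code = np.empty((n, m), dtype=np.uint8)
    for count, c in _CODE_OF_COUNT.items():
        code[g.genotypes == count] = c
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.zeros((pad, m), dtype=np.uint8)])
    blocks = code.reshape(-1, 4, m)  # (n/4, 4, m)
    packed = (
        blocks[:, 0] | (blocks[:, 1] << 2) | (blocks[:, 2] << 4) | (blocks[:, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.T.tobytes())  # SNP-major: all bytes of SNP 0, then SNP 1, ...

    mk = g.markers
    bim = pd.DataFrame(
        {
            "chrom": mk["chrom"].to_numpy(),
            "id": mk.index.to_numpy(),
            "cm": 0,
            "pos": mk["pos"].to_numpy(),
            "a1": mk["a1"].to_numpy() if "a1" in mk else "A",
            "a2": mk["a2"].to_numpy() if "a2" in mk else "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": g.samples["population"].to_numpy()
            if "population" in g.samples
            else 0,
            "iid": g.sample_ids.to_numpy(),
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 triplet into a :class:`GenotypeMatrix`.

    Allele counts count the A1 allele of the .bim; sample order follows the
    .fam; missing genotypes decode to :data:`MISSING`.
    """
    prefix = Path(prefix)
    try:
        fam = pd.read_csv(
            prefix.with_suffix(".fam"),
            sep=r"\s+",
            header=None,
            names=["fid", "iid", "pat", "mat", "sex", "pheno"],
            dtype={"fid": str, "iid": str},
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{prefix}.fam lists no samples") from exc
    if fam.empty:
        raise FormatError(f"{prefix}.fam lists no samples")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != PLINK_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1)")
    bps = (n + 3) // 4  # bytes per SNP
    body = raw[3:]
    if body.size != bps * m:
        raise FormatError(
            f"{prefix}.bed: expected {bps * m} data bytes for {n} samples x "
            f"{m} SNPs, found {body.size}"
        )
    by = body.reshape(m, bps)
    codes = np.empty((m, bps * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (by >> (2 * k)) & 0b11
    counts = _COUNT_OF_CODE[codes[:, :n]].T  # (n, m)

    samples = pd.DataFrame({"population": fam["fid"].to_numpy()}, index=fam["iid"])
    samples.index.name = "sample_id"
    markers = pd.DataFrame(
        {
            "chrom": bim["chrom"].to_numpy(),
            "pos": bim["pos"].to_numpy(),
            "a1": bim["a1"].to_numpy(),
            "a2": bim["a2"].to_numpy(),
        },
        index=pd.Index(bim["id"], name="snp_id"),
    )
    return GenotypeMatrix(counts, samples, markers)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def qc_filter(
    g: GenotypeMatrix,
    min_snp_call_rate: float = 0.90,
    min_sample_call_rate: float = 0.90,
    autosomes_only: bool = True,
) -> GenotypeMatrix:
    """Apply SNP/sample quality control and impute sporadic missingness.

    Drops SNPs below the call-rate threshold and, when ``autosomes_only``,
    SNPs without a valid autosome (chromosome outside 1..29) or position;
    then drops samples below the sample call rate.  Minor allele frequency is
    deliberately NOT filtered, so rare-breed-informative SNPs survive.
    Remaining sporadic missing genotypes are imputed to the per-SNP mean
    rounded to the nearest allele count (ties round half up) — a documented
    stand-in for pedigree-aware imputation, exact on complete data.
    """
    geno = g.genotypes
    obs = geno != MISSING

    snp_cr = obs.mean(axis=0) if len(geno) else np.zeros(g.n_markers)
    keep_snp = snp_cr >= min_snp_call_rate
    if autosomes_only:
        chrom = g.markers["chrom"].to_numpy()
        pos = g.markers["pos"].to_numpy()
        keep_snp &= (chrom >= 1) & (chrom <= N_AUTOSOMES) & (pos > 0)
    if not keep_snp.any():
        raise EmptyPanelError("quality control removed every SNP")

    geno = geno[:, keep_snp]
    obs = obs[:, keep_snp]
    sample_cr = obs.mean(axis=1)
    keep_sample = sample_cr >= min_sample_call_rate
    if not keep_sample.any():
        raise EmptyPanelError("quality control removed every sample")
    geno = geno[keep_sample][:, :]
    obs = obs[keep_sample]

    geno = geno.astype(np.int8, copy=True)
    miss_cols = np.flatnonzero(~obs.all(axis=0))
    for j in miss_cols:
        col = geno[:, j]
        seen = col != MISSING
        mean = col[seen].mean() if seen.any() else 0.0
        fill = int(np.floor(mean + 0.5))  # half rounds up, stays in {0,1,2}
        geno[~seen, j] = min(max(fill, 0), 2)

    return GenotypeMatrix(
        geno,
        g.samples.loc[keep_sample].copy(),
        g.markers.loc[keep_snp].copy(),
    )
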