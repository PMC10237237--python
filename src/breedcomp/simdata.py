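"""Synthetic multi-breed cattle genotype simulation.

The real study data (a 49,213-SNP array on Irish dairy and beef cattle) is
proprietary, so this module generates datasets with the statistical
structure the breed-composition analysis assumes:

* breed divergence under the Balding–Nichols model — each breed's allele
  frequency at a SNP is Beta-distributed around a shared ancestral
  frequency, with a per-breed drift coefficient ``F`` that sets the
  expected pairwise Fst;
* Hardy–Weinberg genotypes within breed (allele counts Binomial(2, f));
* crossbreds built from explicit parental gametes with Haldane-model
  recombination on a linear genetic map, so each transmitted locus carries
  a breed of origin and every animal has a *realized* genome fraction per
  breed alongside its pedigree expectation.

Defaults mirror the emulated study design: 13 breeds, 29 autosomes,
per-breed training / purebred-validation / SNP-selection populations at
realistic sizes (500 / up to 250 / up to 1,000), and two- and three-way
cross designs.  Everything is deterministic given
``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import largest_remainder, spawn_rngs
from .genotype_io import GenotypeMatrix, write_plink

# 13 cattle breeds, in the order used throughout (abbreviations as labels).
BREEDS: list[str] = [
    "AA",  # Angus
    "AU",  # Aubrac
    "BA",  # Blonde d'Aquitaine
    "BB",  # Belgian Blue
    "CH",  # Charolais
    "FR",  # Friesian
    "HE",  # Hereford
    "HO",  # Holstein
    "LM",  # Limousin
    "PT",  # Parthenaise
    "SA",  # Saler
    "SH",  # Shorthorn
    "SI",  # Simmental
]

BREED_NAMES: dict[str, str] = {
    "AA": "Angus",
    "AU": "Aubrac",
    "BA": "Blonde d'Aquitaine",
    "BB": "Belgian Blue",
    "CH": "Charolais",
    "FR": "Friesian",
    "HE": "Hereford",
    "HO": "Holstein",
    "LM": "Limousin",
    "PT": "Parthenaise",
    "SA": "Saler",
    "SH": "Shorthorn",
    "SI": "Simmental",
}

# Default per-breed population sizes (training, purebred
# validation, SNP selection), same breed order as BREEDS.
TABLE_POP_SIZES: dict[str, list[int]] = {
    "training": [500] * 13,
    "validation": [250, 250, 250, 129, 250, 250, 250, 250, 250, 73, 250, 250, 250],
    "snp_selection": [1000, 1000, 302, 189, 1000, 249, 1000, 1000, 1000, 220, 1000, 995, 1000],
}

# Approximate cattle autosome lengths (Mbp), chromosomes 1..29, ~2.5 Gbp total.
CATTLE_AUTOSOME_MB: list[float] = [
    158.5, 136.2, 121.0, 120.8, 120.1, 117.8, 110.7, 113.4, 105.7, 103.3,
    106.9, 87.2, 83.5, 82.4, 85.0, 81.0, 73.2, 65.8, 63.4, 71.9,
    69.9, 60.7, 52.5, 62.3, 42.4, 51.7, 45.4, 45.9, 51.1,
]


class UnsupportedDesignError(ValueError):
    """Cross pedigree deeper than two generations."""


class SizingError(ValueError):
    """Requested population sizes cannot be met."""


@dataclass(frozen=True)
class CrossDesign:
    """A two- or three-way cross: ``pedigree`` is (sire, dam) where each
    parent is either a breed index (purebred) or a pair of breed indices
    (an F1 of those two breeds).  Depth beyond two generations is not
    supported."""

    label: str
    pedigree: tuple
    n_animals: int

    def __post_init__(self) -> None:
        if len(self.pedigree) != 2:
            raise ValueError("pedigree must be a (sire, dam) pair")
        for parent in self.pedigree:
            if isinstance(parent, (int, np.integer)):
                continue
            if isinstance(parent, tuple) and len(parent) == 2 and all(
                isinstance(b, (int, np.integer)) for b in parent
            ):
                continue
            raise UnsupportedDesignError(
                f"{self.label}: parent {parent!r} is neither a breed index nor "
                "an F1 pair; pedigrees deeper than two generations are unsupported"
            )
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")

    def expected_fractions(self, n_breeds: int) -> np.ndarray:
        """Pedigree-expected breed fractions (each parent contributes 1/2)."""
        frac = np.zeros(n_breeds)
        for parent in self.pedigree:
            if isinstance(parent, tuple):
                for b in parent:
                    frac[b] += 0.25
            else:
                frac[parent] += 0.5
        if not np.isclose(frac.sum(), 1.0):
            raise ValueError(f"{self.label}: pedigree fractions sum to {frac.sum()}")
        return frac


def default_cross_designs() -> list[CrossDesign]:
    """Default crossbred validation designs (two- and three-way)."""
    ix = {b: i for i, b in enumerate(BREEDS)}
    two_way = [("AA", "CH", 998), ("AA", "HE", 144), ("AA", "SI", 311),
               ("CH", "LM", 140), ("HO", "FR", 233)]
    three_way = [("AA", "HO", "FR", 474), ("AA", "BA", "LM", 180),
                 ("AU", "BA", "LM", 1280), ("SI", "HO", "FR", 80),
                 ("SI", "SH", "CH", 55)]
    designs = [
        CrossDesign(f"{a}x{b} F1", (ix[a], ix[b]), n) for a, b, n in two_way
    ]
    designs += [
        CrossDesign(f"{a}x({b}x{c})", (ix[a], (ix[b], ix[c])), n)
        for a, b, c, n in three_way
    ]
    return designs


@dataclass
class AlleleFrequencyTable:
    """Breeds x SNPs reference-allele frequencies plus the marker map."""

    freqs: np.ndarray  # (B, m) in [0, 1]
    breeds: list[str]
    markers: pd.DataFrame
    ancestral: np.ndarray | None = None  # (m,) ancestral frequencies, if known
    seed: int | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.breeds), len(self.markers)):
            raise ValueError("freqs shape must be (n_breeds, n_markers)")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]


@dataclass
class SimulationConfig:
    """Conditions of the simulated study.

    ``drift_F`` (scalar or per-breed) is the Balding–Nichols drift
    coefficient.  The default (``None``) assigns breeds drifts evenly
    spaced on [0.075, 0.34], calibrated so realized *pairwise* Fst under
    Wright's divide-by-B convention spans the 0.039–0.146 envelope observed
    between real European cattle breeds — two breeds with drifts F_a, F_b
    realize pairwise Fst near (F_a+F_b)/4 / (1 - (F_a+F_b)/4), well below
    the single-breed drift, so a uniform F would compress all pairs onto
    one value and a scalar 0.07 would land below the envelope entirely.
    ``recomb_rate`` is cM per Mb on a linear genetic map.  ``pop_sizes``
    gives per-breed counts for the three purebred populations.
    """

    n_breeds: int = 13
    n_snps: int = 49_213
    chromosomes: list[tuple[int, int]] = field(
        default_factory=lambda: [
            (i + 1, int(mb * 1_000_000)) for i, mb in enumerate(CATTLE_AUTOSOME_MB)
        ]
    )
    drift_F: float | list[float] | None = None
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    recomb_rate: float = 1.0
    pop_sizes: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in TABLE_POP_SIZES.items()}
    )
    cross_designs: list[CrossDesign] = field(default_factory=default_cross_designs)
    breed_labels: list[str] = field(default_factory=lambda: list(BREEDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 2:
            raise ValueError("need at least 2 breeds")
        if self.drift_F is None:
            self.drift_F = list(np.round(np.linspace(0.075, 0.34, self.n_breeds), 4))
        F = np.broadcast_to(np.asarray(self.drift_F, dtype=float), (self.n_breeds,))
        if ((F <= 0) | (F >= 1)).any():
            raise ValueError("drift_F values must lie strictly in (0, 1)")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_freq_range must be an interval within (0, 1)")
        if len(self.breed_labels) != self.n_breeds:
            self.breed_labels = [f"B{i:02d}" for i in range(self.n_breeds)]
        for pop, sizes in self.pop_sizes.items():
            if len(sizes) != self.n_breeds:
                raise ValueError(f"pop_sizes[{pop!r}] must list one count per breed")
        for d in self.cross_designs:
            flat = [
                b
                for parent in d.pedigree
                for b in (parent if isinstance(parent, tuple) else (parent,))
            ]
            if any(b < 0 or b >= self.n_breeds for b in flat):
                raise ValueError(f"cross design {d.label}: breed index out of range")

    @property
    def drift(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.drift_F, dtype=float), (self.n_breeds,)
        ).copy()

    @classmethod
    def scaled(
        cls,
        n_breeds: int = 13,
        n_snps: int = 5_000,
        n_chromosomes: int = 5,
        n_training: int = 50,
        n_validation: int = 25,
        n_snp_selection: int = 100,
        cross_designs: list[CrossDesign] | None = None,
        **kwargs,
    ) -> "SimulationConfig":
        """A desk-scale configuration preserving the study's structure."""
        chroms = [
            (i + 1, int(mb * 1_000_000))
            for i, mb in enumerate(CATTLE_AUTOSOME_MB[:n_chromosomes])
        ]
        labels = BREEDS[:n_breeds] if n_breeds <= 13 else [
            f"B{i:02d}" for i in range(n_breeds)
        ]
        if cross_designs is None:
            cross_designs = [
                CrossDesign(f"{labels[0]}x{labels[1]} F1", (0, 1), 50)
            ]
            if n_breeds >= 3:
                cross_designs.append(
                    CrossDesign(
                        f"{labels[0]}x({labels[1]}x{labels[2]})", (0, (1, 2)), 50
                    )
                )
        return cls(
            n_breeds=n_breeds,
            n_snps=n_snps,
            chromosomes=chroms,
            pop_sizes={
                "training": [n_training] * n_breeds,
                "validation": [n_validation] * n_breeds,
                "snp_selection": [n_snp_selection] * n_breeds,
            },
            cross_designs=cross_designs,
            breed_labels=labels,
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "chromosomes" in raw:
            raw["chromosomes"] = [tuple(c) for c in raw["chromosomes"]]
        if "cross_designs" in raw:
            raw["cross_designs"] = [
                CrossDesign(
                    d["label"],
                    tuple(
                        tuple(p) if isinstance(p, list) else p for p in d["pedigree"]
                    ),
                    d["n_animals"],
                )
                for d in raw["cross_designs"]
            ]
        return cls(**raw)


def _marker_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """SNP positions: counts per chromosome proportional to length, uniform
    unique positions within each chromosome, sorted."""
    lengths = [length for _, length in config.chromosomes]
    counts = largest_remainder(config.n_snps, lengths)
    chroms, positions = [], []
    for (cid, length), c in zip(config.chromosomes, counts):
        if c > length:
            raise SizingError(f"chromosome {cid}: more SNPs than basepairs")
        pos = np.sort(rng.choice(length, size=c, replace=False) + 1)
        chroms.append(np.full(c, cid))
        positions.append(pos)
    ids = [
        f"snp_c{c}_{p}" for c, p in zip(np.concatenate(chroms), np.concatenate(positions))
    ]
    return pd.DataFrame(
        {"chrom": np.concatenate(chroms), "pos": np.concatenate(positions)},
        index=pd.Index(ids, name="snp_id"),
    )


def simulate_breed_frequencies(config: SimulationConfig) -> AlleleFrequencyTable:
    """Draw per-breed allele frequencies under the Balding–Nichols model.

    Ancestral frequency p is uniform on ``ancestral_freq_range`` per SNP;
    breed k's frequency is Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), which has
    mean p and variance F_k p(1-p) — so two breeds with drift F diverge with
    expected Fst close to F.
    """
    rng_map, rng_anc, rng_breed = spawn_rngs(config.seed, 3)
    markers = _marker_map(config, rng_map)
    m = len(markers)
    lo, hi = config.ancestral_freq_range
    p = rng_anc.uniform(lo, hi, size=m)
    F = config.drift
    freqs = np.empty((config.n_breeds, m))
    for k in range(config.n_breeds):
        scale = (1.0 - F[k]) / F[k]
        freqs[k] = rng_breed.beta(p * scale, (1.0 - p) * scale)
    return AlleleFrequencyTable(
        freqs, list(config.breed_labels), markers, ancestral=p, seed=config.seed
    )


def simulate_purebreds(
    freqs: AlleleFrequencyTable,
    n_per_breed: int | list[int],
    seed: int,
    population: str = "purebred",
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """HWE purebred genotypes: allele count ~ Binomial(2, f_breed) per SNP."""
    B, m = freqs.n_breeds, freqs.n_snps
    n_per_breed = np.broadcast_to(np.asarray(n_per_breed, dtype=int), (B,))
    if (n_per_breed < 0).any():
        raise SizingError("n_per_breed must be non-negative")
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else population
    blocks, rows = [], []
    for k, breed in enumerate(freqs.breeds):
        n = int(n_per_breed[k])
        if n == 0:
            continue
        blocks.append(
            rng.binomial(2, freqs.freqs[k], size=(n, m)).astype(np.int8)
        )
        rows += [
            {"sample_id": f"{prefix}_{breed}_{i:05d}", "breed": breed,
             "population": population}
            for i in range(n)
        ]
    if not blocks:
        raise SizingError("no animals requested")
    samples = pd.DataFrame(rows).set_index("sample_id")
    frac = pd.DataFrame(
        0.0, index=samples.index, columns=[f"frac_{b}" for b in freqs.breeds]
    )
    for k, breed in enumerate(freqs.breeds):
        frac.loc[samples["breed"] == breed, f"frac_{breed}"] = 1.0
    samples = pd.concat([samples, frac], axis=1)
    return GenotypeMatrix(np.vstack(blocks), samples, freqs.markers.copy())


def _genetic_positions(markers: pd.DataFrame, recomb_rate: float):
    """Per-chromosome marker genetic positions (Morgans) on a linear map."""
    out = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = markers.index.get_indexer(sub.index)
        gpos = sub["pos"].to_numpy() * recomb_rate * 1e-8  # cM/Mb * bp -> M
        out.append((idx, gpos))
    return out


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chrom_gpos,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiosis: Haldane (Poisson) crossovers on each chromosome, random
    starting haplotype, returns the transmitted per-locus values."""
    out = np.empty_like(hap_a)
    for idx, gpos in chrom_gpos:
        length = gpos[-1] if len(gpos) else 0.0
        n_xo = rng.poisson(length)
        xo = np.sort(rng.uniform(0.0, length, size=n_xo)) if n_xo else np.empty(0)
        parity = (rng.integers(2) + np.searchsorted(xo, gpos)) % 2
        out[idx] = np.where(parity == 0, hap_a[idx], hap_b[idx])
    return out


def simulate_crossbreds(
    freqs: AlleleFrequencyTable,
    designs: list[CrossDesign],
    config: SimulationConfig,
    seed: int | None = None,
    model: str = "haldane",
) -> GenotypeMatrix:
    """Simulate crossbreds as recombination mosaics of breed origins.

    Each parent transmits one gamete: a purebred parent transmits its breed
    everywhere; an F1 parent transmits a Haldane-model mosaic of its two
    breeds.  The genotype at a locus is the sum of two Bernoulli alleles
    drawn from the origin breeds' frequencies.  The per-animal *realized*
    fraction of transmitted loci per breed is recorded alongside the
    pedigree expectation.

    ``model="independent"`` instead draws each locus' origins independently
    with the pedigree-expected probabilities (no linkage; cheap, for tests).
    """
    if not designs:
        raise ValueError("designs must be non-empty")
    if model not in ("haldane", "independent"):
        raise ValueError(f"unknown recombination model {model!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    B, m = freqs.n_breeds, freqs.n_snps
    chrom_gpos = _genetic_positions(freqs.markers, config.recomb_rate)
    jj = np.arange(m)

    geno_rows, rows, frac_rows, exp_rows = [], [], [], []
    for design in designs:
        exp = design.expected_fractions(B)
        for i in range(design.n_animals):
            haps = []
            for parent in design.pedigree:
                if isinstance(parent, tuple):
                    a = np.full(m, parent[0], dtype=np.int16)
                    b = np.full(m, parent[1], dtype=np.int16)
                    if model == "haldane":
                        haps.append(_gamete(a, b, chrom_gpos, rng))
                    else:
                        pick = rng.integers(2, size=m)
                        haps.append(np.where(pick == 0, a, b))
                else:
                    haps.append(np.full(m, parent, dtype=np.int16))
            geno = np.zeros(m, dtype=np.int8)
            realized = np.zeros(B)
            for hap in haps:
                geno += (rng.random(m) < freqs.freqs[hap, jj]).astype(np.int8)
                realized += np.bincount(hap, minlength=B) / (2.0 * m)
            geno_rows.append(geno)
            rows.append(
                {
                    "sample_id": f"cross_{design.label.replace(' ', '')}_{i:05d}",
                    "breed": design.label,
                    "population": "crossbred_validation",
                }
            )
            frac_rows.append(realized)
            exp_rows.append(exp)

    samples = pd.DataFrame(rows).set_index("sample_id")
    frac = pd.DataFrame(
        np.array(frac_rows),
        index=samples.index,
        columns=[f"frac_{b}" for b in freqs.breeds],
    )
    exp = pd.DataFrame(
        np.array(exp_rows),
        index=samples.index,
        columns=[f"pedigree_frac_{b}" for b in freqs.breeds],
    )
    samples = pd.concat([samples, frac, exp], axis=1)
    return GenotypeMatrix(np.array(geno_rows), samples, freqs.markers.copy())


@dataclass
class StudyDataset:
    """The four disjoint study populations plus the generating frequencies."""

    config: SimulationConfig
    freqs: AlleleFrequencyTable
    training: GenotypeMatrix
    purebred_validation: GenotypeMatrix
    crossbred_validation: GenotypeMatrix
    snp_selection: GenotypeMatrix

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gm in self.populations.values():
            ids = set(gm.sample_ids)
            if seen & ids:
                raise ValueError("populations share sample ids")
            seen |= ids

    @property
    def populations(self) -> dict[str, GenotypeMatrix]:
        return {
            "training": self.training,
            "purebred_validation": self.purebred_validation,
            "crossbred_validation": self.crossbred_validation,
            "snp_selection": self.snp_selection,
        }

    @property
    def breeds(self) -> list[str]:
        return list(self.freqs.breeds)


def assemble_study_dataset(config: SimulationConfig) -> StudyDataset:
    """Simulate frequencies and the four study populations.

    All purebreds are drawn unrelated, and crossbred parents are fresh
    simulated purebreds, so no parent–offspring pair spans training and
    validation by construction.
    """
    freqs = simulate_breed_frequencies(config)
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    training = simulate_purebreds(
        freqs, config.pop_sizes["training"], sub[3], population="training"
    )
    validation = simulate_purebreds(
        freqs,
        config.pop_sizes["validation"],
        sub[4],
        population="purebred_validation",
    )
    selection = simulate_purebreds(
        freqs,
        config.pop_sizes["snp_selection"],
        sub[5],
        population="snp_selection",
    )
    crossbreds = simulate_crossbreds(freqs, config.cross_designs, config, seed=sub[6])
    return StudyDataset(config, freqs, training, validation, crossbreds, selection)


def write_dataset(dataset: StudyDataset, outdir: str | Path) -> None:
    """Write each population as PLINK .bed/.bim/.fam plus one sidecar TSV of
    true breed labels and realized/pedigree breed fractions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecars = []
    for name, gm in dataset.populations.items():
        write_plink(gm, outdir / name)
        sc = gm.samples.copy()
        sc.insert(0, "sample_id", sc.index)
        sidecars.append(sc)
    sidecar = pd.concat(sidecars, axis=0)
    for b in dataset.breeds:
        if f"pedigree_frac_{b}" not in sidecar:
            sidecar[f"pedigree_frac_{b}"] = sidecar[f"frac_{b}"]
    cols = (
        ["sample_id", "population", "breed"]
        + [f"frac_{b}" for b in dataset.breeds]
        + [f"pedigree_frac_{b}" for b in dataset.breeds]
    )
    sidecar[cols].to_csv(outdir / "samples.tsv", sep="\t", index=False, na_rep="NA")
    with open(outdir / "seed.txt", "w") as fh:
        fh.write(f"{dataset.config.seed}\n")
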