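"""Simulate a multi-breed cattle study dataset and write it as PLINK files.

Builds a desk-scale version of the study design — 5 breeds, training /
purebred-validation / SNP-selection purebreds plus two- and three-way
crossbreds — and writes .bed/.bim/.fam triplets with a sidecar TSV of true
breed fractions.
"""

from pathlib import Path

from breedcomp import SimulationConfig, assemble_study_dataset
from breedcomp.simdata import write_dataset

cfg = SimulationConfig.scaled(
    n_breeds=5,
    n_snps=2000,
    n_chromosomes=3,
    n_training=50,
    n_validation=25,
    n_snp_selection=100,
    seed=7,
)
dataset = assemble_study_dataset(cfg)

out = Path("scratch/example_dataset")
write_dataset(dataset, out)

print(f"breeds: {dataset.breeds}")
for name, gm in dataset.populations.items():
    print(f"{name}: {gm.n_samples} animals x {gm.n_markers} SNPs")
print(f"written to {out}/ (PLINK triplets + samples.tsv)")
# The crossbred sidecar rows carry both the pedigree-expected fractions
# (exactly 0.5/0.25/...) and the realized genome fractions, which vary
# around the expectation because of recombination.
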