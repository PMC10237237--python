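"""End-to-end breed-composition prediction for a train/test pair.

Thin orchestration over :mod:`snp_blup` and :mod:`admixture`: both
predictors share the training population, the optional SNP panel, and the
post-processing rules (zero < 0.05, rescale to the simplex, assign a
purebred at >= 0.90), so their outputs are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import admixture, snp_blup
from .genotype_io import GenotypeMatrix


@dataclass
class CompositionResult:
    """Predicted breed composition for a set of animals."""

    proportions: pd.DataFrame  # samples x breeds, rows on the simplex (or 0)
    raw: pd.DataFrame  # pre-processing scores (SNP-BLUP) or EM q (admixture)
    assigned: pd.Series  # breed label or "unassigned"
    unassignable: pd.Series  # rows zeroed out entirely by thresholding
    method: str

    @property
    def breeds(self) -> list[str]:
        return list(self.proportions.columns)


def _package(raw: np.ndarray, breeds, index, method: str) -> CompositionResult:
    proc, unass = snp_blup.postprocess_composition(raw)
    assigned = snp_blup.assign_breed(proc, breeds, unassignable=unass)
    assigned.index = index
    return CompositionResult(
        proportions=pd.DataFrame(proc, index=index, columns=breeds),
        raw=pd.DataFrame(raw, index=index, columns=breeds),
        assigned=assigned,
        unassignable=pd.Series(unass, index=index),
        method=method,
    )


def _restrict(train: GenotypeMatrix, test: GenotypeMatrix, panel):
    if panel is not None:
        ids = list(panel.marker_ids) if hasattr(panel, "marker_ids") else list(panel)
        train = train.subset(markers=ids)
        test = test.subset(markers=ids)
    return train, test


def predict_snp_blup(
    train: GenotypeMatrix,
    test: GenotypeMatrix,
    labels: pd.Series | None = None,
    panel=None,
    h2: float = 0.999,
    lambda_mode: str = "per-snp",
    include_intercept: bool = False,
    seed: int = 0,
) -> CompositionResult:
    """Per-breed SNP-BLUP fits on the training population, scored on test.

    ``panel`` restricts both populations to a marker subset (a
    :class:`~breedcomp.panels.PanelSpec` or an id list); ``None`` uses the
    full map.  Raw scores are allele counts times effects (no intercept by
    default; see :func:`breedcomp.snp_blup.predict_raw_scores`).
    """
    labels = (labels if labels is not None else train.samples["breed"]).astype(str)
    train, test = _restrict(train, test, panel)
    breeds = list(pd.unique(labels))
    rngs = np.random.SeedSequence(seed).spawn(len(breeds))
    effects = []
    for b, breed in enumerate(breeds):
        design = snp_blup.build_breed_coding(
            labels, breed, seed=int(rngs[b].generate_state(1)[0] % 2**31)
        )
        rows = train.sample_ids.get_indexer(design.sample_ids)
        vc = snp_blup.VarianceComponents(
            p=design.n_ones / len(design.y),
            m=train.n_markers,
            h2=h2,
            lambda_mode=lambda_mode,
        )
        effects.append(
            snp_blup.fit_snp_blup(
                train.genotypes[rows],
                design.y,
                vc,
                target=breed,
                marker_ids=train.marker_ids,
            )
        )
    raw = snp_blup.predict_raw_scores(
        effects, test.genotypes, test.marker_ids, include_intercept=include_intercept
    )
    return _package(raw, breeds, test.sample_ids, "snp_blup")


def predict_admixture(
    train: GenotypeMatrix,
    test: GenotypeMatrix,
    labels: pd.Series | None = None,
    panel=None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> CompositionResult:
    """Supervised admixture EM with frequencies frozen from training."""
    labels = (labels if labels is not None else train.samples["breed"]).astype(str)
    train, test = _restrict(train, test, panel)
    model = admixture.estimate_breed_frequencies(train, labels)
    est = admixture.fit_admixture_em(
        test.genotypes, model, tol=tol, max_iter=max_iter
    )
    return _package(est.q, model.breeds, test.sample_ids, "admixture")


PREDICTORS = {"snp_blup": predict_snp_blup, "admixture": predict_admixture}
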