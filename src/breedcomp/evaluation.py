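"""Agreement statistics, gold-standard comparisons and the mislabeling
robustness experiment.

Low-density panel predictions are judged against the *gold standard*: the
SNP-BLUP composition predicted from the full SNP set.  Purebreds are scored
by the assignment rate (fraction predicted >= 0.90 for their true breed);
crossbreds by the absolute deviation of the main-breed proportion (the
breed largest in the gold standard) from the gold standard estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import CompositionResult, predict_admixture, predict_snp_blup
from .simdata import CrossDesign, StudyDataset, simulate_crossbreds
from .snp_blup import ASSIGN_THRESHOLD, UNASSIGNED


class SizingError(ValueError):
    pass


@dataclass
class AgreementStats:
    """Method-comparison summary of paired differences (a - b)."""

    n: int
    mean_diff: float
    mean_abs_diff: float
    sd_diff: float
    rmse: float
    loa_lower: float  # Bland-Altman limits: mean +/- 2 SD
    loa_upper: float
    p_value: float  # paired two-sided t test of mean difference = 0

    @classmethod
    def from_differences(cls, diff: np.ndarray) -> "AgreementStats":
        diff = np.asarray(diff, dtype=float)
        n = diff.size
        mean = float(diff.mean())
        sd = float(diff.std(ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            p = float(stats.ttest_1samp(diff, 0.0).pvalue)
        else:
            p = 1.0 if mean == 0 else 0.0
        return cls(
            n=n,
            mean_diff=mean,
            mean_abs_diff=float(np.abs(diff).mean()),
            sd_diff=sd,
            rmse=float(np.sqrt((diff**2).mean())),
            loa_lower=mean - 2 * sd,
            loa_upper=mean + 2 * sd,
            p_value=p,
        )


def _proportions(x) -> pd.DataFrame:
    return x.proportions if isinstance(x, CompositionResult) else x


def composition_agreement(
    a, b, scope: str = "overall", presence_min: float = 0.0
):
    """Agreement between two composition tables on the same animals.

    ``scope="overall"`` pools every (animal, breed) cell into one set of
    paired differences.  ``scope="per_breed"`` returns one
    :class:`AgreementStats` per breed over the animals where that breed is
    present (above ``presence_min``, i.e. nonzero by default, in either
    table).
    """
    pa, pb = _proportions(a), _proportions(b)
    if not pa.index.equals(pb.index) or list(pa.columns) != list(pb.columns):
        raise ValueError("composition tables must share animals and breed order")
    diff = pa.to_numpy() - pb.to_numpy()
    if scope == "overall":
        return AgreementStats.from_differences(diff.ravel())
    if scope != "per_breed":
        raise ValueError(f"unknown scope {scope!r}")
    out = {}
    for j, breed in enumerate(pa.columns):
        present = (pa.iloc[:, j].to_numpy() > presence_min) | (
            pb.iloc[:, j].to_numpy() > presence_min
        )
        if present.any():
            out[breed] = AgreementStats.from_differences(diff[present, j])
    return out


def assignment_rate(
    predictions,
    true_labels: pd.Series,
    threshold: float = ASSIGN_THRESHOLD,
) -> float:
    """Percent of purebreds whose predicted composition reaches ``threshold``
    for their true breed."""
    prop = _proportions(predictions)
    true_labels = true_labels.astype(str)
    common = prop.index.intersection(true_labels.index)
    if len(common) == 0:
        raise ValueError("no shared animals between predictions and labels")
    prop = prop.loc[common]
    truth = true_labels.loc[common]
    cols = prop.columns.get_indexer(truth)
    if (cols < 0).any():
        bad = sorted(set(truth[cols < 0]))
        raise ValueError(f"true labels not among predicted breeds: {bad[:5]}")
    own = prop.to_numpy()[np.arange(len(prop)), cols]
    return float((own >= threshold).mean() * 100.0)


def main_breed_deviation(
    predictions, gold, presence_min: float = 0.05
) -> pd.Series:
    """Per-animal |prediction - gold| on the gold standard's main breed."""
    pp, pg = _proportions(predictions), _proportions(gold)
    if not pp.index.equals(pg.index):
        raise ValueError("prediction and gold standard must share animals")
    main = pg.to_numpy().argmax(axis=1)
    rows = np.arange(len(pg))
    dev = np.abs(pp.to_numpy()[rows, main] - pg.to_numpy()[rows, main])
    return pd.Series(dev, index=pg.index, name="main_breed_abs_dev")


def gold_standard_comparison(
    panel_predictions: dict,
    gold: CompositionResult,
    purebred_labels: pd.Series | None = None,
    crossbred_ids=None,
) -> pd.DataFrame:
    """Long-format table of panel performance against the gold standard.

    ``panel_predictions`` maps (strategy, density, predictor) to a
    :class:`CompositionResult` on the same validation animals as ``gold``.
    Reports the purebred assignment rate (when labels are supplied) and the
    crossbred mean absolute main-breed deviation from the gold standard
    (over ``crossbred_ids``, or all animals not covered by the labels).
    """
    rows = []
    for (strategy, density, predictor), pred in panel_predictions.items():
        row = {"strategy": strategy, "density": density, "predictor": predictor}
        if purebred_labels is not None:
            row["purebred_assignment_rate"] = assignment_rate(pred, purebred_labels)
        ids = crossbred_ids
        if ids is None and purebred_labels is not None:
            ids = gold.proportions.index.difference(purebred_labels.index)
        if ids is not None and len(ids):
            dev = main_breed_deviation(
                _proportions(pred).loc[ids],
                CompositionResult(
                    gold.proportions.loc[ids],
                    gold.raw.loc[ids],
                    gold.assigned.loc[ids],
                    gold.unassignable.loc[ids],
                    gold.method,
                ),
            )
            row["crossbred_mean_abs_dev"] = float(dev.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def mislabeling_experiment(
    dataset: StudyDataset,
    breed: str,
    fraction_mislabeled: float = 0.5,
    partner_breed: str | None = None,
    seed: int = 0,
    secondary_threshold: float = 0.60,
) -> pd.DataFrame:
    """Contaminate one breed's training set with F1 crossbreds and refit.

    The stated fraction of the target breed's training animals is replaced
    by freshly simulated F1 crosses (target x partner) that keep the target
    breed's label — mimicking mislabeled crossbreds entering a purebred
    training population.  Both predictors are refit on the contaminated
    training set and scored on the target breed's purebred validation
    animals; rates are reported at the 0.90 assignment threshold and at a
    secondary 0.60 threshold.
    """
    if not 0 <= fraction_mislabeled <= 1:
        raise ValueError("fraction_mislabeled must be in [0, 1]")
    breeds = dataset.breeds
    if breed not in breeds:
        raise ValueError(f"unknown breed {breed!r}")
    if partner_breed is None:
        partner_breed = next(b for b in breeds if b != breed)
    train = dataset.training
    labels = train.samples["breed"].astype(str)
    target_ids = labels.index[labels == breed]
    n_replace = int(round(fraction_mislabeled * len(target_ids)))

    if n_replace:
        rng = np.random.default_rng(seed)
        drop = rng.choice(target_ids, size=n_replace, replace=False)
        bi, pi = breeds.index(breed), breeds.index(partner_breed)
        design = CrossDesign(f"{breed}x{partner_breed} F1", (bi, pi), n_replace)
        crosses = simulate_crossbreds(
            dataset.freqs, [design], dataset.config, seed=seed + 1
        )
        crosses.samples["breed"] = breed  # the mislabeling
        crosses.samples["population"] = "training"
        keep = train.subset(samples=train.sample_ids.difference(drop, sort=False))
        geno = np.vstack([keep.genotypes, crosses.genotypes])
        samples = pd.concat(
            [keep.samples, crosses.samples.reindex(columns=keep.samples.columns)]
        )
        from .genotype_io import GenotypeMatrix

        train = GenotypeMatrix(geno, samples, keep.markers)

    val = dataset.purebred_validation
    val_labels = val.samples["breed"].astype(str)
    target_val = val.subset(samples=val_labels.index[val_labels == breed])
    truth = target_val.samples["breed"].astype(str)

    rows = []
    for name, fn in (("snp_blup", predict_snp_blup), ("admixture", predict_admixture)):
        pred = fn(train, target_val)
        rows.append(
            {
                "predictor": name,
                "assignment_rate_090": assignment_rate(pred, truth),
                "assignment_rate_secondary": assignment_rate(
                    pred, truth, threshold=secondary_threshold
                ),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def bland_altman_plot(a, b, ax=None):
    """Bland–Altman plot of two composition tables (difference vs mean)."""
    import matplotlib.pyplot as plt

    pa, pb = _proportions(a), _proportions(b)
    diff = (pa.to_numpy() - pb.to_numpy()).ravel()
    mean = ((pa.to_numpy() + pb.to_numpy()) / 2.0).ravel()
    stats_ = AgreementStats.from_differences(diff)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean, diff, s=4, alpha=0.4)
    ax.axhline(stats_.mean_diff, color="tab:blue")
    ax.axhline(stats_.loa_lower, color="tab:red", linestyle="--")
    ax.axhline(stats_.loa_upper, color="tab:red", linestyle="--")
    ax.set_xlabel("mean of the two predictions")
    ax.set_ylabel("difference")
    return ax
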