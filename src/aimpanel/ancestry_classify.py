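"""Naive-Bayes population assignment with leave-one-out cross-validation.

Each class (population or pooled continental group) is summarized by smoothed
per-locus insertion frequencies; an individual's class log-likelihood is the
sum over loci of the log Hardy-Weinberg genotype probability.  LOOCV removes
the held-out individual from its own class before retraining frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyClassError, NoUsableLociError, SingletonClassError
from .io_formats import MISSING, GenotypeTable


@dataclass
class TrainingFrequencies:
    """Smoothed per-class insertion frequencies.

    ``freqs[k, l]`` is the smoothed frequency of class ``k`` at locus ``l``;
    ``ins_counts``/``allele_totals`` keep the raw counts so single individuals
    can be subtracted for LOOCV.
    """

    class_labels: list[str]
    locus_ids: list[str]
    freqs: np.ndarray          # (K, L), strictly inside (0, 1) when s > 0
    ins_counts: np.ndarray     # (K, L) observed insertion-allele counts
    allele_totals: np.ndarray  # (K, L) observed allele counts (2 * genotyped)
    smoothing: float


@dataclass
class AssignmentResult:
    sample_id: str
    class_labels: list[str]
    log_likelihoods: np.ndarray
    assigned: str
    posteriors: np.ndarray     # equal priors

    def posterior(self, label: str) -> float:
        return float(self.posteriors[self.class_labels.index(label)])


def _smooth(ins: np.ndarray, total: np.ndarray, s: float) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ins + s) / (total + 2 * s)


def train_frequencies(table: GenotypeTable, class_labels=None,
                      smoothing: float = 0.5, classes=None) -> TrainingFrequencies:
    """Estimate per-class smoothed insertion frequencies.

    ``class_labels`` overrides the table's population labels (e.g., to pool
    populations into continental groups); default uses them as-is.
    ``classes`` fixes the class universe explicitly; a listed class with no
    members raises :class:`EmptyClassError`.
    """
    labels = list(class_labels) if class_labels is not None else list(table.population_labels)
    if len(labels) != table.n_samples:
        raise ValueError("class_labels length mismatch")
    classes = list(classes) if classes is not None else list(dict.fromkeys(labels))
    lab_arr = np.asarray(labels)
    K, L = len(classes), table.n_loci
    ins = np.zeros((K, L))
    tot = np.zeros((K, L))
    d = table.dosage
    observed = d != MISSING
    dos = np.where(observed, d, 0)
    for k, cls in enumerate(classes):
        rows = lab_arr == cls
        if not rows.any():
            raise EmptyClassError(f"class {cls!r} has no individuals")
        ins[k] = dos[rows].sum(axis=0)
        tot[k] = 2 * observed[rows].sum(axis=0)
    return TrainingFrequencies(classes, list(table.locus_ids),
                               _smooth(ins, tot, smoothing), ins, tot, smoothing)


def _genotype_loglik(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Log-likelihood of one individual's dosage vector under each class.

    ``dosages``: (L,) with MISSING skipped; ``freqs``: (K, L).
    """
    obs = dosages != MISSING
    if not obs.any():
        raise NoUsableLociError("individual has no genotype at any trained locus")
    g = dosages[obs].astype(float)
    p = freqs[:, obs]
    q = 1 - p
    logprob = np.where(g == 2, 2 * np.log(p),
                       np.where(g == 1, np.log(2) + np.log(p) + np.log(q),
                                2 * np.log(q)))
    return logprob.sum(axis=1)


def classify(dosages: np.ndarray, training: TrainingFrequencies,
             sample_id: str = "") -> AssignmentResult:
    """Assign one individual by maximum HWE naive-Bayes log-likelihood.

    Ties are broken toward the lexically smallest class label.
    """
    ll = _genotype_loglik(np.asarray(dosages), training.freqs)
    shifted = np.exp(ll - ll.max())
    post = shifted / shifted.sum()
    top = ll.max()
    tied = [k for k in range(len(ll)) if ll[k] == top]
    best = min(tied, key=lambda k: training.class_labels[k])
    return AssignmentResult(sample_id, list(training.class_labels), ll,
                            training.class_labels[best], post)


@dataclass
class ConfusionMatrix:
    """Origin x assigned-class counts and row-normalized proportions."""

    counts: pd.DataFrame

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def success_ratios(self) -> pd.Series:
        """Diagonal of the proportion matrix (per-class success)."""
        prop = self.proportions
        return pd.Series({c: prop.loc[c, c] for c in prop.index})


def loocv(table: GenotypeTable, class_labels=None, smoothing: float = 0.5,
          *, remove_held_out: bool = True) -> ConfusionMatrix:
    """Leave-one-out cross-validated confusion matrix.

    Every individual is reclassified after its genotypes are removed from its
    own class's training counts (``remove_held_out=False`` disables the
    removal; only useful as a sanity check).
    """
    training = train_frequencies(table, class_labels, smoothing)
    labels = list(class_labels) if class_labels is not None else list(table.population_labels)
    classes = training.class_labels
    sizes = pd.Series(labels).value_counts()
    tiny = [c for c in classes if sizes[c] < 2]
    if tiny and remove_held_out:
        raise SingletonClassError(f"classes with a single individual: {tiny}")

    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    d = table.dosage
    for i in range(table.n_samples):
        cls = labels[i]
        k = classes.index(cls)
        if remove_held_out:
            obs = d[i] != MISSING
            dos = np.where(obs, d[i], 0)
            ins = training.ins_counts[k] - dos
            tot = training.allele_totals[k] - 2 * obs
            freqs = training.freqs.copy()
            freqs[k] = _smooth(ins, tot, training.smoothing)
            held = TrainingFrequencies(classes, training.locus_ids, freqs,
                                       training.ins_counts, training.allele_totals,
                                       training.smoothing)
        else:
            held = training
        result = classify(d[i], held, table.sample_ids[i])
        counts.loc[cls, result.assigned] += 1
    return ConfusionMatrix(counts)


def success_ratios(confusion: ConfusionMatrix) -> pd.Series:
    return confusion.success_ratios()
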