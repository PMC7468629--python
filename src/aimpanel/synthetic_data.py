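"""Seeded genotype simulation under the Balding-Nichols divergence model.

Each locus draws an ancestral insertion frequency from a uniform window; each
divergent group then draws its own frequency from the Balding-Nichols Beta
distribution ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` whose expected F_st equals
``F``.  Admixed groups are simulated per allele copy: every copy first draws
its source group from the individual's ancestry vector Q, then the allele
from that group's frequency — exactly the likelihood the admixture fitter
maximizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io_formats import MISSING, GenotypeTable


@dataclass
class GroupSpec:
    label: str
    n: int
    F: float

    def __post_init__(self) -> None:
        if not (0 < self.F < 1):
            raise ConfigError(f"F must be in (0,1), got {self.F}")
        if self.n < 1:
            raise ConfigError("group size must be >= 1")


@dataclass
class AdmixedGroupSpec:
    label: str
    n: int
    q: tuple[float, ...]  # over the divergent groups, in order

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if (q < 0).any() or abs(q.sum() - 1) > 1e-9:
            raise ConfigError(f"Q vector must be a simplex point, got {self.q}")


@dataclass
class SimConfig:
    L: int
    groups: list[GroupSpec]
    admixed_groups: list[AdmixedGroupSpec] = field(default_factory=list)
    ancestral_low: float = 0.1
    ancestral_high: float = 0.9
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ancestral_low < self.ancestral_high < 1):
            raise ConfigError("ancestral frequency window must satisfy 0 < lo < hi < 1")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        for ag in self.admixed_groups:
            if len(ag.q) != len(self.groups):
                raise ConfigError(f"admixed group {ag.label!r}: Q length != group count")


@dataclass
class SimulatedDataset:
    table: GenotypeTable
    true_ancestral_freqs: np.ndarray           # (L,)
    true_group_freqs: dict[str, np.ndarray]    # label -> (L,)
    true_q: dict[str, np.ndarray]              # admixed sample id -> Q vector
    config: SimConfig

    def group_freq_matrix(self) -> np.ndarray:
        """(K, L) true frequencies of the divergent groups, config order."""
        return np.vstack([self.true_group_freqs[g.label] for g in self.config.groups])


def simulate(config: SimConfig) -> SimulatedDataset:
    """Draw a full dataset from the seeded generator described in the module docstring."""
    rng = np.random.default_rng(config.seed)
    L = config.L
    p0 = rng.uniform(config.ancestral_low, config.ancestral_high, size=L)

    group_freqs: dict[str, np.ndarray] = {}
    for g in config.groups:
        ratio = (1 - g.F) / g.F
        pk = rng.beta(p0 * ratio, (1 - p0) * ratio)
        group_freqs[g.label] = np.clip(pk, 1e-9, 1 - 1e-9)

    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for g in config.groups:
        pk = group_freqs[g.label]
        geno = rng.binomial(2, pk, size=(g.n, L)).astype(np.int16)
        rows.append(geno)
        sample_ids += [f"{g.label}_{i:04d}" for i in range(g.n)]
        labels += [g.label] * g.n

    true_q: dict[str, np.ndarray] = {}
    freq_stack = np.vstack([group_freqs[g.label] for g in config.groups])  # (K, L)
    for ag in config.admixed_groups:
        q = np.asarray(ag.q, dtype=float)
        geno = np.empty((ag.n, L), dtype=np.int16)
        for i in range(ag.n):
            # each of the two copies draws its source group independently
            src = rng.choice(len(q), size=(2, L), p=q)
            copies = rng.random((2, L)) < freq_stack[src, np.arange(L)[None, :]]
            geno[i] = copies.sum(axis=0)
        rows.append(geno)
        ids = [f"{ag.label}_{i:04d}" for i in range(ag.n)]
        sample_ids += ids
        labels += [ag.label] * ag.n
        for sid in ids:
            true_q[sid] = q

    dosage = np.vstack(rows)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(mask, MISSING, dosage)

    table = GenotypeTable(sample_ids, labels,
                          [f"L{j:04d}" for j in range(L)], dosage)
    return SimulatedDataset(table, p0, group_freqs, true_q, config)


#: Generating ancestry of the admixed "AMR-like" group over (AFR, EUR, EAS, SAS).
AMR_LIKE_Q = (0.10, 0.45, 0.05, 0.40)
#: Generating ancestry of the study-target group over (AFR, EUR, EAS, SAS).
TARGET_Q = (0.03, 0.08, 0.89, 0.00)


def make_world_fixture(seed: int = 0, n_per_group: int = 100, L: int = 38) -> SimulatedDataset:
    """Five-continent world with one admixed target group.

    Four divergent groups (AFR-like F=0.20, EUR-like F=0.12, EAS-like F=0.15,
    SAS-like F=0.10), an admixed AMR-like group, and a TARGET group with
    ancestry dominated by the EAS-like source — the structure every pipeline
    stage is exercised on.
    """
    config = SimConfig(
        L=L,
        groups=[
            GroupSpec("AFR-like", n_per_group, 0.20),
            GroupSpec("EUR-like", n_per_group, 0.12),
            GroupSpec("EAS-like", n_per_group, 0.15),
            GroupSpec("SAS-like", n_per_group, 0.10),
        ],
        admixed_groups=[
            AdmixedGroupSpec("AMR-like", n_per_group, AMR_LIKE_Q),
            AdmixedGroupSpec("TARGET", n_per_group, TARGET_Q),
        ],
        seed=seed,
    )
    return simulate(config)
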