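"""Synthetic longitudinal multimodal cohorts with planted effects.

Emulates the shape of a two-modality (fMRI/sMRI ROI summaries), four-visit,
90-region case-control neuroimaging cohort: per (modality, time point) a
subjects x features matrix, one shared binary diagnosis, and a small set of
informative features whose class separation grows linearly across visits
(progressive disease effect).  The generative model per entry is

    x[i, j, t, m] = u_i + c_i * delta(j, t, m) + e

with subject random effect ``u_i ~ N(0, subject_random_effect_sd^2)``
(shared across all features, visits and modalities — the simplest structure
that makes coefficient profiles temporally smooth), case indicator
``c_i in {0, 1}``, planted effect ``delta = effect_base + (t-1) *
effect_slope`` on informative features (0 elsewhere), and iid Gaussian noise
``e ~ N(0, noise_sd^2)``.  Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import CohortTable

__all__ = ["SimSpec", "generate", "degrade"]


@dataclass(frozen=True)
class SimSpec:
    """Cohort design. Defaults mirror the target study's shape: 200
    subjects per class, 90 ROI features, 4 visits, 2 modalities, 10
    informative features with a 1.5-SD baseline effect growing by 0.25 SD
    per visit, unit noise."""

    n_per_class: int = 200
    d: int = 90
    T: int = 4
    M: int = 2
    n_informative: int = 10
    effect_base: float = 1.5
    effect_slope: float = 0.25
    cross_modality_overlap: float = 0.5
    noise_sd: float = 1.0
    subject_random_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.d:
            raise ValueError("n_informative cannot exceed d")
        if min(self.noise_sd, self.subject_random_effect_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.cross_modality_overlap <= 1:
            raise ValueError("cross_modality_overlap must lie in [0, 1]")
        if min(self.n_per_class, self.d, self.T, self.M) < 1:
            raise ValueError("degenerate cohort dimensions")


def _informative_sets(spec: SimSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Planted informative feature indices per modality.

    Modality 0 gets ``n_informative`` random features; each further modality
    shares a ``cross_modality_overlap`` fraction with modality 0 and draws
    the remainder from the uninformative pool (complementary information).
    """
    base = rng.choice(spec.d, size=spec.n_informative, replace=False)
    sets = [np.sort(base)]
    n_shared = int(round(spec.cross_modality_overlap * spec.n_informative))
    pool = np.setdiff1d(np.arange(spec.d), base)
    for _ in range(1, spec.M):
        shared = rng.choice(base, size=n_shared, replace=False)
        fresh_n = spec.n_informative - n_shared
        fresh = rng.choice(pool, size=min(fresh_n, pool.size), replace=False)
        sets.append(np.sort(np.concatenate([shared, fresh])))
    return sets


def generate(spec: SimSpec) -> tuple[CohortTable, list[np.ndarray]]:
    """Draw one cohort; returns the table and the planted support per
    modality (ground truth for selection benchmarks)."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    labels = np.concatenate([np.ones(spec.n_per_class, dtype=int),
                             -np.ones(spec.n_per_class, dtype=int)])
    order = rng.permutation(n)
    labels = labels[order]
    case = (labels == 1).astype(float)

    support = _informative_sets(spec, rng)
    subject_effect = rng.normal(0.0, spec.subject_random_effect_sd, size=n)

    cells: dict[tuple[int, int], np.ndarray] = {}
    for m in range(spec.M):
        delta_j = np.zeros(spec.d)
        delta_j[support[m]] = 1.0
        for t in range(spec.T):
            effect = spec.effect_base + t * spec.effect_slope
            X = rng.normal(0.0, spec.noise_sd, size=(n, spec.d))
            X += subject_effect[:, None]
            X += np.outer(case, effect * delta_j)
            cells[(m, t)] = X

    table = CohortTable(
        cells,
        labels,
        modality_names=tuple(f"mod{m + 1}" for m in range(spec.M)),
        timepoint_names=tuple(f"t{t + 1}" for t in range(spec.T)),
        feature_names=tuple(f"f{j + 1}" for j in range(spec.d)),
    )
    return table, support


def degrade(
    table: CohortTable,
    flip_fraction: float = 0.0,
    extra_noise_sd: float = 0.0,
    seed: int = 0,
) -> CohortTable:
    """Stress a cohort: flip an exact fraction of labels and add feature
    noise, reproducibly.  ``flip_fraction`` must be < 0.5 so the majority
    signal survives."""
    if not 0 <= flip_fraction < 0.5:
        raise ValueError("flip_fraction must lie in [0, 0.5)")
    if extra_noise_sd < 0:
        raise ValueError("extra_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.asarray(table.labels).copy()
    n_flip = int(round(flip_fraction * labels.size))
    if n_flip:
        flip_idx = rng.choice(labels.size, size=n_flip, replace=False)
        labels[flip_idx] = -labels[flip_idx]
    cells = {}
    for key, X in table.features.items():
        X = X.copy()
        if extra_noise_sd > 0:
            X += rng.normal(0.0, extra_noise_sd, size=X.shape)
        cells[key] = X
    return CohortTable(cells, labels, table.modality_names,
                       table.timepoint_names, table.feature_names)
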