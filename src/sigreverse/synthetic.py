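"""Synthetic drug-perturbation and disease expression libraries.

The generator emulates the statistical structure a signature-reversal
repositioning screen assumes: a library of compounds profiled under several
cell-context × dose conditions against vehicle controls, and a disease
library in which one target disease profile is an attenuated, noisy
mirror-image of one planted compound's effect vector.

Counts are negative-binomial around a shared lognormal per-gene baseline.
The planted compound shifts its effect genes' log2 means by ±``effect_size``
(full at high dose, halved at low dose); decoy compounds receive their own
independently drawn effect gene sets and directions, so the planted compound
is distinguished only by its relationship to the target disease. The target
disease carries the planted effect genes with opposite signs at magnitude
``reversal_strength × effect_size``; decoy diseases carry independent effects
at full magnitude.

Every output is a pure function of the configuration: each entity (baseline,
ground truth, compound-condition arm, disease cohort) draws from its own RNG
stream seeded from ``config.seed`` plus a stable per-entity offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .signatures import ConditionKey, ExpressionMatrix

#: case/control cohort sizes used for the target disease when
#: ``samples_per_arm`` is unset — emulating a 12-patient / 5-control biopsy
#: cohort, the typical shape of a small clinical disease signature.
DEFAULT_DISEASE_COHORT = (12, 5)
DEFAULT_COMPOUND_ARM = 5

_CELLS = ("cellA", "cellB")
_DOSES = ("high", "low")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of one synthetic repositioning study.

    ``effect_size`` is the log2 fold-change magnitude of planted genes;
    ``reversal_strength`` in [0, 1] attenuates the mirrored disease effect;
    ``dispersion`` is the negative-binomial overdispersion (variance
    mu + dispersion·mu²); baselines are lognormal with the given natural-log
    mean and sd. ``samples_per_arm`` of None uses 5 per compound arm and a
    12/5 case-control disease cohort.
    """

    n_genes: int = 2000
    n_effect_genes: int = 100
    effect_size: float = 2.0
    reversal_strength: float = 0.5
    n_compounds: int = 51
    n_conditions: int = 4
    n_diseases: int = 10
    samples_per_arm: int | None = None
    dispersion: float = 0.1
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_compounds < 1 or self.n_diseases < 1:
            raise ConfigurationError("dimensions must be positive")
        if self.n_conditions < 1:
            raise ConfigurationError("n_conditions must be positive")
        if not (1 <= self.n_effect_genes <= self.n_genes):
            raise ConfigurationError("n_effect_genes must be in [1, n_genes]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if not (0.0 <= self.reversal_strength <= 1.0):
            raise ConfigurationError("reversal_strength must be in [0, 1]")
        if self.samples_per_arm is not None and self.samples_per_arm < 2:
            raise ConfigurationError("samples_per_arm must be >= 2")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def compound_ids(self) -> list[str]:
        width = len(str(self.n_compounds - 1))
        return [f"cmpd{i:0{width}d}" for i in range(self.n_compounds)]

    @property
    def disease_ids(self) -> list[str]:
        width = len(str(self.n_diseases - 1))
        return [f"disease{i:0{width}d}" for i in range(self.n_diseases)]

    @property
    def conditions(self) -> list[tuple[str, str]]:
        """(cell, dose) labels; contexts alternate, doses pair within context."""
        out = []
        for j in range(self.n_conditions):
            cell = _CELLS[(j // 2) % 2] if j // 2 < 2 else f"cell{j // 2}"
            out.append((cell, _DOSES[j % 2]))
        return out

    def compound_arm_size(self) -> int:
        return self.samples_per_arm or DEFAULT_COMPOUND_ARM

    def disease_cohort(self, disease_index: int) -> tuple[int, int]:
        if self.samples_per_arm is not None:
            return self.samples_per_arm, self.samples_per_arm
        return DEFAULT_DISEASE_COHORT

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """The planted relationship a run is expected to recover."""

    planted_compound_id: str
    target_disease_id: str
    effect_genes: frozenset
    effect_directions: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.effect_directions) != set(self.effect_genes):
            raise ConsistencyError("directions must cover exactly the effect genes")
        if any(d not in (-1, 1) for d in self.effect_directions.values()):
            raise ConsistencyError("directions must be ±1")


def _rng(config: SyntheticStudyConfig, *offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, *offset]))


def _baseline_means(config: SyntheticStudyConfig) -> np.ndarray:
    rng = _rng(config, 1)
    return np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes))


def _draw_effect(rng: np.random.Generator, config: SyntheticStudyConfig) -> dict[str, int]:
    genes = config.gene_ids
    idx = rng.choice(config.n_genes, size=config.n_effect_genes, replace=False)
    signs = rng.integers(0, 2, size=config.n_effect_genes) * 2 - 1
    return {genes[i]: int(s) for i, s in zip(idx, signs)}


def ground_truth(config: SyntheticStudyConfig) -> GroundTruth:
    """Deterministically derive the planted compound, target disease and effects."""
    rng = _rng(config, 0)
    planted = int(rng.integers(config.n_compounds))
    target = int(rng.integers(config.n_diseases))
    directions = _draw_effect(rng, config)
    return GroundTruth(
        planted_compound_id=config.compound_ids[planted],
        target_disease_id=config.disease_ids[target],
        effect_genes=frozenset(directions),
        effect_directions=directions,
    )


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, n_samples: int
) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p[:, None], size=(len(mean), n_samples))


def _arm_matrix(
    rng: np.random.Generator,
    config: SyntheticStudyConfig,
    mean: np.ndarray,
    n_samples: int,
    sample_prefix: str,
) -> ExpressionMatrix:
    counts = _nb_counts(rng, mean, config.dispersion, n_samples)
    samples = [f"{sample_prefix}{i}" for i in range(n_samples)]
    df = pd.DataFrame(counts, index=config.gene_ids, columns=samples)
    return ExpressionMatrix(df)


def _effect_vector(
    config: SyntheticStudyConfig, directions: Mapping[str, int], magnitude: float
) -> np.ndarray:
    gene_index = {g: i for i, g in enumerate(config.gene_ids)}
    delta = np.zeros(config.n_genes)
    for g, s in directions.items():
        delta[gene_index[g]] = s * magnitude
    return delta


def _compound_effects(
    config: SyntheticStudyConfig, truth: GroundTruth
) -> dict[str, Mapping[str, int]]:
    effects: dict[str, Mapping[str, int]] = {}
    for i, cid in enumerate(config.compound_ids):
        if cid == truth.planted_compound_id:
            effects[cid] = truth.effect_directions
        else:
            effects[cid] = _draw_effect(_rng(config, 4, i), config)
    return effects


def generate_compound_library(
    config: SyntheticStudyConfig,
) -> Iterator[tuple[ConditionKey, ExpressionMatrix, ExpressionMatrix]]:
    """Yield (key, treated, control) for every compound-condition.

    High-dose conditions apply the full ``effect_size`` shift to each
    compound's effect genes; low-dose conditions apply half. Cell contexts
    share effect genes and differ only in noise draws.
    """
    truth = ground_truth(config)
    baseline = _baseline_means(config)
    effects = _compound_effects(config, truth)
    arm = config.compound_arm_size()
    for i, cid in enumerate(config.compound_ids):
        for j, (cell, dose) in enumerate(config.conditions):
            key = ConditionKey(cid, cell, dose)
            magnitude = config.effect_size * (1.0 if dose == "high" else 0.5)
            delta = _effect_vector(config, effects[cid], magnitude)
            treated_mean = baseline * np.exp2(delta)
            rng_t = _rng(config, 2, i, j, 0)
            rng_c = _rng(config, 2, i, j, 1)
            treated = _arm_matrix(rng_t, config, treated_mean, arm, "t")
            control = _arm_matrix(rng_c, config, baseline, arm, "c")
            yield key, treated, control


def generate_disease_library(
    config: SyntheticStudyConfig, truth: GroundTruth
) -> Iterator[tuple[str, ExpressionMatrix, ExpressionMatrix]]:
    """Yield (disease id, case, control) cohorts.

    The target disease's effect genes are the planted compound's with opposite
    directions at magnitude ``reversal_strength × effect_size``; decoys get
    independent effect sets at full ``effect_size``.
    """
    unknown = set(truth.effect_genes) - set(config.gene_ids)
    if unknown:
        raise ConsistencyError(f"ground truth genes outside the universe: {sorted(unknown)[:5]}")
    baseline = _baseline_means(config)
    for k, did in enumerate(config.disease_ids):
        if did == truth.target_disease_id:
            directions = {g: -s for g, s in truth.effect_directions.items()}
            magnitude = config.reversal_strength * config.effect_size
        else:
            directions = _draw_effect(_rng(config, 5, k), config)
            magnitude = config.effect_size
        delta = _effect_vector(config, directions, magnitude)
        case_mean = baseline * np.exp2(delta)
        n_case, n_ctrl = config.disease_cohort(k)
        rng_case = _rng(config, 3, k, 0)
        rng_ctrl = _rng(config, 3, k, 1)
        case = _arm_matrix(rng_case, config, case_mean, n_case, "case")
        control = _arm_matrix(rng_ctrl, config, baseline, n_ctrl, "ctrl")
        yield did, case, control
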