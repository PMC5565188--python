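"""Estimators that turn field tables into stage transition distributions.

Three recruitment stages follow seed deposition:

* ``PREDATION_SURVIVAL`` — probability a seed escapes post-dispersal
  predation; one replicate proportion per (uncensored) predation tray.
* ``EMERGENCE`` — probability a surviving seed emerges as a seedling; one
  replicate per sowing station x treatment.
* ``SEEDLING_SURVIVAL`` — probability an emerged seedling is alive at the
  final census; conditional on emergence, so stations with zero emergence
  contribute no replicate.

Deposition (the seed shadow) is estimated either from the dropping survey
(realized seed arrival, the default) or from direct disperser observations
(time allocation among microhabitats).  A use-versus-availability
selection index with a multinomial bootstrap, a permutation test for
differences between replicate groups, and a step-down sequential
Bonferroni (Holm) correction complete the module.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .datamodel import (
    CORE_MICROHABITATS,
    CoverTable,
    ConfigurationError,
    EstimationError,
    FaecesSurvey,
    FieldDataset,
    PredationTrialRecord,
    SowingRecord,
    UseObservation,
    ValidationError,
    canonical_microhabitat,
)

__all__ = [
    "PREDATION_SURVIVAL",
    "EMERGENCE",
    "SEEDLING_SURVIVAL",
    "STAGES",
    "TransitionTable",
    "DispersalDistribution",
    "SelectionEntry",
    "SelectionIndex",
    "PermutationTest",
    "replicate_proportions",
    "estimate_transition_tables",
    "estimate_dispersal_distribution",
    "microhabitat_selection",
    "compare_proportions",
    "holm_adjust",
]

PREDATION_SURVIVAL = "PREDATION_SURVIVAL"
EMERGENCE = "EMERGENCE"
SEEDLING_SURVIVAL = "SEEDLING_SURVIVAL"
STAGES: tuple[str, ...] = (PREDATION_SURVIVAL, EMERGENCE, SEEDLING_SURVIVAL)

_GROUP_KEY_SEP = "|"
_PROB_SUM_TOL = 1e-9

GroupKey = tuple[str, ...]


@dataclass(frozen=True)
class TransitionTable:
    """Replicate-level transition proportions for one stage, by group.

    Groups are keyed by ``(microhabitat,)`` for the predation stage and by
    ``(microhabitat, treatment)`` for the sowing stages.  This is the
    empirical distribution the recruitment simulation bootstraps.
    """

    stage: str
    groups: dict[GroupKey, list[float]]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        for key, values in self.groups.items():
            if not values:
                raise ValidationError(f"{self.stage}: empty replicate group {key}")
            for v in values:
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"{self.stage} group {key}: proportion {v} outside [0, 1]"
                    )

    def group(self, microhabitat: str, treatment: Optional[str] = None) -> list[float]:
        key: GroupKey = (
            (canonical_microhabitat(microhabitat),)
            if treatment is None
            else (canonical_microhabitat(microhabitat), treatment.upper())
        )
        if key not in self.groups:
            raise EstimationError(f"{self.stage}: no replicate group {key}")
        return self.groups[key]

    def group_means(self) -> dict[GroupKey, float]:
        return {k: float(np.mean(v)) for k, v in self.groups.items()}

    def to_json(self) -> dict:
        return {
            "stage": self.stage,
            "groups": {_GROUP_KEY_SEP.join(k): list(map(float, v)) for k, v in self.groups.items()},
        }

    @classmethod
    def from_json(cls, payload: dict) -> "TransitionTable":
        groups = {
            tuple(key.split(_GROUP_KEY_SEP)): [float(v) for v in values]
            for key, values in payload["groups"].items()
        }
        return cls(stage=payload["stage"], groups=groups)


@dataclass(frozen=True)
class DispersalDistribution:
    """Probability that a dispersed seed is deposited in each microhabitat."""

    probs: dict[str, float]

    def __init__(self, probs: dict[str, float]) -> None:
        canon = {canonical_microhabitat(m): float(p) for m, p in probs.items()}
        for m, p in canon.items():
            if p < 0:
                raise ValidationError(f"deposition probability for {m} is negative: {p}")
        total = sum(canon.values())
        if not math.isclose(total, 1.0, abs_tol=_PROB_SUM_TOL):
            raise ValidationError(f"deposition probabilities sum to {total}, not 1")
        object.__setattr__(self, "probs", canon)

    def to_json(self) -> dict:
        return {"probs": dict(self.probs)}

    @classmethod
    def from_json(cls, payload: dict) -> "DispersalDistribution":
        return cls(payload["probs"])


def replicate_proportions(
    records: Sequence[Union[PredationTrialRecord, SowingRecord]],
    stage: str,
    grouping: Optional[str] = None,
) -> TransitionTable:
    """Build the replicate-level transition table for one stage.

    ``grouping`` is ``"microhabitat"`` or ``"microhabitat_treatment"``; by
    default the predation stage groups by microhabitat only (trays carry no
    treatment) and the sowing stages by microhabitat x treatment.

    Censored trays are excluded; stations with zero emergence contribute no
    seedling-survival replicate.  A group whose every replicate is excluded
    raises :class:`EstimationError` naming the group.
    """
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    if grouping is None:
        grouping = "microhabitat" if stage == PREDATION_SURVIVAL else "microhabitat_treatment"
    if grouping not in ("microhabitat", "microhabitat_treatment"):
        raise ConfigurationError(f"unknown grouping {grouping!r}")

    def key_of(rec) -> GroupKey:
        if grouping == "microhabitat":
            return (rec.microhabitat,)
        if isinstance(rec, PredationTrialRecord):
            raise ValidationError("predation trays carry no treatment; use grouping='microhabitat'")
        return (rec.microhabitat, rec.treatment)

    raw_keys: set[GroupKey] = set()
    groups: dict[GroupKey, list[float]] = {}
    for rec in records:
        key = key_of(rec)
        raw_keys.add(key)
        if stage == PREDATION_SURVIVAL:
            if not isinstance(rec, PredationTrialRecord):
                raise ValidationError("PREDATION_SURVIVAL requires predation tray records")
            if rec.censored:
                continue
            value = rec.n_surviving / rec.n_exposed
        elif stage == EMERGENCE:
            if not isinstance(rec, SowingRecord):
                raise ValidationError("EMERGENCE requires sowing records")
            value = rec.n_emerged / rec.n_sown
        else:  # SEEDLING_SURVIVAL, conditional on emergence
            if not isinstance(rec, SowingRecord):
                raise ValidationError("SEEDLING_SURVIVAL requires sowing records")
            if rec.n_emerged == 0:
                continue
            value = rec.n_surviving / rec.n_emerged
        groups.setdefault(key, []).append(value)

    for key in sorted(raw_keys):
        if key not in groups:
            raise EstimationError(
                f"{stage}: group {key} has no usable replicates after exclusions"
            )
    if not groups:
        raise EstimationError(f"{stage}: no records supplied")
    return TransitionTable(stage=stage, groups={k: groups[k] for k in sorted(groups)})


def estimate_transition_tables(dataset: FieldDataset) -> dict[str, TransitionTable]:
    """All three stage tables from one campaign, with the default groupings."""
    return {
        PREDATION_SURVIVAL: replicate_proportions(dataset.predation, PREDATION_SURVIVAL),
        EMERGENCE: replicate_proportions(dataset.sowing, EMERGENCE),
        SEEDLING_SURVIVAL: replicate_proportions(dataset.sowing, SEEDLING_SURVIVAL),
    }


def estimate_dispersal_distribution(
    source: Union[FaecesSurvey, Sequence[UseObservation]],
    restrict_to: Optional[Iterable[str]] = None,
) -> DispersalDistribution:
    """Estimate the deposition distribution from droppings or sightings.

    Probabilities are proportional to counts, renormalized over
    ``restrict_to`` (default: the three core microhabitats).
    """
    if restrict_to is None:
        restrict_to = CORE_MICROHABITATS
    restrict = [canonical_microhabitat(m) for m in restrict_to]

    if isinstance(source, FaecesSurvey):
        counts = {m: source.counts.get(m, 0) for m in restrict}
    else:
        counts = {m: 0 for m in restrict}
        for obs in source:
            if obs.microhabitat in counts:
                counts[obs.microhabitat] += 1
    total = sum(counts.values())
    if total <= 0:
        raise EstimationError(
            f"no droppings/observations within microhabitats {restrict}"
        )
    return DispersalDistribution({m: c / total for m, c in counts.items()})


@dataclass(frozen=True)
class SelectionEntry:
    droppings_pct: float
    cover_pct: float
    index: float  # droppings_pct - cover_pct, in percentage points
    ci_low: float
    ci_high: float

    @property
    def positively_selected(self) -> bool:
        return self.ci_low > 0

    @property
    def negatively_selected(self) -> bool:
        return self.ci_high < 0


@dataclass(frozen=True)
class SelectionIndex:
    """Use-versus-availability selection of deposition microhabitats.

    For each microhabitat: the percentage of droppings found there minus
    its percentage cover.  Zero means deposition at random with respect to
    cover; positive means the microhabitat receives more droppings than
    expected.  The confidence interval comes from a multinomial bootstrap
    of the dropping counts with cover held fixed.
    """

    entries: dict[str, SelectionEntry]
    n_boot: int
    seed: int


def microhabitat_selection(
    faeces: FaecesSurvey,
    cover: CoverTable,
    n_boot: int = 2000,
    seed: int = 0,
) -> SelectionIndex:
    """Selection index per microhabitat with a percentile bootstrap interval."""
    if n_boot < 1:
        raise ConfigurationError(f"n_boot must be >= 1, got {n_boot}")
    total = faeces.total
    if total <= 0:
        raise EstimationError("faeces survey has zero total count")

    names = list(cover.names)
    counts = np.array([faeces.counts.get(m, 0) for m in names], dtype=float)
    obs_props = counts / total
    cover_pct = np.array([cover.cover(m) for m in names]) * 100.0

    rng = np.random.default_rng(seed)
    resampled = rng.multinomial(total, obs_props, size=n_boot)  # (n_boot, k)
    boot_index = resampled / total * 100.0 - cover_pct
    lo = np.percentile(boot_index, 2.5, axis=0)
    hi = np.percentile(boot_index, 97.5, axis=0)

    entries = {
        m: SelectionEntry(
            droppings_pct=float(obs_props[i] * 100.0),
            cover_pct=float(cover_pct[i]),
            index=float(obs_props[i] * 100.0 - cover_pct[i]),
            ci_low=float(lo[i]),
            ci_high=float(hi[i]),
        )
        for i, m in enumerate(names)
    }
    return SelectionIndex(entries=entries, n_boot=n_boot, seed=seed)


@dataclass(frozen=True)
class PermutationTest:
    difference: float  # mean(group_a) - mean(group_b)
    p_value: float
    n_permutations: int
    exact: bool


def compare_proportions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 9999,
    seed: int = 0,
    exact: bool = False,
) -> PermutationTest:
    """Two-sided permutation test for a difference in mean proportions.

    ``exact=True`` enumerates every assignment of the pooled replicates to
    the two group sizes (feasible for small replicate counts) and reports
    the exact proportion of assignments at least as extreme as observed.
    The Monte-Carlo version uses the (1 + count) / (1 + n_perm) convention,
    so p is always in (0, 1].
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")

    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    tol = 1e-12

    if exact:
        total = math.comb(n, na)
        count = 0
        for idx in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            d = pooled[mask].mean() - pooled[~mask].mean()
            if abs(d) >= abs(observed) - tol:
                count += 1
        return PermutationTest(observed, count / total, total, True)

    rng = np.random.default_rng(seed)
    count = 0
    # vectorized in blocks to bound memory on large n_perm
    block = 2000
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        order = np.argsort(rng.random((k, n)), axis=1)
        perm = pooled[order]
        d = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
        count += int(np.sum(np.abs(d) >= abs(observed) - tol))
        done += k
    p = (1 + count) / (1 + n_perm)
    return PermutationTest(observed, float(p), n_perm, False)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down sequential Bonferroni (Holm) adjustment, input order preserved.

    Sort ascending, multiply the i-th smallest by (m - i), enforce monotone
    non-decreasing adjusted values, cap at 1.
    """
    p = list(map(float, p_values))
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"p-value {v} outside [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        value = min(1.0, (m - rank) * p[i])
        running = max(running, value)
        adjusted[i] = running
    return adjusted
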