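"""Domain types for seed-fate field campaigns.

A campaign records, for one fruiting season of an animal-dispersed plant:

* ground cover of each deposition microhabitat (open interspaces vs. the
  canopies of named shrub species),
* direct observations of disperser activity per microhabitat,
* a survey of disperser droppings containing seeds of the target species,
* seed-predation trays (seeds exposed on the ground, survivors counted at
  the end of monitoring), and
* sowing stations (seeds sown per gut-passage treatment, with seedling
  emergence and first-season survival recorded).

Every record carries the microhabitat, zone and spatial-block ("set")
labels of the underlying field design so the replicate structure survives
the trip through estimation.  Microhabitat labels are case-insensitive on
input and canonical upper-case in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "OPEN",
    "EPHEDRA",
    "PISTACIA",
    "OTHER",
    "CORE_MICROHABITATS",
    "ALL_MICROHABITATS",
    "DIGESTED",
    "RED",
    "YELLOW",
    "TREATMENTS",
    "SeedFateError",
    "SchemaError",
    "ValidationError",
    "EstimationError",
    "SimulationError",
    "ConfigurationError",
    "Microhabitat",
    "CoverTable",
    "UseObservation",
    "FaecesSurvey",
    "PredationTrialRecord",
    "SowingRecord",
    "FieldDataset",
    "canonical_microhabitat",
]

# Canonical microhabitat labels.  OPEN is bare ground; EPHEDRA and PISTACIA
# are the canopies of the focal shrub and the dominant companion shrub;
# OTHER aggregates all remaining vegetation.
OPEN = "OPEN"
EPHEDRA = "EPHEDRA"
PISTACIA = "PISTACIA"
OTHER = "OTHER"
CORE_MICROHABITATS: tuple[str, ...] = (OPEN, EPHEDRA, PISTACIA)
ALL_MICROHABITATS: tuple[str, ...] = (OPEN, EPHEDRA, PISTACIA, OTHER)

# Seed treatments at the sowing stations: gut-passed seeds recovered from
# droppings, and undigested seeds taken from red- or yellow-fruited plants.
DIGESTED = "DIGESTED"
RED = "RED"
YELLOW = "YELLOW"
TREATMENTS: tuple[str, ...] = (DIGESTED, RED, YELLOW)

_COVER_SUM_TOL = 1e-9


class SeedFateError(Exception):
    """Base class for all package errors."""


class SchemaError(SeedFateError):
    """A table is missing a required column or has an unreadable layout."""


class ValidationError(SeedFateError):
    """A record violates a domain invariant."""


class EstimationError(SeedFateError):
    """An estimator cannot be computed from the supplied records."""


class SimulationError(SeedFateError):
    """The simulation inputs are incomplete or inconsistent."""


class ConfigurationError(SeedFateError):
    """A configuration value is out of range."""


def canonical_microhabitat(label: str) -> str:
    """Return the canonical (upper-case, stripped) form of a microhabitat label."""
    if not isinstance(label, str) or not label.strip():
        raise ValidationError(f"empty or non-string microhabitat label: {label!r}")
    return label.strip().upper()


@dataclass(frozen=True)
class Microhabitat:
    """A deposition microhabitat and its fraction of ground cover."""

    name: str
    cover: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", canonical_microhabitat(self.name))
        if not 0.0 <= self.cover <= 1.0:
            raise ValidationError(
                f"microhabitat {self.name}: cover {self.cover} outside [0, 1]"
            )


@dataclass(frozen=True)
class CoverTable:
    """Ground-cover fractions of all microhabitats at the study site.

    Covers must be unique by name, each in [0, 1], sum to at most 1 (a sum
    of exactly 1 means the named microhabitats tile the site), and the
    three core microhabitats must always be present.
    """

    entries: tuple[Microhabitat, ...]

    def __init__(self, entries: Iterable[Microhabitat]) -> None:
        object.__setattr__(self, "entries", tuple(entries))
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate microhabitat names in cover table: {names}")
        for core in CORE_MICROHABITATS:
            if core not in names:
                raise ValidationError(f"cover table missing required microhabitat {core}")
        total = sum(e.cover for e in self.entries)
        if not 0.0 < total <= 1.0 + _COVER_SUM_TOL:
            raise ValidationError(f"cover fractions sum to {total}, outside (0, 1]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def cover(self, name: str) -> float:
        name = canonical_microhabitat(name)
        for e in self.entries:
            if e.name == name:
                return e.cover
        raise ValidationError(f"microhabitat {name} not in cover table")

    def as_dict(self) -> dict[str, float]:
        return {e.name: e.cover for e in self.entries}

    def relative(self, subset: Sequence[str]) -> dict[str, float]:
        """Covers of ``subset`` renormalized to sum to 1 among themselves."""
        subset = [canonical_microhabitat(s) for s in subset]
        covers = {s: self.cover(s) for s in subset}
        total = sum(covers.values())
        if total <= 0:
            raise ValidationError(f"zero total cover over subset {subset}")
        return {s: c / total for s, c in covers.items()}


@dataclass(frozen=True)
class UseObservation:
    """One sighting of the disperser, tagged by microhabitat, zone and transect."""

    microhabitat: str
    zone: str
    transect: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "microhabitat", canonical_microhabitat(self.microhabitat))


@dataclass(frozen=True)
class FaecesSurvey:
    """Counts of disperser droppings containing target seeds, per microhabitat."""

    counts: Mapping[str, int]

    def __init__(self, counts: Mapping[str, int]) -> None:
        canon: dict[str, int] = {}
        for name, c in counts.items():
            name = canonical_microhabitat(name)
            if c < 0 or int(c) != c:
                raise ValidationError(f"faeces count for {name} must be a non-negative integer, got {c}")
            canon[name] = int(c)
        object.__setattr__(self, "counts", canon)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PredationTrialRecord:
    """One predation tray: seeds exposed and seeds left at the end of monitoring.

    A censored tray (destroyed or removed during monitoring) is retained
    with ``censored=True`` and carries no usable ``n_surviving``.
    """

    tray_id: str
    microhabitat: str
    zone: str
    set_id: str
    n_exposed: int
    n_surviving: Optional[int]
    censored: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "microhabitat", canonical_microhabitat(self.microhabitat))
        if self.n_exposed <= 0:
            raise ValidationError(f"tray {self.tray_id}: n_exposed must be positive")
        if self.censored:
            object.__setattr__(self, "n_surviving", None)
        else:
            if self.n_surviving is None:
                raise ValidationError(f"tray {self.tray_id}: n_surviving missing on an uncensored tray")
            if not 0 <= self.n_surviving <= self.n_exposed:
                raise ValidationError(
                    f"tray {self.tray_id}: n_surviving={self.n_surviving} "
                    f"outside [0, n_exposed={self.n_exposed}]"
                )

    @property
    def survival_proportion(self) -> Optional[float]:
        if self.censored:
            return None
        return self.n_surviving / self.n_exposed


@dataclass(frozen=True)
class SowingRecord:
    """One sowing station x treatment: seeds sown, seedlings emerged and alive at the final census."""

    station_id: str
    microhabitat: str
    zone: str
    set_id: str
    treatment: str
    n_sown: int
    n_emerged: int
    n_surviving: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "microhabitat", canonical_microhabitat(self.microhabitat))
        treatment = self.treatment.strip().upper()
        if treatment not in TREATMENTS:
            raise ValidationError(
                f"station {self.station_id}: unknown treatment {self.treatment!r} "
                f"(expected one of {TREATMENTS})"
            )
        object.__setattr__(self, "treatment", treatment)
        if self.n_sown <= 0:
            raise ValidationError(f"station {self.station_id}: n_sown must be positive")
        if not 0 <= self.n_surviving <= self.n_emerged <= self.n_sown:
            raise ValidationError(
                f"station {self.station_id} ({treatment}): require "
                f"0 <= n_surviving={self.n_surviving} <= n_emerged={self.n_emerged} "
                f"<= n_sown={self.n_sown}"
            )


@dataclass
class FieldDataset:
    """All observed inputs of one campaign, cross-validated.

    ``validate`` checks that every record's microhabitat exists in the
    cover table and that zone labels are consistent between the predation
    and sowing tables.
    """

    cover: CoverTable
    use_observations: list[UseObservation] = field(default_factory=list)
    faeces: FaecesSurvey = field(default_factory=lambda: FaecesSurvey({}))
    predation: list[PredationTrialRecord] = field(default_factory=list)
    sowing: list[SowingRecord] = field(default_factory=list)

    def validate(self) -> "FieldDataset":
        known = set(self.cover.names)
        for obs in self.use_observations:
            if obs.microhabitat not in known:
                raise ValidationError(
                    f"use observation in unknown microhabitat {obs.microhabitat}"
                )
        for name in self.faeces.counts:
            if name not in known:
                raise ValidationError(f"faeces survey names unknown microhabitat {name}")
        for rec in self.predation:
            if rec.microhabitat not in known:
                raise ValidationError(
                    f"tray {rec.tray_id}: unknown microhabitat {rec.microhabitat}"
                )
        for rec in self.sowing:
            if rec.microhabitat not in known:
                raise ValidationError(
                    f"station {rec.station_id}: unknown microhabitat {rec.microhabitat}"
                )
        pred_zones = {r.zone for r in self.predation}
        sow_zones = {r.zone for r in self.sowing}
        if pred_zones and sow_zones and pred_zones != sow_zones:
            raise ValidationError(
                f"zone labels differ between predation ({sorted(pred_zones)}) "
                f"and sowing ({sorted(sow_zones)}) tables"
            )
        return self

    @property
    def n_censored_trays(self) -> int:
        return sum(1 for r in self.predation if r.censored)

    def with_censored(self, tray_ids: Iterable[str]) -> "FieldDataset":
        """Return a copy with the named trays marked censored."""
        ids = set(tray_ids)
        missing = ids - {r.tray_id for r in self.predation}
        if missing:
            raise ValidationError(f"cannot censor unknown trays: {sorted(missing)}")
        predation = [
            replace(r, censored=True, n_surviving=None) if r.tray_id in ids else r
            for r in self.predation
        ]
        return FieldDataset(
            cover=self.cover,
            use_observations=list(self.use_observations),
            faeces=self.faeces,
            predation=predation,
            sowing=list(self.sowing),
        )
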