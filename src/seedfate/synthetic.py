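"""Synthetic field-campaign generator with known truth.

The generator emulates the structure of a real seed-fate campaign — the
same tables, replicate layout, censoring and binomial outcomes — from a
set of true parameters, so the whole pipeline (read/validate, estimate,
simulate) can be exercised and checked for parameter recovery without any
external data.

Between-replicate variability uses a mean/concentration (beta)
parameterization: the true per-replicate transition probability is drawn
from Beta(mean * kappa, (1 - mean) * kappa), then counts are binomial
given that probability.  kappa -> infinity recovers a pure binomial;
smaller kappa gives the overdispersion real trays show.  Boundary means
(0 or 1) are treated as degenerate point masses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .datamodel import (
    CORE_MICROHABITATS,
    CoverTable,
    EPHEDRA,
    FaecesSurvey,
    FieldDataset,
    Microhabitat,
    OPEN,
    OTHER,
    PISTACIA,
    PredationTrialRecord,
    SowingRecord,
    TREATMENTS,
    UseObservation,
    ValidationError,
    YELLOW,
    canonical_microhabitat,
)
from .estimation import (
    DispersalDistribution,
    EMERGENCE,
    PREDATION_SURVIVAL,
    SEEDLING_SURVIVAL,
    TransitionTable,
    estimate_dispersal_distribution,
    estimate_transition_tables,
)
from .simulation import (
    DISPERSED,
    SimulationConfig,
    UNDISPERSED,
    analytic_expected_outcome,
    dispersal_advantage,
    run_seed_fate_simulation,
)

__all__ = [
    "STUDY_COVER",
    "FieldDesign",
    "TrueParameters",
    "study_design",
    "study_truth",
    "generate_field_dataset",
    "tables_from_truth",
    "truth_implied_outcome",
    "RecoveryReport",
    "recovery_experiment",
]

# Measured ground cover at the study site: open ground 45.1%, the
# companion shrub 27.0%, the focal shrub 17.5%; OTHER is the remainder.
STUDY_COVER = CoverTable(
    [
        Microhabitat(OPEN, 0.451),
        Microhabitat(PISTACIA, 0.270),
        Microhabitat(EPHEDRA, 0.175),
        Microhabitat(OTHER, 1.0 - (0.451 + 0.270 + 0.175)),
    ]
)

_ZONES = ("A", "B")


@dataclass(frozen=True)
class FieldDesign:
    """Replicate layout of the field experiments."""

    n_zones: int = 2
    sets_per_zone: int = 10
    trays_per_microhabitat_per_zone: int = 10
    seeds_per_tray: int = 10
    stations_per_microhabitat_per_zone: int = 10
    seeds_per_treatment_per_station: int = 10
    monitored_days_predation: int = 90
    monitored_days_sowing: int = 200

    def __post_init__(self) -> None:
        for name in (
            "n_zones",
            "sets_per_zone",
            "trays_per_microhabitat_per_zone",
            "seeds_per_tray",
            "stations_per_microhabitat_per_zone",
            "seeds_per_treatment_per_station",
            "monitored_days_predation",
            "monitored_days_sowing",
        ):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ValidationError(f"design field {name} must be a positive integer, got {value}")

    @property
    def n_trays(self) -> int:
        return self.n_zones * self.trays_per_microhabitat_per_zone * len(CORE_MICROHABITATS)

    @property
    def n_stations(self) -> int:
        return self.n_zones * self.stations_per_microhabitat_per_zone * len(CORE_MICROHABITATS)

    @property
    def seeds_per_station(self) -> int:
        return self.seeds_per_treatment_per_station * len(TREATMENTS)

    def scaled(self, factor: int) -> "FieldDesign":
        """Multiply the replicate counts (trays, stations, sets) by ``factor``."""
        if int(factor) != factor or factor < 1:
            raise ValidationError(f"scale factor must be a positive integer, got {factor}")
        return replace(
            self,
            sets_per_zone=self.sets_per_zone * factor,
            trays_per_microhabitat_per_zone=self.trays_per_microhabitat_per_zone * factor,
            stations_per_microhabitat_per_zone=self.stations_per_microhabitat_per_zone * factor,
        )

    def to_json(self) -> dict:
        return {
            "n_zones": self.n_zones,
            "sets_per_zone": self.sets_per_zone,
            "trays_per_microhabitat_per_zone": self.trays_per_microhabitat_per_zone,
            "seeds_per_tray": self.seeds_per_tray,
            "stations_per_microhabitat_per_zone": self.stations_per_microhabitat_per_zone,
            "seeds_per_treatment_per_station": self.seeds_per_treatment_per_station,
            "monitored_days_predation": self.monitored_days_predation,
            "monitored_days_sowing": self.monitored_days_sowing,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "FieldDesign":
        return cls(**payload)


def study_design() -> FieldDesign:
    """The original field layout: 2 zones x 10 sets, 60 trays of 10 seeds,
    60 stations of 3 treatments x 10 seeds, over 3 microhabitats."""
    return FieldDesign()


@dataclass(frozen=True)
class TrueParameters:
    """The generator's known truth.

    ``deposition`` is the dispersed seed shadow over microhabitats (sums
    to 1; may include OTHER).  Stage means are per microhabitat for
    predation survival and per (microhabitat, treatment) for emergence and
    seedling survival.  ``kappa`` is the beta concentration controlling
    between-replicate spread; ``censor_prob`` the per-tray destruction
    probability; ``morph_ratio`` the fraction of dispersed seeds
    originating from red-fruited plants.
    """

    deposition: dict[str, float]
    predation_survival: dict[str, float]
    emergence: dict[tuple[str, str], float]
    seedling_survival: dict[tuple[str, str], float]
    kappa: float = 20.0
    censor_prob: float = 0.0
    morph_ratio: float = 0.8
    n_faeces: int = 140
    n_use_observations: int = 200
    use_distribution: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        deposition = {canonical_microhabitat(m): float(p) for m, p in self.deposition.items()}
        if any(p < 0 for p in deposition.values()):
            raise ValidationError("deposition probabilities must be non-negative")
        if not math.isclose(sum(deposition.values()), 1.0, abs_tol=1e-9):
            raise ValidationError(f"deposition sums to {sum(deposition.values())}, not 1")
        object.__setattr__(self, "deposition", deposition)
        for label, mapping in (
            ("predation_survival", self.predation_survival),
            ("emergence", self.emergence),
            ("seedling_survival", self.seedling_survival),
        ):
            for key, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"{label}[{key}] = {p} outside [0, 1]")
        if self.kappa <= 0:
            raise ValidationError(f"kappa must be > 0, got {self.kappa}")
        if not 0.0 <= self.censor_prob < 1.0:
            raise ValidationError(f"censor_prob {self.censor_prob} outside [0, 1)")
        if not 0.0 <= self.morph_ratio <= 1.0:
            raise ValidationError(f"morph_ratio {self.morph_ratio} outside [0, 1]")
        if self.n_faeces < 1 or self.n_use_observations < 1:
            raise ValidationError("n_faeces and n_use_observations must be positive")
        if self.use_distribution is not None:
            use = {canonical_microhabitat(m): float(p) for m, p in self.use_distribution.items()}
            if not math.isclose(sum(use.values()), 1.0, abs_tol=1e-9):
                raise ValidationError("use_distribution must sum to 1")
            object.__setattr__(self, "use_distribution", use)

    @property
    def effective_use_distribution(self) -> dict[str, float]:
        return self.use_distribution if self.use_distribution is not None else self.deposition

    def stage_means(self) -> dict[tuple, float]:
        """Flat (stage, microhabitat[, treatment]) -> mean view of the truth."""
        flat: dict[tuple, float] = {}
        for m, p in self.predation_survival.items():
            flat[(PREDATION_SURVIVAL, m)] = p
        for (m, t), p in self.emergence.items():
            flat[(EMERGENCE, m, t)] = p
        for (m, t), p in self.seedling_survival.items():
            flat[(SEEDLING_SURVIVAL, m, t)] = p
        return flat

    def to_json(self) -> dict:
        return {
            "deposition": dict(self.deposition),
            "predation_survival": dict(self.predation_survival),
            "emergence": {f"{m}|{t}": p for (m, t), p in self.emergence.items()},
            "seedling_survival": {f"{m}|{t}": p for (m, t), p in self.seedling_survival.items()},
            "kappa": self.kappa,
            "censor_prob": self.censor_prob,
            "morph_ratio": self.morph_ratio,
            "n_faeces": self.n_faeces,
            "n_use_observations": self.n_use_observations,
            "use_distribution": self.use_distribution,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "TrueParameters":
        def unflatten(mapping: dict) -> dict[tuple[str, str], float]:
            return {tuple(k.split("|")): float(v) for k, v in mapping.items()}

        return cls(
            deposition=payload["deposition"],
            predation_survival=payload["predation_survival"],
            emergence=unflatten(payload["emergence"]),
            seedling_survival=unflatten(payload["seedling_survival"]),
            kappa=payload.get("kappa", 20.0),
            censor_prob=payload.get("censor_prob", 0.0),
            morph_ratio=payload.get("morph_ratio", 0.8),
            n_faeces=payload.get("n_faeces", 140),
            n_use_observations=payload.get("n_use_observations", 200),
            use_distribution=payload.get("use_distribution"),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_json(), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "TrueParameters":
        return cls.from_json(json.loads(Path(path).read_text()))


def study_truth() -> TrueParameters:
    """A truth preset shaped like the study system.

    Deposition is skewed toward open ground; the focal-shrub microhabitat
    (where undispersed seeds fall) is the harshest at every stage, with
    zero seedling survival beneath it; digested seeds behave like seeds of
    the commoner red morph, and red fruits outnumber yellow 4:1.  The
    numeric values are realistic choices for a semiarid-shrubland
    campaign, not estimates of any particular dataset.
    """
    emergence_by_micro = {OPEN: 0.50, PISTACIA: 0.35, EPHEDRA: 0.15}
    survival_by_micro = {OPEN: 0.10, PISTACIA: 0.06, EPHEDRA: 0.0}
    emergence = {}
    seedling_survival = {}
    for m in CORE_MICROHABITATS:
        for t in TREATMENTS:
            # the yellow morph germinates less readily; digestion ~ red morph
            factor = 0.6 if t == YELLOW else 1.0
            emergence[(m, t)] = emergence_by_micro[m] * factor
            seedling_survival[(m, t)] = survival_by_micro[m]
    return TrueParameters(
        deposition={OPEN: 0.72, PISTACIA: 0.14, EPHEDRA: 0.06, OTHER: 0.08},
        predation_survival={OPEN: 0.12, PISTACIA: 0.10, EPHEDRA: 0.04},
        emergence=emergence,
        seedling_survival=seedling_survival,
        kappa=20.0,
        censor_prob=7.0 / 60.0,
        morph_ratio=0.8,
    )


def _replicate_probs(rng: np.random.Generator, mean: float, kappa: float, size: int) -> np.ndarray:
    if mean <= 0.0:
        return np.zeros(size)
    if mean >= 1.0:
        return np.ones(size)
    return rng.beta(mean * kappa, (1.0 - mean) * kappa, size=size)


def generate_field_dataset(
    truth: TrueParameters,
    design: FieldDesign,
    seed: int,
    cover: Optional[CoverTable] = None,
) -> FieldDataset:
    """Draw one complete campaign from the truth; deterministic under ``seed``."""
    if cover is None:
        cover = STUDY_COVER
    rng = np.random.default_rng(seed)
    zones = [_ZONES[i] if i < len(_ZONES) else f"Z{i + 1}" for i in range(design.n_zones)]

    # Disperser sightings: multinomial over microhabitats, spread over two
    # transects per zone in a fixed rotation.
    use_dist = truth.effective_use_distribution
    use_micros = sorted(use_dist)
    use_counts = rng.multinomial(truth.n_use_observations, [use_dist[m] for m in use_micros])
    transects = [(z, f"T{z}{k}") for z in zones for k in (1, 2)]
    use_observations = []
    i = 0
    for m, count in zip(use_micros, use_counts):
        for _ in range(count):
            zone, transect = transects[i % len(transects)]
            use_observations.append(UseObservation(m, zone, transect))
            i += 1

    # Dropping survey: multinomial from the deposition distribution.
    dep_micros = sorted(truth.deposition)
    faeces_counts = rng.multinomial(truth.n_faeces, [truth.deposition[m] for m in dep_micros])
    faeces = FaecesSurvey(dict(zip(dep_micros, faeces_counts)))

    # Predation trays: one tray per microhabitat per set; beta-binomial
    # survivors; independent censoring.
    predation = []
    tray_no = 0
    for zone in zones:
        for m in CORE_MICROHABITATS:
            means = _replicate_probs(
                rng, truth.predation_survival[m], truth.kappa, design.trays_per_microhabitat_per_zone
            )
            for j in range(design.trays_per_microhabitat_per_zone):
                tray_no += 1
                n_surv = int(rng.binomial(design.seeds_per_tray, means[j]))
                censored = bool(rng.random() < truth.censor_prob)
                predation.append(
                    PredationTrialRecord(
                        tray_id=f"T{tray_no:03d}",
                        microhabitat=m,
                        zone=zone,
                        set_id=f"S{zone}{(j % design.sets_per_zone) + 1}",
                        n_exposed=design.seeds_per_tray,
                        n_surviving=None if censored else n_surv,
                        censored=censored,
                    )
                )

    # Sowing stations: per station x treatment, beta-binomial emergence and
    # beta-binomial survival conditional on the emerged count.
    sowing = []
    station_no = 0
    for zone in zones:
        for m in CORE_MICROHABITATS:
            for j in range(design.stations_per_microhabitat_per_zone):
                station_no += 1
                station_id = f"ST{station_no:03d}"
                set_id = f"S{zone}{(j % design.sets_per_zone) + 1}"
                for t in TREATMENTS:
                    p_em = _replicate_probs(rng, truth.emergence[(m, t)], truth.kappa, 1)[0]
                    n_emerged = int(rng.binomial(design.seeds_per_treatment_per_station, p_em))
                    p_sv = _replicate_probs(rng, truth.seedling_survival[(m, t)], truth.kappa, 1)[0]
                    n_surviving = int(rng.binomial(n_emerged, p_sv)) if n_emerged else 0
                    sowing.append(
                        SowingRecord(
                            station_id=station_id,
                            microhabitat=m,
                            zone=zone,
                            set_id=set_id,
                            treatment=t,
                            n_sown=design.seeds_per_treatment_per_station,
                            n_emerged=n_emerged,
                            n_surviving=n_surviving,
                        )
                    )

    return FieldDataset(
        cover=cover,
        use_observations=use_observations,
        faeces=faeces,
        predation=predation,
        sowing=sowing,
    ).validate()


def tables_from_truth(truth: TrueParameters) -> dict[str, TransitionTable]:
    """Degenerate transition tables whose single replicate is the true mean."""
    pred = TransitionTable(
        PREDATION_SURVIVAL, {(m,): [p] for m, p in truth.predation_survival.items()}
    )
    emer = TransitionTable(EMERGENCE, {(m, t): [p] for (m, t), p in truth.emergence.items()})
    surv = TransitionTable(
        SEEDLING_SURVIVAL, {(m, t): [p] for (m, t), p in truth.seedling_survival.items()}
    )
    return {PREDATION_SURVIVAL: pred, EMERGENCE: emer, SEEDLING_SURVIVAL: surv}


def truth_implied_outcome(
    truth: TrueParameters,
    config: Optional[SimulationConfig] = None,
    cover: Optional[CoverTable] = None,
) -> dict:
    """The exact pathway outcomes implied by the true parameters."""
    if config is None:
        config = SimulationConfig()
    dispersal = DispersalDistribution(
        _renormalize({m: truth.deposition.get(m, 0.0) for m in CORE_MICROHABITATS})
    )
    return analytic_expected_outcome(
        tables_from_truth(truth), dispersal, cover or STUDY_COVER, config
    )


def _renormalize(probs: dict[str, float]) -> dict[str, float]:
    total = sum(probs.values())
    if total <= 0:
        raise ValidationError("cannot renormalize an all-zero distribution")
    return {m: p / total for m, p in probs.items()}


@dataclass(frozen=True)
class RecoveryReport:
    """Generate -> estimate -> simulate, repeated; bias/RMSE against the truth."""

    truth_implied: dict
    estimated_advantage: np.ndarray  # per-dataset newly-emerged advantage ratio
    estimated_newly_emerged: dict[str, np.ndarray]
    estimated_surviving: dict[str, np.ndarray]
    n_datasets: int

    @property
    def truth_advantage(self) -> float:
        t = self.truth_implied
        return t[DISPERSED]["p_newly_emerged"] / t[UNDISPERSED]["p_newly_emerged"]

    @property
    def advantage_bias(self) -> float:
        return float(np.mean(self.estimated_advantage)) - self.truth_advantage

    @property
    def advantage_relative_bias(self) -> float:
        return self.advantage_bias / self.truth_advantage

    @property
    def advantage_rmse(self) -> float:
        return float(np.sqrt(np.mean((self.estimated_advantage - self.truth_advantage) ** 2)))


def recovery_experiment(
    truth: TrueParameters,
    design: FieldDesign,
    sim_config: SimulationConfig,
    n_datasets: int,
    seed: int,
) -> RecoveryReport:
    """Parameter-recovery study for the full pipeline.

    For each replicate dataset: generate from the truth, estimate the
    transition tables and deposition distribution, run the bootstrap
    simulation, and record the pathway outcomes and the newly-emerged
    advantage ratio.  Bias and RMSE are reported against the outcome the
    truth implies analytically.
    """
    if n_datasets < 1:
        raise ValidationError(f"n_datasets must be >= 1, got {n_datasets}")
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    implied = truth_implied_outcome(truth, sim_config)

    advantages = np.empty(n_datasets)
    newly = {DISPERSED: np.empty(n_datasets), UNDISPERSED: np.empty(n_datasets)}
    surviving = {DISPERSED: np.empty(n_datasets), UNDISPERSED: np.empty(n_datasets)}
    for i, child in enumerate(children):
        data_seed, sim_seed = child.generate_state(2, dtype=np.uint32) >> np.uint32(1)
        dataset = generate_field_dataset(truth, design, int(data_seed))
        tables = estimate_transition_tables(dataset)
        dispersal = estimate_dispersal_distribution(dataset.faeces)
        config = replace(sim_config, rng_seed=int(sim_seed))
        result = run_seed_fate_simulation(tables, dispersal, dataset.cover, config)
        advantages[i] = dispersal_advantage(result)["newly_emerged"]
        for pathway in (DISPERSED, UNDISPERSED):
            newly[pathway][i] = result.summaries[pathway]["p_newly_emerged"]["mean"]
            surviving[pathway][i] = result.summaries[pathway]["p_surviving"]["mean"]

    return RecoveryReport(
        truth_implied=implied,
        estimated_advantage=advantages,
        estimated_newly_emerged=newly,
        estimated_surviving=surviving,
        n_datasets=n_datasets,
    )
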