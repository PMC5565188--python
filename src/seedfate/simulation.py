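"""Stochastic seed-fate simulation for dispersed vs. undispersed seeds.

A seed's recruitment probability is a product of stage transitions,

    p_newly_emerged = sum_m  w_m * s2_m * s3_m
    p_surviving     = sum_m  w_m * s2_m * s3_m * s4_m

where ``w_m`` is the probability of deposition in microhabitat ``m``,
``s2`` survival of post-dispersal predation, ``s3`` seedling emergence and
``s4`` first-season seedling survival.  Each iteration of the simulation
draws the stage transitions at random from the empirical replicate-level
distributions (a bootstrap of the field replicates), so the spread of the
iteration outputs reflects the between-replicate variability measured in
the field.

Two pathways are compared:

* ``DISPERSED`` — seeds pass the disperser's gut (the ``DIGESTED``
  treatment) and land according to the estimated deposition distribution.
* ``UNDISPERSED`` — seeds drop beneath the mother plant (a point mass on
  the EPHEDRA microhabitat) and keep their fruit-morph identity, mixed
  red:yellow according to morph frequency in the population.

The per-iteration bootstrap admits two readings of "randomly selected
transition probabilities": pick one replicate per stage per iteration
(``SINGLE_REPLICATE``, the default), or resample each replicate list to
its own size and use its mean (``RESAMPLED_MEAN``).  Deposition weights
may optionally be multiplied by relative microhabitat cover
(``DISPERSAL_TIMES_COVER``).  Both switches are first-class and echoed in
results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import (
    ConfigurationError,
    CoverTable,
    DIGESTED,
    EPHEDRA,
    RED,
    SimulationError,
    ValidationError,
    YELLOW,
)
from .estimation import (
    DispersalDistribution,
    EMERGENCE,
    PREDATION_SURVIVAL,
    SEEDLING_SURVIVAL,
    TransitionTable,
)

__all__ = [
    "SINGLE_REPLICATE",
    "RESAMPLED_MEAN",
    "DISPERSAL_ONLY",
    "DISPERSAL_TIMES_COVER",
    "DISPERSED",
    "UNDISPERSED",
    "SimulationConfig",
    "PathwayOutcome",
    "SimulationResult",
    "chain_product",
    "run_seed_fate_simulation",
    "analytic_expected_outcome",
    "stage_loss_decomposition",
    "dispersal_advantage",
]

SINGLE_REPLICATE = "SINGLE_REPLICATE"
RESAMPLED_MEAN = "RESAMPLED_MEAN"
DISPERSAL_ONLY = "DISPERSAL_ONLY"
DISPERSAL_TIMES_COVER = "DISPERSAL_TIMES_COVER"
DISPERSED = "DISPERSED"
UNDISPERSED = "UNDISPERSED"

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class SimulationConfig:
    """Iteration count, seed, draw mode, weighting mode and morph mix."""

    n_iterations: int = 500
    rng_seed: int = 0
    iteration_draw_mode: str = SINGLE_REPLICATE
    weighting_mode: str = DISPERSAL_ONLY
    undispersed_treatment_mix: dict[str, float] = field(
        default_factory=lambda: {RED: 0.8, YELLOW: 0.2}
    )

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.iteration_draw_mode not in (SINGLE_REPLICATE, RESAMPLED_MEAN):
            raise ConfigurationError(f"unknown draw mode {self.iteration_draw_mode!r}")
        if self.weighting_mode not in (DISPERSAL_ONLY, DISPERSAL_TIMES_COVER):
            raise ConfigurationError(f"unknown weighting mode {self.weighting_mode!r}")
        mix = {t.upper(): float(w) for t, w in self.undispersed_treatment_mix.items()}
        for t, w in mix.items():
            if w < 0:
                raise ConfigurationError(f"treatment weight for {t} is negative")
        total = sum(mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"treatment-mix weights sum to {total}, not 1")
        object.__setattr__(self, "undispersed_treatment_mix", mix)

    def to_json(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "rng_seed": self.rng_seed,
            "iteration_draw_mode": self.iteration_draw_mode,
            "weighting_mode": self.weighting_mode,
            "undispersed_treatment_mix": dict(self.undispersed_treatment_mix),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "SimulationConfig":
        return cls(**payload)


@dataclass(frozen=True)
class PathwayOutcome:
    """Per-iteration recruitment probabilities for one pathway.

    ``survived_predation`` is the per-iteration probability of passing the
    predation stage only; it feeds the stage-loss decomposition.
    """

    pathway: str
    p_newly_emerged: np.ndarray
    p_surviving: np.ndarray
    survived_predation: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.p_surviving > self.p_newly_emerged + 1e-15) or np.any(
            self.p_newly_emerged > self.survived_predation + 1e-15
        ):
            raise SimulationError(
                f"{self.pathway}: iteration ordering violated "
                "(need p_surviving <= p_newly_emerged <= survived_predation)"
            )


@dataclass(frozen=True)
class SimulationResult:
    config: SimulationConfig
    dispersed: PathwayOutcome
    undispersed: PathwayOutcome
    summaries: dict
    stage_losses: dict
    advantage: dict

    def outcome(self, pathway: str) -> PathwayOutcome:
        if pathway == DISPERSED:
            return self.dispersed
        if pathway == UNDISPERSED:
            return self.undispersed
        raise ValidationError(f"unknown pathway {pathway!r}")

    def to_json(self, include_iterations: bool = False) -> dict:
        payload = {
            "config": self.config.to_json(),
            "summaries": self.summaries,
            "stage_losses": self.stage_losses,
            "advantage": {
                k: ("infinite" if math.isinf(v) else ("undefined" if isinstance(v, float) and math.isnan(v) else v))
                for k, v in self.advantage.items()
            },
        }
        if include_iterations:
            payload["iterations"] = {
                p.pathway: {
                    "p_newly_emerged": p.p_newly_emerged.tolist(),
                    "p_surviving": p.p_surviving.tolist(),
                    "survived_predation": p.survived_predation.tolist(),
                }
                for p in (self.dispersed, self.undispersed)
            }
        return payload


def chain_product(
    p_deposit: float,
    p_predation_survival: float,
    p_emergence: float,
    p_seedling_survival: float,
) -> tuple[float, float]:
    """Recruitment contribution of one microhabitat along the stage chain."""
    for name, v in (
        ("p_deposit", p_deposit),
        ("p_predation_survival", p_predation_survival),
        ("p_emergence", p_emergence),
        ("p_seedling_survival", p_seedling_survival),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [0, 1]")
    p_newly = p_deposit * p_predation_survival * p_emergence
    return p_newly, p_newly * p_seedling_survival


def _draw(rng: np.random.Generator, values: list[float], n: int, mode: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if mode == SINGLE_REPLICATE:
        return arr[rng.integers(0, arr.size, size=n)]
    idx = rng.integers(0, arr.size, size=(n, arr.size))
    return arr[idx].mean(axis=1)


def _dispersal_weights(
    dispersal: DispersalDistribution,
    cover: Optional[CoverTable],
    weighting_mode: str,
) -> dict[str, float]:
    active = {m: p for m, p in dispersal.probs.items() if p > 0}
    if weighting_mode == DISPERSAL_ONLY:
        return active
    if cover is None:
        raise SimulationError("DISPERSAL_TIMES_COVER weighting requires a cover table")
    rel = cover.relative(list(active))
    weighted = {m: p * rel[m] for m, p in active.items()}
    total = sum(weighted.values())
    if total <= 0:
        raise SimulationError("cover weighting annihilated every deposition weight")
    return {m: w / total for m, w in weighted.items()}


def _require_group(table: TransitionTable, key: tuple[str, ...]) -> list[float]:
    if key not in table.groups:
        raise SimulationError(f"{table.stage}: missing replicate group {key}")
    return table.groups[key]


def _stage_tables(tables: dict[str, TransitionTable]) -> tuple[TransitionTable, TransitionTable, TransitionTable]:
    try:
        return tables[PREDATION_SURVIVAL], tables[EMERGENCE], tables[SEEDLING_SURVIVAL]
    except KeyError as exc:
        raise SimulationError(f"missing transition table for stage {exc.args[0]}") from exc


def _has_groups(tables: tuple[TransitionTable, ...], m: str) -> bool:
    pred, emer, surv = tables
    return (m,) in pred.groups and (m, DIGESTED) in emer.groups and (m, DIGESTED) in surv.groups


def run_seed_fate_simulation(
    tables: dict[str, TransitionTable],
    dispersal: DispersalDistribution,
    cover: Optional[CoverTable],
    config: SimulationConfig,
    unstudied_to_zero: bool = False,
) -> SimulationResult:
    """Bootstrap the stage transitions and chain them through both pathways.

    One seeded generator drives the whole run in a fixed draw order, so an
    identical config yields a bit-identical result.

    ``unstudied_to_zero`` lets the deposition distribution carry mass on
    microhabitats without stage tables (e.g. OTHER vegetation): those
    seeds count as deposited but contribute zero recruitment, instead of
    raising a missing-group error.
    """
    pred_table, emer_table, surv_table = _stage_tables(tables)
    weights = _dispersal_weights(dispersal, cover, config.weighting_mode)

    rng = np.random.default_rng(config.rng_seed)
    n = config.n_iterations
    mode = config.iteration_draw_mode

    # Dispersed pathway: DIGESTED-treatment tables, summed over microhabitats.
    disp_a2 = np.zeros(n)
    disp_a3 = np.zeros(n)
    disp_a4 = np.zeros(n)
    for m in sorted(weights):
        w = weights[m]
        if unstudied_to_zero and not _has_groups((pred_table, emer_table, surv_table), m):
            continue  # deposited there, but recruits nothing
        s2 = _draw(rng, _require_group(pred_table, (m,)), n, mode)
        s3 = _draw(rng, _require_group(emer_table, (m, DIGESTED)), n, mode)
        s4 = _draw(rng, _require_group(surv_table, (m, DIGESTED)), n, mode)
        disp_a2 += w * s2
        disp_a3 += w * s2 * s3
        disp_a4 += w * s2 * s3 * s4

    # Undispersed pathway: all seeds beneath the mother plant (EPHEDRA),
    # mixed across fruit morphs.
    mix = {t: w for t, w in config.undispersed_treatment_mix.items() if w > 0}
    u_s2 = _draw(rng, _require_group(pred_table, (EPHEDRA,)), n, mode)
    u_emerge = np.zeros(n)
    u_survive = np.zeros(n)
    for t in sorted(mix):
        wt = mix[t]
        s3 = _draw(rng, _require_group(emer_table, (EPHEDRA, t)), n, mode)
        s4 = _draw(rng, _require_group(surv_table, (EPHEDRA, t)), n, mode)
        u_emerge += wt * s3
        u_survive += wt * s3 * s4
    und_a2 = u_s2
    und_a3 = u_s2 * u_emerge
    und_a4 = u_s2 * u_survive

    dispersed = PathwayOutcome(DISPERSED, disp_a3, disp_a4, disp_a2)
    undispersed = PathwayOutcome(UNDISPERSED, und_a3, und_a4, und_a2)

    summaries = {
        p.pathway: {
            "p_newly_emerged": _summary(p.p_newly_emerged),
            "p_surviving": _summary(p.p_surviving),
        }
        for p in (dispersed, undispersed)
    }
    losses = _losses(dispersed, undispersed)
    advantage = _advantage(dispersed, undispersed)
    return SimulationResult(
        config=config,
        dispersed=dispersed,
        undispersed=undispersed,
        summaries=summaries,
        stage_losses=losses,
        advantage=advantage,
    )


def _summary(values: np.ndarray) -> dict:
    # Bootstrap SE convention: the SD of the iteration outputs.
    se = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {"mean": float(values.mean()), "se": se}


def _conditional_mean(numer: np.ndarray, denom: np.ndarray) -> tuple[float, int]:
    """Mean of numer/denom over iterations with denom > 0; returns (mean, n_undefined)."""
    defined = denom > 0
    n_undef = int(np.sum(~defined))
    if not np.any(defined):
        return float("nan"), n_undef
    return float(np.mean(numer[defined] / denom[defined])), n_undef


def _losses(*outcomes: PathwayOutcome) -> dict:
    result = {}
    for p in outcomes:
        a2, a3, a4 = p.survived_predation, p.p_newly_emerged, p.p_surviving
        fail_emerge, n_undef_emerge = _conditional_mean(a2 - a3, a2)
        seedling_death, n_undef_surv = _conditional_mean(a3 - a4, a3)
        result[p.pathway] = {
            "predation_mortality": float(np.mean(1.0 - a2)),
            "emergence_failure_of_survivors": fail_emerge,
            "seedling_mortality_of_emerged": seedling_death,
            "n_undefined_emergence_fraction": n_undef_emerge,
            "n_undefined_seedling_fraction": n_undef_surv,
            # Fate fractions on the starting-seed scale; they sum to 1 by
            # construction in every iteration.
            "fate_fractions": {
                "predated": float(np.mean(1.0 - a2)),
                "ungerminated": float(np.mean(a2 - a3)),
                "died_as_seedling": float(np.mean(a3 - a4)),
                "surviving": float(np.mean(a4)),
            },
        }
    return result


def _ratio(num: float, den: float) -> float:
    if den > 0:
        return num / den
    if num > 0:
        return float("inf")
    return float("nan")


def _advantage(dispersed: PathwayOutcome, undispersed: PathwayOutcome) -> dict:
    return {
        "newly_emerged": _ratio(
            float(dispersed.p_newly_emerged.mean()), float(undispersed.p_newly_emerged.mean())
        ),
        "surviving": _ratio(
            float(dispersed.p_surviving.mean()), float(undispersed.p_surviving.mean())
        ),
    }


def stage_loss_decomposition(result: SimulationResult) -> dict:
    """Per-pathway mean stage losses (recomputed from the iteration arrays).

    Reports, per pathway: the mean fraction of seeds predated; of the
    predation survivors, the mean fraction failing to emerge; of the
    emerged seedlings, the mean fraction dying — each averaged over
    iterations, with 0/0 iterations excluded and counted.
    """
    return _losses(result.dispersed, result.undispersed)


def dispersal_advantage(result: SimulationResult) -> dict:
    """Ratio of pathway mean outcomes, DISPERSED / UNDISPERSED.

    Infinite when the undispersed mean is zero but the dispersed mean is
    positive (the 'no undispersed seedling survived' situation); NaN when
    both means are zero.
    """
    return _advantage(result.dispersed, result.undispersed)


def analytic_expected_outcome(
    tables: dict[str, TransitionTable],
    dispersal: DispersalDistribution,
    cover: Optional[CoverTable],
    config: SimulationConfig,
    unstudied_to_zero: bool = False,
) -> dict:
    """Closed-form expectation of the simulation under independent stage draws.

    Because stage draws are independent within an iteration and the
    expectation of a drawn transition equals its replicate-group mean (for
    either draw mode), the expected iteration output is the weighted chain
    evaluated at the group means.  Serves as the convergence oracle for
    the simulation means.
    """
    pred_table, emer_table, surv_table = _stage_tables(tables)
    weights = _dispersal_weights(dispersal, cover, config.weighting_mode)

    def mean_of(table: TransitionTable, key: tuple[str, ...]) -> float:
        return float(np.mean(_require_group(table, key)))

    disp_newly = 0.0
    disp_surv = 0.0
    for m, w in weights.items():
        if unstudied_to_zero and not _has_groups((pred_table, emer_table, surv_table), m):
            continue
        s2 = mean_of(pred_table, (m,))
        s3 = mean_of(emer_table, (m, DIGESTED))
        s4 = mean_of(surv_table, (m, DIGESTED))
        newly, surv = chain_product(w, s2, s3, s4)
        disp_newly += newly
        disp_surv += surv

    mix = {t: w for t, w in config.undispersed_treatment_mix.items() if w > 0}
    s2 = mean_of(pred_table, (EPHEDRA,))
    und_newly = 0.0
    und_surv = 0.0
    for t, wt in mix.items():
        s3 = mean_of(emer_table, (EPHEDRA, t))
        s4 = mean_of(surv_table, (EPHEDRA, t))
        newly, surv = chain_product(wt, s2, s3, s4)
        und_newly += newly
        und_surv += surv

    return {
        DISPERSED: {"p_newly_emerged": disp_newly, "p_surviving": disp_surv},
        UNDISPERSED: {"p_newly_emerged": und_newly, "p_surviving": und_surv},
    }
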