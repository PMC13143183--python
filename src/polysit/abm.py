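"""Stochastic daily-step agent-based model of SIT with polyandrous females.

The model is well-mixed and advances in one-day steps. Wild males,
sterilized males and larvae carry no individual state beyond survival,
so they are represented as integer pools with binomial daily draws —
statistically identical to per-agent Bernoulli draws. Females are
individual agents: each carries a refractory counter and an ordered
sperm store, because the six sperm-use scenarios read different
features of the mating history:

=============  =====================================================
FIRST          exclusive use of the first mate's sperm (equivalent to
               no multiple mating)
LAST           exclusive use of the most recent mate's sperm
MIXED          fertile sperm used in proportion to the share of
               fertile records stored
PREFERENCE_W   complete preference for fertile (wild) sperm when any
               is stored
PREFERENCE_I   relative preference for fertile sperm (weight 0.8 by
               default) when both kinds are stored
PREFERENCE_S   complete preference for sterilized sperm when any is
               stored (best case for SIT)
=============  =====================================================

Continuous ODE rates map to daily probabilities via q = 1 − exp(−rate),
so sojourn times match the exponential durations of the compartmental
model. Refractory durations are drawn geometrically with daily
end-probability 1 − exp(−τ); τ = 0 therefore means the female never
re-mates.

For speed, ``run_abm`` executes females as a struct-of-arrays
population: per female it tracks the refractory counter, the numbers of
fertile and sterile records, and the origins of the first and last
records — sufficient statistics for every scenario above. The scalar
per-agent API (:class:`FemaleAgent`, :func:`sperm_selection`,
:func:`mate_event`) implements the same rules one agent at a time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .parameters import ModelParameters, ReleasePolicy, default_suzukii_parameters

__all__ = [
    "SpermUseScenario",
    "FIRST", "LAST", "MIXED", "PREFERENCE_W", "PREFERENCE_I", "PREFERENCE_S",
    "SCENARIOS",
    "MatingRecord",
    "SpermStore",
    "FemaleAgent",
    "ABMConfig",
    "ABMState",
    "ABMTimeSeries",
    "sperm_selection",
    "mate_event",
    "daily_step",
    "run_abm",
    "replicate_rng",
    "write_timeseries",
]

Origin = Literal["fertile", "sterile"]

_NEVER = np.iinfo(np.int64).max // 2  # refractory sentinel for tau = 0


@dataclass(frozen=True)
class SpermUseScenario:
    """One of the six sperm-use rules; ``preference_weight`` is only
    read by the intermediate-preference rule."""

    kind: Literal["first", "last", "mixed", "preference_w", "preference_i", "preference_s"]
    preference_weight: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.preference_weight <= 1):
            raise ValueError(f"preference weight must lie in [0, 1], got {self.preference_weight!r}")

    @classmethod
    def from_name(cls, name: str, preference_weight: float = 0.8) -> "SpermUseScenario":
        return cls(kind=name.lower(), preference_weight=preference_weight)  # type: ignore[arg-type]


FIRST = SpermUseScenario("first")
LAST = SpermUseScenario("last")
MIXED = SpermUseScenario("mixed")
PREFERENCE_W = SpermUseScenario("preference_w")
PREFERENCE_I = SpermUseScenario("preference_i")
PREFERENCE_S = SpermUseScenario("preference_s")
SCENARIOS = (FIRST, LAST, MIXED, PREFERENCE_W, PREFERENCE_I, PREFERENCE_S)


@dataclass(frozen=True)
class MatingRecord:
    origin: Origin
    day: int = 0


@dataclass
class SpermStore:
    """Ordered mating history; order equals mating order, never reordered."""

    records: list[MatingRecord] = field(default_factory=list)

    def add(self, origin: Origin, day: int = 0) -> None:
        self.records.append(MatingRecord(origin, day))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_fertile(self) -> int:
        return sum(1 for r in self.records if r.origin == "fertile")

    @property
    def n_sterile(self) -> int:
        return len(self.records) - self.n_fertile


@dataclass
class FemaleAgent:
    alive: bool = True
    refractory: int = 0  # days remaining; 0 = available
    store: SpermStore = field(default_factory=SpermStore)
    age: int = 0


def sperm_selection(scenario: SpermUseScenario, store: SpermStore, rng: np.random.Generator) -> Origin:
    """Origin of the sperm fertilizing one egg, given the stored history.

    The store must be non-empty (a female with an empty store lays no
    viable larvae and must not be asked).
    """
    if len(store) == 0:
        raise ValueError("sperm_selection requires a non-empty sperm store")
    kind = scenario.kind
    if kind == "first":
        return store.records[0].origin
    if kind == "last":
        return store.records[-1].origin
    n_f = store.n_fertile
    n_s = len(store) - n_f
    if kind == "mixed":
        return "fertile" if rng.random() < n_f / len(store) else "sterile"
    if kind == "preference_w":
        return "fertile" if n_f > 0 else "sterile"
    if kind == "preference_s":
        return "sterile" if n_s > 0 else "fertile"
    if kind == "preference_i":
        if n_f > 0 and n_s > 0:
            return "fertile" if rng.random() < scenario.preference_weight else "sterile"
        return "fertile" if n_f > 0 else "sterile"
    raise ValueError(f"unknown scenario kind {kind!r}")


def _refractory_draw(tau: float, rng: np.random.Generator) -> int:
    q = 1.0 - math.exp(-tau)
    if q <= 0:
        return _NEVER
    return int(rng.geometric(q))


def mate_event(
    female: FemaleAgent,
    wild_count: int,
    sterile_count: int,
    params: ModelParameters,
    rng: np.random.Generator,
    day: int = 0,
) -> FemaleAgent:
    """One day's mating opportunity for an available female.

    With any males present the female mates with daily probability
    1 − exp(−χ) (≈ 1 at χ = 10); the mate is sterilized with probability
    ηS/(M + ηS). A record is appended and a geometric refractory
    duration drawn with daily end-probability 1 − exp(−τF) (wild mate)
    or 1 − exp(−τI) (sterile mate).
    """
    if female.refractory != 0:
        raise ValueError("mate_event requires an available female (refractory = 0)")
    total = wild_count + params.eta * sterile_count
    if wild_count + sterile_count <= 0:
        return female
    if rng.random() >= 1.0 - math.exp(-params.chi):
        return female
    sterile = rng.random() < params.eta * sterile_count / total
    female.store.add("sterile" if sterile else "fertile", day)
    tau = params.tau_I if sterile else params.tau_F
    female.refractory = _refractory_draw(tau, rng)
    return female


# ---------------------------------------------------------------------------
# Vectorized population engine


@dataclass
class ABMConfig:
    params: ModelParameters = field(default_factory=default_suzukii_parameters)
    scenario: SpermUseScenario = LAST
    release: ReleasePolicy = field(default_factory=ReleasePolicy)
    wild_males: int = 1000
    females: int = 1000
    larvae: int = 0
    sterile_males: int = 0
    fertilized_females: int = 0  # start with one fertile record + refractory
    horizon: int = 100
    seed: int | np.random.Generator = 0
    mating_cap: int | None = None  # max matings per female; None = unlimited

    def __post_init__(self) -> None:
        for name in ("wild_males", "females", "larvae", "sterile_males", "fertilized_females"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")


@dataclass
class ABMState:
    """Mutable population state: integer pools plus per-female arrays.

    Female arrays are parallel: ``refractory`` (days remaining),
    ``n_fert``/``n_ster`` (record counts) and ``first_sterile``/
    ``last_sterile`` (0 fertile, 1 sterile; meaningful only when the
    store is non-empty).
    """

    larvae: int
    wild: int
    sterile: int
    refractory: np.ndarray
    n_fert: np.ndarray
    n_ster: np.ndarray
    first_sterile: np.ndarray
    last_sterile: np.ndarray

    @classmethod
    def from_config(cls, config: ABMConfig, rng: np.random.Generator) -> "ABMState":
        n_plain, n_fert = config.females, config.fertilized_females
        n = n_plain + n_fert
        refractory = np.zeros(n, dtype=np.int64)
        n_f = np.zeros(n, dtype=np.int64)
        if n_fert:
            n_f[n_plain:] = 1
            q = 1.0 - math.exp(-config.params.tau_F)
            refractory[n_plain:] = rng.geometric(q, n_fert) if q > 0 else _NEVER
        return cls(
            larvae=config.larvae,
            wild=config.wild_males,
            sterile=config.sterile_males,
            refractory=refractory,
            n_fert=n_f,
            n_ster=np.zeros(n, dtype=np.int64),
            first_sterile=np.zeros(n, dtype=np.int8),
            last_sterile=np.zeros(n, dtype=np.int8),
        )

    @property
    def n_females(self) -> int:
        return self.refractory.size

    def counts(self) -> dict[str, int]:
        inseminated = (self.n_fert + self.n_ster) > 0
        refr = self.refractory > 0
        return {
            "larvae": int(self.larvae),
            "wild_males": int(self.wild),
            "sterile_males": int(self.sterile),
            "females_available": int(np.sum(~refr)),
            "females_fertile_refractory": int(np.sum(refr & inseminated & (self.last_sterile == 0))),
            "females_infertile_refractory": int(np.sum(refr & (self.last_sterile == 1))),
        }


def _viable_eggs(
    eggs: np.ndarray,
    scenario: SpermUseScenario,
    n_fert: np.ndarray,
    n_ster: np.ndarray,
    first_sterile: np.ndarray,
    last_sterile: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-female viable egg counts, applying sperm selection per egg.

    Callers pass only inseminated females (n_fert + n_ster > 0).
    """
    kind = scenario.kind
    if kind == "first":
        return np.where(first_sterile == 0, eggs, 0)
    if kind == "last":
        return np.where(last_sterile == 0, eggs, 0)
    if kind == "preference_w":
        return np.where(n_fert > 0, eggs, 0)
    if kind == "preference_s":
        return np.where(n_ster == 0, eggs, 0)
    if kind == "mixed":
        p = n_fert / (n_fert + n_ster)
        return rng.binomial(eggs, p)
    if kind == "preference_i":
        p = np.where(n_fert > 0, np.where(n_ster > 0, scenario.preference_weight, 1.0), 0.0)
        return rng.binomial(eggs, p)
    raise ValueError(f"unknown scenario kind {kind!r}")


def daily_step(
    state: ABMState,
    params: ModelParameters,
    scenario: SpermUseScenario,
    release: ReleasePolicy,
    rng: np.random.Generator,
    day: int = 0,
    mating_cap: int | None = None,
) -> dict[str, int]:
    """Advance the population by one day, in the fixed scheduler order:
    release → sterilized males → wild males → larvae → females → counts.

    Mutates ``state`` in place and returns the day's counts plus the
    accounting entries (releases, deaths, emergences, admissions) that
    let a per-day population ledger balance exactly.
    """
    pr = params

    # (1) release
    released = release.abm_batch if release.releases_on(day) else 0
    state.sterile += released

    # (2-3) adult male survival
    sterile_deaths = int(rng.binomial(state.sterile, 1.0 - math.exp(-pr.mu_S)))
    state.sterile -= sterile_deaths
    wild_deaths = int(rng.binomial(state.wild, 1.0 - math.exp(-pr.mu_M)))
    state.wild -= wild_deaths

    # (4) larvae: survival, then maturation, then sex split
    larva_deaths = int(rng.binomial(state.larvae, 1.0 - math.exp(-pr.mu_L)))
    survivors = state.larvae - larva_deaths
    matured = int(rng.binomial(survivors, 1.0 - math.exp(-pr.nu)))
    state.larvae = survivors - matured
    emerged_males = int(rng.binomial(matured, pr.p))
    emerged_females = matured - emerged_males
    state.wild += emerged_males

    # (5) females
    n = state.n_females
    survive = rng.random(n) < math.exp(-pr.mu_F)
    female_deaths = int(n - survive.sum())
    for name in ("refractory", "n_fert", "n_ster", "first_sterile", "last_sterile"):
        setattr(state, name, getattr(state, name)[survive])
    if emerged_females:
        z64 = np.zeros(emerged_females, dtype=np.int64)
        z8 = np.zeros(emerged_females, dtype=np.int8)
        state.refractory = np.concatenate([state.refractory, z64])
        state.n_fert = np.concatenate([state.n_fert, z64])
        state.n_ster = np.concatenate([state.n_ster, z64])
        state.first_sterile = np.concatenate([state.first_sterile, z8])
        state.last_sterile = np.concatenate([state.last_sterile, z8])
    n = state.n_females

    np.maximum(state.refractory - 1, 0, out=state.refractory)
    available = state.refractory == 0
    if mating_cap is not None:
        available &= (state.n_fert + state.n_ster) < mating_cap

    if state.wild + state.sterile > 0 and available.any():
        q_mate = 1.0 - math.exp(-pr.chi)
        mates = available & (rng.random(n) < q_mate)
        idx = np.flatnonzero(mates)
        if idx.size:
            p_sterile = pr.eta * state.sterile / (state.wild + pr.eta * state.sterile)
            sterile_mate = rng.random(idx.size) < p_sterile
            empty = (state.n_fert[idx] + state.n_ster[idx]) == 0
            origin8 = sterile_mate.astype(np.int8)
            state.first_sterile[idx[empty]] = origin8[empty]
            state.last_sterile[idx] = origin8
            state.n_ster[idx] += sterile_mate
            state.n_fert[idx] += ~sterile_mate
            q_F = 1.0 - math.exp(-pr.tau_F)
            q_I = 1.0 - math.exp(-pr.tau_I)
            dur = np.full(idx.size, _NEVER, dtype=np.int64)
            w = ~sterile_mate
            if q_F > 0 and w.any():
                dur[w] = rng.geometric(q_F, int(w.sum()))
            if q_I > 0 and sterile_mate.any():
                dur[sterile_mate] = rng.geometric(q_I, int(sterile_mate.sum()))
            state.refractory[idx] = dur

    # oviposition: every inseminated female lays Poisson(omega) eggs;
    # viability by sperm selection, admission by the start-of-day
    # density factor, hard-capped so larvae never exceed K.
    admitted = 0
    inseminated = (state.n_fert + state.n_ster) > 0
    if inseminated.any():
        ii = np.flatnonzero(inseminated)
        eggs = rng.poisson(pr.omega, ii.size)
        viable = _viable_eggs(
            eggs, scenario,
            state.n_fert[ii], state.n_ster[ii],
            state.first_sterile[ii], state.last_sterile[ii], rng,
        )
        total_viable = int(viable.sum())
        p_admit = max(0.0, 1.0 - state.larvae / pr.K)
        admitted = min(int(rng.binomial(total_viable, p_admit)), int(pr.K) - state.larvae)
        admitted = max(admitted, 0)
        state.larvae += admitted

    out = state.counts()
    out.update(
        released=released,
        sterile_deaths=sterile_deaths,
        wild_deaths=wild_deaths,
        larva_deaths=larva_deaths,
        emerged_males=emerged_males,
        emerged_females=emerged_females,
        female_deaths=female_deaths,
        larvae_admitted=admitted,
    )
    return out


_SERIES_COLUMNS = (
    "larvae", "wild_males", "sterile_males",
    "females_available", "females_fertile_refractory", "females_infertile_refractory",
)


@dataclass
class ABMTimeSeries:
    """Per-day integer counts; day 0 is the initial configuration."""

    day: np.ndarray
    data: dict[str, np.ndarray]
    config: ABMConfig | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    @property
    def larvae(self) -> np.ndarray:
        return self.data["larvae"]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"day": self.day, **self.data})


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Stable per-replicate stream: the generator is seeded with the
    sequence (master_seed, replicate)."""
    return np.random.default_rng([int(master_seed), int(replicate)])


def run_abm(config: ABMConfig, collect_ledger: bool = False) -> ABMTimeSeries:
    """Run the ABM for ``config.horizon`` days from the initial state.

    Initial females start available with empty stores; initial
    fertilized females carry one fertile record and a freshly drawn
    refractory duration; initial larvae start as one undifferentiated
    pool (maturation is memoryless). Identical config + seed gives a
    bit-identical series.
    """
    rng = config.seed if isinstance(config.seed, np.random.Generator) \
        else np.random.default_rng(config.seed)
    state = ABMState.from_config(config, rng)
    rows = [state.counts()]
    ledger = []
    for day in range(config.horizon):
        stats = daily_step(state, config.params, config.scenario, config.release,
                           rng, day=day, mating_cap=config.mating_cap)
        rows.append({k: stats[k] for k in _SERIES_COLUMNS})
        if collect_ledger:
            ledger.append(stats)
    data = {k: np.array([r[k] for r in rows], dtype=np.int64) for k in _SERIES_COLUMNS}
    series = ABMTimeSeries(day=np.arange(config.horizon + 1), data=data, config=config)
    if collect_ledger:
        series.ledger = ledger  # type: ignore[attr-defined]
    return series


def write_timeseries(series: ABMTimeSeries, csv_path: str, meta_path: str | None = None) -> None:
    """CSV writer (`day,larvae,wild_males,...`) with a JSON config sidecar."""
    series.to_dataframe().to_csv(csv_path, index=False)
    if meta_path and series.config is not None:
        cfg = series.config
        meta = {
            "parameters": cfg.params.to_dict(),
            "scenario": {"kind": cfg.scenario.kind, "preference_weight": cfg.scenario.preference_weight},
            "release": {"sigma": cfg.release.sigma, "batch_size": cfg.release.abm_batch,
                        "period": cfg.release.period, "start_day": cfg.release.start_day},
            "initial": {"wild_males": cfg.wild_males, "females": cfg.females,
                        "larvae": cfg.larvae, "sterile_males": cfg.sterile_males,
                        "fertilized_females": cfg.fertilized_females},
            "horizon": cfg.horizon,
            "seed": cfg.seed if not isinstance(cfg.seed, np.random.Generator) else None,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)
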