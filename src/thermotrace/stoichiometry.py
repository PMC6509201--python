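"""Electron-balance stoichiometry of sulfate reduction, and a microcosm
geochemistry simulator.

The model is plain redox bookkeeping. Completely oxidizing one mole of an
organic molecule CxHyOz to CO2 and H2O transfers

    e = 4x + y - 2z

electrons, and reducing one mole of sulfate to sulfide accepts 8
electrons, so a substrate mix consumed to completion drives

    sum_i (c_i * e_i) / 8   mM of sulfate reduction.

For the incubation medium used in the study system — formate, acetate,
lactate, succinate, propionate and butyrate at 1 mM each — this gives
70 electron-mM, i.e. 8.75 mM of expected sulfate drawdown; adding the
1 mM ethanol amendment raises it to 10.25 mM.

The simulator generates per-analyte concentration time series for one
microcosm: each substrate follows a logistic depletion schedule (lag,
duration, terminal fraction consumed), optionally routed through
incomplete-oxidation rules (e.g. lactate -> acetate + 4 e-, or the
redox-neutral decarboxylation succinate -> propionate) whose products
accumulate and are later consumed on their own schedules. Sulfate is
drawn down by exactly 1/8 of the electrons released so far, so electron
and carbon conservation hold to machine precision at every timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import DETECTION_LIMITS_MM, ConfigError, GeochemSeries

__all__ = [
    "SubstrateSpec",
    "ReactionRule",
    "ConsumptionSchedule",
    "GeochemSimConfig",
    "GeochemSimResult",
    "electrons_complete_oxidation",
    "expected_sulfate_reduction",
    "apply_reaction_rule",
    "simulate_microcosm_geochem",
    "substrate",
    "SIX_ORGANIC_ACIDS",
    "MEDIUM_WITH_ETHANOL",
    "SUCCINATE_TO_PROPIONATE",
    "LACTATE_TO_ACETATE",
    "BUTYRATE_TO_ACETATE",
    "ETHANOL_TO_ACETATE",
    "ELECTRONS_PER_SULFATE",
    "default_microcosm_config",
]

#: electrons accepted reducing one sulfate to sulfide
ELECTRONS_PER_SULFATE = 8


@dataclass(frozen=True)
class SubstrateSpec:
    """An electron-donor substrate: neutral-molecule composition CxHyOz."""

    name: str
    c: int
    h: int
    o: int
    concentration_mm: float = 0.0

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.o) < 0:
            raise ConfigError(f"{self.name}: element counts must be non-negative")
        if self.concentration_mm < 0:
            raise ConfigError(f"{self.name}: concentration must be non-negative")


#: neutral (protonated) compositions of the study's substrates
_COMPOSITIONS = {
    "formate": (1, 2, 2),
    "acetate": (2, 4, 2),
    "lactate": (3, 6, 3),
    "succinate": (4, 6, 4),
    "propionate": (3, 6, 2),
    "butyrate": (4, 8, 2),
    "ethanol": (2, 6, 1),
    "co2": (1, 0, 2),
}


def substrate(name: str, concentration_mm: float = 0.0) -> SubstrateSpec:
    """Look up a known substrate by name at a given concentration."""
    try:
        c, h, o = _COMPOSITIONS[name.lower()]
    except KeyError:
        raise ConfigError(f"unknown substrate {name!r}") from None
    return SubstrateSpec(name.lower(), c, h, o, concentration_mm)


#: the six organic acids of the incubation medium, 1 mM each
SIX_ORGANIC_ACIDS = tuple(
    substrate(n, 1.0)
    for n in ("formate", "acetate", "lactate", "succinate", "propionate", "butyrate")
)

#: the full amendment including 1 mM ethanol
MEDIUM_WITH_ETHANOL = SIX_ORGANIC_ACIDS + (substrate("ethanol", 1.0),)


def electrons_complete_oxidation(s: SubstrateSpec) -> int:
    """Electrons per mol transferred oxidizing CxHyOz to CO2 and H2O."""
    e = 4 * s.c + s.h - 2 * s.o
    if e < 0:
        raise ConfigError(
            f"{s.name}: 4C+H-2O = {e} < 0; not an oxidizable organic compound"
        )
    return e


def expected_sulfate_reduction(mix) -> float:
    """mM of sulfate reduced if the whole mix is oxidized to CO2."""
    return sum(
        s.concentration_mm * electrons_complete_oxidation(s) for s in mix
    ) / ELECTRONS_PER_SULFATE


@dataclass(frozen=True)
class ReactionRule:
    """Partial transformation of one substrate into product substrates.

    Carbon not accounted for by the listed products is released as CO2.
    ``electrons_released`` must equal the electron deficit between the
    reactant and its products, so that any chain of rules ending in CO2
    releases exactly the complete-oxidation electron count.
    """

    name: str
    reactant: str
    products: tuple[tuple[str, float], ...]  # (substrate name, mol per mol)
    electrons_released: int
    to_sulfate: bool = True  # False marks a fermentative rule

    def __post_init__(self) -> None:
        r = substrate(self.reactant)
        prod_c = sum(coeff * substrate(n).c for n, coeff in self.products)
        if prod_c - r.c > 1e-12:
            raise ConfigError(f"rule {self.name}: products carry more carbon than reactant")
        e_full = electrons_complete_oxidation(r)
        e_products = sum(
            coeff * electrons_complete_oxidation(substrate(n))
            for n, coeff in self.products
        )
        if self.electrons_released < 0 or self.electrons_released > e_full:
            raise ConfigError(
                f"rule {self.name}: electrons_released outside [0, {e_full}]"
            )
        if abs((e_full - e_products) - self.electrons_released) > 1e-9:
            raise ConfigError(
                f"rule {self.name}: electron balance broken — reactant carries "
                f"{e_full} e-, products {e_products} e-, rule claims "
                f"{self.electrons_released} released"
            )

    @property
    def co2_per_mol(self) -> float:
        r = substrate(self.reactant)
        return r.c - sum(coeff * substrate(n).c for n, coeff in self.products)


SUCCINATE_TO_PROPIONATE = ReactionRule(
    "succinate_decarboxylation", "succinate", (("propionate", 1.0),), 0
)
LACTATE_TO_ACETATE = ReactionRule(
    "lactate_incomplete_oxidation", "lactate", (("acetate", 1.0),), 4
)
BUTYRATE_TO_ACETATE = ReactionRule(
    "butyrate_incomplete_oxidation", "butyrate", (("acetate", 2.0),), 4
)
ETHANOL_TO_ACETATE = ReactionRule(
    "ethanol_incomplete_oxidation", "ethanol", (("acetate", 1.0),), 4
)


def apply_reaction_rule(rule: ReactionRule, amount_mm: float):
    """Transform ``amount_mm`` of the reactant; return (products, sulfate used).

    Products are a dict of substrate name -> mM produced (CO2 included);
    sulfate consumed is electrons_released/8 per mol when the rule is
    respiratory, 0 when fermentative.
    """
    if amount_mm < 0:
        raise ConfigError("amount must be non-negative")
    products = {n: coeff * amount_mm for n, coeff in rule.products}
    co2 = rule.co2_per_mol * amount_mm
    if co2 > 0:
        products["co2"] = products.get("co2", 0.0) + co2
    sulfate = (
        rule.electrons_released * amount_mm / ELECTRONS_PER_SULFATE
        if rule.to_sulfate
        else 0.0
    )
    return products, sulfate


@dataclass(frozen=True)
class ConsumptionSchedule:
    """Logistic depletion window for one substrate's pool.

    Consumption is zero before ``lag_days``, then follows a logistic curve
    over ``duration_days`` (rescaled so it starts and ends exactly at the
    window edges), removing ``terminal_fraction`` of whatever pool existed
    at each point in time. ``duration_days == 0`` is an instantaneous step.
    """

    lag_days: float = 0.0
    duration_days: float = 1.0
    terminal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.lag_days < 0 or self.duration_days < 0:
            raise ConfigError("lag and duration must be non-negative")
        if not 0.0 <= self.terminal_fraction <= 1.0:
            raise ConfigError("terminal_fraction must lie in [0, 1]")

    def progress(self, t: float, offset_days: float = 0.0) -> float:
        """Completed fraction of the depletion window at time ``t`` in [0,1]."""
        start = self.lag_days + offset_days
        if t <= start:
            return 0.0
        if self.duration_days == 0.0 or t >= start + self.duration_days:
            return 1.0
        # logistic with k = 10/duration, rescaled to hit 0 and 1 exactly
        x = (t - start) / self.duration_days  # in (0, 1)
        g = 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
        g0 = 1.0 / (1.0 + np.exp(5.0))
        g1 = 1.0 / (1.0 + np.exp(-5.0))
        return float((g - g0) / (g1 - g0))


@dataclass
class GeochemSimConfig:
    """One microcosm's geochemistry simulation.

    ``routing`` maps a reactant name to a list of (rule, fraction) pairs:
    that fraction of each consumed mole passes through the rule, the
    remainder is completely oxidized to CO2. ``lag_offset_days`` shifts
    every schedule, modeling the delayed onset after harsher freezing
    pretreatments.
    """

    substrates: tuple[SubstrateSpec, ...]
    initial_sulfate_mm: float = 20.0
    schedules: dict[str, ConsumptionSchedule] = field(default_factory=dict)
    routing: dict[str, list[tuple[ReactionRule, float]]] = field(default_factory=dict)
    lag_offset_days: float = 0.0
    t_end_days: float = 21.0
    dt_days: float = 0.25
    noise_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_sulfate_mm < 0:
            raise ConfigError("initial sulfate must be non-negative")
        if self.dt_days <= 0 or self.t_end_days <= 0:
            raise ConfigError("dt and t_end must be positive")
        names = {s.name for s in self.substrates}
        produced = {
            n
            for rules in self.routing.values()
            for rule, _ in rules
            for n, _ in rule.products
        }
        for name in self.schedules:
            if name not in names | produced:
                raise ConfigError(f"schedule references unknown substrate {name!r}")
        for reactant, rules in self.routing.items():
            if reactant not in names | produced:
                raise ConfigError(f"routing references unknown substrate {reactant!r}")
            total = sum(f for _, f in rules)
            if any(f < 0 for _, f in rules) or total > 1.0 + 1e-12:
                raise ConfigError(
                    f"routing fractions for {reactant!r} must be non-negative "
                    f"and sum to at most 1"
                )
            for rule, _ in rules:
                if rule.reactant != reactant:
                    raise ConfigError(
                        f"rule {rule.name!r} does not consume {reactant!r}"
                    )


@dataclass
class GeochemSimResult:
    """Simulator output: the analyte series plus conservation ledgers."""

    series: list[GeochemSeries]
    times: np.ndarray
    sulfate: np.ndarray  # noise-free trajectory, mM
    electrons_to_sulfate: np.ndarray  # cumulative, electron-mM
    electrons_fermented: np.ndarray  # cumulative, electron-mM (no sulfate sink)
    co2: np.ndarray  # cumulative CO2 carbon pool, mM
    carbon_total: np.ndarray  # total organic + CO2 carbon, mM

    @property
    def terminal_drawdown_mm(self) -> float:
        return float(self.sulfate[0] - self.sulfate[-1])

    def by_analyte(self, analyte: str) -> GeochemSeries:
        for s in self.series:
            if s.analyte == analyte:
                return s
        raise KeyError(analyte)


def simulate_microcosm_geochem(
    cfg: GeochemSimConfig, microcosm_id: str = "microcosm"
) -> GeochemSimResult:
    """Integrate the depletion schedules and the electron balance.

    At each timestep, every scheduled substrate pool is reduced by the
    survival ratio of its schedule; the consumed amount is split across
    its routing rules and complete oxidation, releasing electrons and
    products. Sulfate drawdown is electrons-to-sulfate / 8 by construction.
    """
    compositions = dict(_COMPOSITIONS)
    pools: dict[str, float] = {}
    for s in cfg.substrates:
        compositions[s.name] = (s.c, s.h, s.o)
        pools[s.name] = pools.get(s.name, 0.0) + s.concentration_mm
    for rules in cfg.routing.values():
        for rule, _ in rules:
            for n, _ in rule.products:
                pools.setdefault(n, 0.0)

    times = np.arange(0.0, cfg.t_end_days + cfg.dt_days / 2, cfg.dt_days)
    n_t = len(times)
    names = sorted(pools)
    traj = {n: np.zeros(n_t) for n in names}
    e_sulf = np.zeros(n_t)
    e_ferm = np.zeros(n_t)
    co2 = np.zeros(n_t)

    def _electrons(name: str) -> int:
        c, h, o = compositions[name]
        return 4 * c + h - 2 * o

    cum_e_sulf = 0.0
    cum_e_ferm = 0.0
    cum_co2 = 0.0
    prev_progress = {n: 0.0 for n in cfg.schedules}
    for it, t in enumerate(times):
        if it > 0:
            inflow: dict[str, float] = {}
            for name, sched in cfg.schedules.items():
                prog = sched.progress(t, cfg.lag_offset_days)
                p0 = prev_progress[name]
                prev_progress[name] = prog
                # survival S = 1 - terminal*progress; multiplicative update so
                # late inflows are consumed by the remaining schedule only
                s_prev = 1.0 - sched.terminal_fraction * p0
                s_now = 1.0 - sched.terminal_fraction * prog
                ratio = s_now / s_prev if s_prev > 0 else 0.0
                consumed = pools[name] * (1.0 - ratio)
                if consumed <= 0:
                    continue
                pools[name] -= consumed
                routed = 0.0
                for rule, frac in cfg.routing.get(name, ()):
                    amt = consumed * frac
                    routed += amt
                    products, sulf = apply_reaction_rule(rule, amt)
                    for pname, pmm in products.items():
                        if pname == "co2":
                            cum_co2 += pmm
                        else:
                            inflow[pname] = inflow.get(pname, 0.0) + pmm
                    if rule.to_sulfate:
                        cum_e_sulf += rule.electrons_released * amt
                    else:
                        cum_e_ferm += rule.electrons_released * amt
                direct = consumed - routed
                if direct > 0:
                    cum_e_sulf += _electrons(name) * direct
                    cum_co2 += compositions[name][0] * direct
            for pname, pmm in inflow.items():
                pools[pname] = pools.get(pname, 0.0) + pmm
        for n in names:
            traj[n][it] = pools.get(n, 0.0)
        e_sulf[it] = cum_e_sulf
        e_ferm[it] = cum_e_ferm
        co2[it] = cum_co2

    sulfate = cfg.initial_sulfate_mm - e_sulf / ELECTRONS_PER_SULFATE
    if (sulfate < -1e-9).any():
        raise ConfigError(
            "substrate mix releases more electrons than the initial sulfate "
            "can accept; raise initial_sulfate_mm"
        )
    carbon_total = co2 + sum(
        traj[n] * compositions[n][0] for n in names
    )

    rng = np.random.default_rng(cfg.seed)

    def _noisy(values: np.ndarray) -> np.ndarray:
        if cfg.noise_sigma_mm <= 0:
            return values
        return np.clip(values + rng.normal(0.0, cfg.noise_sigma_mm, len(values)), 0.0, None)

    series = [
        GeochemSeries(microcosm_id, "sulfate", times, _noisy(np.clip(sulfate, 0, None)))
    ]
    for n in names:
        if n == "co2":
            continue
        series.append(GeochemSeries(microcosm_id, n, times, _noisy(traj[n])))
    return GeochemSimResult(
        series=series,
        times=times,
        sulfate=sulfate,
        electrons_to_sulfate=e_sulf,
        electrons_fermented=e_ferm,
        co2=co2,
        carbon_total=carbon_total,
    )


def default_microcosm_config(
    lag_offset_days: float = 0.0,
    include_ethanol: bool = True,
    consume_ethanol: bool = False,
    seed: int = 0,
) -> GeochemSimConfig:
    """A microcosm emulating the observed +50 degC dynamics.

    Formate and lactate go first, succinate converts stoichiometrically to
    propionate, propionate and butyrate follow, and acetate — fed by
    incomplete oxidation of lactate and butyrate on top of its initial
    1 mM — overshoots up to about fourfold before its own late depletion.
    Ethanol is present in the medium but left unconsumed by default, so
    the terminal drawdown matches the 8.75 mM complete-oxidation
    expectation for the six organic acids. ``lag_offset_days`` delays every
    schedule (e.g. ~5 days emulates the slow onset after a -80 degC
    pretreatment).
    """
    substrates = MEDIUM_WITH_ETHANOL if include_ethanol else SIX_ORGANIC_ACIDS
    schedules = {
        "formate": ConsumptionSchedule(0.5, 1.0, 1.0),
        "lactate": ConsumptionSchedule(0.5, 1.0, 1.0),
        "succinate": ConsumptionSchedule(1.0, 2.0, 1.0),
        "propionate": ConsumptionSchedule(3.5, 2.5, 1.0),
        "butyrate": ConsumptionSchedule(3.5, 2.5, 1.0),
        "acetate": ConsumptionSchedule(6.0, 4.0, 1.0),
    }
    routing = {
        "succinate": [(SUCCINATE_TO_PROPIONATE, 1.0)],
        "lactate": [(LACTATE_TO_ACETATE, 1.0)],
        "butyrate": [(BUTYRATE_TO_ACETATE, 1.0)],
    }
    if include_ethanol and consume_ethanol:
        schedules["ethanol"] = ConsumptionSchedule(1.0, 2.0, 1.0)
        routing["ethanol"] = [(ETHANOL_TO_ACETATE, 1.0)]
    return GeochemSimConfig(
        substrates=tuple(substrates),
        initial_sulfate_mm=20.0,
        schedules=schedules,
        routing=routing,
        lag_offset_days=lag_offset_days,
        seed=seed,
    )
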