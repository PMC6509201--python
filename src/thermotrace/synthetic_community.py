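"""Synthetic microcosm studies with known ground truth.

Emulates the statistical structure the calling pipeline assumes: a
dominant background community (an abundant log-normal core plus a rare
tail of OTUs near the sequencing detection limit) in which a handful of
thermospore OTUs sit as a dormant, very low-abundance seed bank (default
day-0 seed fractions of 1e-5 to 5e-5, i.e. below ~0.005%);
freezing pretreatments kill each thermospore's spores all-or-nothing per
microcosm with class-specific survival probabilities; survivors germinate
and grow during the +50 degC incubation (growth factors of 200-5000 over
7 days); and each library is a multinomial read sample (default 45,000
reads) from the resulting composition. Dormant/dead background DNA
persists, so day-0 libraries remain dominated by the background even
after pasteurization.

Three default thermospore classes mirror the phenotypes the study design
can distinguish: freeze-robust (viable everywhere), freeze-sensitive
(mostly lost at -80 degC) and freeze-revealed (out-competed in unfrozen
controls, enriched after freezing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ConfigError, OtuCountTable, Pretreatment, SampleRecord, ValidationError

__all__ = [
    "ThermosporeClass",
    "CommunitySimConfig",
    "MicrocosmTruth",
    "StudyTruth",
    "default_classes",
    "draw_seedbank",
    "apply_pretreatment",
    "incubate",
    "sequence_sample",
    "generate_study",
    "recovery_summary",
]


@dataclass(frozen=True)
class ThermosporeClass:
    """A survival/growth phenotype shared by a group of thermospore OTUs."""

    label: str
    survival: dict[Pretreatment, float]
    growth_range: tuple[float, float] = (200.0, 5000.0)

    def __post_init__(self) -> None:
        for p in Pretreatment:
            if p not in self.survival:
                raise ConfigError(f"class {self.label!r}: missing survival for {p.name}")
            if not 0.0 <= self.survival[p] <= 1.0:
                raise ConfigError(f"class {self.label!r}: survival must lie in [0, 1]")
        lo, hi = self.growth_range
        if lo < 1.0 or hi < lo:
            raise ConfigError(f"class {self.label!r}: growth factors must be >= 1")


def default_classes() -> tuple[ThermosporeClass, ...]:
    P4, M20, M80 = Pretreatment.PLUS4, Pretreatment.MINUS20, Pretreatment.MINUS80
    return (
        ThermosporeClass("freeze_robust", {P4: 0.95, M20: 0.95, M80: 0.9}),
        ThermosporeClass("freeze_sensitive", {P4: 0.95, M20: 0.8, M80: 0.15}),
        ThermosporeClass("freeze_revealed", {P4: 0.1, M20: 0.85, M80: 0.85}),
    )


@dataclass
class CommunitySimConfig:
    n_background_otus: int = 300
    n_thermospore_otus: int = 20
    background_lognormal_mu: float = 0.0
    background_lognormal_sigma: float = 0.8
    background_rare_fraction: float = 0.5
    rare_fraction_range: tuple[float, float] = (5e-6, 5e-5)
    seed_fraction_range: tuple[float, float] = (1e-5, 5e-5)
    classes: tuple[ThermosporeClass, ...] = field(default_factory=default_classes)
    library_size: int = 45000
    replicates: int = 3
    fractional_survival: bool = False
    fractional_survival_n: int = 100  # viable spores represented per OTU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_otus < 0 or self.n_thermospore_otus < 0:
            raise ConfigError("OTU counts must be non-negative")
        if self.n_background_otus + self.n_thermospore_otus == 0:
            raise ConfigError("community must contain at least one OTU")
        if self.library_size <= 0:
            raise ConfigError("library size must be positive")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate")
        for rng_name in ("seed_fraction_range", "rare_fraction_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi < 1):
                raise ConfigError(f"{rng_name} must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.background_rare_fraction <= 1.0:
            raise ConfigError("background_rare_fraction must lie in [0, 1]")
        if self.n_thermospore_otus > 0 and not self.classes:
            raise ConfigError("thermospore OTUs require at least one class")


@dataclass
class MicrocosmTruth:
    """Ground truth for one microcosm (one pretreatment x replicate)."""

    microcosm_id: str
    pretreatment: Pretreatment
    replicate: str
    survived: np.ndarray  # per-thermospore bool (or survival fraction weight)
    survival_weight: np.ndarray  # fraction of the seed that stays viable
    realized_growth: np.ndarray  # per-thermospore growth factor (1 if dead)
    day0_composition: np.ndarray = None  # type: ignore[assignment]
    day7_composition: np.ndarray = None  # type: ignore[assignment]


@dataclass
class StudyTruth:
    """Ground truth of a whole synthetic study."""

    otu_ids: list[str]
    is_thermospore: np.ndarray  # bool per OTU
    class_labels: list[str | None]
    growth_factor: np.ndarray  # per OTU (1 for background)
    day0_composition: np.ndarray  # shared across microcosms
    microcosms: dict[str, MicrocosmTruth] = field(default_factory=dict)

    @property
    def thermospore_ids(self) -> list[str]:
        return [o for o, t in zip(self.otu_ids, self.is_thermospore) if t]


def draw_seedbank(cfg: CommunitySimConfig, rng: np.random.Generator) -> StudyTruth:
    """Draw the shared day-0 community: background plus dormant seeds.

    The background has two components, as marine sediment communities do:
    an abundant core with log-normal fractions (renormalized to fill
    whatever the rare tail and the thermospore seed bank leave of the
    total), and a rare tail of OTUs sitting near the sequencing detection
    limit (log-uniform absolute fractions), which carries the richness
    response to compositional compression. Thermospore seeds are uniform
    within the configured range; growth factors are log-uniform within
    each class's range, drawn once per OTU.
    """
    n_bg, n_ts = cfg.n_background_otus, cfg.n_thermospore_otus
    otu_ids = [f"BG_{i + 1:04d}" for i in range(n_bg)] + [
        f"TS_{i + 1:02d}" for i in range(n_ts)
    ]
    seeds = rng.uniform(*cfg.seed_fraction_range, size=n_ts)
    if n_bg:
        n_rare = int(round(n_bg * cfg.background_rare_fraction))
        n_common = n_bg - n_rare
        lo, hi = cfg.rare_fraction_range
        rare = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_rare))
        if n_common == 0:
            rare = rare / rare.sum() * (1.0 - seeds.sum())
            bg = rare
        else:
            common_mass = 1.0 - seeds.sum() - rare.sum()
            if common_mass <= 0:
                raise ConfigError(
                    "rare tail and seed bank leave no mass for the abundant "
                    "core; reduce rare_fraction_range or background_rare_fraction"
                )
            raw = rng.lognormal(
                cfg.background_lognormal_mu, cfg.background_lognormal_sigma,
                size=n_common,
            )
            bg = np.concatenate([raw / raw.sum() * common_mass, rare])
    else:
        bg = np.array([])
        seeds = seeds / seeds.sum()
    composition = np.concatenate([bg, seeds])

    labels: list[str | None] = [None] * n_bg
    growth = np.ones(n_bg + n_ts)
    for i in range(n_ts):
        cls = cfg.classes[i % len(cfg.classes)]
        labels.append(cls.label)
        lo, hi = cls.growth_range
        growth[n_bg + i] = np.exp(rng.uniform(np.log(lo), np.log(hi)))

    return StudyTruth(
        otu_ids=otu_ids,
        is_thermospore=np.arange(n_bg + n_ts) >= n_bg,
        class_labels=labels,
        growth_factor=growth,
        day0_composition=composition,
    )


def _class_of(truth: StudyTruth, cfg: CommunitySimConfig, idx: int) -> ThermosporeClass:
    label = truth.class_labels[idx]
    for cls in cfg.classes:
        if cls.label == label:
            return cls
    raise ConfigError(f"unknown thermospore class label {label!r}")


def apply_pretreatment(
    truth: StudyTruth,
    cfg: CommunitySimConfig,
    pretreatment: Pretreatment,
    replicate: str,
    rng: np.random.Generator,
) -> MicrocosmTruth:
    """Decide which thermospores stay viable in one microcosm.

    Survival is Bernoulli per OTU per microcosm by default (all spores of
    an OTU live or die together — the simplest mechanism generating the
    observed between-replicate variability). With
    ``cfg.fractional_survival`` the viable seed is instead binomially
    thinned across ``fractional_survival_n`` virtual spores.
    """
    ts_idx = np.flatnonzero(truth.is_thermospore)
    survived = np.ones(len(ts_idx), dtype=bool)
    weight = np.ones(len(ts_idx))
    growth = np.ones(len(ts_idx))
    for j, idx in enumerate(ts_idx):
        cls = _class_of(truth, cfg, idx)
        p = cls.survival[pretreatment]
        if cfg.fractional_survival:
            k = rng.binomial(cfg.fractional_survival_n, p)
            weight[j] = k / cfg.fractional_survival_n
            survived[j] = k > 0
        else:
            survived[j] = rng.random() < p
        growth[j] = truth.growth_factor[idx] if survived[j] else 1.0
        if cfg.fractional_survival and survived[j]:
            # only the viable sub-population germinates; dead DNA persists
            growth[j] = 1.0 + (truth.growth_factor[idx] - 1.0) * weight[j]
    return MicrocosmTruth(
        microcosm_id=f"{pretreatment.name}_{replicate}",
        pretreatment=pretreatment,
        replicate=replicate,
        survived=survived,
        survival_weight=weight,
        realized_growth=growth,
        day0_composition=truth.day0_composition.copy(),
    )


def incubate(truth: StudyTruth, microcosm: MicrocosmTruth) -> MicrocosmTruth:
    """Grow survivors: day-7 fractions proportional to day-0 x growth."""
    ts_idx = np.flatnonzero(truth.is_thermospore)
    factors = np.ones(len(truth.otu_ids))
    factors[ts_idx] = microcosm.realized_growth
    day7 = microcosm.day0_composition * factors
    microcosm.day7_composition = day7 / day7.sum()
    return microcosm


def sequence_sample(
    composition: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read sampling; the column sum equals ``depth`` exactly."""
    p = np.asarray(composition, dtype=float)
    if (p < 0).any():
        raise ValidationError("composition fractions must be non-negative")
    if depth <= 0:
        raise ValidationError("sequencing depth must be positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("composition must sum to 1")
    return rng.multinomial(depth, p / p.sum())


def generate_study(
    cfg: CommunitySimConfig,
) -> tuple[OtuCountTable, list[SampleRecord], StudyTruth]:
    """Generate a full synthetic study: 3 pretreatments x replicates x
    {day 0, day 7}, with paired metadata and ground truth.

    RNG streams are split per microcosm from the config seed, so adding
    replicates never perturbs earlier draws.
    """
    truth = draw_seedbank(
        cfg, np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    )

    # one stream per (pretreatment, replicate) cell, keyed by position so
    # adding replicates or reordering loops never perturbs earlier draws
    design = [
        (pre, f"R{r + 1}", np.random.SeedSequence(cfg.seed, spawn_key=(1 + p_i, r)))
        for p_i, pre in enumerate(Pretreatment)
        for r in range(cfg.replicates)
    ]

    columns: dict[str, np.ndarray] = {}
    meta: list[SampleRecord] = []
    for pre, rep, ss in design:
        rng = np.random.default_rng(ss)
        mc = apply_pretreatment(truth, cfg, pre, rep, rng)
        mc = incubate(truth, mc)
        truth.microcosms[mc.microcosm_id] = mc
        for day, comp in ((0, mc.day0_composition), (7, mc.day7_composition)):
            sid = SampleRecord.make_id(pre, rep, day)
            columns[sid] = sequence_sample(comp, cfg.library_size, rng)
            meta.append(SampleRecord(sid, pre, rep, day))

    counts = pd.DataFrame(columns, index=truth.otu_ids, dtype=np.int64)
    return OtuCountTable(counts), meta, truth


def recovery_summary(calls, truth: StudyTruth, abundance_floor: float = 0.005) -> dict:
    """Score a calling run against ground truth.

    Eligibility is per (OTU, microcosm): a thermospore that survived that
    microcosm's pretreatment and whose expected day-7 fraction exceeds the
    abundance floor there should qualify in that same microcosm. Any
    background OTU called a thermospore is a false positive.
    """
    by_id = {c.otu_id: c for c in calls}
    ts_ids = truth.thermospore_ids
    ts_idx = {o: j for j, o in enumerate(ts_ids)}
    idx_of = {o: i for i, o in enumerate(truth.otu_ids)}

    n_eligible = 0
    n_recovered = 0
    for mc in truth.microcosms.values():
        for otu in ts_ids:
            j = ts_idx[otu]
            if not mc.survived[j]:
                continue
            if mc.day7_composition[idx_of[otu]] <= abundance_floor:
                continue
            n_eligible += 1
            call = by_id.get(otu)
            if call and call.per_microcosm[mc.microcosm_id].qualifies:
                n_recovered += 1

    false_positives = [
        c.otu_id
        for c in calls
        if c.is_thermospore and not truth.is_thermospore[idx_of[c.otu_id]]
    ]
    return {
        "n_eligible": n_eligible,
        "n_recovered": n_recovered,
        "recovery_rate": (n_recovered / n_eligible) if n_eligible else float("nan"),
        "false_positive_background": false_positives,
    }
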