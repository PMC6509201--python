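"""Thermospore OTU detection from paired day-0 / day-7 amplicon libraries.

An OTU is called a *thermospore* — a germinating thermophilic endospore —
when, in at least one microcosm's before/after pair of libraries, it

1. exceeds an abundance floor (default 0.5% relative abundance) in the
   day-7 library,
2. increases at least ``fold_change_min``-fold (default 10x) relative to
   the same microcosm's day-0 library, and
3. the count change is significant under a two-sided Fisher exact test
   with Bonferroni correction across all OTUs of that pair (default
   family-wise alpha 0.001).

All three criteria are evaluated conjunctively within the same microcosm
pair: a fold change only makes sense against its own baseline. For OTUs
absent at day 0 the fold-change denominator defaults to half a read at
the day-0 sequencing depth, the smallest sub-detection mass, so the
expected signal (OTUs germinating from below the detection limit) is not
lost to division by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import (
    OtuCountTable,
    Pretreatment,
    RelAbundanceTable,
    SampleRecord,
    ValidationError,
)
from .tables_io import validate_pairing

__all__ = [
    "CallingThresholds",
    "MicrocosmTest",
    "ThermosporeCall",
    "VennPartition",
    "relative_abundance",
    "fisher_exact_two_sided",
    "bonferroni",
    "fold_change",
    "call_thermospores",
    "detection_by_group",
    "venn_partition",
    "summarize_counts",
    "detection_sets_from_abundance",
    "summarize_abundance_table",
]

#: relative tolerance for "as extreme as observed" ties in the Fisher test
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class CallingThresholds:
    """Detection criteria; defaults follow the study's stated cutoffs."""

    abundance_floor: float = 0.005  # day-7 fraction must exceed this
    fold_change_min: float = 10.0
    alpha: float = 0.001  # on Bonferroni-adjusted p
    detection_floor: float = 0.0005  # per-microcosm "detected" for summaries
    day0_pseudoreads: float = 0.5  # fold-change denominator when day-0 count is 0

    def __post_init__(self) -> None:
        if min(self.abundance_floor, self.fold_change_min, self.alpha,
               self.detection_floor, self.day0_pseudoreads) <= 0:
            raise ValidationError("all thresholds must be positive")
        if self.abundance_floor < self.detection_floor:
            raise ValidationError("abundance_floor must be >= detection_floor")


@dataclass
class MicrocosmTest:
    """Per-OTU result within one microcosm's day-0/day-7 pair."""

    day0_fraction: float
    day7_fraction: float
    fold_change: float
    p_raw: float
    p_adjusted: float
    passes_abundance: bool
    passes_fold: bool
    passes_significance: bool

    @property
    def qualifies(self) -> bool:
        return self.passes_abundance and self.passes_fold and self.passes_significance


@dataclass
class ThermosporeCall:
    """Calling result for one OTU across all microcosms."""

    otu_id: str
    per_microcosm: dict[str, MicrocosmTest]
    is_thermospore: bool
    detected_in: set[str] = field(default_factory=set)  # microcosm ids

    def detected_pretreatments(self) -> set[Pretreatment]:
        return {Pretreatment[mc.split("_")[0]] for mc in self.detected_in}


def relative_abundance(table: OtuCountTable) -> RelAbundanceTable:
    """Counts divided by their column's library size."""
    sizes = table.library_sizes()
    if (sizes <= 0).any():
        bad = sizes.index[int(np.argmax(sizes.to_numpy() <= 0))]
        raise ValidationError(f"sample {bad!r} has zero library size")
    return RelAbundanceTable(table.counts / sizes)


# -- Fisher exact test -------------------------------------------------------

_LOGFACT = np.zeros(1)


def _log_factorials(n: int) -> np.ndarray:
    """Cached cumulative log-factorial table up to n."""
    global _LOGFACT
    if len(_LOGFACT) <= n:
        m = max(n + 1, 2 * len(_LOGFACT))
        tab = np.zeros(m)
        tab[1:] = np.cumsum(np.log(np.arange(1, m)))
        _LOGFACT = tab
    return _LOGFACT


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of every table sharing the observed
    margins whose probability does not exceed the observed table's (within
    a relative tie tolerance of 1e-7). Returns a value in (0, 1].
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("table cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lf = _log_factorials(n)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # log hypergeometric pmf over the support
    logpmf = (
        lf[row1] + lf[n - row1] + lf[col1] + lf[n - col1] - lf[n]
        - lf[support] - lf[row1 - support] - lf[col1 - support]
        - lf[n - row1 - col1 + support]
    )
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + math.log1p(FISHER_TIE_RTOL)
    if keep.all():
        return 1.0  # the whole support is as extreme as observed
    # sum in linear space, stabilized by the max kept term
    shift = logpmf[keep].max()
    p = float(np.exp(shift) * np.exp(logpmf[keep] - shift).sum())
    return min(p, 1.0)


def bonferroni(p_values: Sequence[float], m: int) -> np.ndarray:
    """Adjusted p-values min(1, p*m) for a family of m tests."""
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if len(p) > m:
        raise ValidationError(f"family size {m} smaller than {len(p)} tests")
    return np.minimum(1.0, p * m)


def fold_change(
    day0_fraction: float,
    day7_fraction: float,
    day0_library_size: int,
    pseudoreads: float = 0.5,
) -> float:
    """day-7 / day-0 abundance ratio with a sub-detection denominator policy.

    When the OTU is absent at day 0 the denominator is ``pseudoreads``
    reads at the day-0 depth; when absent at both timepoints the fold
    change is defined as 0 (no enrichment signal).
    """
    if not (0 <= day0_fraction <= 1 and 0 <= day7_fraction <= 1):
        raise ValidationError("fractions must lie in [0, 1]")
    if day0_fraction > 0:
        return day7_fraction / day0_fraction
    if day7_fraction == 0:
        return 0.0
    return day7_fraction / (pseudoreads / day0_library_size)


def call_thermospores(
    table: OtuCountTable,
    meta: Sequence[SampleRecord],
    thresholds: CallingThresholds = CallingThresholds(),
) -> list[ThermosporeCall]:
    """Apply the three-criteria screen to every OTU in every microcosm pair.

    The Bonferroni family is the number of OTUs in the table, applied per
    microcosm pair. ``detected_in`` lists the microcosms whose day-7
    abundance reaches ``detection_floor`` (thermospore OTUs only).
    """
    pairs = validate_pairing(meta)
    if not pairs:
        raise ValidationError("no day-0/day-7 microcosm pairs in metadata")
    known = set(table.sample_ids)
    counts = table.counts
    n_otus = table.n_otus
    otu_ids = table.otu_ids

    per_otu: dict[str, dict[str, MicrocosmTest]] = {o: {} for o in otu_ids}
    for microcosm, (rec0, rec7) in sorted(pairs.items()):
        for rec in (rec0, rec7):
            if rec.sample_id not in known:
                raise ValidationError(
                    f"metadata sample {rec.sample_id!r} not in the count table"
                )
        c0 = counts[rec0.sample_id].to_numpy()
        c7 = counts[rec7.sample_id].to_numpy()
        lib0, lib7 = int(c0.sum()), int(c7.sum())
        f0 = c0 / lib0
        f7 = c7 / lib7
        praw = np.ones(n_otus)
        for i in range(n_otus):
            praw[i] = fisher_exact_two_sided(
                int(c0[i]), lib0 - int(c0[i]), int(c7[i]), lib7 - int(c7[i])
            )
        padj = bonferroni(praw, n_otus)
        for i, otu in enumerate(otu_ids):
            fc = fold_change(
                float(f0[i]), float(f7[i]), lib0, thresholds.day0_pseudoreads
            )
            per_otu[otu][microcosm] = MicrocosmTest(
                day0_fraction=float(f0[i]),
                day7_fraction=float(f7[i]),
                fold_change=fc,
                p_raw=float(praw[i]),
                p_adjusted=float(padj[i]),
                passes_abundance=bool(f7[i] > thresholds.abundance_floor),
                passes_fold=bool(fc >= thresholds.fold_change_min),
                passes_significance=bool(padj[i] < thresholds.alpha),
            )

    calls = []
    for otu in otu_ids:
        tests = per_otu[otu]
        is_ts = any(t.qualifies for t in tests.values())
        detected = (
            {mc for mc, t in tests.items() if t.day7_fraction >= thresholds.detection_floor}
            if is_ts
            else set()
        )
        calls.append(ThermosporeCall(otu, tests, is_ts, detected))
    return calls


def detection_by_group(calls: Iterable[ThermosporeCall]) -> dict[Pretreatment, set[str]]:
    """OTUs detected in >=1 replicate of each pretreatment group."""
    groups: dict[Pretreatment, set[str]] = {p: set() for p in Pretreatment}
    for call in calls:
        for pre in call.detected_pretreatments():
            groups[pre].add(call.otu_id)
    return groups


@dataclass
class VennPartition:
    """Counts of the seven exclusive regions of three sets."""

    group_names: tuple[str, str, str]
    regions: dict[frozenset, int]
    total: int

    def only(self, name) -> int:
        return self.regions[frozenset([self._key(name)])]

    def exactly(self, *names) -> int:
        return self.regions[frozenset(self._key(n) for n in names)]

    @property
    def all_three(self) -> int:
        return self.regions[frozenset(self.group_names)]

    def exclusive_to(self, *names) -> int:
        """OTUs present in >=1 of ``names`` and in none of the others."""
        keys = {self._key(n) for n in names}
        return sum(
            count
            for region, count in self.regions.items()
            if region and region <= keys
        )

    def _key(self, name):
        key = name.name if isinstance(name, Pretreatment) else str(name)
        if key not in self.group_names:
            raise KeyError(name)
        return key


def venn_partition(groups: Mapping) -> VennPartition:
    """Partition three labeled sets into their seven exclusive regions."""
    if len(groups) != 3:
        raise ValidationError(f"expected exactly 3 groups, got {len(groups)}")
    named = {
        (k.name if isinstance(k, Pretreatment) else str(k)): set(v)
        for k, v in groups.items()
    }
    names = tuple(named)
    universe = set().union(*named.values())
    regions: dict[frozenset, int] = {}
    for mask in range(1, 8):
        members = frozenset(n for j, n in enumerate(names) if mask >> j & 1)
        inside = set(universe)
        for n in names:
            if n in members:
                inside &= named[n]
            else:
                inside -= named[n]
        regions[members] = len(inside)
    return VennPartition(names, regions, len(universe))


def summarize_counts(
    calls: Iterable[ThermosporeCall], meta: Sequence[SampleRecord]
) -> "pd.DataFrame":
    """Per-microcosm thermospore OTU count and total day-7 abundance."""
    import pandas as pd

    pairs = validate_pairing(meta)
    rows = []
    for microcosm in sorted(pairs):
        n = 0
        total = 0.0
        for call in calls:
            if not call.is_thermospore or microcosm not in call.detected_in:
                continue
            n += 1
            total += call.per_microcosm[microcosm].day7_fraction
        pre, rep = microcosm.split("_")
        rows.append(
            {
                "microcosm": microcosm,
                "pretreatment": pre,
                "replicate": rep,
                "n_thermospore_otus": n,
                "total_thermospore_fraction": total,
            }
        )
    return pd.DataFrame(rows).set_index("microcosm")


# -- fixture-style summaries (abundance table only, no counts) ---------------

def detection_sets_from_abundance(
    rel: RelAbundanceTable, detection_floor: float = 0.0
) -> dict[Pretreatment, set[str]]:
    """Detection sets when only a per-OTU abundance table is available.

    With ``detection_floor=0`` detection means "non-zero cell", the right
    reading for a printed table whose blanks encode non-detection.
    """
    groups: dict[Pretreatment, set[str]] = {p: set() for p in Pretreatment}
    for sample in rel.sample_ids:
        pre = Pretreatment[sample.split("_")[0]]
        col = rel.fractions[sample]
        for otu, val in col.items():
            if val > detection_floor:
                groups[pre].add(str(otu))
    return groups


def summarize_abundance_table(
    rel: RelAbundanceTable, detection_floor: float = 0.0
) -> "pd.DataFrame":
    """Per-microcosm OTU count and summed abundance from an abundance table."""
    import pandas as pd

    rows = []
    for sample in rel.sample_ids:
        col = rel.fractions[sample]
        present = col[col > detection_floor]
        rows.append(
            {
                "microcosm": sample,
                "n_thermospore_otus": int(len(present)),
                "total_thermospore_fraction": float(present.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("microcosm")
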