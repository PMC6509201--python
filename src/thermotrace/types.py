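"""Core domain types shared across the pipeline.

The central object is the :class:`OtuCountTable` — integer read counts per
OTU (rows) per sample (columns) — together with :class:`SampleRecord`
metadata describing the microcosm design: three freezing pretreatments
(+4 °C unfrozen control, −20 °C, −80 °C), triplicate microcosms, sampled
before (day 0) and after (day 7) incubation at +50 °C.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pretreatment",
    "REPLICATES",
    "SampleRecord",
    "OtuCountTable",
    "RelAbundanceTable",
    "GeochemSeries",
    "DETECTION_LIMITS_MM",
    "TableFormatError",
    "ValidationError",
    "PairingError",
    "ConfigError",
]


class TableFormatError(ValueError):
    """A tabular input violates its file-format contract."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


class PairingError(ValidationError):
    """A day-7 sample has no matching day-0 sample (or vice versa)."""


class ConfigError(ValueError):
    """A simulation or run configuration is internally inconsistent."""


class Pretreatment(enum.Enum):
    """Ten-day temperature exposure applied before pasteurization."""

    PLUS4 = "+4C"
    MINUS20 = "-20C"
    MINUS80 = "-80C"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, token: str) -> "Pretreatment":
        t = str(token).strip().upper().replace("°", "").replace(" ", "")
        t = t.replace("−", "-")  # unicode minus
        aliases = {
            "PLUS4": cls.PLUS4, "+4": cls.PLUS4, "+4C": cls.PLUS4, "4C": cls.PLUS4,
            "MINUS20": cls.MINUS20, "-20": cls.MINUS20, "-20C": cls.MINUS20,
            "MINUS80": cls.MINUS80, "-80": cls.MINUS80, "-80C": cls.MINUS80,
        }
        if t in aliases:
            return aliases[t]
        raise ValidationError(f"unknown pretreatment token: {token!r}")


REPLICATES = ("R1", "R2", "R3")


@dataclass(frozen=True)
class SampleRecord:
    """Identity of one amplicon library: which microcosm, which day."""

    sample_id: str
    pretreatment: Pretreatment
    replicate: str
    timepoint_days: int

    def __post_init__(self) -> None:
        if self.timepoint_days not in (0, 7):
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint_days must be 0 or 7, "
                f"got {self.timepoint_days}"
            )
        if not str(self.replicate).startswith("R"):
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must look like 'R1', "
                f"got {self.replicate!r}"
            )

    @property
    def microcosm_id(self) -> str:
        return f"{self.pretreatment.name}_{self.replicate}"

    @staticmethod
    def make_id(pretreatment: Pretreatment, replicate: str, timepoint_days: int) -> str:
        return f"{pretreatment.name}_{replicate}_d{timepoint_days}"


def _check_axis(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableFormatError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class OtuCountTable:
    """Integer read counts, OTUs as rows, samples as columns."""

    counts: pd.DataFrame  # int dtype, index=otu_ids, columns=sample_ids

    def __post_init__(self) -> None:
        df = self.counts
        _check_axis(df.index, "OTU")
        _check_axis(df.columns, "sample")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            as_float = np.asarray(values, dtype=float)
            rounded = np.rint(as_float)
            if not np.array_equal(as_float, rounded):
                raise ValidationError("counts must be whole numbers")
            df = df.astype(np.int64)
        if values.size and (df.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        sizes = df.sum(axis=0)
        empty = sizes[sizes <= 0]
        if len(empty):
            raise ValidationError(f"sample {empty.index[0]!r} has zero library size")
        self.counts = df

    @property
    def otu_ids(self) -> list[str]:
        return list(map(str, self.counts.index))

    @property
    def sample_ids(self) -> list[str]:
        return list(map(str, self.counts.columns))

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class RelAbundanceTable:
    """Fractions per OTU per sample; columns of a full table sum to 1.

    ``partial=True`` marks a table holding only a subset of the community
    (e.g. only the thermospore OTUs, as printed in the study's per-OTU
    abundance table), whose columns legitimately sum to less than 1.
    """

    fractions: pd.DataFrame
    partial: bool = False

    def __post_init__(self) -> None:
        df = self.fractions.astype(float)
        _check_axis(df.index, "OTU")
        _check_axis(df.columns, "sample")
        vals = df.to_numpy()
        if vals.size and ((vals < 0).any() or (vals > 1).any()):
            raise ValidationError("relative abundances must lie in [0, 1]")
        if not self.partial and vals.size:
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = df.columns[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValidationError(
                    f"sample {bad!r} fractions sum to {sums.max():.6g}, expected 1"
                )
        self.fractions = df

    @property
    def otu_ids(self) -> list[str]:
        return list(map(str, self.fractions.index))

    @property
    def sample_ids(self) -> list[str]:
        return list(map(str, self.fractions.columns))


#: analyte → detection limit in mM (sulfate 100 uM; organic acids 2.5 uM)
DETECTION_LIMITS_MM = {
    "sulfate": 0.1,
    "formate": 0.0025,
    "acetate": 0.0025,
    "lactate": 0.0025,
    "propionate": 0.0025,
    "butyrate": 0.0025,
    "succinate": 0.0025,
    "ethanol": 0.0025,
}


@dataclass
class GeochemSeries:
    """One analyte's concentration time series in one microcosm."""

    microcosm_id: str
    analyte: str
    times: np.ndarray  # days
    concentrations: np.ndarray  # mM
    below_detection: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValidationError("times and concentrations must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if (self.concentrations < 0).any():
            raise ValidationError("concentrations must be non-negative")
        limit = DETECTION_LIMITS_MM.get(self.analyte)
        flags = self.below_detection
        if flags is None:
            if limit is None:
                flags = np.zeros_like(self.concentrations, dtype=bool)
            else:
                flags = self.concentrations < limit
        self.below_detection = np.asarray(flags, dtype=bool)
        if limit is not None and not np.array_equal(
            self.below_detection, self.concentrations < limit
        ):
            raise ValidationError(
                f"below_detection flags inconsistent with the {self.analyte} "
                f"detection limit of {limit} mM"
            )
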