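"""Readers and writers for the pipeline's tabular artifacts.

All files are plain UTF-8 text: tab-separated OTU count / metadata /
taxonomy tables, comma-separated geochemistry time series, and JSON run
summaries. The per-OTU thermospore abundance table printed in the source
study is embedded as a package fixture (22 thermospore OTUs x 9
microcosms, day-7 relative abundances in percent; blank cells are encoded
as exact 0).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    DETECTION_LIMITS_MM,
    GeochemSeries,
    OtuCountTable,
    PairingError,
    Pretreatment,
    RelAbundanceTable,
    SampleRecord,
    TableFormatError,
    ValidationError,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "read_geochem",
    "write_geochem",
    "load_reported_abundance_fixture",
    "load_reported_taxonomy",
    "FIXTURE_MICROCOSMS",
    "write_results",
]

#: (pretreatment, replicate) column order of the embedded fixture
FIXTURE_MICROCOSMS = tuple(
    f"{p.name}_{r}"
    for p in (Pretreatment.PLUS4, Pretreatment.MINUS20, Pretreatment.MINUS80)
    for r in ("R1", "R2", "R3")
)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file") from exc
    return df


def read_otu_table(
    path: str | Path, orientation: str = "otus_as_rows"
) -> OtuCountTable:
    """Read a tab-separated count table.

    ``orientation`` selects the dialect: ``"otus_as_rows"`` (one leading
    column of OTU IDs, one header row of sample IDs) or
    ``"samples_as_rows"`` for the transposed layout.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        kind = "OTU" if orientation == "otus_as_rows" else "sample"
        raise TableFormatError(f"{path}: duplicate {kind} ID: {dup[0]!r}")
    if orientation == "samples_as_rows":
        df = df.T
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise TableFormatError(f"{path}: duplicate OTU ID: {dup[0]!r}")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: non-numeric count cell ({exc})") from exc
    vals = numeric.to_numpy(dtype=float)
    if not np.array_equal(vals, np.rint(vals)):
        raise ValidationError(f"{path}: counts must be whole numbers")
    if (vals < 0).any():
        raise ValidationError(f"{path}: counts must be non-negative")
    return OtuCountTable(numeric.astype(np.int64))


def write_otu_table(table: OtuCountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="otu_id")


_META_COLUMNS = ("sample_id", "pretreatment", "replicate", "timepoint_days")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata and enforce the day-0/day-7 pairing invariant."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns {missing}")
    records = [
        SampleRecord(
            sample_id=str(row.sample_id),
            pretreatment=Pretreatment.parse(row.pretreatment),
            replicate=str(row.replicate),
            timepoint_days=int(row.timepoint_days),
        )
        for row in df.itertuples()
    ]
    validate_pairing(records)
    return records


def validate_pairing(records: Sequence[SampleRecord]) -> dict[str, tuple[SampleRecord, SampleRecord]]:
    """Check uniqueness and pairing; return microcosm_id -> (day0, day7)."""
    seen: dict[tuple, SampleRecord] = {}
    for r in records:
        key = (r.pretreatment, r.replicate, r.timepoint_days)
        if key in seen:
            raise ValidationError(
                f"duplicate design cell {key} (samples {seen[key].sample_id!r} "
                f"and {r.sample_id!r})"
            )
        seen[key] = r
    pairs: dict[str, tuple[SampleRecord, SampleRecord]] = {}
    for (pre, rep, day), r in seen.items():
        if day != 7:
            continue
        mate = seen.get((pre, rep, 0))
        if mate is None:
            raise PairingError(
                f"day-7 sample {r.sample_id!r} has no matching day-0 sample "
                f"for {pre.name} {rep}"
            )
        pairs[r.microcosm_id] = (mate, r)
    return pairs


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "pretreatment": r.pretreatment.name,
                "replicate": r.replicate,
                "timepoint_days": r.timepoint_days,
            }
            for r in records
        ],
        columns=list(_META_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> dict[str, list[str]]:
    """TSV of (otu_id, semicolon-delimited lineage) -> otu_id -> ranks."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected otu_id and lineage columns")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        otu = str(row.iloc[0])
        if otu in out:
            raise TableFormatError(f"{path}: duplicate OTU ID: {otu!r}")
        out[otu] = [t.strip() for t in str(row.iloc[1]).split(";") if t.strip()]
    return out


def read_geochem(path: str | Path) -> list[GeochemSeries]:
    """CSV of (microcosm_id, analyte, day, mM) -> per-analyte series."""
    df = pd.read_csv(path)
    need = {"microcosm_id", "analyte", "day", "mM"}
    if not need.issubset(df.columns):
        raise TableFormatError(f"{path}: expected columns {sorted(need)}")
    out = []
    for (mc, an), grp in df.groupby(["microcosm_id", "analyte"], sort=False):
        grp = grp.sort_values("day")
        out.append(
            GeochemSeries(
                microcosm_id=str(mc),
                analyte=str(an),
                times=grp["day"].to_numpy(dtype=float),
                concentrations=grp["mM"].to_numpy(dtype=float),
            )
        )
    return out


def write_geochem(series: Iterable[GeochemSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, c in zip(s.times, s.concentrations):
            rows.append(
                {"microcosm_id": s.microcosm_id, "analyte": s.analyte, "day": t, "mM": c}
            )
    pd.DataFrame(rows, columns=["microcosm_id", "analyte", "day", "mM"]).to_csv(
        path, index=False
    )


def _fixture_frame() -> pd.DataFrame:
    with resources.files("thermotrace.data").joinpath(
        "reported_thermospore_abundance.tsv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def load_reported_abundance_fixture() -> RelAbundanceTable:
    """Embedded per-OTU day-7 relative abundance table (as fractions).

    22 thermospore OTUs x 9 microcosms; values are the printed percentages
    divided by 100, blank cells encoded as exact 0. The table is *partial*:
    it lists only the thermospore OTUs, so columns do not sum to 1.
    """
    df = _fixture_frame()
    frac = df[list(FIXTURE_MICROCOSMS)].astype(float) / 100.0
    return RelAbundanceTable(frac, partial=True)


def load_reported_taxonomy() -> pd.DataFrame:
    """Class/order/family assignments of the 22 fixture thermospore OTUs."""
    return _fixture_frame()[["taxon_class", "taxon_order", "family"]]


def write_results(calls, summaries, out_dir: str | Path) -> dict[str, Path]:
    """Emit a per-OTU call TSV and a JSON run summary.

    ``calls`` is a list of ThermosporeCall; ``summaries`` is any
    JSON-serializable mapping (parameters, seeds, headline counts).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calls_path = out / "thermospore_calls.tsv"
    detail_path = out / "thermospore_calls_per_microcosm.tsv"
    summary_path = out / "run_summary.json"

    call_rows, detail_rows = [], []
    for call in calls:
        call_rows.append(
            {
                "otu_id": call.otu_id,
                "is_thermospore": call.is_thermospore,
                "n_qualifying_microcosms": sum(
                    t.qualifies for t in call.per_microcosm.values()
                ),
                "detected_in": ";".join(sorted(call.detected_in)),
            }
        )
        for mc, t in sorted(call.per_microcosm.items()):
            detail_rows.append(
                {
                    "otu_id": call.otu_id,
                    "microcosm": mc,
                    "day0_fraction": t.day0_fraction,
                    "day7_fraction": t.day7_fraction,
                    "fold_change": t.fold_change,
                    "p_raw": t.p_raw,
                    "p_adjusted": t.p_adjusted,
                    "passes_abundance": t.passes_abundance,
                    "passes_fold": t.passes_fold,
                    "passes_significance": t.passes_significance,
                    "qualifies": t.qualifies,
                }
            )
    pd.DataFrame(
        call_rows,
        columns=["otu_id", "is_thermospore", "n_qualifying_microcosms", "detected_in"],
    ).to_csv(calls_path, sep="\t", index=False)
    pd.DataFrame(
        detail_rows,
        columns=[
            "otu_id", "microcosm", "day0_fraction", "day7_fraction",
            "fold_change", "p_raw", "p_adjusted", "passes_abundance",
            "passes_fold", "passes_significance", "qualifies",
        ],
    ).to_csv(detail_path, sep="\t", index=False)

    def _default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, Pretreatment):
            return o.name
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summaries, fh, indent=2, default=_default)
        fh.write("\n")
    return {"calls": calls_path, "detail": detail_path, "summary": summary_path}
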