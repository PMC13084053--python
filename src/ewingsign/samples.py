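"""Core data types shared by all pipeline stages.

Coordinate convention: every genomic interval in this package is 0-based,
half-open (BED convention). A fragment's *midpoint* is ``floor((start+end)/2)``,
a deterministic integer rule used for window assignment throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = (
    "diagnosis",
    "first_line_treatment",
    "relapse",
    "treatment_after_relapse",
    "control",
)
CLINICAL_LABELS = ("EwS", "CIC", "NCC")
COHORTS = ("ncc1", "ncc2", "patient")

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "day",
    "clinical_label",
    "cohort",
    "ichor_tf",
)


class ConfigurationError(ValueError):
    """A required configuration element (e.g. sample-sheet column) is missing."""


class BedFormatError(ValueError):
    """A BED line violates the format contract (reported with line number)."""


@dataclass(frozen=True)
class FragmentRecord:
    """One cfDNA fragment interval; ``length == end - start``."""

    chrom: str
    start: int
    end: int
    mapq: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")
        if self.mapq < 0:
            raise ValueError(f"MAPQ must be non-negative: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class FragmentSet:
    """Columnar collection of fragment intervals (the fragmentomics substrate).

    Stores chrom / start / end / mapq as arrays; lengths and midpoints are
    derived. Iteration yields :class:`FragmentRecord` objects.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        mapq: Sequence[int] | None = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        if mapq is None:
            mapq = np.full(len(self.start), 60, dtype=np.int64)
        self.mapq = np.asarray(mapq, dtype=np.int64)
        n = len(self.start)
        if not (len(self.chrom) == len(self.end) == len(self.mapq) == n):
            raise ValueError("fragment columns must have equal length")
        if n and np.any(self.end <= self.start):
            raise ValueError("every fragment must satisfy end > start")

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self):
        for c, s, e, q in zip(self.chrom, self.start, self.end, self.mapq):
            yield FragmentRecord(str(c), int(s), int(e), int(q))

    def subset(self, mask_or_index) -> "FragmentSet":
        idx = np.asarray(mask_or_index)
        return FragmentSet(
            self.chrom[idx], self.start[idx], self.end[idx], self.mapq[idx]
        )

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord]) -> "FragmentSet":
        recs = list(records)
        return cls(
            [r.chrom for r in recs],
            [r.start for r in recs],
            [r.end for r in recs],
            [r.mapq for r in recs],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "mapq": self.mapq,
            }
        )


@dataclass
class RegionSet:
    """A named list of genomic intervals (binding sites, CpG track, ...)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(
                    f"invalid interval {chrom}:{start}-{end} in region set {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def for_chrom(self, chrom: str) -> np.ndarray:
        """(n, 2) array of start/end for one chromosome, sorted by start."""
        arr = np.array(
            [(s, e) for c, s, e in self.intervals if c == chrom], dtype=np.int64
        ).reshape(-1, 2)
        return arr[np.argsort(arr[:, 0])] if len(arr) else arr


class GenomicWindowGrid:
    """Non-overlapping fixed-size window tiling of a genome.

    The genome is tiled into ``window_size`` bp windows (300 bp by default, the
    resolution at which methylation enrichment counts are aggregated); the last
    window of each chromosome may be shorter.
    """

    def __init__(self, chrom_lengths: Mapping[str, int], window_size: int = 300):
        if window_size < 1:
            raise ValueError("window_size must be >= 1")
        for chrom, length in chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        self.chrom_lengths = dict(chrom_lengths)
        self.window_size = int(window_size)
        self._offsets: dict[str, int] = {}
        windows: list[tuple[str, int, int]] = []
        for chrom, length in self.chrom_lengths.items():
            self._offsets[chrom] = len(windows)
            for start in range(0, length, window_size):
                windows.append((chrom, start, min(start + window_size, length)))
        self.windows = windows

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def lookup(self, chrom: str, pos: int) -> int | None:
        """Window index containing position ``pos``, or None if off-grid."""
        length = self.chrom_lengths.get(chrom)
        if length is None or pos < 0 or pos >= length:
            return None
        return self._offsets[chrom] + pos // self.window_size

    def lookup_array(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorised lookup; -1 marks off-grid positions."""
        out = np.full(len(pos), -1, dtype=np.int64)
        for c in np.unique(chrom.astype(object)):
            length = self.chrom_lengths.get(str(c))
            if length is None:
                continue
            sel = chrom == c
            p = pos[sel]
            ok = (p >= 0) & (p < length)
            idx = np.where(ok, self._offsets[str(c)] + p // self.window_size, -1)
            out[sel] = idx
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["chrom", "start", "end"])


@dataclass
class SampleRecord:
    """One liquid-biopsy (or control) sample from the sample sheet."""

    sample_id: str
    patient_id: str
    timepoint: str
    day: int
    clinical_label: str
    cohort: str
    ichor_tf: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.clinical_label not in CLINICAL_LABELS:
            raise ValueError(f"unknown clinical label {self.clinical_label!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.timepoint == "control" and self.clinical_label != "NCC":
            raise ValueError("control samples must carry clinical label NCC")
        if self.ichor_tf is not None and not (0.0 <= self.ichor_tf <= 1.0):
            raise ValueError("ichor_tf must lie in [0, 1] when present")


def build_grid(chrom_lengths: Mapping[str, int], window_size: int = 300) -> GenomicWindowGrid:
    """Tile each chromosome into ``ceil(length / window_size)`` windows."""
    return GenomicWindowGrid(chrom_lengths, window_size)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Parse a TSV sample sheet into records.

    An unparseable or empty ``ichor_tf`` becomes a missing value (the modality
    is then "not evaluable" downstream — absent WGS must never silently count
    as a negative call).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(
                f"sample sheet {path} is missing required column {col!r}"
            )
    records = []
    for _, row in df.iterrows():
        raw_tf = row["ichor_tf"]
        try:
            tf = float(raw_tf)
            if not np.isfinite(tf):
                tf = None
        except (TypeError, ValueError):
            tf = None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                timepoint=str(row["timepoint"]),
                day=int(row["day"]),
                clinical_label=str(row["clinical_label"]),
                cohort=str(row["cohort"]),
                ichor_tf=tf,
            )
        )
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "timepoint": r.timepoint,
                "day": r.day,
                "clinical_label": r.clinical_label,
                "cohort": r.cohort,
                "ichor_tf": "" if r.ichor_tf is None else repr(r.ichor_tf),
            }
            for r in records
        ],
        columns=list(SAMPLE_SHEET_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a :class:`RegionSet` (extra columns ignored)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            intervals.append((chrom, start, end))
    return RegionSet(name=name or Path(path).stem, intervals=intervals)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
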