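"""Window-level methylation profiles from cfDNA fragments or tissue arrays.

A :class:`MethylationProfile` carries, per 300-bp genome window, the fragment
count, the normalised reads per million (NRPM) and a beta-value in [0, 1]
(methylation level). Beta-values are obtained by linearly anchoring NRPM to
the median signal of a calibration set of consistently hypermethylated
windows (beta = 1 there by construction), clipped to [0, 1] — a transparent
stand-in for enrichment-to-methylation calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .samples import FragmentSet, GenomicWindowGrid, RegionSet

MIN_MAPQ = 10
MIN_FRAGMENT_LENGTH = 70
MAX_FRAGMENT_LENGTH = 1000
MIN_REFERENCE_SPAN = 30  # non-binding given the 70 bp floor, kept explicit


class CalibrationError(ValueError):
    """Beta calibration failed (no signal in the calibration windows)."""


@dataclass
class MethylationProfile:
    sample_id: str
    grid: GenomicWindowGrid
    counts: np.ndarray
    nrpm: np.ndarray | None = None
    beta: np.ndarray | None = None
    total_valid_fragments: int = 0
    unassigned: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.grid.n_windows:
            raise ValueError("counts length must equal grid window count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class QCResult:
    """Library QC: CpG enrichment (relH) and hyperstable signal fraction."""

    relH: float
    hyperstable_fraction: float
    relh_threshold: float = 2.5
    hyperstable_threshold: float = 0.4
    pass_: bool = field(init=False)

    def __post_init__(self) -> None:
        self.pass_ = (
            self.relH > self.relh_threshold
            and self.hyperstable_fraction > self.hyperstable_threshold
        )


def filter_fragments(
    raw: FragmentSet,
    min_mapq: int = MIN_MAPQ,
    min_length: int = MIN_FRAGMENT_LENGTH,
    max_length: int = MAX_FRAGMENT_LENGTH,
    min_span: int = MIN_REFERENCE_SPAN,
) -> FragmentSet:
    """Retain fragments with MAPQ >= 10, length in [70, 1000] and span >= 30 bp.

    Order is preserved. The minimum reference span is read as a predicate on
    fragment extent; with the default 70 bp length floor it never bites.
    """
    length = raw.length
    keep = (
        (raw.mapq >= min_mapq)
        & (length >= min_length)
        & (length <= max_length)
        & (length >= min_span)
    )
    return raw.subset(keep)


def count_windows(
    fragments: FragmentSet, grid: GenomicWindowGrid, sample_id: str = "sample"
) -> MethylationProfile:
    """Assign each fragment to exactly one window by its midpoint.

    Fragments whose midpoint falls off the grid are tallied in
    ``profile.unassigned`` rather than silently dropped or erred on — grids and
    fragment files may legitimately mismatch at chromosome ends.
    """
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    if len(fragments):
        idx = grid.lookup_array(fragments.chrom, fragments.midpoint)
        assigned = idx[idx >= 0]
        np.add.at(counts, assigned, 1)
        unassigned = int(np.sum(idx < 0))
    else:
        unassigned = 0
    return MethylationProfile(
        sample_id=sample_id,
        grid=grid,
        counts=counts,
        total_valid_fragments=int(counts.sum()),
        unassigned=unassigned,
    )


def normalize_nrpm(
    profile: MethylationProfile, cn_correction: np.ndarray | None = None
) -> MethylationProfile:
    """NRPM_w = counts_w / (cn_w * total_valid_fragments) * 1e6 (no TMM)."""
    total = profile.total_valid_fragments
    if total <= 0:
        raise ValueError("cannot normalise a profile with zero valid fragments")
    cn = np.ones(len(profile.counts)) if cn_correction is None else np.asarray(
        cn_correction, dtype=float
    )
    profile.nrpm = profile.counts / (cn * total) * 1e6
    return profile


def _region_window_indices(grid: GenomicWindowGrid, regions: RegionSet) -> np.ndarray:
    """Indices of grid windows whose span overlaps any region interval."""
    hits: set[int] = set()
    for chrom, start, end in regions.intervals:
        length = grid.chrom_lengths.get(chrom)
        if length is None:
            continue
        first = max(0, start) // grid.window_size
        last = (min(end, length) - 1) // grid.window_size
        offset = grid._offsets[chrom]
        for w in range(first, last + 1):
            if w * grid.window_size < length:
                hits.add(offset + w)
    return np.array(sorted(hits), dtype=np.int64)


def compute_beta(
    profile: MethylationProfile, calibration_regions: RegionSet
) -> MethylationProfile:
    """Anchor beta = 1 at the median NRPM of the calibration windows."""
    if profile.nrpm is None:
        raise ValueError("compute NRPM before beta")
    if len(calibration_regions) == 0:
        raise ValueError("calibration region set is empty")
    idx = _region_window_indices(profile.grid, calibration_regions)
    if len(idx) == 0:
        raise CalibrationError("no grid windows overlap the calibration regions")
    ref = float(np.median(profile.nrpm[idx]))
    if ref == 0:
        raise CalibrationError("calibration failure: zero median calibration NRPM")
    profile.beta = np.clip(profile.nrpm / ref, 0.0, 1.0)
    return profile


def beta_from_counts(
    counts: np.ndarray, calibration_idx: np.ndarray
) -> np.ndarray:
    """Beta directly from a count vector given calibration window indices.

    Equivalent to ``normalize_nrpm`` + ``compute_beta`` (the total-fragment
    factor cancels in the ratio), used on mixture count matrices where building
    full profile objects would be wasteful. Accepts a matrix (samples x windows).
    """
    counts = np.asarray(counts, dtype=float)
    ref = np.median(counts[..., calibration_idx], axis=-1, keepdims=True)
    if np.any(ref == 0):
        raise CalibrationError("calibration failure: zero median calibration count")
    return np.clip(counts / ref, 0.0, 1.0)


def _covered_cpg_sites(fragments: FragmentSet, cpg_track: RegionSet) -> int:
    """Number of CpG sites lying inside at least one fragment."""
    n = 0
    for chrom in np.unique(fragments.chrom.astype(object)):
        sel = fragments.chrom == chrom
        starts = np.sort(fragments.start[sel])
        ends = np.sort(fragments.end[sel])
        cpgs = cpg_track.for_chrom(str(chrom))
        if len(cpgs) == 0:
            continue
        pos = cpgs[:, 0]
        # site covered iff (# fragment starts <= pos) > (# fragment ends <= pos)
        n_started = np.searchsorted(starts, pos, side="right")
        n_ended = np.searchsorted(ends, pos, side="right")
        n += int(np.sum(n_started > n_ended))
    return n


def qc_stats(
    fragments: FragmentSet,
    cpg_track: RegionSet,
    hyperstable: RegionSet,
    genome_cpg_density: float,
    relh_threshold: float = 2.5,
    hyperstable_threshold: float = 0.4,
) -> QCResult:
    """relH and hyperstable fraction of a methylation-capture library.

    relH = (CpG sites overlapped by fragments / total fragment bases) divided
    by the genome-wide CpG density per bp; >1 means the library covers CpGs at
    above-genomic rate. The hyperstable fraction is the share of fragment
    midpoints inside consistently hypermethylated regions.
    """
    if len(fragments) == 0:
        raise ValueError("QC requires a non-empty fragment set")
    covered = _covered_cpg_sites(fragments, cpg_track)
    total_bases = int(np.sum(fragments.length))
    relh = (covered / total_bases) / genome_cpg_density

    in_hyper = 0
    mids = fragments.midpoint
    for chrom in np.unique(fragments.chrom.astype(object)):
        sel = fragments.chrom == chrom
        regions = hyperstable.for_chrom(str(chrom))
        if len(regions) == 0:
            continue
        m = mids[sel]
        # regions sorted by start; midpoint in region iff the last region
        # starting at or before it also ends after it
        j = np.searchsorted(regions[:, 0], m, side="right") - 1
        ok = j >= 0
        ok[ok] = m[ok] < regions[j[ok], 1]
        in_hyper += int(np.sum(ok))
    frac = in_hyper / len(fragments)
    return QCResult(relh, frac, relh_threshold, hyperstable_threshold)


def array_to_profile(
    array_betas: np.ndarray,
    grid: GenomicWindowGrid,
    depth: int,
    seed: int | None = None,
    deterministic: bool = False,
    sample_id: str = "array",
) -> MethylationProfile:
    """Convert tissue-array beta-values into an enrichment-style count profile.

    Windows receive counts proportional to ``beta_w * depth / sum(beta)`` —
    the counts a methylation-enrichment library would have produced on the
    same material. Deterministic mode sets counts to their expectation
    (largest-remainder rounded); otherwise counts are multinomial-sampled.
    """
    betas = np.asarray(array_betas, dtype=float)
    if np.any((betas < 0) | (betas > 1)):
        raise ValueError("array betas must lie in [0, 1]")
    total = betas.sum()
    if total == 0:
        raise ValueError("cannot convert an all-zero beta profile")
    p = betas / total
    if deterministic:
        counts = _largest_remainder_round(p * depth, depth)
    else:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(depth, p)
    return MethylationProfile(
        sample_id=sample_id,
        grid=grid,
        counts=counts.astype(np.int64),
        total_valid_fragments=int(depth),
    )


def _largest_remainder_round(expected: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to ``total``."""
    floors = np.floor(expected).astype(np.int64)
    deficit = int(total - floors.sum())
    if deficit > 0:
        remainders = expected - floors
        top = np.argsort(-remainders, kind="stable")[:deficit]
        floors[top] += 1
    return floors
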