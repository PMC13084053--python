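"""cfDNA fragment-size and regional fragmentation statistics.

Three statistics, each with its own positivity threshold learned from
non-cancer controls:

* **p100-150** — the proportion of retained fragments with length in
  [100, 150] bp (inclusive); tumor-derived cfDNA is shorter than the
  ~166 bp mono-nucleosomal mode, so this rises with tumor fraction. The
  threshold is the maximum over the reference NCC cohort; positivity is
  strictly greater.
* **5-Mb short/long fragmentation profile** — per genomic 5 Mb bin, the
  log2 ratio of short (100-150 bp) to long (151-220 bp) fragment counts,
  centred on the genome-wide median bin ratio, plus the Pearson correlation
  to a median reference NCC profile.
* **dip area** — signed area of coverage depletion at a region set (e.g.
  transcription-factor binding sites), measured against a flank baseline on
  a center-aligned, binned mean coverage profile; more negative = stronger
  depletion. The threshold is the lower bound of a normal-theory 95%
  prediction interval over reference NCCs; positivity is strictly below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .samples import FragmentSet, RegionSet

SHORT_RANGE = (100, 150)
LONG_RANGE = (151, 220)


@dataclass
class SizeHistogram:
    counts: np.ndarray  # per integer length 70..1000
    total: int

    @classmethod
    def from_fragments(cls, fragments: FragmentSet) -> "SizeHistogram":
        lengths = fragments.length
        counts = np.bincount(np.clip(lengths, 70, 1000) - 70, minlength=931)
        return cls(counts, int(len(fragments)))


@dataclass
class FragmentationProfile:
    bins: pd.DataFrame  # chrom, start, end, short_count, long_count, score
    correlation_to_reference: float | None = None


@dataclass
class DipResult:
    dip_area: float
    region_set: str
    n_regions: int


@dataclass
class ModalityThresholds:
    """Per-modality positivity thresholds with provenance."""

    tau_p100150: float
    tau_dip: float
    tau_ichor: float = 0.03
    classifier_threshold: float = 0.5
    reference_ids: tuple[str, ...] = ()


def downsample(fragments: FragmentSet, n_target: int, seed: int = 0) -> FragmentSet:
    """Uniform sample without replacement of min(n_target, n) fragments."""
    if n_target < 1:
        raise ValueError("downsampling target must be >= 1")
    n = len(fragments)
    if n <= n_target:
        return fragments
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_target, replace=False))
    return fragments.subset(idx)


def p100_150(fragments: FragmentSet, low: int = 100, high: int = 150) -> float:
    """Proportion of fragments with length in [low, high], inclusive ends.

    The denominator is all retained (70-1000 bp filtered) fragments.
    """
    if len(fragments) == 0:
        raise ValueError("cannot compute p100-150 of an empty fragment set")
    lengths = fragments.length
    return float(np.mean((lengths >= low) & (lengths <= high)))


def max_ncc_threshold(values) -> float:
    """Positivity threshold = maximum statistic over the reference NCCs.

    A test value is positive iff strictly greater than this threshold.
    """
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        raise ValueError("threshold requires at least one reference value")
    return float(values.max())


def make_5mb_bins(chrom_lengths: dict[str, int], bin_bp: int = 5_000_000) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, bin_bp):
            rows.append({"chrom": chrom, "start": start, "end": min(start + bin_bp, length)})
    return pd.DataFrame(rows)


def fragmentation_profile(
    fragments: FragmentSet,
    bins: pd.DataFrame,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    reference: np.ndarray | None = None,
) -> FragmentationProfile:
    """Per-5Mb-bin centred log2 short/long ratio, by fragment midpoint.

    score_b = log2((short_b / long_b) / median_b(short/long)); a bin with no
    long fragments gets a missing score and is excluded from the correlation
    with the reference profile.
    """
    out = bins.copy().reset_index(drop=True)
    short = np.zeros(len(out), dtype=np.int64)
    long_ = np.zeros(len(out), dtype=np.int64)
    lengths = fragments.length
    mids = fragments.midpoint
    is_short = (lengths >= short_range[0]) & (lengths <= short_range[1])
    is_long = (lengths >= long_range[0]) & (lengths <= long_range[1])
    for chrom, sub in out.groupby("chrom"):
        sel = fragments.chrom == chrom
        if not sel.any():
            continue
        edges = np.append(sub["start"].to_numpy(), sub["end"].to_numpy()[-1])
        m = mids[sel]
        which = np.searchsorted(edges, m, side="right") - 1
        ok = (which >= 0) & (which < len(sub))
        # midpoint bin assignment, split by size class
        for mask, acc in ((is_short[sel], short), (is_long[sel], long_)):
            w = which[ok & mask]
            np.add.at(acc, sub.index.to_numpy()[w], 1)
    out["short_count"] = short
    out["long_count"] = long_
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(long_ > 0, short / np.maximum(long_, 1), np.nan)
    med = np.nanmedian(ratio) if np.isfinite(ratio).any() else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2(ratio / med)
    score[~np.isfinite(score)] = np.nan
    out["ratio"] = ratio
    out["score"] = score

    corr = None
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        ok = np.isfinite(ratio) & np.isfinite(reference)
        if ok.sum() >= 2 and np.std(ratio[ok]) > 0 and np.std(reference[ok]) > 0:
            corr = float(np.corrcoef(ratio[ok], reference[ok])[0, 1])
    return FragmentationProfile(out, corr)


def median_reference_profile(profiles: list[FragmentationProfile]) -> np.ndarray:
    """Per-bin median of short/long ratios across reference NCC profiles."""
    if not profiles:
        raise ValueError("need at least one reference profile")
    n = len(profiles[0].bins)
    mats = []
    for p in profiles:
        if len(p.bins) != n:
            raise ValueError("reference profiles have mismatched bins")
        mats.append(p.bins["ratio"].to_numpy())
    return np.nanmedian(np.vstack(mats), axis=0)


def aggregate_region_coverage(
    fragments: FragmentSet,
    region_set: RegionSet,
    extension_bp: int = 5000,
    bin_bp: int = 500,
) -> np.ndarray:
    """Mean per-bin fragment coverage across regions aligned at centers."""
    if len(region_set) == 0:
        raise ValueError("region set must be non-empty")
    n_bins = (2 * extension_bp) // bin_bp
    cov = np.zeros(n_bins)
    used = 0
    for chrom, start, end in region_set.intervals:
        center = (start + end) // 2
        sel = fragments.chrom == chrom
        if not sel.any():
            continue
        fs = fragments.start[sel]
        fe = fragments.end[sel]
        lo = center - extension_bp
        edges = lo + np.arange(n_bins + 1) * bin_bp
        # coverage of bin = total overlapped bases of fragments / bin width
        for b in range(n_bins):
            ov = np.minimum(fe, edges[b + 1]) - np.maximum(fs, edges[b])
            cov[b] += float(np.clip(ov, 0, None).sum()) / bin_bp
        used += 1
    if used == 0:
        raise ValueError("no region overlaps the fragment data")
    return cov / used


def dip_area(
    coverage_or_fragments,
    region_set: RegionSet | None = None,
    extension_bp: int = 5000,
    bin_bp: int = 500,
    flank_fraction: float = 0.2,
    region_name: str | None = None,
) -> DipResult:
    """Signed area between a center-aligned coverage profile and its flank
    baseline; negative when the centre is depleted.

    Accepts either a pre-binned aligned coverage array (one value per
    ``bin_bp`` bin over +-``extension_bp``) or a FragmentSet plus region set,
    in which case the aligned profile is built first. The baseline is the
    mean of the outer ``flank_fraction`` of bins on each side; the dip area
    sums (coverage - baseline) * bin_bp over the non-flank bins.
    """
    if isinstance(coverage_or_fragments, FragmentSet):
        if region_set is None:
            raise ValueError("region set required when passing fragments")
        coverage = aggregate_region_coverage(
            coverage_or_fragments, region_set, extension_bp, bin_bp
        )
    else:
        coverage = np.asarray(coverage_or_fragments, dtype=float)
    n_bins = len(coverage)
    if n_bins < 4:
        raise ValueError("coverage profile too short")
    # flank_fraction of all bins, split evenly across the two sides
    n_flank = max(1, int(round(flank_fraction * n_bins)) // 2)
    baseline = float(np.mean(np.concatenate([coverage[:n_flank], coverage[-n_flank:]])))
    core = coverage[n_flank : n_bins - n_flank]
    area = float(np.sum(core - baseline) * bin_bp)
    n_regions = len(region_set) if region_set is not None else 0
    return DipResult(area, region_name or (region_set.name if region_set else "coverage"), n_regions)


def prediction_interval_threshold(reference_values, level: float = 0.95) -> float:
    """Lower bound of a normal-theory prediction interval over references.

    bound = mean - t_{(1+level)/2, n-1} * sd * sqrt(1 + 1/n); a tested sample
    is positive iff its dip area is strictly below the bound.
    """
    values = np.asarray(list(reference_values), dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("prediction interval requires at least 2 reference values")
    mean = values.mean()
    sd = values.std(ddof=1)
    t = stats.t.ppf((1 + level) / 2, df=n - 1)
    return float(mean - t * sd * np.sqrt(1 + 1 / n))
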