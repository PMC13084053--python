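"""Synthetic cfDNA cohort generator with known ground truth.

Emulates the inputs of a liquid-biopsy sarcoma study: class-structured
window-level methylation beta profiles for EwS and CIC tumor tissue and
non-cancer-control (NCC) cfDNA with planted differentially methylated
windows; cfDNA fragment-length collections whose short-fragment content
scales with tumor fraction; coverage tracks with central dips at a region
set scaling with tumor fraction; and longitudinal patient trajectories
(diagnosis -> treatment -> relapse) with per-timepoint tumor fractions.

Methylation structure
---------------------
Three disjoint sets of windows are planted on top of a hypomethylated
background:

* ``ews_signature``  — EwS hyper (~0.85), NCC low, CIC hypomethylated below NCC;
* ``cic_signature``  — CIC hyper, NCC low, EwS hypomethylated below NCC;
* ``shared_tumor``   — hyper in both tumor classes (same level), NCC low.

Signature windows differ in all three pairwise class comparisons and are the
windows a three-way-intersection DMR filter is designed to find; shared-tumor
windows differ in only two comparisons and act as a built-in negative control
for that filter. A further ``calibration`` set is near-fully methylated in
every class (the anchor for beta calibration and the hyperstable QC track).

Fragment lengths are a two-component truncated-normal mixture (tumor mode
shorter than the mono-nucleosomal control mode); the 100-150 bp fraction of
the tumor component is what every fragmentomic statistic keys on. The real
10.4-bp nucleosome ladder periodicity is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .samples import FragmentSet, GenomicWindowGrid, RegionSet, SampleRecord

COMPARISONS = ("EwS_vs_NCC", "CIC_vs_NCC", "EwS_vs_CIC")

@dataclass
class CohortLayout:
    """Study-design sample counts (the defaults mirror a real study layout:
    37 EwS / 10 CIC tissue arrays, an 83-sample NCC training cohort, a
    24-sample higher-depth NCC test cohort, and 26 longitudinally sampled
    patients)."""

    n_ews_arrays: int = 37
    n_cic_arrays: int = 10
    n_ncc_cohort1: int = 83
    n_ncc_cohort2: int = 24
    n_ews_patients: int = 23
    n_cic_patients: int = 3
    relapse_fraction: float = 0.4


@dataclass
class SimulationConfig:
    seed: int = 0
    n_windows: int = 2000
    window_size: int = 300
    n_dmr_per_pair: int = 100
    n_calibration_windows: int = 50
    beta_background_params: tuple[float, float] = (0.6, 6.0)
    beta_hyper_params: tuple[float, float] = (8.0, 1.5)
    beta_calibration_params: tuple[float, float] = (40.0, 2.0)
    beta_sample_concentration: float = 50.0
    planted_ncc_mu_cap: float = 0.2  # keeps NCC median beta at planted DMRs <= 0.25
    mid_offset: float = 0.1  # intermediate level above the window's background
    depth: int = 20_000
    control_size_mode: int = 166
    tumor_size_mode: int = 145
    size_sd: float = 15.0
    fragment_chrom: str = "chrS"
    fragment_chrom_length: int = 100_000_000
    fragments_per_sample: int = 20_000
    dip_depth: float = 0.6
    dip_sigma_bp: float = 1000.0
    coverage_noise_sd: float = 0.01
    coverage_extension_bp: int = 5000
    coverage_bin_bp: int = 500
    ichor_noise_sd: float = 0.01
    diagnosis_f_range: tuple[float, float] = (0.05, 0.3)
    treatment_f_range: tuple[float, float] = (0.0, 0.01)
    relapse_f_range: tuple[float, float] = (0.05, 0.3)
    tar_f_range: tuple[float, float] = (0.0, 0.05)
    cohort_layout: CohortLayout = field(default_factory=CohortLayout)

    def __post_init__(self) -> None:
        if self.n_windows < 1 or self.n_dmr_per_pair < 0:
            raise ValueError("counts must be positive")
        if 3 * self.n_dmr_per_pair + self.n_calibration_windows > self.n_windows:
            raise ValueError(
                "3 * n_dmr_per_pair + n_calibration_windows must not exceed n_windows"
            )
        for mode in (self.control_size_mode, self.tumor_size_mode):
            if not (70 <= mode <= 1000):
                raise ValueError("size modes must lie within 70-1000 bp")
        if not (0.0 <= self.dip_depth <= 1.0):
            raise ValueError("dip_depth must lie in [0, 1]")

    def grid(self) -> GenomicWindowGrid:
        return GenomicWindowGrid(
            {"chrS": self.n_windows * self.window_size}, self.window_size
        )


@dataclass
class GroundTruth:
    """What the generator planted: per-sample tumor fractions and classes,
    and the planted DMR window indices per pairwise comparison."""

    true_f: dict[str, float]
    true_class: dict[str, str]
    dmr_windows: dict[str, np.ndarray]
    signature_windows: dict[str, np.ndarray]
    calibration_windows: np.ndarray


@dataclass
class MethylationCohort:
    grid: GenomicWindowGrid
    ews_tissue: pd.DataFrame
    cic_tissue: pd.DataFrame
    ncc_cohort1: pd.DataFrame
    ncc_cohort2: pd.DataFrame
    truth: GroundTruth

    def calibration_regions(self) -> RegionSet:
        w = self.grid.window_size
        return RegionSet(
            "calibration",
            [("chrS", int(i) * w, (int(i) + 1) * w) for i in self.truth.calibration_windows],
        )


def _class_levels(config: SimulationConfig, rng: np.random.Generator):
    """Assign planted window sets and per-window base methylation levels mu.

    Windows have a stable identity: a base level mu_w is drawn once per
    cohort and shared across classes wherever the classes do not differ.
    Planted windows keep their NCC mu below ``planted_ncc_mu_cap``, so the
    NCC median beta there stays under the downstream DMR filter's 0.25 cap by
    construction. At a signature window the signature class is hypermethylated
    and the OTHER tumor class is hypomethylated by ``mid_offset`` relative to
    NCC (tumor DMRs run in both directions); this makes the window
    significant in all three pairwise comparisons while keeping every class's
    evidence directionally consistent at any tumor fraction. The two tumor
    classes share one hyper draw at shared-tumor windows (genuinely
    indistinguishable there).
    """
    n = config.n_windows
    k = config.n_dmr_per_pair
    n_cal = config.n_calibration_windows
    special = rng.choice(n, size=3 * k + n_cal, replace=False)
    ews_sig = np.sort(special[:k])
    cic_sig = np.sort(special[k : 2 * k])
    shared = np.sort(special[2 * k : 3 * k])
    calibration = np.sort(special[3 * k :])

    a_bg, b_bg = config.beta_background_params
    base_mu = rng.beta(a_bg, b_bg, size=n)
    a_cal, b_cal = config.beta_calibration_params
    base_mu[calibration] = rng.beta(a_cal, b_cal, size=n_cal)
    if len(shared):
        # inverse-CDF draw from the background beta truncated at the cap
        u = rng.random(len(shared)) * stats.beta.cdf(config.planted_ncc_mu_cap, a_bg, b_bg)
        base_mu[shared] = stats.beta.ppf(u, a_bg, b_bg)
    # signature windows: NCC sits low but with head-room for the other tumor
    # class to be hypomethylated below it
    for sig in (ews_sig, cic_sig):
        if len(sig):
            base_mu[sig] = rng.uniform(
                config.mid_offset + 0.02, config.planted_ncc_mu_cap, size=len(sig)
            )

    a_hy, b_hy = config.beta_hyper_params
    mu = {cls: base_mu.copy() for cls in ("EwS", "CIC", "NCC")}
    mu["EwS"][ews_sig] = rng.beta(a_hy, b_hy, size=k)
    mu["CIC"][ews_sig] = base_mu[ews_sig] - config.mid_offset
    mu["CIC"][cic_sig] = rng.beta(a_hy, b_hy, size=k)
    mu["EwS"][cic_sig] = base_mu[cic_sig] - config.mid_offset
    shared_hyper = rng.beta(a_hy, b_hy, size=k)
    mu["EwS"][shared] = shared_hyper
    mu["CIC"][shared] = shared_hyper
    for cls in mu:
        mu[cls] = np.clip(mu[cls], 0.01, 0.99)

    dmr_windows = {
        "EwS_vs_NCC": np.sort(np.concatenate([ews_sig, cic_sig, shared])),
        "CIC_vs_NCC": np.sort(np.concatenate([ews_sig, cic_sig, shared])),
        "EwS_vs_CIC": np.sort(np.concatenate([ews_sig, cic_sig])),
    }
    signature = {"EwS": ews_sig, "CIC": cic_sig, "shared_tumor": shared}
    return mu, dmr_windows, signature, calibration


def _draw_betas(
    mu: np.ndarray, n_samples: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample betas scattered around the window base levels mu."""
    kappa = config.beta_sample_concentration
    return rng.beta(mu * kappa, (1.0 - mu) * kappa, size=(n_samples, len(mu)))


def simulate_methylation_cohort(
    config: SimulationConfig, seed: int | None = None
) -> MethylationCohort:
    """Tissue-array and NCC cfDNA beta profiles with planted DMR structure."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = config.cohort_layout
    mu, dmr_windows, signature, calibration = _class_levels(config, rng)

    def frame(cls: str, n: int, prefix: str) -> pd.DataFrame:
        betas = _draw_betas(mu[cls], n, config, rng)
        ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
        return pd.DataFrame(betas, index=ids)

    ews = frame("EwS", layout.n_ews_arrays, "ews_array_")
    cic = frame("CIC", layout.n_cic_arrays, "cic_array_")
    ncc1 = frame("NCC", layout.n_ncc_cohort1, "ncc1_")
    ncc2 = frame("NCC", layout.n_ncc_cohort2, "ncc2_")

    true_f = {s: 0.0 for s in [*ncc1.index, *ncc2.index]}
    true_f.update({s: 1.0 for s in [*ews.index, *cic.index]})
    true_class = {s: "NCC" for s in [*ncc1.index, *ncc2.index]}
    true_class.update({s: "EwS" for s in ews.index})
    true_class.update({s: "CIC" for s in cic.index})

    truth = GroundTruth(true_f, true_class, dmr_windows, signature, calibration)
    return MethylationCohort(config.grid(), ews, cic, ncc1, ncc2, truth)


def simulate_fragments(
    f: float, n: int, config: SimulationConfig, seed: int
) -> FragmentSet:
    """cfDNA fragments at tumor fraction ``f``.

    Each fragment's length is drawn from the tumor size distribution with
    probability ``f``, else from the control distribution; both are normals
    truncated to [70, 1000] bp. Positions are uniform on a synthetic
    chromosome.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("tumor fraction must lie in [0, 1]")
    if n <= 0:
        raise ValueError("fragment count must be positive")
    rng = np.random.default_rng(seed)
    is_tumor = rng.random(n) < f
    modes = np.where(is_tumor, config.tumor_size_mode, config.control_size_mode)
    lo = (70 - modes) / config.size_sd
    hi = (1000 - modes) / config.size_sd
    u = rng.random(n)
    lengths = stats.truncnorm.ppf(u, lo, hi, loc=modes, scale=config.size_sd)
    lengths = np.clip(np.rint(lengths), 70, 1000).astype(np.int64)
    starts = rng.integers(0, config.fragment_chrom_length - 1001, size=n)
    return FragmentSet(
        np.full(n, config.fragment_chrom, dtype=object),
        starts,
        starts + lengths,
    )


def simulate_coverage(
    region_set: RegionSet, f: float, config: SimulationConfig, seed: int
) -> np.ndarray:
    """Mean coverage profile aligned at region centers, binned over +-extension.

    Flanks sit at baseline 1.0; central bins are depleted by ``f * dip_depth``
    following a Gaussian bump of width ``dip_sigma_bp``. Noise shrinks with
    the number of averaged regions.
    """
    if len(region_set) == 0:
        raise ValueError("region set must be non-empty")
    if not (0.0 <= f <= 1.0):
        raise ValueError("tumor fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ext, width = config.coverage_extension_bp, config.coverage_bin_bp
    centers = np.arange(-ext + width / 2, ext, width)
    bump = np.exp(-0.5 * (centers / config.dip_sigma_bp) ** 2)
    noise = rng.normal(
        0.0, config.coverage_noise_sd / np.sqrt(len(region_set)), size=len(centers)
    )
    return 1.0 - f * config.dip_depth * bump + noise


_TIMEPOINT_DAYS = {
    "diagnosis": 0,
    "first_line_treatment": 90,
    "relapse": 270,
    "treatment_after_relapse": 360,
}


@dataclass
class CohortStudy:
    """A full simulated study: training material plus longitudinal samples."""

    config: SimulationConfig
    methylation: MethylationCohort
    records: list[SampleRecord]
    ground_truth: pd.DataFrame  # sample_id, true_f, true_class
    sample_betas: pd.DataFrame  # cfDNA beta profiles for patients + controls
    fragments: dict[str, FragmentSet]
    coverage: dict[str, np.ndarray]
    regions: RegionSet


def _f_range_draw(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def simulate_cohort_study(
    config: SimulationConfig,
    seed: int | None = None,
    region_set: RegionSet | None = None,
) -> CohortStudy:
    """Generate every input the multimodal pipeline needs, with ground truth.

    Patients follow diagnosis -> first-line treatment (-> relapse -> treatment
    after relapse) trajectories: tumor fraction high at diagnosis, near zero on
    treatment, high again at relapse. Controls have f = 0. Per sample the
    study emits a cfDNA beta profile (tumor/background blend at fraction f),
    a fragment set, an aligned coverage profile, and a noisy ichorTF value.
    """
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    layout = config.cohort_layout
    cohort = simulate_methylation_cohort(config, seed=base_seed)
    if region_set is None:
        region_set = RegionSet(
            "binding_sites",
            [
                ("chrS", int(s), int(s) + 2000)
                for s in np.linspace(
                    1_000_000, config.fragment_chrom_length - 1_000_000, 200
                )
            ],
        )

    mu, _, _, _ = _class_levels(
        config, np.random.default_rng(base_seed)
    )  # same planted structure and base levels as `cohort` (same seed stream order)

    records: list[SampleRecord] = []
    rows = []
    betas: dict[str, np.ndarray] = {}
    fragments: dict[str, FragmentSet] = {}
    coverage: dict[str, np.ndarray] = {}

    f_ranges = {
        "diagnosis": config.diagnosis_f_range,
        "first_line_treatment": config.treatment_f_range,
        "relapse": config.relapse_f_range,
        "treatment_after_relapse": config.tar_f_range,
    }

    def emit(sample_id, patient_id, timepoint, day, label, cohort_name, f, cls):
        tumor_beta = _draw_betas(mu[cls], 1, config, rng)[0] if cls != "NCC" else None
        ncc_beta = _draw_betas(mu["NCC"], 1, config, rng)[0]
        beta = ncc_beta if tumor_beta is None else f * tumor_beta + (1 - f) * ncc_beta
        betas[sample_id] = beta
        frag_seed = int(rng.integers(0, 2**31 - 1))
        fragments[sample_id] = simulate_fragments(
            f, config.fragments_per_sample, config, frag_seed
        )
        cov_seed = int(rng.integers(0, 2**31 - 1))
        coverage[sample_id] = simulate_coverage(region_set, f, config, cov_seed)
        ichor = max(0.0, f + rng.normal(0.0, config.ichor_noise_sd))
        records.append(
            SampleRecord(sample_id, patient_id, timepoint, day, label, cohort_name, ichor)
        )
        rows.append({"sample_id": sample_id, "true_f": f, "true_class": cls})

    pat_idx = 0
    for label, n_pat in (("EwS", layout.n_ews_patients), ("CIC", layout.n_cic_patients)):
        for _ in range(n_pat):
            pat_idx += 1
            pid = f"patient_{pat_idx:02d}"
            relapses = rng.random() < layout.relapse_fraction
            timepoints = ["diagnosis", "first_line_treatment"]
            if relapses:
                timepoints += ["relapse", "treatment_after_relapse"]
            for tp in timepoints:
                f = _f_range_draw(rng, f_ranges[tp])
                sid = f"{pid}_{tp}"
                emit(sid, pid, tp, _TIMEPOINT_DAYS[tp], label, "patient", f, label)

    for i in range(layout.n_ncc_cohort2):
        sid = f"control_{i + 1:03d}"
        emit(sid, sid, "control", 0, "NCC", "ncc2", 0.0, "NCC")

    ground_truth = pd.DataFrame(rows).set_index("sample_id")
    sample_betas = pd.DataFrame.from_dict(betas, orient="index")
    return CohortStudy(
        config=config,
        methylation=cohort,
        records=records,
        ground_truth=ground_truth,
        sample_betas=sample_betas,
        fragments=fragments,
        coverage=coverage,
        regions=region_set,
    )
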