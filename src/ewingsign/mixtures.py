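"""In-silico mixture samples: training augmentation and evaluation dilutions.

A mixture blends a tumor count profile into a control count profile at a
known tumor fraction f. Mixing operates on depth-normalised count
proportions (p_w = f * t_w + (1 - f) * c_w) and rescales to a common depth,
so f is interpretable as the tumor fraction of the resulting sample.
Expectation mode rounds the expected counts with a largest-remainder rule
(every mixture sums exactly to the configured depth); thinning mode samples
a multinomial for robustness testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MixtureSample:
    counts: np.ndarray
    tumor_source_id: str
    control_source_id: str
    f: float
    purpose: str  # train | evaluation
    label: str  # EwS | CIC | NCC


@dataclass
class MixtureSetSpec:
    """Training-mixture counts and tumor-fraction ranges.

    Defaults are the augmentation scheme of the study this package models:
    7400 EwS+NCC and 2200 CIC+NCC mixtures at tumor fractions uniform in
    0.005-0.1, and 10,000 NCC+NCC mixtures at proportions 0.15-0.5; the
    evaluation dilution series uses 26 fixed proportions spanning 0.001-0.05.
    """

    n_ews_mixtures: int = 7400
    n_cic_mixtures: int = 2200
    n_ncc_mixtures: int = 10_000
    train_f_range: tuple[float, float] = (0.005, 0.1)
    ncc_pair_f_range: tuple[float, float] = (0.15, 0.5)
    eval_proportions: np.ndarray = field(
        default_factory=lambda: np.linspace(0.001, 0.05, 26)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.eval_proportions = np.asarray(self.eval_proportions, dtype=float)
        for lo, hi in (self.train_f_range, self.ncc_pair_f_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("f ranges must lie within [0, 1]")
        if np.any(np.diff(self.eval_proportions) <= 0):
            raise ValueError("eval_proportions must be strictly increasing")
        if np.any((self.eval_proportions <= 0) | (self.eval_proportions >= 1)):
            raise ValueError("eval_proportions must lie in (0, 1)")


def _largest_remainder_rows(expected: np.ndarray, depth: int) -> np.ndarray:
    """Row-wise integer rounding preserving the exact row sum ``depth``."""
    floors = np.floor(expected).astype(np.int64)
    deficit = depth - floors.sum(axis=1)
    rem = expected - floors
    order = np.argsort(-rem, axis=1, kind="stable")
    take = np.arange(expected.shape[1])[None, :] < deficit[:, None]
    bump = np.zeros_like(floors)
    np.put_along_axis(bump, order, take.astype(np.int64), axis=1)
    return floors + bump


def mix_counts(
    tumor: np.ndarray,
    control: np.ndarray,
    f: float | np.ndarray,
    depth: int,
    mode: str = "expectation",
    seed: int | None = None,
) -> np.ndarray:
    """Mix tumor/control count vectors (or row-matched matrices) at fraction f."""
    t = np.atleast_2d(np.asarray(tumor, dtype=float))
    c = np.atleast_2d(np.asarray(control, dtype=float))
    if t.shape[1] != c.shape[1]:
        raise ValueError("profiles must share the same window grid")
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))[:, None]
    if np.any((f_arr < 0) | (f_arr > 1)):
        raise ValueError("f must lie in [0, 1]")
    t_norm = t / t.sum(axis=1, keepdims=True)
    c_norm = c / c.sum(axis=1, keepdims=True)
    p = f_arr * t_norm + (1.0 - f_arr) * c_norm
    if mode == "expectation":
        counts = _largest_remainder_rows(p * depth, depth)
    elif mode == "thinning":
        rng = np.random.default_rng(seed)
        counts = np.vstack([rng.multinomial(depth, row / row.sum()) for row in p])
    else:
        raise ValueError(f"unknown mixing mode {mode!r}")
    out = counts if np.asarray(tumor).ndim > 1 or np.asarray(f).ndim > 0 else counts[0]
    return out


def mix_profiles(tumor_counts, control_counts, f, depth, mode="expectation", seed=None):
    """Single-pair convenience wrapper around :func:`mix_counts`."""
    return mix_counts(tumor_counts, control_counts, float(f), depth, mode, seed)


def build_training_mixtures(
    tissue_arrays: dict[str, dict[str, np.ndarray]],
    ncc_train: dict[str, np.ndarray],
    spec: MixtureSetSpec,
    depth: int,
    mode: str = "expectation",
) -> list[MixtureSample]:
    """Augmented training set: tumor+NCC and NCC+NCC mixtures.

    ``tissue_arrays`` maps class label ("EwS"/"CIC") to {source_id: counts}.
    Source pairing is uniform at random; per-category f ranges follow the
    spec. Fully reproducible under ``spec.seed``.
    """
    if len(ncc_train) < 2:
        raise ValueError("NCC+NCC mixing requires at least 2 NCC training samples")
    rng = np.random.default_rng(spec.seed)
    mixtures: list[MixtureSample] = []
    ncc_ids = list(ncc_train)
    ncc_mat = np.vstack([ncc_train[i] for i in ncc_ids])

    category_plan = [
        ("EwS", spec.n_ews_mixtures, spec.train_f_range),
        ("CIC", spec.n_cic_mixtures, spec.train_f_range),
    ]
    for label, n_mix, f_range in category_plan:
        arrays = tissue_arrays.get(label, {})
        if n_mix and not arrays:
            raise ValueError(f"no tissue arrays available for class {label}")
        if n_mix == 0:
            continue
        arr_ids = list(arrays)
        arr_mat = np.vstack([arrays[i] for i in arr_ids])
        ti = rng.integers(0, len(arr_ids), size=n_mix)
        ci = rng.integers(0, len(ncc_ids), size=n_mix)
        fs = rng.uniform(*f_range, size=n_mix)
        counts = mix_counts(arr_mat[ti], ncc_mat[ci], fs, depth, mode, seed=int(rng.integers(2**31)))
        for k in range(n_mix):
            mixtures.append(
                MixtureSample(counts[k], arr_ids[ti[k]], ncc_ids[ci[k]], float(fs[k]), "train", label)
            )

    n_ncc = spec.n_ncc_mixtures
    if n_ncc:
        ai = rng.integers(0, len(ncc_ids), size=n_ncc)
        bi = rng.integers(0, len(ncc_ids) - 1, size=n_ncc)
        bi = np.where(bi >= ai, bi + 1, bi)  # distinct partner
        fs = rng.uniform(*spec.ncc_pair_f_range, size=n_ncc)
        counts = mix_counts(ncc_mat[ai], ncc_mat[bi], fs, depth, mode, seed=int(rng.integers(2**31)))
        for k in range(n_ncc):
            mixtures.append(
                MixtureSample(counts[k], ncc_ids[ai[k]], ncc_ids[bi[k]], float(fs[k]), "train", "NCC")
            )
    return mixtures


def build_evaluation_mixtures(
    tumor_samples: dict[str, np.ndarray],
    controls: dict[str, np.ndarray],
    proportions: np.ndarray,
    depth: int,
    label: str = "EwS",
) -> list[MixtureSample]:
    """Systematic dilution series: full tumor x control x proportion grid.

    Deterministic (expectation mode); |tumors| * |controls| * |proportions|
    samples.
    """
    proportions = np.asarray(proportions, dtype=float)
    if not len(tumor_samples) or not len(controls):
        raise ValueError("tumor and control sets must be non-empty")
    if np.any((proportions <= 0) | (proportions >= 1)):
        raise ValueError("evaluation proportions must lie in (0, 1)")
    out: list[MixtureSample] = []
    for t_id, t_counts in tumor_samples.items():
        for c_id, c_counts in controls.items():
            counts = mix_counts(
                np.tile(t_counts, (len(proportions), 1)),
                np.tile(c_counts, (len(proportions), 1)),
                proportions,
                depth,
                mode="expectation",
            )
            for k, f in enumerate(proportions):
                out.append(MixtureSample(counts[k], t_id, c_id, float(f), "evaluation", label))
    return out
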