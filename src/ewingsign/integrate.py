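"""Multimodal positivity calls, detection metrics, ROC and longitudinal tables.

Four modalities are integrated per sample: the copy-number tumor-fraction
estimate (ichorTF, positive at >= 0.03), the short-fragment proportion
p100-150 (positive strictly above the reference-NCC maximum), the coverage
dip area at binding sites (positive strictly below the NCC prediction-
interval lower bound), and the EwingSign cancer score (positive above 0.5).
A modality with a missing value is "not evaluable" and never counts as a
negative call. Combination uses the union rule over evaluable modalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .fragmentomics import ModalityThresholds

MODALITIES = ("ichor_tf", "p100_150", "dip_area", "classifier")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ModalityCalls:
    sample_id: str
    values: dict[str, float | None]
    calls: dict[str, bool]  # present only where evaluable
    thresholds: ModalityThresholds

    def evaluable(self, modality: str) -> bool:
        return modality in self.calls

    def n_positive(self, modalities=MODALITIES) -> int:
        return sum(bool(self.calls.get(m)) for m in modalities)


@dataclass
class DetectionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    def summary(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "sensitivity": round_half_up(self.sensitivity, ndigits),
            "specificity": round_half_up(self.specificity, ndigits),
            "accuracy": round_half_up(self.accuracy, ndigits),
        }


def call_modalities(
    sample_id: str,
    values: dict[str, float | None],
    thresholds: ModalityThresholds,
) -> ModalityCalls:
    """Boolean positivity per modality; missing values are not evaluable.

    Rules: ichorTF positive iff value >= tau_ichor (values below the 0.03
    limit of detection are negative); p100-150 positive iff strictly above
    tau_p100150; dip positive iff strictly below tau_dip; classifier positive
    iff cancer score strictly above the classification threshold.
    """
    calls: dict[str, bool] = {}
    v = values.get("ichor_tf")
    if v is not None and not (isinstance(v, float) and np.isnan(v)):
        calls["ichor_tf"] = v >= thresholds.tau_ichor
    v = values.get("p100_150")
    if v is not None and not (isinstance(v, float) and np.isnan(v)):
        calls["p100_150"] = v > thresholds.tau_p100150
    v = values.get("dip_area")
    if v is not None and not (isinstance(v, float) and np.isnan(v)):
        calls["dip_area"] = v < thresholds.tau_dip
    v = values.get("classifier")
    if v is not None and not (isinstance(v, float) and np.isnan(v)):
        calls["classifier"] = v > thresholds.classifier_threshold
    return ModalityCalls(sample_id, dict(values), calls, thresholds)


def combine(calls: ModalityCalls, modalities=MODALITIES, rule: str = "union"):
    """Union combination over the evaluable subset.

    Returns (combined_call, n_positive); combined_call is None when no
    selected modality is evaluable.
    """
    if rule != "union":
        raise ValueError(f"unknown combination rule {rule!r}")
    evaluable = [m for m in modalities if calls.evaluable(m)]
    if not evaluable:
        return None, 0
    n_pos = sum(calls.calls[m] for m in evaluable)
    return n_pos > 0, n_pos


def detection_metrics(sample_calls: dict[str, bool], labels: dict[str, bool]) -> DetectionMetrics:
    """Confusion counts of per-sample boolean calls against cancer labels.

    ``labels[sample] = True`` marks a cancer sample. Unclassified or negative
    calls count as negative.
    """
    ids = list(labels)
    if not any(labels[s] for s in ids) or not any(not labels[s] for s in ids):
        raise ValueError("both a cancer and a control class are required")
    tp = sum(1 for s in ids if labels[s] and sample_calls.get(s, False))
    fn = sum(1 for s in ids if labels[s] and not sample_calls.get(s, False))
    fp = sum(1 for s in ids if not labels[s] and sample_calls.get(s, False))
    tn = sum(1 for s in ids if not labels[s] and not sample_calls.get(s, False))
    return DetectionMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC as the rank statistic P(cancer score > control score), ties 0.5.

    Also returns the ROC curve points (false/true positive rates at every
    threshold) for plotting.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    # collapse ties: keep the last point of each distinct threshold
    distinct = np.append(np.diff(scores[order]) != 0, True)
    curve = pd.DataFrame(
        {
            "threshold": scores[order][distinct],
            "tpr": tps[distinct] / n_pos,
            "fpr": fps[distinct] / n_neg,
        }
    )
    curve = pd.concat(
        [pd.DataFrame({"threshold": [np.inf], "tpr": [0.0], "fpr": [0.0]}), curve],
        ignore_index=True,
    )
    return float(auc), curve


def longitudinal_table(records, calls: dict[str, ModalityCalls]) -> pd.DataFrame:
    """Per-patient timeline ordered by day with modality counts and calls."""
    rows = []
    seen = set()
    for r in records:
        key = (r.patient_id, r.day, r.sample_id)
        if key in seen:
            raise ValueError(f"duplicate sample entry {key}")
        seen.add(key)
        c = calls[r.sample_id]
        combined, n_pos = combine(c)
        rows.append(
            {
                "patient_id": r.patient_id,
                "sample_id": r.sample_id,
                "day": r.day,
                "timepoint": r.timepoint,
                "n_positive_modalities": n_pos,
                "combined_call": combined,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def lead_time(timeline: pd.DataFrame, clinical_relapse_day: int) -> int | None:
    """Days from the latest positive pre-relapse sample to clinical relapse.

    Conservative rule: uses the *latest* sample before ``clinical_relapse_day``
    with at least one positive modality; None when no such sample exists.
    """
    pre = timeline[
        (timeline["day"] < clinical_relapse_day)
        & (timeline["n_positive_modalities"] >= 1)
    ]
    if pre.empty:
        return None
    return int(clinical_relapse_day - pre["day"].max())
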