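"""End-to-end synthetic-cohort run: simulate -> train -> predict -> fragmentome
-> integrate.

The orchestration mirrors a real study: the classifier is trained on tissue
arrays plus the NCC training cohort; the p100-150 positivity threshold is the
maximum over the NCC training cohort; the dip-area threshold is the lower
95% prediction-interval bound over the higher-depth NCC test cohort; all
four modality calls are then integrated per longitudinal sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import EwingSignConfig, EwingSignModel, scaled_down_config
from .fragmentomics import (
    ModalityThresholds,
    dip_area,
    downsample,
    max_ncc_threshold,
    p100_150,
    prediction_interval_threshold,
)
from .integrate import (
    MODALITIES,
    call_modalities,
    combine,
    detection_metrics,
    lead_time,
    longitudinal_table,
    roc_auc,
)
from .mixtures import MixtureSetSpec
from .simulate import CohortStudy, SimulationConfig, simulate_cohort_study, simulate_fragments

CANCER_TIMEPOINTS = ("diagnosis", "relapse")


@dataclass
class PipelineResult:
    study: CohortStudy
    model: EwingSignModel
    scores: pd.DataFrame
    thresholds: ModalityThresholds
    calls: pd.DataFrame
    timeline: pd.DataFrame
    lead_times: dict[str, int | None]
    metrics: dict[str, float]
    roc_curve: pd.DataFrame = field(default_factory=pd.DataFrame)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_full_pipeline(
    sim_config: SimulationConfig | None = None,
    classifier_config: EwingSignConfig | None = None,
    mixture_spec: MixtureSetSpec | None = None,
    seed: int = 0,
    downsample_target: int | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic cohort and integrate the calls."""
    rng = np.random.default_rng(seed)
    sim_config = sim_config or SimulationConfig(seed=seed)
    if classifier_config is None or mixture_spec is None:
        scaled_cfg, scaled_spec = scaled_down_config()
        classifier_config = classifier_config or scaled_cfg
        mixture_spec = mixture_spec or scaled_spec

    study = simulate_cohort_study(sim_config, seed=_sub_seed(rng))

    # --- classifier ---------------------------------------------------------
    model = EwingSignModel.from_cohort(
        study.methylation, classifier_config, mixture_spec, seed=_sub_seed(rng)
    )
    scores = model.predict(study.sample_betas)

    # --- fragmentome thresholds from reference NCCs -------------------------
    ncc1_p100 = []
    for _ in study.methylation.ncc_cohort1.index:
        frags = simulate_fragments(
            0.0, sim_config.fragments_per_sample, sim_config, _sub_seed(rng)
        )
        ncc1_p100.append(p100_150(frags))
    tau_p100 = max_ncc_threshold(ncc1_p100)

    control_ids = [r.sample_id for r in study.records if r.timepoint == "control"]
    control_dips = [
        dip_area(
            study.coverage[s],
            bin_bp=sim_config.coverage_bin_bp,
            region_name=study.regions.name,
        ).dip_area
        for s in control_ids
    ]
    tau_dip = prediction_interval_threshold(control_dips)
    thresholds = ModalityThresholds(
        tau_p100150=tau_p100,
        tau_dip=tau_dip,
        reference_ids=tuple(control_ids),
    )

    # --- per-sample modality values and calls -------------------------------
    rows = []
    calls_by_sample = {}
    for rec in study.records:
        frags = study.fragments[rec.sample_id]
        if downsample_target:
            frags = downsample(frags, downsample_target, seed=_sub_seed(rng))
        values = {
            "ichor_tf": rec.ichor_tf,
            "p100_150": p100_150(frags),
            "dip_area": dip_area(
                study.coverage[rec.sample_id],
                bin_bp=sim_config.coverage_bin_bp,
                region_name=study.regions.name,
            ).dip_area,
            "classifier": float(scores.loc[rec.sample_id, "cancer_score"]),
        }
        mc = call_modalities(rec.sample_id, values, thresholds)
        calls_by_sample[rec.sample_id] = mc
        union_call, n_pos = combine(mc)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "patient_id": rec.patient_id,
                "timepoint": rec.timepoint,
                "day": rec.day,
                "clinical_label": rec.clinical_label,
                **{f"value_{m}": values[m] for m in MODALITIES},
                **{f"call_{m}": mc.calls.get(m) for m in MODALITIES},
                "n_positive_modalities": n_pos,
                "union_call": union_call,
                "ewingsign_label": scores.loc[rec.sample_id, "label"],
            }
        )
    calls = pd.DataFrame(rows).set_index("sample_id")

    # --- detection metrics on diagnosis/relapse vs controls -----------------
    eval_ids = [
        r.sample_id
        for r in study.records
        if r.timepoint in CANCER_TIMEPOINTS or r.timepoint == "control"
    ]
    labels = {
        r.sample_id: r.timepoint in CANCER_TIMEPOINTS
        for r in study.records
        if r.sample_id in set(eval_ids)
    }
    metrics: dict[str, float] = {}
    for modality in MODALITIES:
        mod_calls = {
            s: bool(calls.loc[s, f"call_{modality}"])
            for s in eval_ids
            if calls.loc[s, f"call_{modality}"] is not None
        }
        dm = detection_metrics(mod_calls, {s: labels[s] for s in mod_calls})
        metrics[f"sensitivity_{modality}"] = dm.sensitivity
        metrics[f"specificity_{modality}"] = dm.specificity
        metrics[f"accuracy_{modality}"] = dm.accuracy
    union_calls = {s: bool(calls.loc[s, "union_call"]) for s in eval_ids}
    dm_union = detection_metrics(union_calls, labels)
    metrics["sensitivity_union"] = dm_union.sensitivity
    metrics["specificity_union"] = dm_union.specificity
    metrics["accuracy_union"] = dm_union.accuracy

    auc, curve = roc_auc(
        [float(scores.loc[s, "cancer_score"]) for s in eval_ids],
        [labels[s] for s in eval_ids],
    )
    metrics["auc_classifier"] = auc

    # --- longitudinal tables and lead times ---------------------------------
    patient_records = [r for r in study.records if r.cohort == "patient"]
    timeline = longitudinal_table(patient_records, calls_by_sample)
    lead_times: dict[str, int | None] = {}
    for pid, sub in timeline.groupby("patient_id"):
        relapse_rows = sub[sub["timepoint"] == "relapse"]
        if relapse_rows.empty:
            continue
        lead_times[pid] = lead_time(sub, int(relapse_rows["day"].min()))

    return PipelineResult(
        study=study,
        model=model,
        scores=scores,
        thresholds=thresholds,
        calls=calls,
        timeline=timeline,
        lead_times=lead_times,
        metrics=metrics,
        roc_curve=curve,
    )
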