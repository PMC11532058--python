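"""End-to-end driver: ECG simulation -> features -> classifier -> cutoff ->
cohort -> outcome statistics.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(global_seed).spawn``, in a fixed stage order,
so any stage can be reproduced in isolation.  Every artifact is stamped
with the configuration hash and seed; per-record failures are logged and
skipped rather than aborting the run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .classifier import (
    RegionalScores,
    dichotomize_patient,
    train_fqrs_classifier,
    youden_threshold,
)
from .cohort_sim import (
    CohortScenario,
    cohort_to_csv,
    endpoint_frame,
    simulate_cohort,
)
from .errors import FqrsError, NoAnchorError
from .features import FEATURE_NAMES, extract_feature_vector
from .outcome_stats import baseline_table, cox_multivariable_enter
from .qrs_segment import segment_record
from .synth_ecg import (
    LEAD_NAMES,
    AnnotatorModel,
    FragmentationSpec,
    NoiseParams,
    default_templates,
    generate_ecg12,
    simulate_annotators,
)

logger = logging.getLogger(__name__)

_STAGES = ("ecg", "annotation", "classifier", "cohort")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds below 2**31."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def make_training_dataset(
    n_clean_records: int,
    n_fragmented_records: int,
    severity_range: tuple[float, float] = (0.5, 1.0),
    noise: NoiseParams = NoiseParams(),
    annotators: AnnotatorModel = AnnotatorModel(),
    seed: int = 0,
    duration: float = 10.0,
    fs: float = 250.0,
) -> pd.DataFrame:
    """Simulated per-lead training table.

    Each record carries one severity (0 for clean records, uniform within
    ``severity_range`` otherwise) applied to all 12 leads; records are
    segmented and the ten features extracted per lead; the annotator panel
    supplies the 0-5 agreement score.  Returns one row per usable lead
    with columns: record_id, lead, severity, the ten features, score.
    """
    rng = np.random.default_rng(seed)
    templates = default_templates()
    rows = []
    n_total = n_clean_records + n_fragmented_records
    for rec_idx in range(n_total):
        fragmented = rec_idx >= n_clean_records
        severity = float(rng.uniform(*severity_range)) if fragmented else 0.0
        frag = {
            lead: FragmentationSpec.from_severity(
                severity, seed=int(rng.integers(2**31))
            )
            for lead in LEAD_NAMES
        }
        record = generate_ecg12(
            templates,
            frag=frag,
            noise=noise,
            duration=duration,
            fs=fs,
            seed=int(rng.integers(2**31)),
            record_id=f"rec{rec_idx:04d}",
        )
        try:
            segments = segment_record(record)
        except FqrsError as exc:
            logger.warning("record %s skipped: %s", record.record_id, exc)
            continue
        for lead in LEAD_NAMES:
            try:
                fv = extract_feature_vector(segments[lead])
            except NoAnchorError:
                logger.info("lead %s of %s skipped: no PRSA anchors",
                            lead, record.record_id)
                continue
            label = simulate_annotators(
                severity, annotators, seed=int(rng.integers(2**31))
            )
            row = {
                "record_id": record.record_id,
                "lead": lead,
                "severity": severity,
            }
            row.update(dict(zip(FEATURE_NAMES, fv.to_array())))
            row["score"] = label.score
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and write all artifacts; returns a result dict.

    Artifacts (under ``out_dir``): features.csv, model.json, probs.csv,
    cutoff.json, cohort.csv, baseline.csv, cox_<endpoint>.csv, run_log.jsonl.
    """
    config = fio.validate_config(config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = fio.config_hash(config)
    seeds = stage_seeds(int(config["seed"]))
    log_path = out / "run_log.jsonl"
    log_fh = log_path.open("w")

    def log(event: str, **kw) -> None:
        log_fh.write(json.dumps(
            {"t": time.time(), "event": event, "config_hash": chash,
             "seed": config["seed"], **kw}
        ) + "\n")

    log("start")
    results: dict = {"config_hash": chash, "out_dir": str(out)}

    # 1. training data
    ecg_cfg = config["ecg"]
    noise = NoiseParams(**ecg_cfg["noise"])
    table = make_training_dataset(
        ecg_cfg["n_clean_records"],
        ecg_cfg["n_fragmented_records"],
        tuple(ecg_cfg["severity_range"]),
        noise=noise,
        seed=seeds["ecg"],
        duration=ecg_cfg["duration"],
        fs=ecg_cfg["fs"],
    )
    table.insert(0, "config_hash", chash)
    table.to_csv(out / "features.csv", index=False)
    log("features", n_leads=len(table))

    # 2. classifier + Platt calibration
    X = table[list(FEATURE_NAMES)].to_numpy()
    scores = table["score"].to_numpy()
    model = train_fqrs_classifier(
        X, scores, config["classifier"], seed=seeds["classifier"]
    )
    (out / "model.json").write_text(
        model.to_json(metadata={"seed": seeds["classifier"], "n": len(X),
                                "label_policy": "agreement 0 vs 5",
                                "config_hash": chash})
    )

    # 3. per-lead probabilities and the operating cutoff
    table["probability"] = model.predict_proba(X)[:, 1]
    table.to_csv(out / "probs.csv", index=False)
    full = table[(scores == 0) | (scores == 5)]
    cutoff, j, sens, spec = youden_threshold(
        full["probability"].to_numpy(),
        (full["score"].to_numpy() == 5).astype(int),
        min_specificity=config["threshold"]["min_specificity"],
    )
    (out / "cutoff.json").write_text(json.dumps(
        {"cutoff": cutoff, "youden_j": j, "sensitivity": sens,
         "specificity": spec, "config_hash": chash}
    ))
    log("threshold", cutoff=cutoff, youden_j=j)
    results.update({"model": model, "cutoff": cutoff, "youden_j": j,
                    "sensitivity": sens, "specificity": spec,
                    "training_table": table})

    # 4. cohort simulation and dichotomization at the learned cutoff
    scenario = CohortScenario().with_fqrs_log_hr(
        death=config["cohort"]["fqrs_log_hr_death"],
        therapy=config["cohort"]["fqrs_log_hr_therapy"],
    )
    patients = simulate_cohort(config["cohort"]["n"], scenario,
                               seed=seeds["cohort"])
    cohort_to_csv(patients, out / "cohort.csv")
    frame = endpoint_frame(patients)
    eff_cut = min(max(cutoff, 1e-6), 1 - 1e-6)
    flags = []
    for p in patients:
        # regional means are simulated directly by the cohort generator
        scores_r = RegionalScores(
            anterior=p.regional_probs["anterior"],
            lateral=p.regional_probs["lateral"],
            inferior=p.regional_probs["inferior"],
        )
        flags.append(float(dichotomize_patient(scores_r, eff_cut).positive))
    frame["fqrs_status"] = flags
    log("cohort", n=len(patients),
        fqrs_positive=int(np.sum(flags)))

    # 5. statistics
    baseline = baseline_table(
        frame,
        group_col="fqrs_status",
        continuous=["age", "bmi", "lvef", "creatinine", "qtc"],
        categorical=["female", "ihd", "crtd", "dm", "af", "aht", "lbbb"],
    )
    pd.DataFrame([r.__dict__ for r in baseline]).to_csv(
        out / "baseline.csv", index=False
    )
    cox_tables = {}
    for endpoint in config["survival"]["endpoints"]:
        candidates = [
            c if c != "fqrs" else "fqrs_status"
            for c in config["survival"]["candidates"]
        ]
        try:
            res = cox_multivariable_enter(
                frame,
                duration_col=f"{endpoint}_time",
                event_col=f"{endpoint}_event",
                candidates=candidates,
                screen_alpha=config["survival"]["screen_alpha"],
                endpoint=endpoint,
                force_include=("fqrs_status",),
            )
        except FqrsError as exc:
            log("cox_skipped", endpoint=endpoint, reason=str(exc))
            continue
        df = pd.DataFrame([r.__dict__ for r in res])
        df.to_csv(out / f"cox_{endpoint}.csv", index=False)
        cox_tables[endpoint] = df
        log("cox", endpoint=endpoint, n_covariates=len(res))
    results["cohort_frame"] = frame
    results["cox_tables"] = cox_tables
    log("done")
    log_fh.close()
    return results
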