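"""Reading and writing ECG records and pipeline configuration.

Two interchange formats are supported: a wide CSV (column 1 = time in
seconds, columns 2-13 = the twelve leads in fixed order) and a minimal
WFDB record (format-16 interleaved int16 ``.dat`` plus ``.hea`` header,
the subset of the WFDB specification that the synthetic generator emits).
Fragmentation ground truth travels in a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, MissingLeadError
from .synth_ecg import LEAD_NAMES, EcgRecord, FragmentationSpec

WFDB_GAIN = 200.0   # adu per mV
_ADC_MAX = 32767


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_ecg_csv(record: EcgRecord, path) -> None:
    df = pd.DataFrame({"time_s": record.time})
    for lead in LEAD_NAMES:
        df[lead] = record.lead_signal(lead)
    df.to_csv(path, index=False, float_format="%.6f")


def read_ecg_csv(path) -> EcgRecord:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("CSV lacks the time_s column")
    for lead in LEAD_NAMES:
        if lead not in df.columns:
            raise MissingLeadError(f"CSV missing lead column {lead}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.ptp(dt) > 1e-6 * max(dt.mean(), 1e-12):
        raise FormatError("non-uniform sampling in time_s column")
    fs = 1.0 / dt.mean()
    data = np.stack([df[lead].to_numpy(dtype=float) for lead in LEAD_NAMES])
    return EcgRecord(
        sampling_rate=float(round(fs, 6)),
        duration=t.size / fs,
        data=data,
        record_id=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Minimal WFDB (format 16)
# ---------------------------------------------------------------------------

def write_ecg_wfdb(record: EcgRecord, path_base) -> None:
    """Write ``<base>.hea`` and ``<base>.dat`` (int16, sample-interleaved)."""
    base = Path(path_base)
    name = base.name
    n = record.n_samples
    digital = np.clip(
        np.round(record.data * WFDB_GAIN), -_ADC_MAX - 1, _ADC_MAX
    ).astype("<i2")
    lines = [f"{name} {len(LEAD_NAMES)} {record.sampling_rate:g} {n}"]
    for i, lead in enumerate(LEAD_NAMES):
        first = int(digital[i, 0])
        checksum = int(np.sum(digital[i], dtype=np.int64) % 65536)
        lines.append(
            f"{name}.dat 16 {WFDB_GAIN:g}(0)/mV 16 0 {first} {checksum} 0 {lead}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    digital.T.tofile(base.with_suffix(".dat"))


def read_ecg_wfdb(path_base) -> EcgRecord:
    base = Path(path_base)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header {hea} not found")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    try:
        n_sig, fs, n = int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as exc:
        raise FormatError("unreadable WFDB header line") from exc
    sig_lines = lines[1 : 1 + n_sig]
    leads, gains = [], []
    for ln in sig_lines:
        tok = ln.split()
        if tok[1] != "16":
            raise FormatError(f"unsupported WFDB format {tok[1]} (only 16)")
        gains.append(float(tok[2].split("(")[0]))
        leads.append(tok[-1])
    missing = [ld for ld in LEAD_NAMES if ld not in leads]
    if missing:
        raise MissingLeadError(f"WFDB record missing leads {missing}")
    raw = np.fromfile(base.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n:
        raise FormatError("WFDB .dat size does not match header")
    digital = raw.reshape(n, n_sig).T
    order = [leads.index(ld) for ld in LEAD_NAMES]
    data = digital[order] / np.asarray(gains)[order, None]
    return EcgRecord(
        sampling_rate=fs, duration=n / fs, data=data, record_id=base.name
    )


def read_ecg(path, fmt: str = "csv") -> EcgRecord:
    """Dispatch on format in {"csv", "wfdb"}."""
    if fmt == "csv":
        return read_ecg_csv(path)
    if fmt == "wfdb":
        return read_ecg_wfdb(path)
    raise FormatError(f"unknown ECG format {fmt!r}")


def write_ecg(record: EcgRecord, path, fmt: str = "csv") -> None:
    if fmt == "csv":
        write_ecg_csv(record, path)
    elif fmt == "wfdb":
        write_ecg_wfdb(record, path)
    else:
        raise FormatError(f"unknown ECG format {fmt!r}")


def write_truth_json(record: EcgRecord, path) -> None:
    """Ground-truth sidecar: per-lead fragmentation specs and R times."""
    payload = {
        "record_id": record.record_id,
        "r_times": None if record.r_times is None else record.r_times.tolist(),
        "fragmentation": {
            lead: dataclasses.asdict(spec)
            for lead, spec in record.fragmentation.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> dict:
    d = json.loads(Path(path).read_text())
    d["fragmentation"] = {
        lead: FragmentationSpec(**spec)
        for lead, spec in d["fragmentation"].items()
    }
    if d["r_times"] is not None:
        d["r_times"] = np.asarray(d["r_times"])
    return d


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "fqrs_run",
    "ecg": {
        "n_clean_records": 50,
        "n_fragmented_records": 50,
        "severity_range": [0.5, 1.0],
        "duration": 10.0,
        "fs": 250.0,
        "mean_rr": 1.0,
        "noise": {
            "baseline_amplitude": 0.05,
            "baseline_frequency": 0.30,
            "powerline_amplitude": 0.01,
            "powerline_frequency": 50.0,
            "white_sd": 0.01,
        },
    },
    "segmentation": {
        "min_correlation": 0.90,
        "window_clamp_ms": [40.0, 200.0],
    },
    "features": {
        "prsa_l": 16,
        "vmd_k": 5,
        "vmd_alpha": 2000.0,
        "prominence_fraction": 0.05,
    },
    "classifier": {"C": 1.0, "gamma": "scale", "platt_cv": 3},
    "threshold": {"min_specificity": 0.95},
    "cohort": {
        "n": 500,
        "fqrs_log_hr_death": 0.0,
        "fqrs_log_hr_therapy": 0.0,
    },
    "survival": {
        "screen_alpha": 0.100,
        "endpoints": ["icd_rm", "mortality_overall"],
        "candidates": [
            "age", "bmi", "lvef", "creatinine", "qtc", "female", "ihd",
            "secondary_prevention", "nyha", "crtd", "stroke", "dm", "af",
            "aht", "bb", "acei_arb", "loop", "aldactone", "antiaggregant",
            "anticoagulation", "amiodarone", "digitalis", "statin", "lbbb",
            "fqrs",
        ],
    },
}


def _merge_validate(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = {}
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {prefix}{key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"key {prefix}{key!r} must be a mapping")
            out[key] = _merge_validate(defaults[key], val, f"{prefix}{key}.")
        else:
            out[key] = val
    for key, val in defaults.items():
        if key not in out:
            out[key] = json.loads(json.dumps(val))  # deep copy
    return out


def validate_config(user: dict) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    return _merge_validate(DEFAULT_CONFIG, user or {})


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
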