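"""File formats: PNG stimuli with JSON sidecars, manifests, CSV trial logs.

Stimulus sets are written as 8-bit single-channel grayscale PNGs (two per
pair) with one JSON sidecar per pair and a set manifest carrying the
master seed and generation parameters; the manifest alone suffices to
regenerate every pixel byte-identically.  Trial logs are plain CSV, one
row per trial, with empty fields for absent values (undetected trials).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .observer import TrialRecord, validate_record
from .stimuli import StimulusPair, build_stimulus_set

logger = logging.getLogger(__name__)

TRIAL_LOG_COLUMNS = [
    "participant_id", "condition", "pair_id", "strength", "detected",
    "detection_time_s", "mark_x_cm", "mark_y_cm", "target_x_cm", "target_y_cm",
]


# ---------------------------------------------------------------------------
# stimulus export / regeneration


def pair_sidecar(pair: StimulusPair) -> dict:
    return {
        "pair_id": pair.pair_id,
        "strength": pair.strength,
        "polarity": pair.target.polarity,
        "target_center_cm": [pair.target.center_x_cm, pair.target.center_y_cm],
        "sigma_cm": pair.target.sigma_cm,
        "lattice_seed": pair.base.lattice_seed,
        "anisotropy_score": pair.base.anisotropy,
        "scale_px_per_cm": pair.base.scale_px_per_cm,
        "side_cm": pair.base.side_cm,
        "clamped_pixels": pair.clamped_pixels,
    }


def write_stimulus_set(pairs: list[StimulusPair], directory: str | Path,
                       generation_params: dict | None = None) -> Path:
    """Export PNGs + sidecars + set manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for pair in pairs:
        for label, img in (("base", pair.base), ("target", pair.with_target)):
            name = f"{pair.pair_id}_{label}.png"
            Image.fromarray(img.pixels, mode="L").save(directory / name)
            files.append(name)
        sidecar = f"{pair.pair_id}.json"
        (directory / sidecar).write_text(json.dumps(pair_sidecar(pair), indent=2))
        files.append(sidecar)
    manifest = {
        "software_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "generation": generation_params or {},
        "pairs": [pair_sidecar(p) for p in pairs],
        "files": files,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def regenerate_from_manifest(manifest_path: str | Path) -> list[StimulusPair]:
    """Rebuild a stimulus set, pixel-identically, from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    gen = manifest["generation"]
    return build_stimulus_set(
        n_pairs=gen["n_pairs"], strengths=tuple(gen["strengths"]), seed=gen["seed"],
        side_cm=gen["side_cm"], scale_px_per_cm=gen["scale_px_per_cm"],
        grid_cells=gen["grid_cells"], sigma_cm=gen["sigma_cm"],
        margin_cm=gen["margin_cm"], screening_threshold=gen["screening_threshold"],
    )


@dataclass
class _TargetHandle:
    center_x_cm: float
    center_y_cm: float


@dataclass
class _ImageHandle:
    side_cm: float


@dataclass
class PairHandle:
    """Lightweight stand-in for a StimulusPair built from manifest metadata.

    Carries everything trial simulation needs (identity, strength, target
    geometry, image side) without re-rendering pixels.
    """

    pair_id: str
    strength: int
    target: _TargetHandle
    base: _ImageHandle


def load_pair_handles(manifest_path: str | Path) -> list[PairHandle]:
    manifest = json.loads(Path(manifest_path).read_text())
    handles = []
    for entry in manifest["pairs"]:
        handles.append(PairHandle(
            pair_id=entry["pair_id"], strength=entry["strength"],
            target=_TargetHandle(*entry["target_center_cm"]),
            base=_ImageHandle(entry["side_cm"]),
        ))
    return handles


# ---------------------------------------------------------------------------
# trial logs


def write_trial_log(records: list[TrialRecord], path: str | Path) -> None:
    """Write a trial log CSV (comma-separated, '.' decimals, header row)."""
    rows = []
    for i, rec in enumerate(records):
        validate_record(rec, row=i)
        rows.append({
            "participant_id": rec.participant_id,
            "condition": rec.condition,
            "pair_id": rec.pair_id,
            "strength": rec.strength,
            "detected": int(rec.detected),
            "detection_time_s": rec.detection_time_s,
            "mark_x_cm": rec.mark_x_cm,
            "mark_y_cm": rec.mark_y_cm,
            "target_x_cm": rec.target_x_cm,
            "target_y_cm": rec.target_y_cm,
        })
    df = pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # .17g guarantees a lossless float round trip
    df.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trial log CSV.

    Detected trials with times above the 30 s limit are coerced to
    timeouts with a warning; structurally inconsistent rows (e.g. a mark
    on an undetected trial) are rejected with their row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path}: missing required column(s) {missing}")
    records: list[TrialRecord] = []
    n_coerced = 0
    for i, row in enumerate(df.itertuples(index=False)):
        detected = bool(row.detected)
        time = None if pd.isna(row.detection_time_s) else float(row.detection_time_s)
        mx = None if pd.isna(row.mark_x_cm) else float(row.mark_x_cm)
        my = None if pd.isna(row.mark_y_cm) else float(row.mark_y_cm)
        if detected and time is not None and time > 30.0:
            detected, time, mx, my = False, None, None, None
            n_coerced += 1
        rec = TrialRecord(
            participant_id=str(row.participant_id), condition=str(row.condition),
            pair_id=str(row.pair_id), strength=int(row.strength),
            detected=detected, detection_time_s=time,
            mark_x_cm=mx, mark_y_cm=my,
            target_x_cm=float(row.target_x_cm), target_y_cm=float(row.target_y_cm),
        )
        try:
            validate_record(rec, row=i)
        except ValueError as exc:
            raise ValueError(f"trial log {path}: {exc}") from exc
        records.append(rec)
    if n_coerced:
        warnings.warn(f"{n_coerced} trial(s) with detection_time_s > 30 coerced to timeout",
                      stacklevel=2)
    return records


# ---------------------------------------------------------------------------
# summaries and reports


def write_participant_summaries(summaries, path: str | Path) -> None:
    df = pd.DataFrame([s.__dict__ for s in summaries])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _jsonify(obj):
    from .inference import StatResult

    if isinstance(obj, StatResult):
        return {"name": obj.name, "statistic": _jsonify(obj.statistic),
                "df": list(obj.df), "p_value": obj.p_value,
                "bf10": _jsonify(obj.bf10), "method": _jsonify(obj.method)}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else repr(f)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonify(report), indent=2))


def report_to_rows(report: dict) -> pd.DataFrame:
    """Flatten every StatResult in a report into a table."""
    from .inference import StatResult

    rows = []

    def walk(prefix, node):
        if isinstance(node, StatResult):
            rows.append({"test": prefix, "name": node.name,
                         "statistic": node.statistic,
                         "df": "/".join(f"{d:g}" for d in node.df),
                         "p_value": node.p_value, "bf10": node.bf10})
        elif isinstance(node, dict):
            for k, v in node.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)

    walk("", report)
    return pd.DataFrame(rows)
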