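"""Annotation JSON and roster CSV input/output.

The annotation file is plain JSON: a schema-version field plus one object
per eye holding the four quadrant boundary traces in um. The reader
validates each scan's structural invariants; by default an invalid scan is
downgraded to ungradable (with its failures reported) rather than aborting
the file, mirroring how poor-quality acquisitions are handled clinically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enums import Eye, Quadrant
from .errors import ValidationError
from .geometry import AngleScan, normalize_scan, validate_scan
from .screening import ParticipantRecord

__all__ = [
    "SCHEMA_VERSION",
    "EyeAnnotation",
    "write_annotations",
    "read_annotations",
    "annotations_mapping",
    "read_roster",
    "write_roster",
]

SCHEMA_VERSION = "angleguard-annotation-v1"


@dataclass
class EyeAnnotation:
    participant_id: str
    eye: Eye
    scans: list[AngleScan]
    validation_report: dict[str, list[str]] = field(default_factory=dict)


def _scan_to_dict(scan: AngleScan) -> dict:
    d = {
        "quadrant": scan.quadrant.value,
        "pixel_scale_um": scan.pixel_scale,
        "cornea_inner": np.asarray(scan.cornea_inner).tolist(),
        "iris_anterior": np.asarray(scan.iris_anterior).tolist(),
        "scleral_spur": np.asarray(scan.scleral_spur).tolist(),
        "iris_recess": np.asarray(scan.iris_recess).tolist(),
        "gradable": bool(scan.gradable),
    }
    if scan.iris_posterior is not None:
        d["iris_posterior"] = np.asarray(scan.iris_posterior).tolist()
    return d


def write_annotations(eyes: Sequence[EyeAnnotation], path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "eyes": [
            {
                "participant_id": e.participant_id,
                "eye": Eye(e.eye).value,
                "scans": [_scan_to_dict(s) for s in e.scans],
            }
            for e in eyes
        ],
    }
    Path(path).write_text(json.dumps(payload))


_REQUIRED = ("quadrant", "cornea_inner", "iris_anterior", "scleral_spur", "iris_recess")


def _scan_from_dict(d: dict) -> tuple[AngleScan | None, list[str]]:
    missing = [k for k in _REQUIRED if k not in d]
    if missing:
        return None, [f"{k}: missing" for k in missing]
    try:
        scan = AngleScan(
            quadrant=Quadrant(d["quadrant"]),
            cornea_inner=np.asarray(d["cornea_inner"], float),
            iris_anterior=np.asarray(d["iris_anterior"], float),
            iris_posterior=(
                np.asarray(d["iris_posterior"], float) if "iris_posterior" in d else None
            ),
            scleral_spur=np.asarray(d["scleral_spur"], float),
            iris_recess=np.asarray(d["iris_recess"], float),
            pixel_scale=float(d.get("pixel_scale_um", 1.0)),
            gradable=bool(d.get("gradable", True)),
        )
    except (ValueError, TypeError) as err:
        return None, [f"scan: {err}"]
    failures = validate_scan(scan)
    if failures:
        return scan, failures
    return normalize_scan(scan), []


def read_annotations(path, strict: bool = False) -> list[EyeAnnotation]:
    """Read and validate an annotation file.

    Each scan is checked against the structural invariants (trace sizes,
    monotone arc length, landmark-to-trace tolerances) and normalized into
    the package frame (um, cornea on the positive-y side). With
    ``strict=True`` any failure raises :class:`ValidationError` listing
    every offending field; otherwise failing scans are kept but marked
    ungradable and the messages are collected per quadrant in each
    annotation's ``validation_report``.
    """
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError([f"schema_version: expected {SCHEMA_VERSION!r}, got {version!r}"])
    eyes: list[EyeAnnotation] = []
    all_failures: list[str] = []
    for entry in payload.get("eyes", []):
        pid = entry.get("participant_id", "?")
        report: dict[str, list[str]] = {}
        scans: list[AngleScan] = []
        for sd in entry.get("scans", []):
            scan, failures = _scan_from_dict(sd)
            if failures:
                tag = f"{pid}/{entry.get('eye', '?')}/{sd.get('quadrant', '?')}"
                report[sd.get("quadrant", "?")] = failures
                all_failures.extend(f"{tag}: {msg}" for msg in failures)
                if scan is not None:
                    scan.gradable = False
                    scans.append(scan)
            else:
                scans.append(scan)
        eyes.append(
            EyeAnnotation(
                participant_id=pid,
                eye=Eye(entry.get("eye", "OD")),
                scans=scans,
                validation_report=report,
            )
        )
    if strict and all_failures:
        raise ValidationError(all_failures)
    return eyes


def annotations_mapping(eyes: Sequence[EyeAnnotation]) -> dict[str, dict[str, list[AngleScan]]]:
    """Regroup annotations as the pid -> eye -> scans mapping the pipeline uses."""
    out: dict[str, dict[str, list[AngleScan]]] = {}
    for e in eyes:
        out.setdefault(e.participant_id, {})[Eye(e.eye).value] = e.scans
    return out


# ---------------------------------------------------------------------------
# roster CSV

_ROSTER_COLUMNS = [
    "id",
    "age",
    "gender",
    "pva_better_eye",
    "iop_od",
    "iop_os",
    "fundus_glaucoma_suspect",
    "fundus_other_abnormal",
    "prior_ocular_surgery",
    "bilateral_poor_image",
    "hrac_label",
]

_BOOL_COLUMNS = [
    "fundus_glaucoma_suspect",
    "fundus_other_abnormal",
    "prior_ocular_surgery",
    "bilateral_poor_image",
]


def write_roster(roster: Sequence[ParticipantRecord], path) -> None:
    rows = []
    for r in roster:
        rows.append(
            {
                "id": r.id,
                "age": r.age,
                "gender": r.gender.value,
                "pva_better_eye": r.pva_better_eye,
                "iop_od": r.iop_od,
                "iop_os": r.iop_os,
                "fundus_glaucoma_suspect": r.fundus_glaucoma_suspect,
                "fundus_other_abnormal": r.fundus_other_abnormal,
                "prior_ocular_surgery": r.prior_ocular_surgery,
                "bilateral_poor_image": r.bilateral_poor_image,
                "hrac_label": "" if r.hrac_label is None else r.hrac_label,
            }
        )
    pd.DataFrame(rows, columns=_ROSTER_COLUMNS).to_csv(path, index=False)


def read_roster(path) -> list[ParticipantRecord]:
    """Read a roster CSV, validating each record; errors list every bad field."""
    df = pd.read_csv(path)
    missing = [c for c in _ROSTER_COLUMNS if c not in df.columns and c != "hrac_label"]
    if missing:
        raise ValidationError([f"{c}: column missing" for c in missing])
    roster = []
    failures = []
    for i, row in df.iterrows():
        try:
            label = row.get("hrac_label")
            if pd.isna(label) or label == "":
                label = None
            else:
                label = str(label).strip().lower() in ("true", "1", "1.0", "yes")
            roster.append(
                ParticipantRecord(
                    id=str(row["id"]),
                    age=float(row["age"]),
                    gender=str(row["gender"]),
                    pva_better_eye=float(row["pva_better_eye"]),
                    iop_od=float(row["iop_od"]),
                    iop_os=float(row["iop_os"]),
                    hrac_label=label,
                    **{c: _as_bool(row[c]) for c in _BOOL_COLUMNS},
                )
            )
        except (ValidationError, ValueError) as err:
            failures.append(f"row {i} (id={row.get('id', '?')}): {err}")
    if failures:
        raise ValidationError(failures)
    return roster


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)
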