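"""Container I/O: HDF5 RF frames, ROI JSON, cohort manifests, YAML config.

Frame files hold one dataset ``rf`` (n_samples × n_lines) plus transducer
and medium metadata as attributes, under a version-stamped schema.  A
cohort directory contains one frame file per (patient, system, frame), a
ROI JSON per (patient, frame), and a ``manifest.json`` mapping patients to
their files and ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .core import RFFrame, ROIPolygon
from .synthesis import Cohort, CohortSpec, PatientRecord, TransducerProfile

__all__ = [
    "SchemaError",
    "write_frame",
    "read_frame",
    "write_roi",
    "read_roi",
    "write_cohort",
    "read_cohort",
    "read_phantom_table",
]

SCHEMA_VERSION = 1

_PROFILE_FIELDS = (
    "name",
    "center_frequency_mhz",
    "band_low_mhz",
    "band_high_mhz",
    "sampling_rate_mhz",
    "lateral_pitch_mm",
    "axial_pitch_mm",
    "n_lines",
    "n_samples",
    "focal_depth_mm",
)


class SchemaError(ValueError):
    """Raised when a container is missing required datasets or attributes."""


def write_frame(frame: RFFrame, path) -> None:
    """Write one RF frame to an HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("rf", data=frame.samples)
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["axial_pitch_mm"] = frame.axial_pitch_mm
        h5.attrs["lateral_pitch_mm"] = frame.lateral_pitch_mm
        if frame.profile is not None:
            for f in _PROFILE_FIELDS:
                h5.attrs[f"profile.{f}"] = getattr(frame.profile, f)
        for k, v in frame.metadata.items():
            h5.attrs[f"meta.{k}"] = v


def read_frame(path) -> RFFrame:
    """Read an RF frame; raises :class:`SchemaError` naming absent fields."""
    with h5py.File(path, "r") as h5:
        missing = []
        if "rf" not in h5:
            missing.append("dataset 'rf'")
        for attr in ("schema_version", "axial_pitch_mm", "lateral_pitch_mm"):
            if attr not in h5.attrs:
                missing.append(f"attr '{attr}'")
        if missing:
            raise SchemaError(f"{path}: missing {', '.join(missing)}")
        samples = h5["rf"][()]
        profile = None
        if "profile.name" in h5.attrs:
            kwargs = {}
            for f in _PROFILE_FIELDS:
                key = f"profile.{f}"
                if key not in h5.attrs:
                    raise SchemaError(f"{path}: missing attr '{key}'")
                v = h5.attrs[key]
                kwargs[f] = str(v) if f == "name" else (int(v) if f in ("n_lines", "n_samples") else float(v))
            profile = TransducerProfile(**kwargs)
        metadata = {
            k[5:]: (v.item() if isinstance(v, np.generic) else v)
            for k, v in h5.attrs.items()
            if k.startswith("meta.")
        }
        return RFFrame(
            samples,
            profile=profile,
            axial_pitch_mm=float(h5.attrs["axial_pitch_mm"]),
            lateral_pitch_mm=float(h5.attrs["lateral_pitch_mm"]),
            metadata=metadata,
        )


def read_phantom_table(
    path,
    attenuation_slope: float = 0.7861,
    speed_of_sound: float = 1488.0,
):
    """Load a measured phantom BSC table from a two-column CSV.

    The file must have columns ``f_MHz`` and ``sigma_r`` (1/(cm·sr));
    attenuation slope and sound speed are supplied separately since BSC
    tables are typically published without them.
    """
    import pandas as pd

    from .backscatter import PhantomSpec

    table = pd.read_csv(path)
    missing = {"f_MHz", "sigma_r"} - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return PhantomSpec(
        attenuation_slope=attenuation_slope,
        speed_of_sound=speed_of_sound,
        freq_mhz=table["f_MHz"].to_numpy(dtype=float),
        bsc=table["sigma_r"].to_numpy(dtype=float),
    )


def write_roi(roi: ROIPolygon, path) -> None:
    Path(path).write_text(json.dumps(np.asarray(roi.vertices).tolist()))


def read_roi(path) -> ROIPolygon:
    return ROIPolygon(json.loads(Path(path).read_text()))


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort to a directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "systems": list(cohort.system_names), "patients": []}
    for p in cohort.patients:
        entry = {"id": p.patient_id, "group": p.group, "frames": {}, "rois": [], "truth": p.truth}
        for system, frames in p.frames.items():
            paths = []
            for k, fr in enumerate(frames):
                rel = f"{p.patient_id}_{system}_f{k}.h5"
                write_frame(fr, out / rel)
                paths.append(rel)
            entry["frames"][system] = paths
        for k, roi in enumerate(p.rois):
            rel = f"{p.patient_id}_roi_f{k}.json"
            write_roi(roi, out / rel)
            entry["rois"].append(rel)
        manifest["patients"].append(entry)
    spec = cohort.spec
    manifest["profiles"] = [
        {f: getattr(prof, f) for f in _PROFILE_FIELDS} for prof in spec.profiles
    ]
    manifest["spec"] = {
        "frames_per_patient": list(spec.frames_per_patient),
        "heterogeneity_scale": spec.heterogeneity_scale,
        "seed": spec.seed,
        "tumor_top_mm": spec.tumor_top_mm,
        "tumor_bottom_mm": spec.tumor_bottom_mm,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_cohort(in_dir) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise SchemaError(f"{root}: missing manifest.json")
    manifest = json.loads(mpath.read_text())
    profiles = tuple(TransducerProfile(**p) for p in manifest["profiles"])
    patients = []
    for entry in manifest["patients"]:
        frames = {
            system: [read_frame(root / rel) for rel in rels]
            for system, rels in entry["frames"].items()
        }
        rois = [read_roi(root / rel) for rel in entry["rois"]]
        patients.append(
            PatientRecord(
                patient_id=entry["id"],
                group=entry["group"],
                frames=frames,
                rois=rois,
                truth=entry.get("truth", []),
            )
        )
    n_b = sum(1 for p in patients if p.group == "benign")
    n_m = sum(1 for p in patients if p.group == "malignant")
    extra = manifest.get("spec", {})
    if "frames_per_patient" in extra:
        extra["frames_per_patient"] = tuple(extra["frames_per_patient"])
    spec = CohortSpec(
        n_patients_benign=n_b, n_patients_malignant=n_m, profiles=profiles, **extra
    )
    return Cohort(spec=spec, patients=patients)
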