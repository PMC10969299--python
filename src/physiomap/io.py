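"""NIfTI/JSON persistence for simulated cohorts and biomarker maps.

Each patient is a directory of NIfTI volumes (4-D for echo series and DSC,
5-D for hybrid GESE) with one JSON sidecar of timing/echo metadata; a cohort
is tied together by a ``cohort.json`` manifest (patient id, label, paths).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import VolumeGrid
from .perfusion import DynamicSeries
from .phantom import (GroundTruthMaps, PatientBundle, Phantom, PhantomSpec)
from .relaxometry import DiffusionPair, EchoSeries

__all__ = ["save_patient", "load_patient", "save_cohort", "load_cohort", "save_maps"]


def _write(path: Path, data: np.ndarray, voxel_mm: float) -> None:
    ndim3 = (voxel_mm,) * 3
    affine = np.diag([*ndim3, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def _read(path: Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(float)


def save_patient(bundle: PatientBundle, out_dir: str | Path) -> dict:
    """Write one patient's volumes and sidecar; returns the manifest entry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = bundle.phantom.spec.voxel_size_mm
    gt = bundle.phantom.gt

    _write(out / "ge_echo.nii", bundle.ge_echo.stack, vs)
    _write(out / "se_echo.nii", bundle.se_echo.stack, vs)
    _write(out / "dwi_b0.nii", bundle.dwi.s0.data, vs)
    _write(out / "dwi_b1000.nii", bundle.dwi.s1000.data, vs)
    _write(out / "cet1w.nii", bundle.cet1w.data, vs)
    _write(out / "flair.nii", bundle.flair.data, vs)
    _write(out / "brain_mask.nii", bundle.phantom.brain_mask.astype(np.uint8), vs)
    _write(out / "tumor_mask.nii", bundle.phantom.tumor_mask.astype(np.uint8), vs)
    _write(out / "arterial_mask.nii", bundle.phantom.arterial_mask.astype(np.uint8), vs)
    for key, series in bundle.dsc.items():
        _write(out / f"dsc_{key}.nii", series.signal, vs)
    gt_fields = {k: v for k, v in asdict(gt).items() if isinstance(v, np.ndarray)}
    for name, arr in gt_fields.items():
        _write(out / f"gt_{name}.nii", arr, vs)

    any_dsc = next(iter(bundle.dsc.values()))
    sidecar = {
        "pid": bundle.pid,
        "label": bundle.label,
        "spec": {**asdict(bundle.phantom.spec)},
        "ge_echo_times_ms": list(bundle.ge_echo.echo_times_ms),
        "se_echo_times_ms": list(bundle.se_echo.echo_times_ms),
        "dsc": {key: {"frame_interval": s.frame_interval,
                      "echo_time_ms": s.echo_time_ms if np.ndim(s.echo_time_ms) == 0
                      else list(s.echo_time_ms),
                      "echo_kind": s.echo_kind,
                      "baseline_window": list(s.baseline_window)}
                for key, s in bundle.dsc.items()},
        "b_values": [0.0, 1000.0],
        "voxel_size_mm": vs,
        "n_frames": any_dsc.n_frames,
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return {"pid": bundle.pid, "label": bundle.label, "path": str(out)}


def load_patient(patient_dir: str | Path) -> PatientBundle:
    """Reconstruct a patient bundle from a saved directory."""
    p = Path(patient_dir)
    meta = json.loads((p / "sidecar.json").read_text())
    vs = float(meta["voxel_size_mm"])
    spec = PhantomSpec(**{**meta["spec"],
                          "grid_shape": tuple(meta["spec"]["grid_shape"]),
                          "tumor_center": tuple(meta["spec"]["tumor_center"])
                          if meta["spec"]["tumor_center"] else None,
                          "tumor_radii": tuple(meta["spec"]["tumor_radii"])})

    gt_kwargs = {}
    for name in ("oef", "cbv", "cbf", "adc", "micro_cbv", "r2", "s0",
                 "loop_orientation", "mvd", "vsi"):
        gt_kwargs[name] = _read(p / f"gt_{name}.nii")
    gt_kwargs["loop_orientation"] = gt_kwargs["loop_orientation"].astype(int)
    gt = GroundTruthMaps(**gt_kwargs, voxel_size_mm=vs)
    phantom = Phantom(spec, gt,
                      _read(p / "brain_mask.nii").astype(bool),
                      _read(p / "tumor_mask.nii").astype(bool),
                      _read(p / "arterial_mask.nii").astype(bool))

    def echo(fname, times, kind):
        stack = _read(p / fname)
        vols = [VolumeGrid(stack[..., i], (vs,) * 3) for i in range(stack.shape[-1])]
        return EchoSeries(vols, np.asarray(times, dtype=float), kind)

    dsc = {}
    for key, s in meta["dsc"].items():
        te = s["echo_time_ms"]
        dsc[key] = DynamicSeries(_read(p / f"dsc_{key}.nii"), s["frame_interval"],
                                 tuple(te) if isinstance(te, list) else float(te),
                                 echo_kind=s["echo_kind"],
                                 baseline_window=tuple(s["baseline_window"]),
                                 voxel_size_mm=(vs,) * 3)
    return PatientBundle(
        meta["pid"], meta["label"], phantom,
        echo("ge_echo.nii", meta["ge_echo_times_ms"], "GE"),
        echo("se_echo.nii", meta["se_echo_times_ms"], "SE"),
        DiffusionPair(VolumeGrid(_read(p / "dwi_b0.nii"), (vs,) * 3),
                      VolumeGrid(_read(p / "dwi_b1000.nii"), (vs,) * 3)),
        VolumeGrid(_read(p / "cet1w.nii"), (vs,) * 3),
        VolumeGrid(_read(p / "flair.nii"), (vs,) * 3),
        dsc)


def save_cohort(bundles: list[PatientBundle], out_dir: str | Path) -> Path:
    """Write a cohort tree plus its manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = [save_patient(b, out / b.pid) for b in bundles]
    manifest = out / "cohort.json"
    manifest.write_text(json.dumps({"patients": entries}, indent=2))
    return manifest


def load_cohort(cohort_dir: str | Path) -> list[PatientBundle]:
    manifest = json.loads((Path(cohort_dir) / "cohort.json").read_text())
    return [load_patient(e["path"]) for e in manifest["patients"]]


def save_maps(mapped: dict, out_dir: str | Path) -> None:
    """Write the twelve computed maps (plus parse provenance) of one patient."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = mapped["voxel_size_mm"]
    for name, arr in mapped["maps"].items():
        _write(out / f"{name}.nii", arr, vs)
    (out / "provenance.json").write_text(json.dumps({"parses": mapped["parses"]}, indent=2))
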