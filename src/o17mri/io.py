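"""File input/output: NIfTI volumes, YAML configuration, CSV tables.

Volumes are written as NIfTI-1 with an affine that places the FOV centre
at the world origin.  Real acquired data enters the package here: a 4D
image series plus label masks (already registered to the oxygen grid) and
a protocol/sequence description.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import GridSpec
from .phantom import InhalationProtocol, Label, LabeledPhantom, TissueParams
from .recon import ImageFrame, ImageSeries

__all__ = [
    "save_volume",
    "load_volume",
    "save_labeled_phantom",
    "save_image_series",
    "load_image_series",
    "load_mask",
    "save_kspace",
    "load_kspace",
    "tissue_table_to_dict",
    "tissue_table_from_dict",
    "load_protocol_yaml",
]


def save_volume(data: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine())
    img.header.set_zooms((grid.voxel_size_mm,) * 3)
    nib.save(img, path)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError("only isotropic volumes are supported")
    grid = GridSpec(tuple(int(s) for s in img.shape[:3]), float(zooms[0]))
    return np.asarray(img.dataobj), grid


def load_mask(path: str | Path) -> np.ndarray:
    data, _ = load_volume(path)
    return data > 0.5


def save_labeled_phantom(phantom: LabeledPhantom, out_dir: str | Path) -> None:
    """Write the label volume plus one binary NIfTI per tissue mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(phantom.labels, phantom.grid, out / "labels.nii.gz")
    for lab, mask in phantom.masks.items():
        save_volume(mask.astype(np.uint8), phantom.grid, out / f"mask_{lab.name.lower()}.nii.gz")


def save_image_series(series: ImageSeries, path: str | Path) -> None:
    """4D NIfTI plus a JSON sidecar with the frame timing."""
    path = Path(path)
    grid = series.grid
    img = nib.Nifti1Image(series.as_4d().astype(np.float32), grid.affine())
    img.header.set_zooms((grid.voxel_size_mm,) * 3 + (series.frame_duration_s,))
    nib.save(img, path)
    sidecar = {
        "frame_duration_s": series.frame_duration_s,
        "frame_start_s": [f.t_start_s for f in series.frames],
        "frame_mid_s": [f.mid_time_s for f in series.frames],
        "projections_per_frame": [f.n_projections for f in series.frames],
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_image_series(path: str | Path, frame_duration_s: float | None = None) -> ImageSeries:
    """Read a 4D NIfTI series (the real-data entry point).

    Frame timing is taken from the JSON sidecar written by
    :func:`save_image_series` when present, else from ``frame_duration_s``
    with frames assumed contiguous from t = 0.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4D image series")
    zooms = img.header.get_zooms()
    grid = GridSpec(tuple(int(s) for s in data.shape[:3]), float(zooms[0]))
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        dur = float(sidecar["frame_duration_s"])
        starts = [float(t) for t in sidecar["frame_start_s"]]
        nproj = sidecar.get("projections_per_frame", [0] * data.shape[3])
    elif frame_duration_s is not None:
        dur = float(frame_duration_s)
        starts = [i * dur for i in range(data.shape[3])]
        nproj = [0] * data.shape[3]
    else:
        raise ValueError("no timing sidecar found; pass frame_duration_s")
    frames = tuple(
        ImageFrame(
            data=np.abs(data[..., i]).astype(float),
            grid=grid,
            t_start_s=starts[i],
            t_end_s=starts[i] + dur,
            n_projections=int(nproj[i]),
        )
        for i in range(data.shape[3])
    )
    return ImageSeries(frames=frames, frame_duration_s=dur)


def save_kspace(kspace, path: str | Path) -> None:
    """Write a k-space series as raw binary plus a JSON sidecar.

    Layout: spoke-major little-endian complex128 pairs (``<c16``), one
    record per (spoke, sample); the sidecar carries shapes, the radius
    schedule, spoke directions, timing and noise metadata so the series
    can be reloaded without the generating code.
    """
    from .acquisition import KSpaceSeries, RadialTrajectory, SequenceParams

    path = Path(path)
    kspace.samples.astype("<c16").tofile(path)
    seq = kspace.sequence
    sidecar = {
        "n_spokes": int(kspace.trajectory.n_spokes),
        "samples_per_spoke": int(kspace.trajectory.samples_per_spoke),
        "dtype": "<c16",
        "order": "spoke-major",
        "timestamps_s": kspace.timestamps_s.tolist(),
        "directions": kspace.trajectory.directions.tolist(),
        "sample_times_ms": kspace.trajectory.sample_times_ms.tolist(),
        "radii_per_mm": kspace.trajectory.radii_per_mm.tolist(),
        "radial_speed": kspace.trajectory.radial_speed.tolist(),
        "kmax_per_mm": kspace.trajectory.kmax_per_mm,
        "noise_sd": kspace.noise_sd,
        "seed": kspace.seed,
        "sequence": {
            "te_ms": seq.te_ms, "tr_ms": seq.tr_ms, "flip_deg": seq.flip_deg,
            "t_pulse_ms": seq.t_pulse_ms, "readout_ms": seq.readout_ms,
            "nominal_resolution_mm": seq.nominal_resolution_mm,
            "n_projections": seq.n_projections,
            "samples_per_spoke": seq.samples_per_spoke,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_kspace(path: str | Path):
    """Inverse of :func:`save_kspace`."""
    from .acquisition import KSpaceSeries, RadialTrajectory, SequenceParams

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    shape = (meta["n_spokes"], meta["samples_per_spoke"])
    samples = np.fromfile(path, dtype="<c16").reshape(shape)
    traj = RadialTrajectory(
        directions=np.array(meta["directions"]),
        sample_times_ms=np.array(meta["sample_times_ms"]),
        radii_per_mm=np.array(meta["radii_per_mm"]),
        radial_speed=np.array(meta["radial_speed"]),
        kmax_per_mm=meta["kmax_per_mm"],
    )
    return KSpaceSeries(
        samples=samples,
        timestamps_s=np.array(meta["timestamps_s"]),
        trajectory=traj,
        sequence=SequenceParams(**meta["sequence"]),
        noise_sd=meta["noise_sd"],
        seed=meta["seed"],
    )


# -- configuration ------------------------------------------------------


def tissue_table_to_dict(table: dict[Label, TissueParams]) -> dict:
    return {
        lab.name: {
            "t1_ms": p.t1_ms,
            "t2star_ms": p.t2star_ms,
            "baseline": p.baseline,
            "uptake_rate_per_min": p.uptake_rate_per_min,
            "post_rate_per_min": p.post_rate_per_min,
        }
        for lab, p in table.items()
    }


def tissue_table_from_dict(d: dict) -> dict[Label, TissueParams]:
    return {Label[name]: TissueParams(**params) for name, params in d.items()}


def load_protocol_yaml(path: str | Path) -> InhalationProtocol:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return InhalationProtocol(**raw)
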