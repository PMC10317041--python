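"""Digital brain phantom with three-phase inhalation kinetics.

The phantom stands in for a patient examination in which metabolically
produced oxygen-17 water (H2-17O) accumulates in brain tissue while the
subject breathes 17O2-enriched gas.  Geometry is deliberately schematic —
an ellipsoidal brain with a cortical grey-matter shell, paired paramedian
ventricle slabs, a spherical stroke lesion placed face-adjacent to one
ventricle, and the lesion's exact left-right mirror as a contralateral
control region — but it carries the topological features the downstream
analysis depends on: a small lesion next to CSF, a mirrored healthy
control, and mutually exclusive tissue masks on a common grid.

Signal dynamics follow the three-phase inhalation protocol: a constant
natural-abundance baseline while breathing room air, a linear rise during
17O2 inhalation (the slope proxies the cerebral metabolic rate of oxygen
consumption of that tissue), and a second linear segment after the switch
back to room air.  The rates are per-tissue and user-configurable; the
defaults are calibrated so that healthy tissue reaches a relative plateau
of ~1.18 and CSF ~1.14 after a 5 min baseline and 6 min inhalation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .grids import GridSpec

__all__ = [
    "Label",
    "TissueParams",
    "InhalationProtocol",
    "LabeledPhantom",
    "default_tissue_table",
    "build_phantom",
    "tissue_timecourse",
    "dynamic_image",
]


class Label(IntEnum):
    """Integer tissue labels of the phantom volume."""

    BACKGROUND = 0
    GM = 1
    WM = 2
    CSF = 3
    STROKE = 4
    CONTROL = 5


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and H2-17O kinetic parameters of one tissue class.

    ``baseline`` is the natural-abundance H2-17O signal level in arbitrary
    concentration units; ``uptake_rate_per_min`` is the linear accumulation
    rate during 17O2 inhalation and ``post_rate_per_min`` the rate after the
    switch back to room air (negative for washout, positive for continued
    accumulation, zero for a plateau).
    """

    t1_ms: float
    t2star_ms: float
    baseline: float
    uptake_rate_per_min: float = 0.0
    post_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1_ms > 0 and self.t2star_ms > 0):
            raise ValueError("T1 and T2* must be positive")
        if not self.baseline > 0:
            raise ValueError("baseline signal level must be positive")


@dataclass(frozen=True)
class InhalationProtocol:
    """Timing of the three-phase inhalation experiment (minutes).

    Baseline room air until ``t1_min``, 17O2-enriched gas until ``t2_min``,
    room air again until ``total_min``.
    """

    t1_min: float = 5.0
    t2_min: float = 11.0
    total_min: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.t1_min < self.t2_min < self.total_min):
            raise ValueError("protocol must satisfy 0 < t1 < t2 < total")


def default_tissue_table() -> dict[Label, TissueParams]:
    """Per-tissue defaults.

    T1 = 5 ms for all tissues and T2* of 2.5 / 2.8 / 5 ms for GM / WM / CSF
    (7 T oxygen-17 literature values).  Baselines are all 1.0 — natural
    abundance H2-17O is taken as spatially uniform; tissue-dependent signal
    weighting (the T2* bias) arises in the acquisition model, not here.
    Healthy uptake 0.030 units/min gives a plateau of 1.18 after 6 min of
    inhalation; CSF, which only drains metabolised water from neighbouring
    tissue, rises more slowly (plateau ~1.135).  Stroke and mirrored control
    default to white-matter kinetics, i.e. no built-in metabolic deficit.
    """
    gm = TissueParams(t1_ms=5.0, t2star_ms=2.5, baseline=1.0,
                      uptake_rate_per_min=0.030)
    wm = TissueParams(t1_ms=5.0, t2star_ms=2.8, baseline=1.0,
                      uptake_rate_per_min=0.030)
    csf = TissueParams(t1_ms=5.0, t2star_ms=5.0, baseline=1.0,
                       uptake_rate_per_min=0.0225)
    return {
        Label.GM: gm,
        Label.WM: wm,
        Label.CSF: csf,
        Label.STROKE: wm,
        Label.CONTROL: wm,
    }


@dataclass(frozen=True)
class LabeledPhantom:
    """Integer label volume plus derived per-tissue binary masks."""

    labels: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError("label volume does not match the grid")

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)

    @property
    def masks(self) -> dict[Label, np.ndarray]:
        """Binary mask per nonbackground label present in the volume."""
        return {
            lab: self.mask(lab)
            for lab in Label
            if lab != Label.BACKGROUND and np.any(self.labels == int(lab))
        }

    def brain_mask(self) -> np.ndarray:
        return self.labels != int(Label.BACKGROUND)


def _mirror(mask: np.ndarray) -> np.ndarray:
    # left-right reflection about the central voxel plane of axis 0
    return mask[::-1, :, :].copy()


def build_phantom(
    grid: GridSpec,
    lesion_radius_mm: float = 15.0,
    lesion_center_mm: tuple[float, float, float] | None = None,
    brain_axes_frac: tuple[float, float, float] = (0.30, 0.36, 0.28),
    white_frac: float = 0.72,
    ventricle_box_frac: tuple[tuple[float, float], ...] = (
        (0.03, 0.09),
        (-0.08, 0.12),
        (-0.04, 0.06),
    ),
) -> LabeledPhantom:
    """Build the labelled phantom.

    Geometry (all lengths derived from the FOV so the phantom scales with
    the grid): the brain is an ellipsoid with semi-axes
    ``brain_axes_frac * FOV``; white matter is an inner ellipsoid scaled by
    ``white_frac`` with the cortical grey-matter shell outside it; the
    lateral ventricles are a mirror-symmetric pair of paramedian boxes
    (``ventricle_box_frac`` gives the right ventricle's extent as FOV
    fractions, the left one is its reflection); the stroke lesion is a
    sphere of ``lesion_radius_mm``.  When ``lesion_center_mm`` is None the
    lesion is placed against the outer face of the left ventricle so that
    the two masks share a face-adjacent boundary; the CSF label takes
    precedence where they overlap.  The mirrored control label is the exact
    left-right reflection of the final stroke mask.

    Raises
    ------
    ValueError
        If the lesion sphere is not contained in the brain ellipsoid, if it
        would be swallowed entirely by the ventricle label, or if it
        crosses the midline (its mirror would overlap it).
    """
    if lesion_radius_mm <= 0:
        raise ValueError("lesion radius must be positive")
    fov = grid.fov_mm
    x, y, z = grid.meshgrid_mm()
    semi = np.array([f * fv for f, fv in zip(brain_axes_frac, fov)])
    brain = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0
    inner = (
        (x / (white_frac * semi[0])) ** 2
        + (y / (white_frac * semi[1])) ** 2
        + (z / (white_frac * semi[2])) ** 2
        <= 1.0
    )

    (vx0, vx1), (vy0, vy1), (vz0, vz1) = (
        (lo * fov[ax], hi * fov[ax])
        for ax, (lo, hi) in enumerate(ventricle_box_frac)
    )
    in_y = (y >= vy0) & (y <= vy1)
    in_z = (z >= vz0) & (z <= vz1)
    vent_right = (x >= vx0) & (x <= vx1) & in_y & in_z & brain
    ventricles = (vent_right | _mirror(vent_right)) & brain
    if not ventricles.any():
        raise ValueError("ventricle mask is empty on this grid")

    if lesion_center_mm is None:
        # against the left ventricle's outer face, penetrating by about one
        # voxel so that CSF precedence leaves a face-adjacent boundary
        lesion_center_mm = (
            -(vx1 + lesion_radius_mm - grid.voxel_size_mm),
            0.5 * (vy0 + vy1),
            0.5 * (vz0 + vz1),
        )
        default_placement = True
    else:
        default_placement = False
    cx, cy, cz = lesion_center_mm
    # containment of the analytic sphere in the analytic brain ellipsoid
    centre_norm = np.sqrt((cx / semi[0]) ** 2 + (cy / semi[1]) ** 2 + (cz / semi[2]) ** 2)
    if centre_norm + lesion_radius_mm / semi.min() > 1.0:
        raise ValueError("lesion sphere does not fit inside the brain ellipsoid")
    lesion = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= lesion_radius_mm**2
    stroke = lesion & ~ventricles  # CSF label wins on overlap
    if not stroke.any():
        raise ValueError("lesion lies entirely inside the ventricle label")
    control = _mirror(stroke)
    if (stroke & control).any():
        raise ValueError("lesion crosses the midline; mirrored control overlaps it")

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[brain & ~inner] = int(Label.GM)
    labels[inner] = int(Label.WM)
    labels[ventricles] = int(Label.CSF)
    labels[stroke] = int(Label.STROKE)
    labels[control] = int(Label.CONTROL)

    if default_placement:
        struct = ndimage.generate_binary_structure(3, 1)
        touching = ndimage.binary_dilation(stroke, structure=struct) & ventricles
        if not touching.any():
            raise ValueError("default lesion placement failed to touch the ventricle")
    return LabeledPhantom(labels=labels, grid=grid)


def tissue_timecourse(
    params: TissueParams,
    protocol: InhalationProtocol,
    times_min: np.ndarray,
) -> np.ndarray:
    """Piecewise-linear three-phase H2-17O concentration at ``times_min``.

    Constant at ``baseline`` up to the first switch, linear rise at the
    uptake rate during inhalation, linear evolution at the post rate
    afterwards; continuous at both switches and clipped at zero.
    """
    t = np.asarray(times_min, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    if np.any(t < 0) or np.any(t > protocol.total_min):
        raise ValueError("times must lie within [0, total duration]")
    t1, t2 = protocol.t1_min, protocol.t2_min
    plateau = params.baseline + params.uptake_rate_per_min * (t2 - t1)
    c = np.where(
        t <= t1,
        params.baseline,
        np.where(
            t <= t2,
            params.baseline + params.uptake_rate_per_min * (t - t1),
            plateau + params.post_rate_per_min * (t - t2),
        ),
    )
    return np.maximum(c, 0.0)


def dynamic_image(
    phantom: LabeledPhantom,
    tissue_table: dict[Label, TissueParams],
    protocol: InhalationProtocol,
    t_min: float,
) -> np.ndarray:
    """3D concentration map at time ``t_min`` (background stays zero)."""
    out = np.zeros(phantom.grid.shape, dtype=float)
    present = np.unique(phantom.labels)
    for lab in present:
        if lab == int(Label.BACKGROUND):
            continue
        label = Label(lab)
        if label not in tissue_table:
            raise KeyError(f"tissue table has no entry for label {label.name}")
        value = tissue_timecourse(tissue_table[label], protocol, np.array([t_min]))[0]
        out[phantom.labels == lab] = value
    return out
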