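"""Density-adapted 3D radial oxygen-17 acquisition simulator.

Models a spoiled steady-state, centre-out 3D radial readout of the kind
used for X-nuclei imaging at ultra-high field.  Each spoke starts at the
k-space centre and follows a shared radius schedule k(t): linear during an
initial gradient-ramp segment, then "density adapted" so that the sample
density falls as 1/k^2 and the density-compensation weights stay flat at
high spatial frequencies.  The default sequence parameters are the 7 T
oxygen-17 protocol values: TE/TR = 0.56/20 ms, flip 60 deg, 1 ms pulse,
5.5 ms readout, (7.5 mm)^3 nominal resolution, 90000 projections
(30 min of data at one spoke per TR).

The signal model is a steady-state amplitude times mono-exponential T2*
decay along the readout times the spatial Fourier transform of the
per-tissue concentration map, summed over tissues, plus circular complex
Gaussian noise.  B0/B1 inhomogeneity and flow are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nufft import GriddingPlan
from .grids import GridSpec
from .phantom import InhalationProtocol, Label, LabeledPhantom, TissueParams, tissue_timecourse

__all__ = [
    "SequenceParams",
    "RadialTrajectory",
    "KSpaceSeries",
    "steady_state_weight",
    "golden_directions",
    "make_da_radial_trajectory",
    "simulate_kspace",
]

log = logging.getLogger(__name__)

# 2D golden means driving the spherical spoke ordering; consecutive spokes
# (and therefore every contiguous window of spokes) cover the sphere
# near-uniformly.
_GOLDEN_1 = 0.4656476265463405
_GOLDEN_2 = 0.6823278038280193


@dataclass(frozen=True)
class SequenceParams:
    """Printed pulse-sequence parameters of the dynamic 17O protocol."""

    te_ms: float = 0.56
    tr_ms: float = 20.0
    flip_deg: float = 60.0
    t_pulse_ms: float = 1.0
    readout_ms: float = 5.5
    nominal_resolution_mm: float = 7.5
    n_projections: int = 90000
    samples_per_spoke: int = 64

    def __post_init__(self) -> None:
        if not self.te_ms < self.tr_ms:
            raise ValueError("TE must be shorter than TR")
        if self.te_ms + self.readout_ms > self.tr_ms:
            raise ValueError("readout must finish within TR")
        if self.n_projections <= 0:
            raise ValueError("need at least one projection")
        if self.samples_per_spoke < 2:
            raise ValueError("need at least two samples per spoke")

    @property
    def kmax_per_mm(self) -> float:
        """Nyquist radius 1/(2 * nominal resolution)."""
        return 1.0 / (2.0 * self.nominal_resolution_mm)


def steady_state_weight(flip_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Spoiled steady-state amplitude sin(a)(1-E1)/(1-cos(a)E1), E1=e^-TR/T1."""
    if not 0.0 < flip_deg <= 180.0:
        raise ValueError("flip angle must lie in (0, 180] degrees")
    if not t1_ms > 0:
        raise ValueError("T1 must be positive")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return float(np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1))


def golden_directions(n: int, mirror_pairs: bool = True) -> np.ndarray:
    """``(n, 3)`` unit spoke directions.

    Low-discrepancy spherical scheme driven by the two-dimensional golden
    means, so every contiguous block of spokes is itself near-uniform on
    the sphere (what a sliding-window reconstruction needs).  With
    ``mirror_pairs`` each odd spoke is the exact left-right (axis 0)
    reflection of the preceding even spoke, making the sampling pattern
    symmetric about the midsagittal plane.
    """
    if n <= 0:
        raise ValueError("need at least one direction")
    if mirror_pairs:
        m = (n + 1) // 2
        base = golden_directions(m, mirror_pairs=False)
        out = np.empty((2 * m, 3))
        out[0::2] = base
        out[1::2] = base * np.array([-1.0, 1.0, 1.0])
        return out[:n]
    i = np.arange(n)
    z = 2.0 * ((i * _GOLDEN_1) % 1.0) - 1.0
    phi = 2.0 * np.pi * ((i * _GOLDEN_2) % 1.0)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class RadialTrajectory:
    """Spoke directions plus the shared density-adapted radius schedule.

    ``sample_times_ms`` are offsets from TE along the readout;
    ``radii_per_mm`` is k(t) with ``radii_per_mm[-1] == kmax_per_mm``;
    ``radial_speed`` is dk/dt, used for closed-form density compensation.
    """

    directions: np.ndarray
    sample_times_ms: np.ndarray
    radii_per_mm: np.ndarray
    radial_speed: np.ndarray
    kmax_per_mm: float

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]

    @property
    def samples_per_spoke(self) -> int:
        return self.radii_per_mm.size

    def points_per_mm(self, spoke_indices: np.ndarray | slice | None = None) -> np.ndarray:
        """``(n_spokes * S, 3)`` k-space points in 1/mm, spoke-major."""
        d = self.directions if spoke_indices is None else self.directions[spoke_indices]
        return (d[:, None, :] * self.radii_per_mm[None, :, None]).reshape(-1, 3)

    def density_weights(self) -> np.ndarray:
        """Per-sample radial quadrature weight k^2 dk/dt dt (unnormalised).

        Proportional to k^2 in the linear ramp and constant in the
        density-adapted segment, where the 1/k^2 sample density already
        equalises the k-space measure.  Endpoint samples get trapezoid
        half-weights.
        """
        dt = np.gradient(self.sample_times_ms)
        w = self.radii_per_mm**2 * self.radial_speed * dt
        w[0] *= 0.5
        w[-1] *= 0.5
        return w


def make_da_radial_trajectory(
    seq: SequenceParams,
    t0_fraction: float = 0.3,
    n_spokes: int | None = None,
    mirror_pairs: bool = True,
) -> RadialTrajectory:
    """Build the two-segment density-adapted radial trajectory.

    k(t) is linear on [0, t0] with t0 = ``t0_fraction`` * readout and
    follows k(t) = (k0^3 + c (t - t0))^(1/3) beyond, with c fixed by
    continuity of dk/dt at t0.  The overall slope is solved in closed form
    so that k(readout end) equals the Nyquist radius 1/(2 * resolution).
    """
    if not 0.0 < t0_fraction < 1.0:
        raise ValueError("t0_fraction must lie in (0, 1)")
    t_ro = seq.readout_ms
    t0 = t0_fraction * t_ro
    kmax = seq.kmax_per_mm
    # kmax^3 = s^3 t0^2 (3 t_ro - 2 t0)  =>  s
    s = kmax / (t0**2 * (3.0 * t_ro - 2.0 * t0)) ** (1.0 / 3.0)
    k0 = s * t0
    c = 3.0 * k0**2 * s
    t = np.linspace(0.0, t_ro, seq.samples_per_spoke)
    lin = t <= t0
    k = np.where(lin, s * t, (k0**3 + c * np.maximum(t - t0, 0.0)) ** (1.0 / 3.0))
    speed = np.where(lin, s, c / (3.0 * np.maximum(k, 1e-30) ** 2))
    k[-1] = kmax  # guard against rounding in the cube root
    n = seq.n_projections if n_spokes is None else int(n_spokes)
    return RadialTrajectory(
        directions=golden_directions(n, mirror_pairs=mirror_pairs),
        sample_times_ms=t,
        radii_per_mm=k,
        radial_speed=speed,
        kmax_per_mm=kmax,
    )


@dataclass(frozen=True)
class KSpaceSeries:
    """Time-ordered radial k-space data of one dynamic experiment."""

    samples: np.ndarray  # (n_spokes, samples_per_spoke) complex
    timestamps_s: np.ndarray  # per-spoke acquisition time from scan start
    trajectory: RadialTrajectory
    sequence: SequenceParams
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.samples.shape != (
            self.trajectory.n_spokes,
            self.trajectory.samples_per_spoke,
        ):
            raise ValueError("sample array does not match the trajectory")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("spoke timestamps must be strictly increasing")


def _relaxation_decay(seq: SequenceParams, traj: RadialTrajectory, t2star_ms: float) -> np.ndarray:
    return np.exp(-(seq.te_ms + traj.sample_times_ms) / t2star_ms)


def simulate_kspace(
    phantom: LabeledPhantom,
    tissue_table: dict[Label, TissueParams],
    protocol: InhalationProtocol,
    traj: RadialTrajectory,
    seq: SequenceParams,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    granularity_min: float = 1.0,
) -> KSpaceSeries:
    """Simulate the dynamic radial acquisition of the phantom.

    Spoke ``n`` is acquired at ``n * TR``.  The phantom concentration is
    held piecewise-constant over ``granularity_min`` intervals (evaluated
    at the interval midpoint), matching the one-minute frame rate of the
    sliding-window reconstruction.  Each sample is the sum over tissues of
    steady-state weight x T2* readout decay x the tissue mask's Fourier
    transform scaled by its current concentration, plus circular complex
    Gaussian noise of standard deviation ``noise_sd`` per channel.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    grid = phantom.grid
    if not grid.is_cubic():
        raise ValueError("simulation requires a cubic grid")
    nu_halfspan = traj.kmax_per_mm * grid.fov_mm[0]
    if nu_halfspan > grid.shape[0] / 2 + 1e-9:
        raise ValueError("trajectory k_max exceeds the grid Nyquist limit")

    n_spokes, n_samp = traj.n_spokes, traj.samples_per_spoke
    timestamps = np.arange(n_spokes) * seq.tr_ms / 1000.0
    labels = [lab for lab in phantom.masks]
    for lab in labels:
        if lab not in tissue_table:
            raise KeyError(f"tissue table has no entry for label {lab.name}")
    decays = {
        lab: steady_state_weight(seq.flip_deg, seq.tr_ms, tissue_table[lab].t1_ms)
        * _relaxation_decay(seq, traj, tissue_table[lab].t2star_ms)
        for lab in labels
    }
    masks = {lab: phantom.mask(lab).astype(float) for lab in labels}

    samples = np.zeros((n_spokes, n_samp), dtype=complex)
    block_s = granularity_min * 60.0
    block_ids = np.floor(timestamps / block_s).astype(int)
    fov = grid.fov_mm[0]
    for b in np.unique(block_ids):
        spokes = np.nonzero(block_ids == b)[0]
        nu = traj.points_per_mm(spokes) * fov
        plan = GriddingPlan(nu, grid.shape)
        t_mid = (b + 0.5) * granularity_min
        t_mid = min(t_mid, protocol.total_min)
        block = np.zeros((spokes.size, n_samp), dtype=complex)
        for lab in labels:
            conc = tissue_timecourse(tissue_table[lab], protocol, np.array([t_mid]))[0]
            if conc == 0.0:
                continue
            spec = plan.forward(masks[lab]).reshape(spokes.size, n_samp)
            block += conc * decays[lab][None, :] * spec
        samples[spokes] = block

    seed_out: int | None
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, samples.shape) + 1j * rng.normal(
            0.0, noise_sd, samples.shape
        )
        samples = samples + noise
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return KSpaceSeries(
        samples=samples,
        timestamps_s=timestamps,
        trajectory=traj,
        sequence=seq,
        noise_sd=noise_sd,
        seed=seed_out,
    )
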