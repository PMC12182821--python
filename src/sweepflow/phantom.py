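"""Digital pulsatile-flow phantom of a thorax-like volume.

The phantom stands in for a pediatric chest: an elliptical "body" of static
tissue surrounded by air, a low-signal lung region, and a set of tubular
vessels carrying pulsatile laminar flow along the slice (z) axis, optionally
with a bifurcation that splits parental flow between two children.  It
provides time-resolved ground truth (magnitude, 3-component velocity, class
labels) on a regular 3D grid, plus a quasi-periodic cardiac trigger train
for retrospective gating.

Velocity profile is Poiseuille (parabolic): v(r) = v_c * (1 - (r/R)^2) along
the local centreline tangent, scaled by a periodic waveform of the cardiac
phase.  The closed-form lumen flow pi*R^2*v_c/2 of this profile is the
analytic oracle used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# label codes
LABEL_AIR = 0
LABEL_TISSUE = 1
LABEL_LUNG = 2
LABEL_LUMEN_BASE = 3  # vessel i -> LABEL_LUMEN_BASE + i

# relative proton-density-like base magnitudes (arbitrary units)
MAG_BLOOD = 1.0
MAG_TISSUE = 1.0
MAG_LUNG = 0.15  # low-signal parenchyma so lumen/lung CNR is measurable
MAG_AIR = 0.0


class PhantomOverlapError(ValueError):
    """Two unrelated vessels claim the same voxels with different velocities."""


@dataclass(frozen=True)
class VesselSpec:
    """A tubular vessel segment with laminar pulsatile flow.

    centerline : sequence of 3D points (mm, phantom physical coordinates).
    radius_mm : lumen radius.
    peak_velocity_cm_s : systolic centreline speed; ignored (recomputed from
        the parent's flow) when ``branch_of`` is given.
    waveform : "steady" or "pulse"; "pulse" is a raised-cosine systolic pulse
        over a diastolic baseline (see :func:`waveform_factor`).
    waveform_params : parameters of the waveform family.
    branch_of : optional (parent vessel name, flow split fraction).
    """

    name: str
    centerline: Sequence[Sequence[float]]
    radius_mm: float
    peak_velocity_cm_s: float
    waveform: str = "steady"
    waveform_params: dict = field(default_factory=dict)
    branch_of: Optional[tuple] = None


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple = (64, 64, 48)
    voxel_size_mm: float = 1.2
    cardiac_period_ms: float = 800.0  # plausible pediatric R-R
    rr_jitter_frac: float = 0.03
    vessels: Sequence[VesselSpec] = ()
    t1_blood_ms: float = 1600.0
    t1_tissue_ms: float = 900.0
    # 2nd-order in-plane phase field, radians:
    # c0 + c1*x + c2*y + c3*x^2 + c4*x*y + c5*y^2  with x, y in mm
    background_phase_coeffs: Sequence[float] = (0.0,) * 6

    def __post_init__(self):
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape entries must all be >= 8")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.cardiac_period_ms <= 0:
            raise ValueError("cardiac_period_ms must be > 0")
        if not 0.0 <= self.rr_jitter_frac <= 0.2:
            raise ValueError("rr_jitter_frac must lie in [0, 0.2]")
        for v in self.vessels:
            if v.radius_mm < 2.0 * self.voxel_size_mm:
                raise ValueError(
                    f"vessel {v.name!r}: radius_mm must be >= 2*voxel_size_mm"
                )

    @property
    def fov_mm(self):
        return tuple(n * self.voxel_size_mm for n in self.grid_shape)


@dataclass
class FlowPhantom:
    """Ground-truth dynamic phantom.

    magnitude : (nx, ny, nz, n_phases) base signal magnitude (a.u.).
    velocity : (3, nx, ny, nz, n_phases) velocity in cm/s, components (x, y, z).
    labels : (nx, ny, nz) integer class map.
    phases : (n_phases,) cardiac-phase sample points in [0, 1).
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    labels: np.ndarray
    voxel_size_mm: float
    phases: np.ndarray
    config: PhantomConfig

    @property
    def grid_shape(self):
        return self.labels.shape

    @property
    def n_phases(self) -> int:
        return self.phases.size

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.grid_shape[axis]
        return (np.arange(n) - n // 2) * self.voxel_size_mm

    @property
    def z_extent_mm(self):
        z = self.axis_coords(2)
        return float(z[0]), float(z[-1])

    def phase_index(self, phase: float) -> int:
        """Nearest stored phase (cyclic)."""
        return int(np.round((phase % 1.0) * self.n_phases)) % self.n_phases

    def at_phase(self, phase: float):
        """Magnitude and velocity cyclically interpolated at an arbitrary phase."""
        p = (phase % 1.0) * self.n_phases
        i0 = int(np.floor(p)) % self.n_phases
        i1 = (i0 + 1) % self.n_phases
        w = p - np.floor(p)
        mag = (1 - w) * self.magnitude[..., i0] + w * self.magnitude[..., i1]
        vel = (1 - w) * self.velocity[..., i0] + w * self.velocity[..., i1]
        return mag, vel

    def lumen_mask(self, vessel_name: str) -> np.ndarray:
        idx = [v.name for v in self.config.vessels].index(vessel_name)
        return self.labels == LABEL_LUMEN_BASE + idx

    def background_phase_map(self) -> np.ndarray:
        """The injected in-plane phase field, radians, shape (nx, ny)."""
        x = self.axis_coords(0)
        y = self.axis_coords(1)
        return evaluate_background_phase(self.config.background_phase_coeffs, x, y)


def evaluate_background_phase(coeffs, x, y) -> np.ndarray:
    c = np.asarray(coeffs, dtype=float)
    if c.size != 6:
        raise ValueError("background_phase_coeffs must have 6 entries")
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return c[0] + c[1] * xx + c[2] * yy + c[3] * xx**2 + c[4] * xx * yy + c[5] * yy**2


def waveform_factor(name: str, params: dict, phase) -> np.ndarray:
    """Periodic velocity scale factor in [0, 1] with peak value 1.

    "steady": constant 1.
    "pulse": diastolic baseline ``baseline`` plus a raised-cosine systolic
    pulse of half-width ``width`` centred at ``peak_phase`` (cyclic).
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    if name == "steady":
        return np.ones_like(phase)
    if name == "pulse":
        baseline = float(params.get("baseline", 0.2))
        peak_phase = float(params.get("peak_phase", 0.25))
        width = float(params.get("width", 0.35))
        d = np.abs(((phase - peak_phase + 0.5) % 1.0) - 0.5)
        pulse = np.where(d < width / 2, 0.5 * (1 + np.cos(2 * np.pi * d / width)), 0.0)
        return baseline + (1.0 - baseline) * pulse
    raise ValueError(f"unknown waveform {name!r}")


def waveform_mean(name: str, params: dict, n: int = 512) -> float:
    """Cycle-average of the waveform factor."""
    return float(np.mean(waveform_factor(name, params, np.arange(n) / n)))


def analytic_mean_flow_ml_s(radius_mm: float, peak_velocity_cm_s: float,
                            waveform: str = "steady", waveform_params: dict | None = None) -> float:
    """Cycle-averaged volumetric flow of a Poiseuille tube, in mL/s.

    Instantaneous flow is pi*R^2*v_c/2; 1 cm/s * 1 mm^2 = 0.01 mL/s.
    """
    q_peak = np.pi * radius_mm**2 * peak_velocity_cm_s / 2.0 / 100.0
    return q_peak * waveform_mean(waveform, waveform_params or {})


def _segment_geometry(points: np.ndarray, coords: np.ndarray):
    """Distance to a polyline and local tangent for a cloud of points.

    points : (M, 3) centreline vertices.  coords : (N, 3) query points.
    Returns (dist (N,), tangent (N, 3), axial_pos (N,)).
    """
    best_d2 = np.full(coords.shape[0], np.inf)
    tangent = np.zeros_like(coords)
    for p0, p1 in zip(points[:-1], points[1:]):
        seg = p1 - p0
        L2 = float(seg @ seg)
        t = np.clip((coords - p0) @ seg / L2, 0.0, 1.0)
        proj = p0 + t[:, None] * seg
        d2 = ((coords - proj) ** 2).sum(axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        tangent[closer] = seg / np.sqrt(L2)
    return np.sqrt(best_d2), tangent


def resolve_peak_velocities(vessels: Sequence[VesselSpec]) -> dict:
    """Centreline peak velocities with bifurcation flow splits applied.

    A child with ``branch_of = (parent, f)`` carries f of the parent's flow:
    v_child = 2 * f * Q_parent / (pi * R_child^2).  Split fractions of the
    children of one parent must sum to 1.
    """
    by_name = {v.name: v for v in vessels}
    peaks: dict[str, float] = {}

    def peak_of(v: VesselSpec) -> float:
        if v.name in peaks:
            return peaks[v.name]
        if v.branch_of is None:
            peaks[v.name] = float(v.peak_velocity_cm_s)
        else:
            parent_name, frac = v.branch_of
            parent = by_name[parent_name]
            q_parent = np.pi * parent.radius_mm**2 * peak_of(parent) / 2.0
            peaks[v.name] = float(2.0 * frac * q_parent / (np.pi * v.radius_mm**2))
        return peaks[v.name]

    for v in vessels:
        peak_of(v)

    children: dict[str, float] = {}
    for v in vessels:
        if v.branch_of is not None:
            children[v.branch_of[0]] = children.get(v.branch_of[0], 0.0) + v.branch_of[1]
    for parent, total in children.items():
        if not np.isclose(total, 1.0):
            raise ValueError(f"flow split fractions of children of {parent!r} sum to {total}, not 1")
    return peaks


def _related(a: VesselSpec, b: VesselSpec) -> bool:
    pa = a.branch_of[0] if a.branch_of else None
    pb = b.branch_of[0] if b.branch_of else None
    return pa == b.name or pb == a.name or (pa is not None and pa == pb)


def build_phantom(config: PhantomConfig, n_phases: int) -> FlowPhantom:
    """Rasterise the phantom onto its grid at ``n_phases`` cardiac phases.

    Phases are sampled at j/n_phases, j = 0..n_phases-1; all fields are
    periodic in the cardiac phase by construction.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    nx, ny, nz = config.grid_shape
    vox = config.voxel_size_mm
    x = (np.arange(nx) - nx // 2) * vox
    y = (np.arange(ny) - ny // 2) * vox
    z = (np.arange(nz) - nz // 2) * vox
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    coords = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)

    labels = np.full((nx, ny, nz), LABEL_AIR, dtype=np.int16)

    # body: elliptical cylinder of tissue spanning all z
    fovx, fovy, _ = config.fov_mm
    body = (xx / (0.45 * fovx)) ** 2 + (yy / (0.42 * fovy)) ** 2 <= 1.0
    labels[body] = LABEL_TISSUE

    # lung: smaller off-centre elliptical cylinder inside the body
    lung = ((xx - 0.22 * fovx) / (0.14 * fovx)) ** 2 + (yy / (0.20 * fovy)) ** 2 <= 1.0
    labels[lung & body] = LABEL_LUNG

    peaks = resolve_peak_velocities(config.vessels)
    phases = np.arange(n_phases) / n_phases

    # per-vessel static fields: peak velocity vector and lumen mask
    v_peak_fields = []
    owner = np.full(labels.size, -1, dtype=int)
    for i, spec in enumerate(config.vessels):
        pts = np.asarray(spec.centerline, dtype=float)
        dist, tang = _segment_geometry(pts, coords)
        inside = dist <= spec.radius_mm
        profile = np.where(inside, 1.0 - (dist / spec.radius_mm) ** 2, 0.0)
        vfield = (peaks[spec.name] * profile)[:, None] * tang  # (N, 3) cm/s
        clash = inside & (owner >= 0)
        if np.any(clash):
            for j in np.unique(owner[clash]):
                other = config.vessels[int(j)]
                prev = v_peak_fields[int(j)]
                if not _related(spec, other) and not np.allclose(
                    prev[clash & (owner == j)], vfield[clash & (owner == j)], atol=1e-9
                ):
                    raise PhantomOverlapError(
                        f"vessels {spec.name!r} and {other.name!r} overlap with inconsistent velocities"
                    )
        owner[inside] = i
        v_peak_fields.append(vfield)

    # assign each lumen voxel to its owning vessel (later vessels win ties at
    # junctions of related vessels, matching the child-overrides-parent rule)
    for i, spec in enumerate(config.vessels):
        mask = (owner == i).reshape(nx, ny, nz)
        labels[mask] = LABEL_LUMEN_BASE + i

    base_mag = np.select(
        [labels == LABEL_AIR, labels == LABEL_TISSUE, labels == LABEL_LUNG],
        [MAG_AIR, MAG_TISSUE, MAG_LUNG],
        default=MAG_BLOOD,
    )

    magnitude = np.repeat(base_mag[..., None], n_phases, axis=-1).astype(np.float32)
    velocity = np.zeros((3, nx, ny, nz, n_phases), dtype=np.float32)
    for i, spec in enumerate(config.vessels):
        mask_flat = owner == i
        if not np.any(mask_flat):
            continue
        w = waveform_factor(spec.waveform, spec.waveform_params, phases)  # (n_phases,)
        vf = v_peak_fields[i][mask_flat]  # (M, 3)
        contrib = vf[:, :, None] * w[None, None, :]  # (M, 3, n_phases)
        mask3 = mask_flat.reshape(nx, ny, nz)
        for c in range(3):
            velocity[c, mask3, :] = contrib[:, c, :]

    return FlowPhantom(
        magnitude=magnitude,
        velocity=velocity,
        labels=labels,
        voxel_size_mm=vox,
        phases=phases,
        config=config,
    )


def inflow_signal(
    through_plane_speed: float,
    slice_thickness_mm: float,
    tr_ms: float,
    flip_deg: float,
    t1_ms: float,
) -> float:
    """Relative spoiled-gradient-echo signal with inflow enhancement.

    Closed-form time-of-flight model for plug flow through the slice.  A
    spin at depth d into the slice has experienced n(d) = d/(speed*TR) RF
    pulses since entering; its longitudinal magnetisation has relaxed from
    fully recovered toward the steady state M_ss = (1-E1)/(1-cos(a)*E1) as

        M(n) = M_ss + (1 - M_ss) * (cos(a)*E1)**n,      E1 = exp(-TR/T1).

    Averaging over depth (n from 0 to N = thickness/(speed*TR)) gives

        S = sin(a) * [ M_ss + (1 - M_ss) * (r**N - 1)/(N*ln r) ],  r = cos(a)*E1,

    which recovers the static steady state as speed -> 0 (N -> inf) and the
    fully-relaxed signal sin(a) as speed -> inf (N -> 0), and is monotone
    non-decreasing in speed.  A single-TR "replaced fraction" interpolation
    would be wrong here: slow through-plane flow still fills the slice with
    recently entered, lightly saturated spins, so its signal stays far above
    the static steady state — which matters for the temporal magnitude
    contrast seen by the CINE reconstruction.
    """
    for val, name in [
        (slice_thickness_mm, "slice_thickness_mm"),
        (tr_ms, "tr_ms"),
        (flip_deg, "flip_deg"),
        (t1_ms, "t1_ms"),
    ]:
        if np.any(np.asarray(val) <= 0):
            raise ValueError(f"{name} must be > 0")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    r = np.cos(a) * e1
    log_r = np.log(r)
    m_ss = (1 - e1) / (1 - r)
    speed_mm_per_ms = np.abs(np.asarray(through_plane_speed, dtype=float)) * 0.01
    with np.errstate(divide="ignore", over="ignore", under="ignore", invalid="ignore"):
        n_pulses = slice_thickness_mm / (speed_mm_per_ms * tr_ms)
        frac = np.where(
            np.isfinite(n_pulses),
            -np.expm1(n_pulses * log_r) / (n_pulses * (-log_r)),
            0.0,
        )
    frac = np.where(speed_mm_per_ms == 0, 0.0, frac)
    out = np.sin(a) * (m_ss + (1 - m_ss) * frac)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class TriggerTrain:
    """Cardiac trigger (R-peak) times in ms, strictly increasing from 0."""

    r_peak_times_ms: np.ndarray

    @property
    def span_ms(self) -> float:
        return float(self.r_peak_times_ms[-1])

    @property
    def mean_rr_ms(self) -> float:
        return float(np.mean(np.diff(self.r_peak_times_ms)))


def sample_triggers(config: PhantomConfig, duration_ms: float, seed: int) -> TriggerTrain:
    """Draw a quasi-periodic trigger train covering [0, duration_ms].

    R-R intervals are i.i.d. normal with mean ``cardiac_period_ms`` and SD
    ``rr_jitter_frac * cardiac_period_ms``, truncated at +/- 3.9 SD so every
    interval stays within period*(1 +/- 4*jitter).
    """
    if duration_ms <= 2 * config.cardiac_period_ms:
        raise ValueError("duration_ms must exceed 2*cardiac_period_ms")
    rng = np.random.default_rng(seed)
    period = config.cardiac_period_ms
    sd = config.rr_jitter_frac * period
    times = [0.0]
    while times[-1] < duration_ms:
        iv = rng.normal(period, sd) if sd > 0 else period
        iv = float(np.clip(iv, period - 3.9 * sd, period + 3.9 * sd))
        times.append(times[-1] + iv)
    return TriggerTrain(r_peak_times_ms=np.asarray(times))
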