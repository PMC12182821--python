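"""Golden-angle spiral trajectory and SWEEP slice-position scheduling.

The acquisition plays out one spiral arm per TR.  Each TR the arm is rotated
by the golden angle (360/phi^2 degrees), the velocity-encoding direction
cycles through (V_o, V_TP, V_X, V_Y), and the excited slice centre moves a
small constant step along z ("SWEEP").  Any contiguous block of TRs therefore
carries a near-uniform azimuthal spread of arms, a balanced set of flow
encodings, and a narrow band of slice positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 360 / phi**2 with phi the golden ratio.
GOLDEN_ANGLE_DEG = 360.0 / ((1.0 + np.sqrt(5.0)) / 2.0) ** 2

#: Encoding order per TR: flow-compensated, through-plane, in-plane x, in-plane y.
ENCODING_NAMES = ("V_o", "V_TP", "V_X", "V_Y")


@dataclass(frozen=True)
class SpiralArm:
    """A single unrotated spiral readout.

    k_samples : (n, 2) array, cycles/mm, starting at the k-space origin.
    sample_times_ms : (n,) array, time of each sample after excitation.
    n_turns : number of revolutions of the arm (design parameter).
    """

    k_samples: np.ndarray
    sample_times_ms: np.ndarray
    n_turns: float

    @property
    def n_samples(self) -> int:
        return self.k_samples.shape[0]

    @property
    def k_max(self) -> float:
        return float(np.hypot(self.k_samples[:, 0], self.k_samples[:, 1]).max())

    def rotated(self, angle_deg: float) -> np.ndarray:
        """k-space coordinates of the arm rotated by ``angle_deg``."""
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[c, -s], [s, c]])
        return self.k_samples @ rot.T

    def density_weights(self) -> np.ndarray:
        """Relative sample-density compensation along the arm.

        For a uniform-rate Archimedean arm (|k| linear in sample index) the
        annulus area associated with each sample grows linearly with radius,
        so weights proportional to |k| (with a small floor at the origin)
        compensate the centre oversampling.  Normalised to unit mean.
        """
        r = np.hypot(self.k_samples[:, 0], self.k_samples[:, 1])
        dr = self.k_max / max(self.n_samples - 1, 1)
        w = np.maximum(r, 0.5 * dr)
        return w / w.mean()


def design_spiral(
    fov_mm: float,
    resolution_mm: float,
    n_samples: int,
    readout_ms: float,
    n_turns: float = 0.5,
) -> SpiralArm:
    """Design a uniform-rate Archimedean spiral arm.

    The arm starts at k = 0 and reaches ``k_max = 1/(2*resolution_mm)`` with
    |k| increasing linearly along the readout; azimuthal angle advances by
    ``n_turns`` revolutions.  Hardware (slew/amplitude) constraints are not
    modelled.
    """
    if not resolution_mm < fov_mm:
        raise ValueError("resolution_mm must be smaller than fov_mm")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    k_max = 1.0 / (2.0 * resolution_mm)
    tau = np.linspace(0.0, 1.0, n_samples)
    r = k_max * tau
    theta = 2.0 * np.pi * n_turns * tau
    k = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    times = readout_ms * tau
    return SpiralArm(k_samples=k, sample_times_ms=times, n_turns=float(n_turns))


def nyquist_arm_count(grid_size: int, n_turns: float) -> int:
    """Arms per frame for radial Nyquist sampling of ``grid_size`` pixels.

    Interleaving M arms of an Archimedean spiral with ``n_turns`` turns gives
    an effective inter-turn spacing of k_max/(M*n_turns); matching the 1/FOV
    Nyquist spacing requires M*n_turns >= grid_size/2.
    """
    return int(np.ceil(grid_size / (2.0 * n_turns)))


@dataclass(frozen=True)
class TRSchedule:
    """Per-TR acquisition bookkeeping for the SWEEP acquisition."""

    index: np.ndarray
    rotation_deg: np.ndarray
    slice_z_mm: np.ndarray
    encoding_index: np.ndarray
    time_ms: np.ndarray
    tr_ms: float
    shift_per_tr_mm: float
    golden_angle_deg: float = field(default=GOLDEN_ANGLE_DEG)

    def __len__(self) -> int:
        return self.index.size

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.index,
                "rotation_deg": self.rotation_deg,
                "slice_z_mm": self.slice_z_mm,
                "encoding_index": self.encoding_index,
                "encoding": [ENCODING_NAMES[i] for i in self.encoding_index],
                "time_ms": self.time_ms,
            }
        )


def build_schedule(
    n_tr: int,
    tr_ms: float,
    z_start_mm: float,
    shift_per_tr_mm: float,
    golden_angle_deg: float = GOLDEN_ANGLE_DEG,
) -> TRSchedule:
    """Build the per-TR schedule: golden-angle rotation, SWEEP z, encoding cycle.

    TR ``i`` excites at ``z_start + i*shift``, rotated by ``i*golden_angle``
    (mod 360), with encoding ``i mod 4`` in the order V_o, V_TP, V_X, V_Y.
    """
    if n_tr < 4:
        raise ValueError("n_tr must be >= 4")
    idx = np.arange(n_tr)
    return TRSchedule(
        index=idx,
        rotation_deg=(idx * golden_angle_deg) % 360.0,
        slice_z_mm=z_start_mm + idx * shift_per_tr_mm,
        encoding_index=idx % 4,
        time_ms=idx * tr_ms,
        tr_ms=float(tr_ms),
        shift_per_tr_mm=float(shift_per_tr_mm),
        golden_angle_deg=float(golden_angle_deg),
    )
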