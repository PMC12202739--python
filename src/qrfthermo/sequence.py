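"""Sequence definitions for quadratic-RF-phase MR fingerprinting thermometry.

The qRF-MRF sequence is a continuous balanced acquisition with a constant
low flip angle and an RF excitation phase that grows quadratically with the
TR index, ``phi[n] = c * n**2`` degrees.  Sampling that quadratic phase at
the TR period corresponds to an effective resonance frequency that sweeps
linearly between -1/(2 TR) and +1/(2 TR) Hz with period ``180/c`` TRs, which
is what encodes off-resonance (and hence PRF temperature shift) into the
signal timecourse.  This module owns the sequence parameterization, the
phase/frequency schedule, the spiral sampling trajectory, and the spoiled
2DFT GRE comparator parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SequenceParams",
    "GreParams",
    "Trajectory",
    "quadratic_phase",
    "sweep_frequency",
    "sweep_period",
    "ernst_angle",
    "make_spiral_trajectory",
]


@dataclass(frozen=True)
class SequenceParams:
    """Timing, flip and phase parameters of the qRF-MRF sequence.

    Parameters
    ----------
    tr_s : float
        Repetition time in seconds.  The unaliased frequency band is
        ``[-1/(2 tr_s), +1/(2 tr_s))``.
    te_s : float
        Echo time (excitation to sample) in seconds.
    flip_deg : float
        Constant excitation flip angle in degrees; kept low to desensitize
        the signal to T1/T2.
    quad_coeff_deg : float
        Quadratic phase coefficient ``c`` in degrees per TR-index squared.
    n_tr : int
        Total number of TRs simulated / acquired.
    n_interleaves : int
        Number of spiral interleaves; TR ``n`` plays interleaf
        ``n % n_interleaves``.
    readout_s, dwell_s : float
        Spiral readout duration and receiver dwell time in seconds.
    """

    tr_s: float = 0.010
    te_s: float = 0.0018
    flip_deg: float = 10.0
    quad_coeff_deg: float = 4.2
    n_tr: int = 660
    n_interleaves: int = 12
    readout_s: float = 0.006
    dwell_s: float = 2e-6

    def __post_init__(self) -> None:
        if not (self.tr_s > self.te_s > 0):
            raise ValueError("require tr_s > te_s > 0")
        if not (0 <= self.flip_deg <= 90):
            raise ValueError("flip_deg must lie in [0, 90]")
        if self.quad_coeff_deg <= 0:
            raise ValueError("quad_coeff_deg must be positive")
        if self.n_tr < 1:
            raise ValueError("n_tr must be >= 1")
        if self.n_interleaves < 1:
            raise ValueError("n_interleaves must be >= 1")

    @property
    def band_hz(self) -> float:
        """Width of the unaliased frequency band, 1/TR in Hz."""
        return 1.0 / self.tr_s

    @property
    def n_readout(self) -> int:
        """Number of receiver samples per readout."""
        return int(round(self.readout_s / self.dwell_s))


@dataclass(frozen=True)
class GreParams:
    """Cartesian spoiled 2DFT GRE comparator parameters (the conventional
    PRF thermometry benchmark)."""

    tr_s: float = 0.017
    te_s: float = 0.012
    flip_deg: float = 11.6
    bandwidth_hz: float = 40000.0
    matrix: int = 128
    fov_m: float = 0.256

    def __post_init__(self) -> None:
        if not (self.tr_s > self.te_s > 0):
            raise ValueError("require tr_s > te_s > 0")
        if not (0 < self.flip_deg <= 90):
            raise ValueError("flip_deg must lie in (0, 90]")

    @property
    def dwell_s(self) -> float:
        """Receiver dwell time, 1/bandwidth."""
        return 1.0 / self.bandwidth_hz


@dataclass(frozen=True)
class Trajectory:
    """Spiral k-space trajectory shared by all TRs.

    ``coords`` holds one interleaf per row in normalized units of
    cycles/pixel (grid Nyquist at |k| = 0.5); ``dcf`` is the analytic
    annulus-area density compensation weight per sample (identical for every
    interleaf by rotational symmetry).
    """

    coords: np.ndarray  # (n_interleaves, n_samples, 2)
    dcf: np.ndarray  # (n_samples,)
    n_interleaves: int
    matrix: int
    fov_m: float

    def interleaf_order(self, n_tr: int) -> np.ndarray:
        """TR-index -> interleaf-index map (linear acquisition order)."""
        return np.arange(n_tr) % self.n_interleaves

    @property
    def n_samples(self) -> int:
        return self.coords.shape[1]


def quadratic_phase(n, c: float):
    """RF excitation phase ``c * n**2`` degrees, reduced to [0, 360).

    ``n`` may be a scalar TR index or an integer array.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("TR index must be non-negative")
    if not np.issubdtype(n_arr.dtype, np.integer):
        if not np.all(n_arr == np.round(n_arr)):
            raise ValueError("TR index must be integer")
        n_arr = n_arr.astype(np.int64)
    phase = (c * n_arr.astype(np.float64) ** 2) % 360.0
    return phase if phase.ndim else float(phase)


def sweep_period(c: float) -> float:
    """Period of the resonance-frequency sweep in TR indices, 180/c."""
    if c <= 0:
        raise ValueError("quadratic coefficient must be positive")
    return 180.0 / c


def wrap_frequency(f_hz, tr_s: float):
    """Wrap frequencies into the half-open band [-1/(2 TR), +1/(2 TR))."""
    band = 1.0 / tr_s
    return (np.asarray(f_hz, dtype=np.float64) + band / 2) % band - band / 2


def sweep_frequency(n, params: SequenceParams):
    """Effective resonance frequency at TR ``n`` in Hz.

    The instantaneous frequency of the quadratic phase schedule is its
    centered finite difference, ``c*n / (180*TR)`` Hz, wrapped into the
    unaliased band ``[-1/(2 TR), +1/(2 TR))``.
    """
    n_arr = np.asarray(n, dtype=np.float64)
    f = params.quad_coeff_deg * n_arr / (180.0 * params.tr_s)
    out = wrap_frequency(f, params.tr_s)
    return out if out.ndim else float(out)


def ernst_angle(t1_s: float, tr_s: float) -> float:
    """Ernst angle arccos(exp(-TR/T1)) in degrees (spoiled-GRE optimum)."""
    if t1_s <= 0 or tr_s <= 0:
        raise ValueError("T1 and TR must be positive")
    return float(np.degrees(np.arccos(np.exp(-tr_s / t1_s))))


def make_spiral_trajectory(
    params: SequenceParams,
    matrix: int,
    fov_m: float = 0.256,
) -> Trajectory:
    """Build the radially-uniform Archimedean spiral interleaf set.

    One interleaf runs from the k-space center to the grid Nyquist radius
    (0.5 cycles/pixel) at constant radial velocity, with enough turns that
    the full rotated set of ``n_interleaves`` copies meets the Nyquist
    criterion of the reconstruction grid.  TR ``n`` plays interleaf
    ``n % n_interleaves`` (linear order).  Density compensation weights are
    the analytic annulus areas each sample is responsible for.
    """
    if matrix < 16:
        raise ValueError("matrix must be >= 16")
    n_il = params.n_interleaves
    n_samp = params.n_readout
    kmax = 0.5  # cycles/pixel: Nyquist of the recon grid
    # radial spacing of the combined interleaf set must be <= 1/matrix
    n_turns = matrix / (2.0 * n_il)

    t = np.linspace(0.0, 1.0, n_samp)
    radius = kmax * t
    base_angle = 2.0 * np.pi * n_turns * t
    rot = 2.0 * np.pi * np.arange(n_il) / n_il
    angles = base_angle[None, :] + rot[:, None]
    coords = np.stack(
        [radius[None, :] * np.cos(angles), radius[None, :] * np.sin(angles)],
        axis=-1,
    )

    # annulus-area weights for one interleaf reconstructed standalone (the
    # per-TR sliding-window convention): one sample per radial shell of
    # width dr, so weight = shell area
    dr = kmax / (n_samp - 1)
    dcf = 2.0 * np.pi * radius * dr
    dcf[0] = np.pi * (dr / 2.0) ** 2  # center disc
    return Trajectory(
        coords=coords, dcf=dcf, n_interleaves=n_il, matrix=matrix, fov_m=fov_m
    )
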