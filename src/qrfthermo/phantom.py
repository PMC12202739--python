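"""Digital phantoms and synthetic heating scenarios.

Ground-truth voxel parameter maps (M0, T1, T2, T2*, off-resonance
frequency, Gaussian linewidth, temperature change) on a 2D grid, plus the
PRF relation that links temperature change to frequency shift:
df = gamma_bar * alpha * dT * B0, with gamma_bar = 42.577 MHz/T and
alpha = -0.01 ppm/degC for aqueous tissue (so 25 degC of heating at 3 T
shifts the water resonance by about -32 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAMMA_BAR_MHZ_PER_T = 42.577
PRF_COEFF_PPM_PER_C = -0.01

__all__ = [
    "ParameterMaps",
    "HeatingScenario",
    "make_disc_phantom",
    "prf_shift",
    "add_gaussian_hotspot",
    "make_fus_scenario",
    "GAMMA_BAR_MHZ_PER_T",
    "PRF_COEFF_PPM_PER_C",
]


@dataclass
class ParameterMaps:
    """Voxelwise ground-truth maps on an N x N grid (SI units, degC)."""

    m0: np.ndarray
    t1_s: np.ndarray
    t2_s: np.ndarray
    t2star_s: np.ndarray
    freq_hz: np.ndarray
    linewidth_hz: np.ndarray
    temp_c: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.m0.shape
        for name in ("t1_s", "t2_s", "t2star_s", "freq_hz", "linewidth_hz", "temp_c", "mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"map {name} shape mismatch")
        if np.any(self.t2_s[self.mask] > self.t1_s[self.mask]):
            raise ValueError("T2 must not exceed T1 inside the mask")

    @property
    def shape(self) -> tuple:
        return self.m0.shape

    def copy(self) -> "ParameterMaps":
        return ParameterMaps(
            **{
                name: getattr(self, name).copy()
                for name in (
                    "m0",
                    "t1_s",
                    "t2_s",
                    "t2star_s",
                    "freq_hz",
                    "linewidth_hz",
                    "temp_c",
                    "mask",
                )
            }
        )


def prf_shift(
    delta_t_c,
    b0_t: float = 3.0,
    prf_coeff_ppm_per_c: float = PRF_COEFF_PPM_PER_C,
):
    """Frequency shift in Hz for a temperature change in degC.

    df = gamma_bar * alpha * dT * B0; negative for heating with the aqueous
    coefficient alpha = -0.01 ppm/degC.
    """
    out = (
        GAMMA_BAR_MHZ_PER_T
        * 1e6
        * prf_coeff_ppm_per_c
        * 1e-6
        * np.asarray(delta_t_c, dtype=np.float64)
        * b0_t
    )
    return out if out.ndim else float(out)


def make_disc_phantom(
    grid: int = 128,
    diameter_vox: int = 64,
    t1_s: float = 0.825,
    t2_s: float = 0.070,
    t2star_s: float = 0.046,
    linewidth_hz: float = 1.0,
) -> ParameterMaps:
    """Uniform circular object centered on the grid.

    Defaults reproduce the precision-simulation phantom: 64-voxel diameter
    on a 128 x 128 grid, relaxation between grey and white matter at 3 T
    (T1 825 ms, T2 70 ms, T2* 46 ms), uniform 0 Hz frequency map.
    """
    if diameter_vox > grid:
        raise ValueError("diameter cannot exceed grid size")
    c = (grid - 1) / 2.0
    y, x = np.mgrid[0:grid, 0:grid]
    mask = (x - c) ** 2 + (y - c) ** 2 <= (diameter_vox / 2.0) ** 2
    z = np.zeros((grid, grid))
    return ParameterMaps(
        m0=mask.astype(float),
        t1_s=np.full((grid, grid), t1_s),
        t2_s=np.full((grid, grid), t2_s),
        t2star_s=np.full((grid, grid), t2star_s),
        freq_hz=z.copy(),
        linewidth_hz=np.full((grid, grid), linewidth_hz),
        temp_c=z.copy(),
        mask=mask,
    )


def add_gaussian_hotspot(
    maps: ParameterMaps,
    peak_c: float = 25.0,
    fwhm_vox: float = 16.0,
    center=None,
    b0_t: float = 3.0,
    prf_coeff_ppm_per_c: float = PRF_COEFF_PPM_PER_C,
) -> ParameterMaps:
    """Add a Gaussian temperature hot spot and its PRF frequency shift.

    T1/T2 are left unchanged (heating perturbs only frequency in the
    precision studies); the temperature map gains the Gaussian and the
    frequency map the corresponding PRF shift.
    """
    if peak_c < 0:
        raise ValueError("peak temperature rise must be >= 0")
    out = maps.copy()
    n = maps.shape[0]
    if center is None:
        center = (n // 2, n // 2)  # on-voxel so the peak value is exact
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y, x = np.mgrid[0 : maps.shape[0], 0 : maps.shape[1]]
    bump = peak_c * np.exp(
        -((x - center[1]) ** 2 + (y - center[0]) ** 2) / (2.0 * sigma**2)
    )
    out.temp_c = maps.temp_c + bump
    out.freq_hz = maps.freq_hz + prf_shift(bump, b0_t, prf_coeff_ppm_per_c)
    return out


@dataclass
class HeatingScenario:
    """Baseline maps plus a per-frame temperature-rise timecourse.

    Frequency maps for frame ``i`` follow from the PRF relation applied to
    ``temp_timecourse[i]`` on top of the baseline frequency map.
    """

    baseline_maps: ParameterMaps
    temp_timecourse: np.ndarray  # (n_frames, N, N) temperature rise in degC
    prf_coeff_ppm_per_c: float = PRF_COEFF_PPM_PER_C
    b0_t: float = 3.0

    def __post_init__(self) -> None:
        if self.temp_timecourse.ndim != 3 or self.temp_timecourse.shape[0] < 1:
            raise ValueError("temp_timecourse must be (n_frames, N, N), n_frames >= 1")
        if self.temp_timecourse.shape[1:] != self.baseline_maps.shape:
            raise ValueError("timecourse grid does not match baseline maps")

    @property
    def n_frames(self) -> int:
        return self.temp_timecourse.shape[0]

    def frame_freq_hz(self, i: int) -> np.ndarray:
        """Frequency map of frame i (baseline + PRF shift of the frame's
        temperature rise)."""
        return self.baseline_maps.freq_hz + prf_shift(
            self.temp_timecourse[i], self.b0_t, self.prf_coeff_ppm_per_c
        )

    def frame_maps(self, i: int) -> ParameterMaps:
        out = self.baseline_maps.copy()
        out.temp_c = self.baseline_maps.temp_c + self.temp_timecourse[i]
        out.freq_hz = self.frame_freq_hz(i)
        return out


def make_fus_scenario(
    baseline_maps: ParameterMaps,
    n_frames: int,
    heat_frames: int,
    plateau_c: float = 17.6,
    heat_rate: float = 0.25,
    cool_rate: float = 0.10,
    focus_fwhm_vox=(8.0, 24.0),
    center=None,
    b0_t: float = 3.0,
    prf_coeff_ppm_per_c: float = PRF_COEFF_PPM_PER_C,
) -> HeatingScenario:
    """Synthetic focused-ultrasound heating/cooling scenario.

    Temperature approaches ``plateau_c`` exponentially at ``heat_rate`` per
    frame during the first ``heat_frames`` frames, then decays at
    ``cool_rate`` per frame.  The focus is an anisotropic Gaussian
    (elongated along the propagation axis, reminiscent of the bow-tie focal
    pattern); rates of zero give a constant baseline.
    """
    if heat_rate < 0 or cool_rate < 0:
        raise ValueError("rates must be >= 0")
    n = baseline_maps.shape[0]
    if center is None:
        center = (n // 2, n // 2)
    s = 2.0 * np.sqrt(2.0 * np.log(2.0))
    sx, sy = focus_fwhm_vox[0] / s, focus_fwhm_vox[1] / s
    y, x = np.mgrid[0 : baseline_maps.shape[0], 0 : baseline_maps.shape[1]]
    focus = np.exp(
        -((x - center[1]) ** 2) / (2 * sx**2) - ((y - center[0]) ** 2) / (2 * sy**2)
    )
    amp = np.zeros(n_frames)
    for i in range(n_frames):
        if i < heat_frames:
            amp[i] = plateau_c * (1.0 - np.exp(-heat_rate * (i + 1)))
        else:
            amp[i] = amp[heat_frames - 1] * np.exp(-cool_rate * (i + 1 - heat_frames))
    if heat_rate == 0:
        amp[:] = 0.0
    timecourse = amp[:, None, None] * focus[None]
    return HeatingScenario(
        baseline_maps=baseline_maps,
        temp_timecourse=timecourse,
        prf_coeff_ppm_per_c=prf_coeff_ppm_per_c,
        b0_t=b0_t,
    )
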