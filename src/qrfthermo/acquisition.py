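"""Forward simulation of noisy spiral qRF-MRF and Cartesian 2DFT GRE data.

Noise model.  Noise is calibrated to a target SNR in the 2DFT comparator
image.  SNR is defined as mean in-mask magnitude divided by the complex
noise standard deviation (each real component gets sigma/sqrt(2)); the
spiral per-sample k-space noise is the same sigma scaled by
sqrt(dwell_2dft / dwell_qrf) to account for the readout bandwidth
difference between the two acquisitions.  All FFTs use the unitary
convention so k-space and image noise levels coincide for fully sampled
Cartesian data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary, simulate_atoms
from .nufft import NufftPlan
from .phantom import HeatingScenario, ParameterMaps
from .sequence import GreParams, SequenceParams, Trajectory

__all__ = [
    "KSpaceSeries",
    "NoiseModel",
    "render_tr_images",
    "spiral_forward",
    "spoiled_gre_signal",
    "simulate_2dft_pair",
    "calibrate_noise",
    "bloch_timecourse_images",
    "synthetic_coil_maps",
]


def synthetic_coil_maps(matrix: int, n_coils: int = 4, width_frac: float = 0.7) -> np.ndarray:
    """Smooth synthetic receive-sensitivity maps for multicoil testing.

    ``n_coils`` Gaussian-profile coils are placed around the FOV edge, each
    with a gentle linear phase ramp; a single uniform coil remains the
    default everywhere else.
    """
    y, x = np.mgrid[0:matrix, 0:matrix] / (matrix - 1) - 0.5
    maps = np.empty((n_coils, matrix, matrix), dtype=np.complex128)
    for c in range(n_coils):
        th = 2.0 * np.pi * c / n_coils
        cx, cy = 0.55 * np.cos(th), 0.55 * np.sin(th)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2)) / (2.0 * width_frac**2))
        phase = 2.0 * np.pi * 0.15 * (np.cos(th) * x + np.sin(th) * y)
        maps[c] = mag * np.exp(1j * phase)
    return maps


@dataclass(frozen=True)
class NoiseModel:
    """Noise calibration knobs.

    ``snr_target`` is the SNR produced in the 2DFT comparator image
    (magnitude / complex noise std); dwell times set the bandwidth scaling
    between the Cartesian and spiral readouts.
    """

    snr_target: float = 112.0
    dwell_2dft_s: float = 25e-6
    dwell_qrf_s: float = 2e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_target <= 0:
            raise ValueError("snr_target must be positive")
        if self.dwell_2dft_s <= 0 or self.dwell_qrf_s <= 0:
            raise ValueError("dwell times must be positive")


@dataclass
class KSpaceSeries:
    """Per-TR multicoil non-Cartesian samples plus acquisition metadata."""

    samples: np.ndarray  # (n_tr, n_coils, n_samples) complex
    trajectory: Trajectory
    coil_maps: np.ndarray  # (n_coils, N, N) complex
    noise_std: float  # complex per-sample std actually added
    params: SequenceParams

    @property
    def n_tr(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]


def calibrate_noise(noise: NoiseModel, reference_magnitude: float):
    """Noise stds implied by the calibration rule.

    Returns ``(sigma_2dft, sigma_qrf)``: the complex image-domain std for
    the 2DFT scan (reference magnitude / target SNR) and the complex
    per-sample k-space std for the spiral scan (the same std propagated
    through the unitary FFT and scaled by sqrt(dwell_2dft / dwell_qrf)).
    """
    if reference_magnitude <= 0:
        raise ValueError("reference magnitude must be positive")
    sigma_2dft = reference_magnitude / noise.snr_target
    sigma_qrf = sigma_2dft * np.sqrt(noise.dwell_2dft_s / noise.dwell_qrf_s)
    return sigma_2dft, sigma_qrf


def spoiled_gre_signal(
    m0,
    t1_s,
    t2star_s,
    flip_deg: float,
    tr_s: float,
    te_s: float,
):
    """Steady-state spoiled GRE transverse magnitude,
    m0 * sin(a) (1-E1) / (1 - cos(a) E1) * exp(-TE/T2*)."""
    t1 = np.asarray(t1_s, dtype=np.float64)
    t2s = np.asarray(t2star_s, dtype=np.float64)
    if np.any(t1 <= 0) or np.any(t2s <= 0) or tr_s <= 0 or te_s < 0:
        raise ValueError("times must be positive")
    a = np.radians(flip_deg)
    e1 = np.exp(-tr_s / t1)
    out = (
        np.asarray(m0, dtype=np.float64)
        * np.sin(a)
        * (1.0 - e1)
        / (1.0 - np.cos(a) * e1)
        * np.exp(-te_s / t2s)
    )
    return out if out.ndim else float(out)


def render_tr_images(maps: ParameterMaps, dictionary: Dictionary) -> np.ndarray:
    """Per-TR complex images: image[n, x] = m0[x] * atom(params[x])[n].

    Each voxel's (frequency, linewidth, T1, T2) is snapped to the nearest
    dictionary grid entry; frequencies outside the grid range raise.
    """
    grid = dictionary.grid
    freqs = grid.freqs_hz
    df = freqs[1] - freqs[0]
    fmask = maps.freq_hz[maps.mask]
    if np.any(fmask < freqs[0] - df / 2) or np.any(fmask > freqs[-1] + df / 2):
        raise ValueError("voxel frequency outside dictionary grid range")
    n = maps.shape[0]
    n_tr = dictionary.n_tr
    i_f = np.clip(np.round((maps.freq_hz - freqs[0]) / df).astype(int), 0, freqs.size - 1)
    lws = grid.linewidths_hz
    i_l = np.argmin(np.abs(maps.linewidth_hz[..., None] - lws), axis=-1)
    t1s = np.array([p[0] for p in grid.t1t2_pairs_s])
    t2s = np.array([p[1] for p in grid.t1t2_pairs_s])
    i_p = np.argmin(
        (maps.t1_s[..., None] - t1s) ** 2 + (maps.t2_s[..., None] - t2s) ** 2, axis=-1
    )
    images = np.zeros((n_tr,) + maps.shape, dtype=np.complex128)
    vox = np.where(maps.mask)
    atoms_v = dictionary.atoms[i_f[vox], i_l[vox], i_p[vox], :]  # (V, n_tr)
    images[:, vox[0], vox[1]] = (maps.m0[vox][:, None] * atoms_v).T
    return images


def bloch_timecourse_images(
    maps: ParameterMaps,
    params: SequenceParams,
    freq_vs_tr: np.ndarray | None = None,
) -> np.ndarray:
    """Direct per-voxel Bloch simulation of the full sequence.

    ``freq_vs_tr`` optionally gives a per-TR frequency for every voxel,
    shape (n_tr, N, N) -- used for dynamic-heating scenarios where voxel
    frequencies change during the scan.  No linewidth broadening is applied
    on this path.
    """
    vox = np.where(maps.mask)
    if freq_vs_tr is None:
        f0 = maps.freq_hz[vox]
    else:
        if freq_vs_tr.shape != (params.n_tr,) + maps.shape:
            raise ValueError("freq_vs_tr must be (n_tr, N, N)")
        f0 = freq_vs_tr[:, vox[0], vox[1]].T  # (V, n_tr)
    sig = simulate_atoms(f0, maps.t1_s[vox], maps.t2_s[vox], params)
    images = np.zeros((params.n_tr,) + maps.shape, dtype=np.complex128)
    images[:, vox[0], vox[1]] = (maps.m0[vox][:, None] * sig).T
    return images


def scenario_tr_frequencies(scenario: HeatingScenario, params: SequenceParams, discard_tr: int, window_tr: int) -> np.ndarray:
    """Per-TR frequency maps for a heating scenario: the first
    ``discard_tr`` TRs sit at baseline, then each frame occupies one
    ``window_tr``-long block."""
    n_tr = discard_tr + scenario.n_frames * window_tr
    if n_tr != params.n_tr:
        raise ValueError("params.n_tr must equal discard_tr + n_frames*window_tr")
    out = np.empty((n_tr,) + scenario.baseline_maps.shape)
    out[:discard_tr] = scenario.baseline_maps.freq_hz
    for i in range(scenario.n_frames):
        lo = discard_tr + i * window_tr
        out[lo : lo + window_tr] = scenario.frame_freq_hz(i)
    return out


def spiral_forward(
    images: np.ndarray,
    plan: NufftPlan,
    params: SequenceParams,
    coil_maps: np.ndarray | None = None,
    noise_std: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> KSpaceSeries:
    """Per-TR NUFFT of coil-weighted images plus complex Gaussian noise.

    TR ``n`` is sampled on interleaf ``n % n_interleaves``.  ``noise_std``
    is the complex per-sample std (each real component gets
    noise_std/sqrt(2)); the generator is seeded for reproducibility.
    """
    n_tr = images.shape[0]
    traj = plan.traj
    if coil_maps is None:
        coil_maps = np.ones((1,) + images.shape[1:], dtype=np.complex128)
    rng = np.random.default_rng(rng)
    order = traj.interleaf_order(n_tr)
    n_coils = coil_maps.shape[0]
    samples = np.empty((n_tr, n_coils, plan.n_samples), dtype=np.complex128)
    for c in range(n_coils):
        samples[:, c, :] = plan.forward(images * coil_maps[c][None], order)
    if noise_std > 0:
        noise = rng.standard_normal(samples.shape) + 1j * rng.standard_normal(
            samples.shape
        )
        samples += noise * (noise_std / np.sqrt(2.0))
    return KSpaceSeries(
        samples=samples,
        trajectory=traj,
        coil_maps=coil_maps,
        noise_std=noise_std,
        params=params,
    )


def simulate_2dft_pair(
    maps: ParameterMaps,
    gre: GreParams,
    noise: NoiseModel,
    heated_maps: ParameterMaps | None = None,
    rng: np.random.Generator | int | None = None,
):
    """One noisy (baseline, heated) 2DFT GRE image pair.

    Magnitude follows the spoiled-GRE steady state, phase is
    2*pi*TE*frequency, and independent complex Gaussian noise is added in
    the image domain at the calibrated std (equivalent to k-space noise
    under the unitary FFT).
    """
    if heated_maps is None:
        heated_maps = maps
    rng = np.random.default_rng(rng)
    mag = spoiled_gre_signal(
        maps.m0, maps.t1_s, maps.t2star_s, gre.flip_deg, gre.tr_s, gre.te_s
    )
    ref = float(np.mean(mag[maps.mask]))
    sigma, _ = calibrate_noise(noise, ref)
    out = []
    for m in (maps, heated_maps):
        img = mag * np.exp(2j * np.pi * gre.te_s * m.freq_hz)
        n = rng.standard_normal(img.shape) + 1j * rng.standard_normal(img.shape)
        out.append(img + n * (sigma / np.sqrt(2.0)))
    return out[0], out[1]
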