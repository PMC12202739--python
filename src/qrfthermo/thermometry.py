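"""PRF-shift temperature calculation from matched windows.

A window's matched frequency map and mean image are combined into a
synthesized GRE image, I(x) = |I_mean(x)| * exp(i*2*pi*TR*df(x)); the
sequence TR (not TE) sets the phase scale because it determines where
frequency aliasing occurs (+-1/(2TR)).  Temperature change then follows the
standard PRF conversion dT = dtheta / (2*pi*gamma_bar*alpha*T*B0), with the
phase difference taken against a baseline image (single-baseline
subtraction) or against a weighted baseline library with polynomial
background removal (a simplified hybrid multibaseline + referenceless
estimator).

Sign convention: with alpha < 0, heating lowers the resonance frequency.
The default ``heating_positive`` convention makes the returned temperature
change positive for heating on both the qRF-MRF (TR-based) and 2DFT
(TE-based) paths; ``literal`` negates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import GAMMA_BAR_MHZ_PER_T, PRF_COEFF_PPM_PER_C
from .recon import WindowResult
from .sequence import GreParams

__all__ = [
    "ThermoParams",
    "BaselineLibrary",
    "synthesize_gre",
    "temp_from_phase",
    "single_baseline_temp",
    "hybrid_multibaseline_referenceless",
    "gre_phase_difference_temp",
    "temperature_ambiguity_period_c",
]


@dataclass(frozen=True)
class ThermoParams:
    """PRF conversion constants and sign convention."""

    b0_t: float = 3.0
    prf_coeff_ppm_per_c: float = PRF_COEFF_PPM_PER_C
    gamma_bar_mhz_per_t: float = GAMMA_BAR_MHZ_PER_T
    sign_convention: str = "heating_positive"

    def __post_init__(self) -> None:
        if self.b0_t <= 0:
            raise ValueError("B0 must be positive")
        if self.prf_coeff_ppm_per_c == 0:
            raise ValueError("PRF coefficient must be nonzero")
        if self.sign_convention not in ("heating_positive", "literal"):
            raise ValueError("sign_convention must be heating_positive or literal")

    @property
    def hz_per_c(self) -> float:
        """Frequency shift per degC: gamma_bar * alpha * B0 (negative)."""
        return (
            self.gamma_bar_mhz_per_t * 1e6 * self.prf_coeff_ppm_per_c * 1e-6 * self.b0_t
        )


@dataclass
class BaselineLibrary:
    """Synthesized pre-heating GRE images used by the hybrid estimator."""

    images: list
    mask: np.ndarray

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("need at least one baseline image")
        for im in self.images:
            if im.shape != self.mask.shape:
                raise ValueError("baseline image shape mismatch")


def synthesize_gre(window: WindowResult, tr_s: float) -> np.ndarray:
    """Synthesized GRE image: |mean image| with phase 2*pi*TR*frequency."""
    return np.abs(window.mean_image) * np.exp(
        2j * np.pi * tr_s * window.freq_map_hz
    )


def temp_from_phase(
    delta_theta: np.ndarray,
    params: ThermoParams,
    echo_time_like_s: float,
):
    """Convert a phase-difference map (radians) to temperature change (degC).

    ``echo_time_like_s`` is the sequence TR for synthesized qRF-MRF images
    and the TE for conventional GRE images.
    """
    dt = np.asarray(delta_theta, dtype=np.float64) / (
        2.0 * np.pi * echo_time_like_s * params.hz_per_c
    )
    if params.sign_convention == "literal":
        dt = -dt
    return dt if dt.ndim else float(dt)


def single_baseline_temp(
    baseline_gre: np.ndarray,
    dynamic_gre: np.ndarray,
    params: ThermoParams,
    echo_time_like_s: float,
) -> np.ndarray:
    """Temperature change from the phase of dynamic * conj(baseline)."""
    dtheta = np.angle(dynamic_gre * np.conj(baseline_gre))
    return temp_from_phase(dtheta, params, echo_time_like_s)


def gre_phase_difference_temp(
    baseline: np.ndarray,
    dynamic: np.ndarray,
    gre: GreParams,
    params: ThermoParams,
) -> np.ndarray:
    """2DFT comparator: baseline phase subtraction with TE in the
    denominator."""
    return single_baseline_temp(baseline, dynamic, params, gre.te_s)


def temperature_ambiguity_period_c(params: ThermoParams, tr_s: float) -> float:
    """Full temperature aliasing period, (1/TR)/(gamma_bar*|alpha|*B0) degC."""
    return (1.0 / tr_s) / abs(params.hz_per_c)


def _poly_basis(mask: np.ndarray, order: int) -> np.ndarray:
    """2D monomial basis up to ``order``, evaluated on masked voxels,
    coordinates normalized to [-1, 1]."""
    n0, n1 = mask.shape
    y, x = np.mgrid[0:n0, 0:n1]
    xn = 2.0 * x / (n1 - 1) - 1.0
    yn = 2.0 * y / (n0 - 1) - 1.0
    cols = []
    for total in range(order + 1):
        for j in range(total + 1):
            cols.append((xn**(total - j) * yn**j)[mask])
    return np.stack(cols, axis=1)  # (V, n_terms)


def hybrid_multibaseline_referenceless(
    baselines: BaselineLibrary,
    dynamic_gre: np.ndarray,
    params: ThermoParams,
    echo_time_like_s: float,
    poly_order: int = 1,
    sparsity_thresh_c: float = 1.0,
    n_sweeps: int = 10,
    tol: float = 1e-8,
) -> np.ndarray:
    """Simplified hybrid multibaseline + referenceless temperature estimator.

    Alternates three estimation steps until the heat-phase map stabilizes:
    (i) nonnegative baseline weights by least squares fit of the dynamic
    image to the baseline library; (ii) a low-order polynomial background
    phase fit (weighted by image magnitude) over voxels whose current heat
    phase is below the sparsity threshold; (iii) a sparse heat phase from
    the residual, selected by soft-threshold support detection and kept
    unshrunk on the support.  The final heat phase converts to temperature
    via the standard PRF relation.  Deterministic given its inputs.

    This is a self-contained stand-in with the same structure as the full
    hybrid algorithm (weighted baseline + polynomial + sparse heat phase);
    see docs/methods.md for its scope and limitations.
    """
    if poly_order not in (0, 1, 2):
        raise ValueError("poly_order must be 0, 1 or 2")
    from scipy.optimize import nnls

    mask = baselines.mask
    v_dyn = dynamic_gre[mask]
    # (i) nonnegative baseline combination fitted to the complex image
    bmat = np.stack([b[mask] for b in baselines.images], axis=1)  # (V, B)
    areal = np.concatenate([bmat.real, bmat.imag], axis=0)
    yreal = np.concatenate([v_dyn.real, v_dyn.imag])
    w, _ = nnls(areal, yreal)
    if w.sum() == 0:
        w = np.full(len(baselines.images), 1.0 / len(baselines.images))
    combined = bmat @ w

    # phase scale between heat phase and temperature
    rad_per_c = 2.0 * np.pi * echo_time_like_s * params.hz_per_c  # negative
    thresh_rad = abs(rad_per_c) * sparsity_thresh_c

    pbasis = _poly_basis(mask, poly_order)
    weights = np.abs(combined)
    heat_phase = np.zeros(v_dyn.size)
    poly_phase = np.zeros(v_dyn.size)
    converged = False
    for _ in range(n_sweeps):
        resid = np.angle(v_dyn * np.conj(combined)) - 0.0
        # (ii) polynomial fit over currently-cold voxels
        cold = np.abs(heat_phase) < thresh_rad
        wts = weights * cold
        aw = pbasis * wts[:, None]
        coef, *_ = np.linalg.lstsq(aw, (resid - heat_phase) * wts, rcond=None)
        poly_phase = pbasis @ coef
        # (iii) sparse heat phase: support by soft threshold, unshrunk values
        r = resid - poly_phase
        support = np.abs(r) > thresh_rad
        new_heat = np.where(support, r, 0.0)
        if np.max(np.abs(new_heat - heat_phase), initial=0.0) < tol:
            heat_phase = new_heat
            converged = True
            break
        heat_phase = new_heat
    if not converged:
        import warnings

        warnings.warn(
            "hybrid estimator did not converge; returning last iterate",
            RuntimeWarning,
        )
    out = np.zeros(mask.shape)
    out[mask] = temp_from_phase(heat_phase, params, echo_time_like_s)
    return out
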