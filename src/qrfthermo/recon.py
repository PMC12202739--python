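"""Windowed image reconstruction and dictionary matching.

Measured data are split into short windows (default 220 TRs = 2.2 s at
TR = 10 ms, matching the 2DFT comparator's frame time) over which
temperature is treated as constant.  Each window is reconstructed into
per-TR images either by density-compensated gridding (adjoint NUFFT) or by
solving a subspace least-squares problem: coefficient maps in a rank-k SVD
temporal basis of the window's dictionary atoms, expanded to per-TR images,
coil-weighted and NUFFT-ed to match the samples; conjugate gradients on the
normal equations (CGLS), zero-initialized, fixed iteration count, no
regularization or preconditioning.  Voxel timecourses are then matched
exhaustively against the unit-norm dictionary window by normalized inner
product magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import KSpaceSeries
from .dictionary import CompressedWindow, DictionaryGrid
from .nufft import NufftPlan

__all__ = [
    "WindowSpec",
    "WindowResult",
    "sliding_windows",
    "gridding_recon",
    "cg_subspace_recon",
    "match_window",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window partition policy: length in TRs and stride (None means
    nonoverlapping)."""

    length: int = 220
    stride: int | None = None
    start_tr: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("window length must be >= 1")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class WindowResult:
    """Matched maps for one reconstruction window."""

    window: tuple  # (start_tr, length)
    freq_map_hz: np.ndarray
    linewidth_map_hz: np.ndarray
    ip_map: np.ndarray
    mean_image: np.ndarray
    matched_index_map: np.ndarray
    mask: np.ndarray
    time_images: np.ndarray | None = None


def sliding_windows(n_tr: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Deterministic (start, length) window list over ``n_tr`` TRs."""
    stride = spec.stride if spec.stride is not None else spec.length
    if spec.start_tr + spec.length > n_tr:
        raise ValueError("window longer than available data")
    starts = range(spec.start_tr, n_tr - spec.length + 1, stride)
    return [(s, spec.length) for s in starts]


def gridding_recon(
    ks: KSpaceSeries,
    plan: NufftPlan,
    window: tuple[int, int],
) -> np.ndarray:
    """Density-compensated adjoint NUFFT images for every TR of a window.

    Coil images are combined with conjugate sensitivities.  Scaling is
    chosen so a fully sampled interleaf set approximately inverts the
    unitary NUFFT (image amplitudes comparable to the object).
    """
    start, length = window
    traj = ks.trajectory
    order = traj.interleaf_order(ks.n_tr)[start : start + length]
    dcf = traj.dcf
    n = plan.matrix
    out = np.zeros((length, n, n), dtype=np.complex128)
    for c in range(ks.n_coils):
        y = ks.samples[start : start + length, c, :] * dcf[None, :]
        imgs = plan.adjoint(y, order)
        out += np.conj(ks.coil_maps[c])[None] * imgs
    sens = np.sum(np.abs(ks.coil_maps) ** 2, axis=0)
    out *= n * n / np.maximum(sens, 1e-12)[None]
    return out


def _subspace_ops(ks: KSpaceSeries, plan: NufftPlan, cw: CompressedWindow):
    """Forward/adjoint of the subspace model, reorganized so FFTs act on
    the k coefficient maps instead of the per-TR images: with a rank-k
    basis, FFT(sum_j basis[t,j] c_j) = sum_j basis[t,j] FFT(c_j), so each
    operator application needs k (per coil) oversampled FFTs plus sparse
    interpolation per interleaf -- algebraically identical to the per-TR
    formulation."""
    start, length = cw.window
    order = ks.trajectory.interleaf_order(ks.n_tr)[start : start + length]
    basis = cw.basis  # (length, k)
    smaps = ks.coil_maps
    n = plan.matrix
    interleaves = np.unique(order)
    sel_by_il = {l: order == l for l in interleaves}

    def forward(coeffs: np.ndarray) -> np.ndarray:
        out = np.empty((smaps.shape[0], length, plan.n_samples), np.complex128)
        for c in range(smaps.shape[0]):
            spec = plan.fft_grid(coeffs * smaps[c][None])  # (k, M*M)
            for l in interleaves:
                z = plan.sample_spectra(spec, l)  # (k, S)
                sel = sel_by_il[l]
                out[c, sel] = basis[sel] @ z
        return out

    def adjoint(y: np.ndarray) -> np.ndarray:
        coeffs = np.zeros((cw.rank, n, n), dtype=np.complex128)
        for c in range(smaps.shape[0]):
            spec = np.zeros((cw.rank, plan.os_matrix**2), dtype=np.complex128)
            for l in interleaves:
                sel = sel_by_il[l]
                g = basis[sel].conj().T @ y[c, sel]  # (k, S)
                spec += plan.spread_samples(g, l)
            coeffs += np.conj(smaps[c])[None] * plan.ifft_grid(spec)
        return coeffs

    return forward, adjoint


def cg_subspace_recon(
    ks: KSpaceSeries,
    plan: NufftPlan,
    cw: CompressedWindow,
    n_iter: int = 10,
):
    """Subspace CGLS reconstruction of one window.

    Returns ``(coeff_maps, time_images, residuals)``: the rank-k coefficient
    maps, the expanded per-TR images from the final iterate, and the
    residual-norm history.  Warns and returns the best iterate if the
    residual grows for three consecutive iterations.
    """
    start, length = cw.window
    if cw.rank > length:
        raise ValueError("rank exceeds window length")
    fwd, adj = _subspace_ops(ks, plan, cw)
    b = ks.samples[start : start + length].transpose(1, 0, 2)  # (C, length, S)

    x = np.zeros((cw.rank, plan.matrix, plan.matrix), dtype=np.complex128)
    r = b.copy()
    s = adj(r)
    p = s.copy()
    gamma = float(np.vdot(s, s).real)
    residuals = [float(np.linalg.norm(r))]
    best_x, best_res = x.copy(), residuals[0]
    n_bad = 0
    for _ in range(n_iter):
        q = fwd(p)
        qq = float(np.vdot(q, q).real)
        if qq == 0:
            break
        alpha = gamma / qq
        x = x + alpha * p
        r = r - alpha * q
        res = float(np.linalg.norm(r))
        residuals.append(res)
        if res < best_res:
            best_res, best_x = res, x.copy()
            n_bad = 0
        else:
            n_bad += 1
            if n_bad >= 3:
                warnings.warn(
                    "CGLS residual increased over 3 consecutive iterations; "
                    "returning best iterate",
                    RuntimeWarning,
                )
                x = best_x
                break
        s = adj(r)
        gamma_new = float(np.vdot(s, s).real)
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    time_images = np.tensordot(cw.basis, x, axes=(1, 0))
    return x, time_images, np.asarray(residuals)


def match_window(
    time_images: np.ndarray,
    window_atoms: np.ndarray,
    grid: DictionaryGrid,
    window: tuple[int, int],
    mask: np.ndarray | None = None,
    dtype=np.complex64,
    keep_images: bool = False,
) -> WindowResult:
    """Exhaustive dictionary matching of a window's voxel timecourses.

    For every voxel the matched entry maximizes |<atom, signal>| / ||signal||
    over the unit-norm atoms (ties resolve to the lowest grid index, the
    numpy argmax convention).  Zero-signal voxels get inner product 0 and
    are excluded from the maps via the mask.
    """
    length = time_images.shape[0]
    if window_atoms.shape[1] != length:
        raise ValueError("atom window length does not match images")
    shape = time_images.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    signals = time_images[:, mask]  # (length, V)
    norms = np.linalg.norm(signals, axis=0)
    ok = norms > 0
    ips = np.abs(window_atoms.conj().astype(dtype) @ signals.astype(dtype))
    idx = np.argmax(ips, axis=0)
    ipmax = ips[idx, np.arange(idx.size)] / np.maximum(norms, 1e-300)
    ipmax[~ok] = 0.0

    i_f, i_l, _ = np.unravel_index(idx, grid.shape)
    freq_map = np.zeros(shape)
    lw_map = np.zeros(shape)
    ip_map = np.zeros(shape)
    idx_map = np.full(shape, -1, dtype=np.int64)
    freq_map[mask] = grid.freqs_hz[i_f]
    lw_map[mask] = grid.linewidths_hz[i_l]
    ip_map[mask] = ipmax
    idx_full = idx.copy()
    idx_full[~ok] = -1
    idx_map[mask] = idx_full
    return WindowResult(
        window=window,
        freq_map_hz=freq_map,
        linewidth_map_hz=lw_map,
        ip_map=ip_map,
        mean_image=time_images.mean(axis=0),
        matched_index_map=idx_map,
        mask=mask,
        time_images=time_images if keep_images else None,
    )
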