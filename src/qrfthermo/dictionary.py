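"""Bloch simulation of the balanced qRF-MRF sequence and dictionary tools.

Each dictionary atom is the complex transverse magnetization sampled at the
echo time of every TR, for one (off-resonance frequency, Gaussian
linewidth, T1, T2) combination.  The per-TR propagation is: instantaneous
rotation by the flip angle about a transverse axis at the quadratic RF
phase phi[n], free precession at 2*pi*f0 with T1/T2 relaxation split into a
TE segment (then sample) and a TR-TE segment.  Magnetization starts at
thermal equilibrium; balanced gradients are idealized (zero net moment per
TR) and relaxation during RF is neglected.

Intravoxel frequency dispersion ("linewidth") is modeled as a Gaussian
frequency distribution realized by circular convolution along the dense
frequency axis of the dictionary -- exact because atoms are periodic in f0
with period 1/TR.  The RF phase is retained in the received signal (no
per-TR demodulation); data simulation and matching share the convention,
so matching is invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import SequenceParams, quadratic_phase

__all__ = [
    "DictionaryGrid",
    "Dictionary",
    "CompressedWindow",
    "simulate_atom",
    "simulate_atoms",
    "apply_linewidth",
    "build_dictionary",
    "extract_window",
    "svd_compress",
]

# guard against accidentally enormous dictionaries (complex128 bytes)
MAX_DICTIONARY_BYTES = 4 * 2**30


def _default_freqs() -> np.ndarray:
    return default_frequency_grid(4096)


def default_frequency_grid(n_points: int, tr_s: float = 0.010) -> np.ndarray:
    """``n_points`` frequencies uniformly spanning [-1/(2TR), +1/(2TR))."""
    band = 1.0 / tr_s
    return -band / 2 + band * np.arange(n_points) / n_points


@dataclass(frozen=True)
class DictionaryGrid:
    """Parameter grid over which atoms are simulated.

    Defaults follow the reconstruction setup used throughout: 4096
    frequencies over [-50, +50) Hz, 17 Gaussian linewidths from 1 to 49 Hz,
    and short/long T1-T2 pairs (250/10 ms and 1250/50 ms).  The fine
    "matching" grid doubles the frequency sampling to 8192 points.
    """

    freqs_hz: np.ndarray = field(default_factory=_default_freqs)
    linewidths_hz: np.ndarray = field(
        default_factory=lambda: np.linspace(1.0, 49.0, 17)
    )
    t1t2_pairs_s: tuple = ((0.25, 0.01), (1.25, 0.05))

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, float))
        object.__setattr__(
            self, "linewidths_hz", np.asarray(self.linewidths_hz, float)
        )
        if np.any(self.linewidths_hz <= 0):
            raise ValueError("linewidths must be positive")
        for t1, t2 in self.t1t2_pairs_s:
            if t2 > t1 or t2 <= 0:
                raise ValueError("require 0 < T2 <= T1")

    @property
    def shape(self) -> tuple:
        return (
            self.freqs_hz.size,
            self.linewidths_hz.size,
            len(self.t1t2_pairs_s),
        )


@dataclass
class Dictionary:
    """Simulated signal atoms on a DictionaryGrid.

    ``atoms`` has shape (n_freq, n_linewidth, n_pairs, n_tr), complex.
    """

    atoms: np.ndarray
    grid: DictionaryGrid
    params: SequenceParams

    @property
    def n_tr(self) -> int:
        return self.atoms.shape[-1]

    def flat_atoms(self) -> np.ndarray:
        """Atoms flattened to (n_entries, n_tr) in grid C-order."""
        return self.atoms.reshape(-1, self.n_tr)

    def entry_index(self, freq_hz: float, linewidth_hz: float, t1_s: float, t2_s: float):
        """Nearest grid entry (i_freq, i_lw, i_pair) for a parameter tuple."""
        i_f = int(np.argmin(np.abs(self.grid.freqs_hz - freq_hz)))
        i_l = int(np.argmin(np.abs(self.grid.linewidths_hz - linewidth_hz)))
        t1s = np.array([p[0] for p in self.grid.t1t2_pairs_s])
        t2s = np.array([p[1] for p in self.grid.t1t2_pairs_s])
        i_p = int(np.argmin((t1s - t1_s) ** 2 + (t2s - t2_s) ** 2))
        return i_f, i_l, i_p


@dataclass
class CompressedWindow:
    """Rank-k SVD compression of one dictionary window.

    ``basis`` holds k orthonormal temporal basis vectors (length x k);
    ``coeffs`` the per-atom projections; ``recon_error`` the relative
    Frobenius reconstruction error of the atom matrix at rank k.
    """

    basis: np.ndarray  # (window_len, k)
    coeffs: np.ndarray  # (n_atoms, k)
    window: tuple  # (start_tr, length)
    rank: int
    recon_error: float


def simulate_atoms(
    f0_hz,
    t1_s,
    t2_s,
    params: SequenceParams,
) -> np.ndarray:
    """Bloch-simulate signal timecourses for a batch of isochromats.

    Parameters
    ----------
    f0_hz : array_like
        Off-resonance in Hz; shape (P,) for static frequencies or
        (P, n_tr) for per-TR (time-varying) frequencies.
    t1_s, t2_s : array_like
        Relaxation times in seconds, shape (P,) or scalars.

    Returns
    -------
    (P, n_tr) complex transverse magnetization sampled at TE each TR.
    """
    f0 = np.atleast_1d(np.asarray(f0_hz, dtype=np.float64))
    t1 = np.broadcast_to(np.asarray(t1_s, dtype=np.float64), f0.shape[:1]).copy()
    t2 = np.broadcast_to(np.asarray(t2_s, dtype=np.float64), f0.shape[:1]).copy()
    if np.any(t1 <= 0) or np.any(t2 <= 0) or np.any(t2 > t1):
        raise ValueError("require 0 < T2 <= T1")
    n_tr = params.n_tr
    if f0.ndim == 1:
        f0 = np.broadcast_to(f0[:, None], (f0.size, n_tr))
    elif f0.shape[1] != n_tr:
        raise ValueError("per-TR frequency array must have n_tr columns")
    n = f0.shape[0]

    alpha = np.radians(params.flip_deg)
    ca, sa = np.cos(alpha), np.sin(alpha)
    te, tfree = params.te_s, params.tr_s - params.te_s
    e1_te, e2_te = np.exp(-te / t1), np.exp(-te / t2)
    e1_fr, e2_fr = np.exp(-tfree / t1), np.exp(-tfree / t2)

    phases = np.radians(quadratic_phase(np.arange(n_tr), params.quad_coeff_deg))
    mxy = np.zeros(n, dtype=np.complex128)
    mz = np.ones(n, dtype=np.float64)
    out = np.empty((n, n_tr), dtype=np.complex128)
    for i in range(n_tr):
        phi = phases[i]
        eip = np.exp(1j * phi)
        # rotation by alpha about the transverse axis at angle phi:
        # Rz(phi) Rx(alpha) Rz(-phi) acting on (mxy, mz)
        mxy_r = (
            mxy * (1 + ca) / 2
            + np.conj(mxy) * eip**2 * (1 - ca) / 2
            - 1j * eip * sa * mz
        )
        mz_r = mz * ca + sa * np.imag(mxy * np.conj(eip))
        # relax + precess to TE, sample
        w = 2.0 * np.pi * f0[:, i]
        mxy = mxy_r * e2_te * np.exp(1j * w * te)
        mz = 1.0 + (mz_r - 1.0) * e1_te
        out[:, i] = mxy
        # relax + precess over the remainder of the TR
        mxy = mxy * e2_fr * np.exp(1j * w * tfree)
        mz = 1.0 + (mz - 1.0) * e1_fr
    return out


def simulate_atom(f0_hz: float, t1_s: float, t2_s: float, params: SequenceParams) -> np.ndarray:
    """Single-isochromat convenience wrapper around :func:`simulate_atoms`."""
    return simulate_atoms([f0_hz], [t1_s], [t2_s], params)[0]


def _gaussian_kernel(freqs_hz: np.ndarray, linewidth_hz: float, fwhm: bool) -> np.ndarray:
    """Circular Gaussian weighting kernel on the (uniform) frequency grid,
    normalized to unit sum.  ``fwhm=True`` interprets linewidth as the full
    width at half maximum, else as the standard deviation."""
    n = freqs_hz.size
    df = freqs_hz[1] - freqs_hz[0]
    sigma = linewidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0))) if fwhm else linewidth_hz
    offsets = (np.arange(n) + n // 2) % n - n // 2  # circular offsets
    kern = np.exp(-0.5 * (offsets * df / sigma) ** 2)
    return kern / kern.sum()


def apply_linewidth(
    atoms: np.ndarray,
    freqs_hz: np.ndarray,
    linewidth_hz: float,
    fwhm: bool = True,
) -> np.ndarray:
    """Broaden atoms over a dense frequency axis by a Gaussian linewidth.

    ``atoms`` has the frequency grid on its first axis.  The broadened atom
    at grid frequency f is the Gaussian-weighted circular sum of atoms over
    the frequency axis -- exact intravoxel dispersion for a voxel whose
    isochromats follow that distribution, because atoms are periodic in f0.
    """
    if linewidth_hz <= 0:
        raise ValueError("linewidth must be positive")
    kern = _gaussian_kernel(np.asarray(freqs_hz, float), linewidth_hz, fwhm)
    spec = np.fft.fft(atoms, axis=0)
    kspec = np.fft.fft(kern)  # kernel stored with zero offset at index 0
    out = np.fft.ifft(spec * kspec.reshape((-1,) + (1,) * (atoms.ndim - 1)), axis=0)
    return out


def build_dictionary(
    grid: DictionaryGrid,
    params: SequenceParams,
    fwhm: bool = True,
) -> Dictionary:
    """Simulate atoms for the Cartesian product of grid entries.

    Base atoms are Bloch-simulated per (frequency, T1/T2 pair), then each
    Gaussian linewidth is applied by circular convolution along the
    frequency axis.  Deterministic: two calls yield bit-identical output.
    """
    n_f, n_l, n_p = grid.shape
    nbytes = n_f * n_l * n_p * params.n_tr * 16
    if nbytes > MAX_DICTIONARY_BYTES:
        raise MemoryError(
            f"dictionary would need {nbytes/2**30:.1f} GiB "
            f"(cap {MAX_DICTIONARY_BYTES/2**30:.0f} GiB)"
        )
    base = np.empty((n_f, n_p, params.n_tr), dtype=np.complex128)
    for ip, (t1, t2) in enumerate(grid.t1t2_pairs_s):
        base[:, ip, :] = simulate_atoms(
            grid.freqs_hz, np.full(n_f, t1), np.full(n_f, t2), params
        )
    atoms = np.empty((n_f, n_l, n_p, params.n_tr), dtype=np.complex128)
    for il, lw in enumerate(grid.linewidths_hz):
        atoms[:, il, :, :] = apply_linewidth(base, grid.freqs_hz, lw, fwhm=fwhm)
    return Dictionary(atoms=atoms, grid=grid, params=params)


def extract_window(dictionary: Dictionary, start_tr: int, length: int) -> np.ndarray:
    """L2-normalized per-atom subsequences for one reconstruction window.

    Returns an (n_entries, length) complex matrix in grid C-order, each row
    unit norm (the form dictionary matching expects).
    """
    if start_tr < 0 or start_tr + length > dictionary.n_tr:
        raise ValueError("window exceeds dictionary extent")
    win = dictionary.flat_atoms()[:, start_tr : start_tr + length]
    norms = np.linalg.norm(win, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("dictionary window contains an identically zero atom")
    return win / norms


def svd_compress(window_atoms: np.ndarray, k: int, window: tuple = (0, 0)) -> CompressedWindow:
    """Rank-k temporal SVD basis of a window's atom matrix.

    The basis spans the dominant temporal subspace of the (atoms x time)
    matrix; coefficients are the atom projections, and the relative
    Frobenius reconstruction error at rank k is reported.
    """
    if k < 1:
        raise ValueError("rank must be >= 1")
    length = window_atoms.shape[1]
    if k > length:
        raise ValueError("rank cannot exceed window length")
    # economy SVD of (n_atoms, length); right singular vectors are the
    # temporal basis
    # A = U S Vh: atom rows are combinations of the rows of Vh, so the
    # temporal basis columns are vh[:k].T (atom = basis @ coeff)
    _, s, vh = np.linalg.svd(window_atoms, full_matrices=False)
    basis = vh[:k].T  # (length, k), orthonormal columns
    coeffs = window_atoms @ basis.conj()  # projections basis^H atom
    total = float(np.sum(s**2))
    err = float(np.sqrt(max(total - np.sum(s[:k] ** 2), 0.0) / total))
    if window == (0, 0):
        window = (0, length)
    return CompressedWindow(
        basis=basis, coeffs=coeffs, window=window, rank=k, recon_error=err
    )
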