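"""Model/results objects tying the reconstruction pipeline together.

``QrfThermometry`` is constructed from a k-space series and a dictionary,
and ``fit()`` runs the windowed reconstruction (gridding or subspace CG),
dictionary matching, GRE synthesis and baseline temperature subtraction,
returning a ``ThermometryResults`` carrying the per-window maps, the
temperature series and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import KSpaceSeries
from .dictionary import Dictionary, extract_window, svd_compress
from .nufft import NufftPlan
from .recon import (
    WindowResult,
    WindowSpec,
    cg_subspace_recon,
    gridding_recon,
    match_window,
    sliding_windows,
)
from .thermometry import ThermoParams, single_baseline_temp, synthesize_gre

__all__ = ["QrfThermometry", "ThermometryResults"]


@dataclass
class ThermometryResults:
    """Fitted window results and derived temperature maps.

    ``temperature_maps[i]`` is the change of window i relative to the
    designated baseline window (single-baseline subtraction of synthesized
    GRE images).
    """

    windows: list  # list[WindowResult]
    temperature_maps: np.ndarray  # (n_windows, N, N)
    gre_images: np.ndarray  # (n_windows, N, N) complex
    baseline_index: int
    method: str
    thermo: ThermoParams
    tr_s: float
    residuals: list | None = None

    @property
    def freq_maps_hz(self) -> np.ndarray:
        return np.stack([w.freq_map_hz for w in self.windows])

    @property
    def ip_maps(self) -> np.ndarray:
        return np.stack([w.ip_map for w in self.windows])

    @property
    def linewidth_maps_hz(self) -> np.ndarray:
        return np.stack([w.linewidth_map_hz for w in self.windows])

    def roi_timecourse(self, roi_mask: np.ndarray) -> pd.DataFrame:
        """Mean/std temperature change per window over an ROI."""
        rows = []
        for i, w in enumerate(self.windows):
            vals = self.temperature_maps[i][roi_mask]
            rows.append(
                {
                    "window": i,
                    "start_tr": w.window[0],
                    "mean_dT_c": float(vals.mean()),
                    "std_dT_c": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "max_dT_c": float(vals.max()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Per-window diagnostics: mean inner product, mean frequency, and
        in-mask temperature statistics."""
        rows = []
        for i, w in enumerate(self.windows):
            m = w.mask
            dt = self.temperature_maps[i][m]
            rows.append(
                {
                    "window": i,
                    "start_tr": w.window[0],
                    "length_tr": w.window[1],
                    "mean_ip": float(w.ip_map[m].mean()),
                    "mean_freq_hz": float(w.freq_map_hz[m].mean()),
                    "mean_dT_c": float(dt.mean()),
                    "max_abs_dT_c": float(np.abs(dt).max()),
                }
            )
        return pd.DataFrame(rows)

    def hybrid_temperature_maps(
        self, n_baselines: int = 8, poly_order: int = 1, mask: np.ndarray | None = None
    ) -> np.ndarray:
        """Temperature maps from the multibaseline + referenceless
        estimator instead of single-baseline subtraction.

        The first ``n_baselines`` windows form the baseline library; every
        window is then re-estimated against it with a polynomial background
        of the given order.  Returns an array shaped like
        ``temperature_maps``.
        """
        from .thermometry import BaselineLibrary, hybrid_multibaseline_referenceless

        if n_baselines < 1 or n_baselines > len(self.windows):
            raise ValueError("n_baselines must be in [1, n_windows]")
        if mask is None:
            mask = self.windows[0].mask
        lib = BaselineLibrary(
            images=[self.gre_images[i] for i in range(n_baselines)], mask=mask
        )
        out = np.zeros_like(self.temperature_maps)
        for i in range(len(self.windows)):
            out[i] = hybrid_multibaseline_referenceless(
                lib, self.gre_images[i], self.thermo, self.tr_s, poly_order=poly_order
            )
        return out

    def plot_temperature(self, roi_mask: np.ndarray, ax=None):
        """ROI mean temperature-change curve versus window index."""
        import matplotlib.pyplot as plt

        tc = self.roi_timecourse(roi_mask)
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(tc["window"], tc["mean_dT_c"], yerr=tc["std_dT_c"], marker="o")
        ax.set_xlabel("window")
        ax.set_ylabel(r"$\Delta T$ ($^\circ$C)")
        return ax


class QrfThermometry:
    """qRF-MRF thermometry model: k-space series + dictionary -> maps.

    Parameters
    ----------
    kspace : KSpaceSeries
        Per-TR multicoil spiral samples (simulated or ingested).
    dictionary : Dictionary
        Bloch dictionary simulated with the same sequence parameters.
    window : WindowSpec
        Window partition (length/stride/first TR); the first TRs are
        typically discarded to remove the transient approach to the
        pseudo steady state.
    thermo : ThermoParams
        PRF conversion constants.
    mask : ndarray of bool, optional
        Object support for matching; defaults to all voxels.
    """

    def __init__(
        self,
        kspace: KSpaceSeries,
        dictionary: Dictionary,
        window: WindowSpec | None = None,
        thermo: ThermoParams | None = None,
        mask: np.ndarray | None = None,
        plan: NufftPlan | None = None,
    ) -> None:
        if dictionary.n_tr < kspace.n_tr:
            raise ValueError("dictionary is shorter than the data")
        self.kspace = kspace
        self.dictionary = dictionary
        self.window = window or WindowSpec()
        self.thermo = thermo or ThermoParams()
        self.mask = mask
        self.plan = plan or NufftPlan(kspace.trajectory)

    def fit(
        self,
        method: str = "cg",
        rank: int = 15,
        n_iter: int = 10,
        baseline_index: int = 0,
    ) -> ThermometryResults:
        """Reconstruct, match and convert every window to temperature.

        ``method`` is ``"cg"`` (SVD-subspace CGLS) or ``"gridding"``.
        """
        if method not in ("cg", "gridding"):
            raise ValueError("method must be 'cg' or 'gridding'")
        windows = sliding_windows(self.kspace.n_tr, self.window)
        results: list[WindowResult] = []
        residuals = []
        for start, length in windows:
            atoms = extract_window(self.dictionary, start, length)
            if method == "cg":
                cw = svd_compress(atoms, rank, window=(start, length))
                _, imgs, res = cg_subspace_recon(
                    self.kspace, self.plan, cw, n_iter=n_iter
                )
                residuals.append(res)
            else:
                imgs = gridding_recon(self.kspace, self.plan, (start, length))
            results.append(
                match_window(
                    imgs,
                    atoms,
                    self.dictionary.grid,
                    (start, length),
                    mask=self.mask,
                )
            )
        tr = self.kspace.params.tr_s
        gres = np.stack([synthesize_gre(w, tr) for w in results])
        base = gres[baseline_index]
        temps = np.stack(
            [
                single_baseline_temp(base, g, self.thermo, tr)
                for g in gres
            ]
        )
        return ThermometryResults(
            windows=results,
            temperature_maps=temps,
            gre_images=gres,
            baseline_index=baseline_index,
            method=method,
            thermo=self.thermo,
            tr_s=tr,
            residuals=residuals or None,
        )
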