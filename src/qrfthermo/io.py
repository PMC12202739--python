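"""HDF5 / NIfTI persistence.

The HDF5 layouts below are also the ingestion contract for user-supplied
data: a k-space file carries ``samples`` (n_tr x n_coils x n_samples,
complex), ``coords`` (n_interleaves x n_samples x 2, cycles/pixel),
``dcf`` (n_samples), ``coil_maps`` (n_coils x N x N) and scalar attrs
(``tr_s``, ``te_s``, ``flip_deg``, ``quad_coeff_deg``, ``noise_std``,
``matrix``, ``fov_m``).  Parameter and result maps are written as NIfTI
with the in-plane voxel size in the header.
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np

from .acquisition import KSpaceSeries
from .dictionary import Dictionary, DictionaryGrid
from .sequence import SequenceParams, Trajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_dictionary",
    "load_dictionary",
    "save_kspace",
    "load_kspace",
    "save_map_nifti",
    "load_sequence_config",
    "save_sequence_config",
    "grid_table",
]

_SEQ_ATTRS = (
    "tr_s",
    "te_s",
    "flip_deg",
    "quad_coeff_deg",
    "n_tr",
    "n_interleaves",
    "readout_s",
    "dwell_s",
)


def _write_params(g, params: SequenceParams) -> None:
    for k in _SEQ_ATTRS:
        g.attrs[k] = getattr(params, k)


def _read_params(g) -> SequenceParams:
    kw = {k: g.attrs[k] for k in _SEQ_ATTRS}
    kw["n_tr"] = int(kw["n_tr"])
    kw["n_interleaves"] = int(kw["n_interleaves"])
    return SequenceParams(**kw)


def save_trajectory(path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=traj.coords)
        f.create_dataset("dcf", data=traj.dcf)
        f.attrs["n_interleaves"] = traj.n_interleaves
        f.attrs["matrix"] = traj.matrix
        f.attrs["fov_m"] = traj.fov_m


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            coords=f["coords"][()],
            dcf=f["dcf"][()],
            n_interleaves=int(f.attrs["n_interleaves"]),
            matrix=int(f.attrs["matrix"]),
            fov_m=float(f.attrs["fov_m"]),
        )


def save_dictionary(path, d: Dictionary) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("atoms", data=d.atoms)
        f.create_dataset("freqs_hz", data=d.grid.freqs_hz)
        f.create_dataset("linewidths_hz", data=d.grid.linewidths_hz)
        f.create_dataset("t1t2_pairs_s", data=np.asarray(d.grid.t1t2_pairs_s))
        _write_params(f, d.params)


def load_dictionary(path) -> Dictionary:
    with h5py.File(path, "r") as f:
        grid = DictionaryGrid(
            freqs_hz=f["freqs_hz"][()],
            linewidths_hz=f["linewidths_hz"][()],
            t1t2_pairs_s=tuple(map(tuple, f["t1t2_pairs_s"][()])),
        )
        return Dictionary(atoms=f["atoms"][()], grid=grid, params=_read_params(f))


def save_kspace(path, ks: KSpaceSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=ks.samples)
        f.create_dataset("coords", data=ks.trajectory.coords)
        f.create_dataset("dcf", data=ks.trajectory.dcf)
        f.create_dataset("coil_maps", data=ks.coil_maps)
        f.attrs["noise_std"] = ks.noise_std
        f.attrs["matrix"] = ks.trajectory.matrix
        f.attrs["fov_m"] = ks.trajectory.fov_m
        _write_params(f, ks.params)


def load_kspace(path) -> KSpaceSeries:
    with h5py.File(path, "r") as f:
        params = _read_params(f)
        traj = Trajectory(
            coords=f["coords"][()],
            dcf=f["dcf"][()],
            n_interleaves=params.n_interleaves,
            matrix=int(f.attrs["matrix"]),
            fov_m=float(f.attrs["fov_m"]),
        )
        return KSpaceSeries(
            samples=f["samples"][()],
            trajectory=traj,
            coil_maps=f["coil_maps"][()],
            noise_std=float(f.attrs["noise_std"]),
            params=params,
        )


def save_sequence_config(path, params: SequenceParams, matrix: int = 128, fov_mm: float = 256.0) -> None:
    """Write sequence parameters as a YAML config (times in milliseconds,
    the convention of protocol files)."""
    import yaml

    cfg = {
        "tr_ms": params.tr_s * 1e3,
        "te_ms": params.te_s * 1e3,
        "flip_deg": params.flip_deg,
        "quad_coeff": params.quad_coeff_deg,
        "n_tr": params.n_tr,
        "interleaves": params.n_interleaves,
        "readout_ms": params.readout_s * 1e3,
        "dwell_us": params.dwell_s * 1e6,
        "matrix": matrix,
        "fov_mm": fov_mm,
    }
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f)


def load_sequence_config(path):
    """Read a YAML sequence config; returns (SequenceParams, matrix, fov_m)."""
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f)
    params = SequenceParams(
        tr_s=cfg["tr_ms"] * 1e-3,
        te_s=cfg["te_ms"] * 1e-3,
        flip_deg=cfg["flip_deg"],
        quad_coeff_deg=cfg["quad_coeff"],
        n_tr=int(cfg["n_tr"]),
        n_interleaves=int(cfg.get("interleaves", 12)),
        readout_s=cfg.get("readout_ms", 6.0) * 1e-3,
        dwell_s=cfg.get("dwell_us", 2.0) * 1e-6,
    )
    return params, int(cfg.get("matrix", 128)), cfg.get("fov_mm", 256.0) * 1e-3


def grid_table(grid: DictionaryGrid):
    """Tidy table of the dictionary grid axes (one row per entry), for CSV
    export alongside a saved dictionary."""
    import pandas as pd

    n_f, n_l, n_p = grid.shape
    i_f, i_l, i_p = np.unravel_index(np.arange(n_f * n_l * n_p), grid.shape)
    t1s = np.array([p[0] for p in grid.t1t2_pairs_s])
    t2s = np.array([p[1] for p in grid.t1t2_pairs_s])
    return pd.DataFrame(
        {
            "freq_hz": grid.freqs_hz[i_f],
            "linewidth_hz": grid.linewidths_hz[i_l],
            "t1_s": t1s[i_p],
            "t2_s": t2s[i_p],
        }
    )


def save_map_nifti(path, data: np.ndarray, voxel_mm: float = 2.0) -> None:
    """Write a 2D map (or stack of maps) as NIfTI."""
    arr = np.asarray(data, dtype=np.float64)
    affine = np.diag([voxel_mm, voxel_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr.T, affine), str(path))
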