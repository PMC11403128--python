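"""HDF5 containers, NIfTI map export, and CSV tables.

Container layouts (all HDF5):

* recording: dataset ``data`` (channels×T) with attrs ``sfreq``, ``kind``,
  ``t0`` and dataset ``labels``;
* lead field: datasets ``G`` (M×2P), ``node_coords`` (P×3, m),
  ``orientation_pairs`` (P×2×3), ``sensor_positions``, ``sensor_orientations``
  and attrs ``spacing``, ``region``.

A FIF adapter is provided for standard MEG files; if the optional ``mne``
dependency is missing the adapter degrades gracefully to container-only mode.
"""

from __future__ import annotations

import numpy as np

from .forward import LeadField
from .geometry import SensorArray, SourceGrid
from .preprocess import Recording
from .solver import SourceImage

__all__ = [
    "save_recording", "load_recording", "save_leadfield", "load_leadfield",
    "save_projection_debug", "save_source_delay_map",
    "image_to_nifti", "save_image_csv", "read_fif",
]


def save_recording(path, rec: Recording) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["kind"] = rec.kind
        f.attrs["t0"] = rec.t0


def load_recording(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            kind=str(f.attrs["kind"]),
            t0=float(f.attrs.get("t0", 0.0)),
            labels=[s.decode() for s in f["labels"][()]],
        )


def save_leadfield(path, lf: LeadField) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("G", data=lf.G)
        f.create_dataset("orientation_pairs", data=lf.orientation_pairs)
        if lf.grid is not None:
            f.create_dataset("node_coords", data=lf.grid.node_coords)
            f.attrs["spacing"] = lf.grid.spacing
            f.attrs["region"] = lf.grid.region
        if lf.sensors is not None:
            f.create_dataset("sensor_positions", data=lf.sensors.positions)
            f.create_dataset("sensor_orientations", data=lf.sensors.orientations)
            f.create_dataset("sphere_center", data=lf.sensors.sphere_center)


def load_leadfield(path) -> LeadField:
    import h5py

    with h5py.File(path, "r") as f:
        grid = None
        if "node_coords" in f:
            grid = SourceGrid(
                node_coords=f["node_coords"][()],
                spacing=float(f.attrs.get("spacing", 0.0)),
                region=str(f.attrs.get("region", "imported")),
            )
        sensors = None
        if "sensor_positions" in f:
            sensors = SensorArray(
                positions=f["sensor_positions"][()],
                orientations=f["sensor_orientations"][()],
                sphere_center=f["sphere_center"][()] if "sphere_center" in f else np.zeros(3),
            )
        return LeadField(
            G=f["G"][()], orientation_pairs=f["orientation_pairs"][()],
            grid=grid, sensors=sensors,
        )


def save_projection_debug(path, E, F=None) -> None:
    """Debug export of the delay matrix (and optionally the projected data)
    with the delay axis labeled in ms."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("E", data=E.E)
        f.create_dataset("delays_ms", data=E.delays_ms)
        f.attrs["emg_channel"] = E.emg_channel
        f.attrs["sfreq"] = E.sfreq
        f.attrs["normalization"] = E.normalization
        if F is not None:
            f.create_dataset("F", data=F.F)
            f.attrs["band"] = F.band


def save_source_delay_map(path, H, Qd=None) -> None:
    """Export the per-mode source maps H (2P×k) and, optionally, the
    delay-domain source matrix Q_d (2P×D)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("H", data=H.H)
        f.create_dataset("delays_ms", data=H.delays_ms)
        f.create_dataset("residuals", data=H.residuals)
        f.attrs["status"] = H.status
        f.attrs["objective"] = H.objective
        f.attrs["delta"] = H.delta
        if Qd is None and H.modes_V is not None and H.H.shape[1] > 0:
            Qd = H.H @ H.modes_V.T
        if Qd is not None:
            f.create_dataset("Qd", data=Qd)


def image_to_nifti(img: SourceImage, grid: SourceGrid, path=None, thresholded: bool = False):
    """Resample the node map onto the grid's bounding lattice (nearest-node
    fill at grid spacing) and wrap it as a NIfTI volume, affine in mm."""
    import nibabel as nib

    sp = grid.spacing
    ijk = np.round((grid.node_coords - grid.node_coords.min(axis=0)) / sp).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.zeros(shape)
    vals = img.A.copy()
    if thresholded and img.threshold is not None:
        vals = np.where(vals >= img.threshold, vals, 0.0)
        if img.saturation is not None:
            vals = np.minimum(vals, img.saturation)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = vals
    affine = np.eye(4)
    affine[:3, :3] *= sp * 1000.0  # voxel -> mm
    affine[:3, 3] = grid.node_coords.min(axis=0) * 1000.0
    nii = nib.Nifti1Image(vol.astype(np.float32), affine)
    if path is not None:
        nib.save(nii, str(path))
    return nii


def save_image_csv(path, img: SourceImage, grid: SourceGrid) -> None:
    """CSV of node index, coordinates (mm), magnitude and winning delay."""
    import pandas as pd

    mm = grid.node_coords * 1000.0
    df = pd.DataFrame(
        {
            "node": np.arange(grid.n_nodes),
            "x_mm": np.round(mm[:, 0], 3),
            "y_mm": np.round(mm[:, 1], 3),
            "z_mm": np.round(mm[:, 2], 3),
            "magnitude": img.A,
        }
    )
    if img.winning_delay_ms is not None:
        df["winning_delay_ms"] = img.winning_delay_ms
    df.to_csv(path, index=False)


def read_fif(path) -> Recording:
    """Load magnetometer data from a FIF file via the optional mne adapter."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading FIF files requires the optional 'mne' dependency; "
            "use the HDF5 recording container instead"
        ) from exc
    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    picks = mne.pick_types(raw.info, meg="mag")
    return Recording(
        data=raw.get_data(picks=picks),
        sfreq=float(raw.info["sfreq"]),
        kind="MEG",
        labels=[raw.ch_names[p] for p in picks],
    )
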