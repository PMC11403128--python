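"""EMG delay matrix, MEG→EMG projection, and spatial-mode decomposition.

The delay matrix E stacks D time-shifted, normalized copies of one EMG channel
spanning the pre-movement window (default −100…0 ms at 1-ms steps, D = 101).
Projecting the band-filtered MEG onto it, F = B Eᵀ (M×D), acts as a temporal
matched filter: brain activity synchronized with the EMG at some lag in the
window survives, while noise — uncorrelated with EMG — averages out. The SVD
of F yields sensor-space spatial modes whose source maps are solved
independently by the inverse step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import NoiseModel, Recording, select_modes

__all__ = [
    "DelayMatrix",
    "ProjectedData",
    "SpatialModes",
    "build_delay_matrix",
    "project",
    "decompose_modes",
]


@dataclass
class DelayMatrix:
    """D×T′ bank of delayed, zero-mean, unit-norm EMG rows (delay ascending)."""

    E: np.ndarray  # (D, T')
    delays_ms: np.ndarray  # (D,) ascending, e.g. -100 … 0
    emg_channel: int = 0
    sfreq: float = 1000.0
    normalization: str = "per-row zero-mean unit-L2"

    @property
    def n_delays(self) -> int:
        return self.E.shape[0]

    @property
    def n_samples(self) -> int:
        return self.E.shape[1]


@dataclass
class ProjectedData:
    """EMG-projected MEG sensor signals, F = B Eᵀ (M×D)."""

    F: np.ndarray
    delays_ms: np.ndarray
    emg_channel: int = 0
    band: str = ""
    whitened: bool = False


@dataclass
class SpatialModes:
    """SVD of the (whitened) projected data; the first k columns of U·diag(S)
    are the dominant sensor-space patterns handed to the inverse solver."""

    U: np.ndarray  # (M, min(M, D))
    S: np.ndarray  # descending
    V: np.ndarray  # (D, min(M, D))
    k: int
    noise_floor: float = 0.0
    warning: str = ""
    delays_ms: np.ndarray = field(default_factory=lambda: np.zeros(0))


def build_delay_matrix(
    emg: Recording,
    delays_ms=(-100.0, 0.0),
    step_ms: float = 1.0,
    channel: int = 0,
) -> DelayMatrix:
    """Bank of delayed EMG copies over the common valid support.

    A row with delay d (d ≤ 0, ms) contains the EMG advanced by |d|: at MEG
    sample t the row holds the EMG at t + |d|, so a brain signal that *leads*
    the muscle by |d| ms correlates maximally with that row. All rows are
    truncated to the support shared by every shift (T′ = T − max|d|·fs
    samples), then zero-meaned and normalized to unit L2.
    """
    lo, hi = float(delays_ms[0]), float(delays_ms[-1])
    if lo > hi or hi > 0 or lo < -1000:
        raise ValueError(f"delay window must satisfy -1000 <= lo <= hi <= 0 ms, got [{lo}, {hi}]")
    delays = np.arange(lo, hi + 0.5 * step_ms, step_ms)
    x = emg.data[channel]
    max_shift = int(round(-lo * emg.sfreq / 1000.0))
    if emg.n_samples < max_shift + 2:
        raise ValueError(
            f"EMG too short: {emg.n_samples} samples leave no common support "
            f"for a {max_shift}-sample delay window"
        )
    if emg.n_samples < max_shift + int(emg.sfreq):
        warnings.warn(
            f"EMG support is under |delay window| + 1 s "
            f"({emg.duration:.2f} s); delay rows are poorly averaged"
        )
    T_prime = emg.n_samples - max_shift
    E = np.empty((delays.size, T_prime))
    for j, d in enumerate(delays):
        shift = int(round(-d * emg.sfreq / 1000.0))
        row = x[shift : shift + T_prime].astype(float)
        row = row - row.mean()
        nrm = np.linalg.norm(row)
        if nrm == 0.0:
            raise ValueError(f"zero-variance row at delay {d} ms: EMG is constant on its support")
        E[j] = row / nrm
    return DelayMatrix(E=E, delays_ms=delays, emg_channel=channel, sfreq=emg.sfreq)


def project(meg_band: Recording, E: DelayMatrix) -> ProjectedData:
    """F = B Eᵀ over the common support (no further scaling)."""
    T_prime = E.n_samples
    if meg_band.n_samples < T_prime:
        raise ValueError(
            f"shape mismatch: MEG has {meg_band.n_samples} samples but the delay "
            f"matrix support is {T_prime}"
        )
    if abs(meg_band.sfreq - E.sfreq) > 1e-9:
        raise ValueError(
            f"sampling mismatch: MEG at {meg_band.sfreq} Hz, delay matrix at {E.sfreq} Hz"
        )
    F = meg_band.data[:, :T_prime] @ E.E.T
    return ProjectedData(
        F=F, delays_ms=E.delays_ms, emg_channel=E.emg_channel,
        band=meg_band.meta.get("band", ""),
    )


def decompose_modes(
    F: ProjectedData,
    noise: NoiseModel | None = None,
    noise_floor: float | None = None,
    factor: float = 3.0,
    kappa_max: int = 10,
) -> SpatialModes:
    """Whiten the sensor dimension, SVD, and pick the dominant mode count.

    ``noise_floor`` is the scale of the leading singular value the identical
    empty-room chain produces; modes above ``factor``×floor are retained. With
    no floor supplied every mode up to ``kappa_max`` above zero is kept.
    """
    Fw = F.F if noise is None else noise.whitener @ F.F
    if not np.all(np.isfinite(Fw)):
        raise ValueError("projected data contains non-finite values")
    if np.allclose(Fw, 0.0):
        return SpatialModes(
            U=np.zeros((Fw.shape[0], 0)), S=np.zeros(0), V=np.zeros((Fw.shape[1], 0)),
            k=0, warning="all-zero projected data: solve skipped", delays_ms=F.delays_ms,
        )
    U, s, Vt = np.linalg.svd(Fw, full_matrices=False)
    for i in range(s.size):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i] = -Vt[i]
    warning = ""
    if noise_floor is None:
        k = int(min(np.sum(s > 1e-12 * s[0]), kappa_max))
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            k = select_modes(s, noise_floor, factor=factor, kappa_max=kappa_max)
        if caught:
            warning = str(caught[0].message)
    return SpatialModes(
        U=U, S=s, V=Vt.T.copy(), k=k,
        noise_floor=0.0 if noise_floor is None else float(noise_floor),
        warning=warning, delays_ms=F.delays_ms,
    )
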