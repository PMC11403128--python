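"""Synthetic MEG+EMG corticomuscular-coupling datasets.

The generator emulates the statistical structure the imaging method assumes:

* a self-paced movement EMG — quasi-periodic bursts (~1 Hz, jittered) of
  amplitude-modulated 20–150 Hz surface-EMG carrier noise, recorded on two
  channels with anti-phase flexor/extensor envelopes;
* one "M1" grid node whose source time course is a band-limited copy of the
  EMG advanced by a fixed lag in the −100…0 ms window (the brain leads the
  muscle), one coupled component per coupled band, plus an uncoupled
  intrinsic oscillation;
* background brain sources at random nodes away from the target, with 1/f
  spectra and an 8–12 Hz alpha bump;
* i.i.d. Gaussian sensor noise, and a matched noise-only empty-room
  recording drawn from the same process.

Every statistical property the pipeline is tested against (EMG spectral
peak, coupling band, lag) is verifiable on the generator's raw output before
any inverse step, and generation is deterministic given the scenario seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .forward import LeadField, reduce_orientations, sphere_leadfield
from .geometry import SensorArray, SourceGrid, build_source_grid, spherical_cap_sensors
from .preprocess import BANDS, Recording

__all__ = [
    "Scenario",
    "GroundTruth",
    "SourceActivity",
    "simulate_emg",
    "simulate_sources",
    "simulate_meg",
    "simulate_dataset",
    "scenario_presets",
    "default_geometry",
    "REFERENCE_SNR",
]

#: Reference sensor-level SNR (RMS of the coupled-source field over RMS of the
#: sensor noise). Calibrated once with scripts/calibrate_snr.py so that the
#: healthy presets localize the simulated M1 node in essentially every run
#: while the no-coupling control stays at the false-positive floor; frozen.
REFERENCE_SNR = 1.0

#: Background brain activity level as a multiple of the sensor-noise RMS.
BACKGROUND_RMS_RATIO = 1.0


@dataclass
class CouplingSpec:
    """One band-limited brain→EMG coupling at a fixed negative lag."""

    band: str  # key into BANDS
    lag_ms: float = -50.0  # in [-100, 0]; brain leads EMG by |lag|
    gain: float = 1.0  # relative weight among coupled bands
    intrinsic_gain: float = 0.3  # uncoupled oscillation in the same band
    orientation_deg: float = 30.0  # fixed mix angle in the tangent plane
    #: optional (lo, hi) Hz overriding the nominal band edges for the coupled
    #: component, used to keep it well inside its band: with finite-order
    #: analysis filters, content at a shared band edge would bleed into the
    #: neighboring band's chain and blur the band assignment.
    band_hz: tuple | None = None


@dataclass
class Scenario:
    name: str = "healthy_theta"
    duration: float = 60.0
    sfreq: float = 1000.0
    movement_rate: float = 1.0  # Hz
    rate_jitter_cv: float = 0.15
    irregular: bool = False  # broad interval distribution, no spectral peak
    side: str = "right"  # moving hand; M1 target is contralateral
    couplings: list = field(default_factory=lambda: [CouplingSpec("theta")])
    n_background: int = 15
    one_over_f_exponent: float = 1.0
    alpha_bump_gain: float = 1.0
    sensor_noise_rms: float = 2.0e-13  # tesla
    target_snr: float = REFERENCE_SNR
    target_coord: np.ndarray | None = None  # meters; overrides the M1 default
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.couplings:
            if not (-100.0 <= c.lag_ms <= 0.0):
                raise ValueError(f"coupling lag {c.lag_ms} ms outside the −100…0 ms window")
            if c.gain < 0 or c.intrinsic_gain < 0:
                raise ValueError("coupling gains must be >= 0")
        if self.target_snr <= 0:
            raise ValueError("target SNR must be positive")


@dataclass
class GroundTruth:
    target_node: int
    target_coord_mm: np.ndarray
    lags_ms: dict  # band -> lag
    coupled_bands: list
    side: str
    seed: int


@dataclass
class SourceActivity:
    """Sparse source time courses: only active nodes are materialized."""

    node_indices: np.ndarray  # (n_active,)
    courses: np.ndarray  # (n_active, 2, T) theta/phi moments, A·m
    n_nodes: int
    coupled_mask: np.ndarray  # (n_active,) True where the node is EMG-coupled

    def to_dense(self) -> np.ndarray:
        Q = np.zeros((2 * self.n_nodes, self.courses.shape[2]))
        for i, node in enumerate(self.node_indices):
            Q[2 * node : 2 * node + 2] = self.courses[i]
        return Q


# ---------------------------------------------------------------------------
# geometry

def default_geometry(spacing: float = 0.01, n_sensors: int = 102):
    """Desk-scale head geometry: 102 magnetometers on a 0.102-m cap and a
    spherical-shell source grid (15–55 mm radius; cortex is not at the head
    center) on a cubic lattice."""
    sensors = spherical_cap_sensors(n_sensors=n_sensors, radius=0.102)
    rmin, rmax = 0.015, 0.055

    def inside(xyz):
        r = np.linalg.norm(xyz, axis=1)
        return (r > rmin) & (r < rmax)

    grid = build_source_grid(("mask", inside, (-rmax * np.ones(3), rmax * np.ones(3))), spacing)
    return grid, sensors


#: Simulated M1 hand-knob locations (meters): left hemisphere (x<0) moves the
#: right hand and vice versa.
M1_COORDS = {"left": np.array([-0.035, -0.005, 0.04]), "right": np.array([0.035, -0.005, 0.04])}


def _m1_node(grid: SourceGrid, scn: Scenario) -> int:
    if scn.target_coord is not None:
        return grid.nearest_node(scn.target_coord)
    hemis = "left" if scn.side == "right" else "right"  # contralateral
    return grid.nearest_node(M1_COORDS[hemis])


# ---------------------------------------------------------------------------
# EMG

def _burst_times(scn: Scenario, rng) -> np.ndarray:
    mean_iv = 1.0 / scn.movement_rate
    times, t = [], 0.4 * mean_iv
    while t < scn.duration - 0.2:
        times.append(t)
        if scn.irregular:
            t += rng.uniform(0.35, 2.2)
        else:
            t += max(0.3 * mean_iv, mean_iv * (1.0 + scn.rate_jitter_cv * rng.standard_normal()))
    return np.asarray(times)


def _burst_train(times, amps, scn: Scenario, rng, env_width: float = 0.150,
                 lf_gain: float = 0.8) -> np.ndarray:
    """EMG burst train: each movement contributes an amplitude-modulated
    20-150 Hz carrier burst plus a slow (~50 ms sigma) deflection — the
    movement-locked low-frequency component that puts the movement rate and
    its harmonics at the top of the raw EMG spectrum."""
    T = int(round(scn.duration * scn.sfreq))
    x = np.zeros(T)
    t = np.arange(T) / scn.sfreq
    nwin = int(round(env_width * scn.sfreq))
    env = np.hanning(nwin)
    sos = sps.butter(4, [20.0, 150.0], btype="bandpass", fs=scn.sfreq, output="sos")
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * scn.sfreq))
        if i0 + nwin > T:
            break
        carrier = sps.sosfilt(sos, rng.standard_normal(nwin + 200))[200:]
        carrier /= carrier.std() + 1e-300
        x[i0 : i0 + nwin] += a * env * carrier
        x += (a * lf_gain) * np.exp(-0.5 * ((t - t0 - env_width / 2) / 0.05) ** 2)
    return x


def simulate_emg(scn: Scenario, rng=None) -> Recording:
    """Two-channel surface EMG of a self-paced flex/extend movement.

    Flexor bursts at the (jittered) movement times; extensor bursts offset by
    roughly half a burst so the two envelopes are in anti-phase. In irregular
    mode, inter-burst intervals are drawn from a broad uniform distribution,
    destroying the movement-frequency spectral peak.
    """
    if scn.duration < 5.0:
        raise ValueError("EMG simulation needs at least 5 s")
    rng = np.random.default_rng(scn.seed) if rng is None else rng
    times = _burst_times(scn, rng)
    if times.size < 5:
        warnings.warn(f"only {times.size} movement bursts in {scn.duration} s")
    amps = 1.0 + 0.2 * rng.standard_normal(times.size)
    flexor = _burst_train(times, amps, scn, rng)
    ext_amps = 1.0 + 0.2 * rng.standard_normal(times.size)
    extensor = _burst_train(times + 0.075, ext_amps, scn, rng)
    data = np.vstack([flexor, extensor])
    data = data + 0.02 * data.std() * rng.standard_normal(data.shape)
    return Recording(
        data=data, sfreq=scn.sfreq, kind="EMG", labels=["flexor", "extensor"],
        meta={"scenario": scn.name, "burst_times": times, "seed": scn.seed},
    )


# ---------------------------------------------------------------------------
# sources

def _advance(x: np.ndarray, n: int) -> np.ndarray:
    """x(t + n/fs): shift left by n samples, zero-padded at the end."""
    if n == 0:
        return x.copy()
    out = np.zeros_like(x)
    out[:-n] = x[n:]
    return out


def _one_over_f_noise(T, sfreq, exponent, alpha_gain, rng):
    white = rng.standard_normal(T)
    freqs = np.fft.rfftfreq(T, 1.0 / sfreq)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    shape += alpha_gain * np.exp(-0.5 * ((freqs - 10.0) / 1.5) ** 2)
    x = np.fft.irfft(np.fft.rfft(white) * shape, n=T)
    return x / (x.std() + 1e-300)


def simulate_sources(scn: Scenario, emg: Recording, grid: SourceGrid, rng=None) -> tuple[SourceActivity, GroundTruth]:
    """Source time courses: coupled M1 node + background sources.

    The coupled component per band is the agonist (flexor) EMG band-filtered
    to the coupling band, advanced by |lag|, RMS-normalized, scaled by the
    coupling gain, and assigned a fixed tangential orientation mix. (Coupling
    to a single channel keeps the lag well defined per delay chain; the
    flexor/extensor envelopes are offset in time, so a summed reference would
    smear the effective lag.) Background sources with 1/f spectra and an
    alpha bump are placed at random nodes at least 15 mm from the target.
    """
    rng = np.random.default_rng(scn.seed + 1) if rng is None else rng
    T = emg.n_samples
    target = _m1_node(grid, scn)
    emg_mix = sps.detrend(emg.data[0], type="linear")

    course = np.zeros((2, T))
    lags = {}
    for c in scn.couplings:
        band = BANDS[c.band]
        if not (-100.0 <= c.lag_ms <= 0.0):
            raise ValueError(f"lag {c.lag_ms} outside window")
        lags[c.band] = c.lag_ms
        if c.gain > 0:
            lo, hi = c.band_hz if c.band_hz is not None else (band.lo, band.hi)
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=scn.sfreq, output="sos")
            comp = sps.sosfiltfilt(sos, emg_mix)
            comp = _advance(comp, int(round(-c.lag_ms * scn.sfreq / 1000.0)))
            comp = comp / (np.sqrt(np.mean(comp**2)) + 1e-300)
        else:
            comp = np.zeros(T)
        if c.intrinsic_gain > 0:
            sos = sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=scn.sfreq, output="sos")
            nb = sps.sosfiltfilt(sos, rng.standard_normal(T))
            nb /= np.sqrt(np.mean(nb**2)) + 1e-300
        else:
            nb = np.zeros(T)
        psi = np.deg2rad(c.orientation_deg)
        mix = c.gain * comp + c.intrinsic_gain * nb
        course[0] += np.cos(psi) * mix
        course[1] += np.sin(psi) * mix

    # background sources away from the target
    dist = np.linalg.norm(grid.node_coords - grid.node_coords[target], axis=1)
    candidates = np.flatnonzero(dist > 0.015)
    n_bg = min(scn.n_background, candidates.size)
    bg_nodes = rng.choice(candidates, size=n_bg, replace=False)
    nodes = [target] + list(bg_nodes)
    courses = np.zeros((len(nodes), 2, T))
    courses[0] = course
    for i in range(n_bg):
        psi = rng.uniform(0, 2 * np.pi)
        x = _one_over_f_noise(T, scn.sfreq, scn.one_over_f_exponent, scn.alpha_bump_gain, rng)
        courses[1 + i, 0] = np.cos(psi) * x
        courses[1 + i, 1] = np.sin(psi) * x

    coupled = np.zeros(len(nodes), dtype=bool)
    coupled[0] = any(c.gain > 0 for c in scn.couplings)
    activity = SourceActivity(
        node_indices=np.asarray(nodes, dtype=int), courses=courses,
        n_nodes=grid.n_nodes, coupled_mask=coupled,
    )
    truth = GroundTruth(
        target_node=target,
        target_coord_mm=grid.node_coords[target] * 1000.0,
        lags_ms=lags,
        coupled_bands=[c.band for c in scn.couplings if c.gain > 0],
        side=scn.side, seed=scn.seed,
    )
    return activity, truth


# ---------------------------------------------------------------------------
# MEG

def simulate_meg(
    activity: SourceActivity,
    leadfield: LeadField,
    sensor_noise_rms: float,
    target_snr: float | None,
    rng=None,
    background_rms_ratio: float = BACKGROUND_RMS_RATIO,
    seed: int = 0,
) -> tuple[Recording, Recording]:
    """Sensor data B = G Q + N and a matched empty-room recording.

    The coupled-source contribution is scaled so its sensor-level RMS is
    ``target_snr`` × the sensor-noise RMS; background sources are scaled to
    ``background_rms_ratio`` × the noise RMS. With zero noise the data are
    exactly G Q (a specified SNR is then ignored with a warning).
    """
    rng = np.random.default_rng(seed + 2) if rng is None else rng
    M = leadfield.n_sensors
    T = activity.courses.shape[2]
    cols = np.concatenate([[2 * n, 2 * n + 1] for n in activity.node_indices])
    Gact = leadfield.G[:, cols]
    Q = activity.courses.reshape(-1, T)
    coupled_rows = np.repeat(activity.coupled_mask, 2)
    B_coup = Gact[:, coupled_rows] @ Q[coupled_rows]
    B_bg = Gact[:, ~coupled_rows] @ Q[~coupled_rows]

    if sensor_noise_rms == 0.0:
        if target_snr is not None:
            warnings.warn("zero sensor noise: target SNR ignored, data are exactly G·Q")
        noise = np.zeros((M, T))
        er = np.zeros((M, T))
        B = B_coup + B_bg
    else:
        noise = sensor_noise_rms * rng.standard_normal((M, T))
        er = sensor_noise_rms * rng.standard_normal((M, T))
        rms = lambda x: np.sqrt(np.mean(x**2))
        if target_snr is not None and rms(B_coup) > 0:
            B_coup = B_coup * (target_snr * sensor_noise_rms / rms(B_coup))
        if rms(B_bg) > 0:
            B_bg = B_bg * (background_rms_ratio * sensor_noise_rms / rms(B_bg))
        B = B_coup + B_bg + noise
    meg = Recording(data=B, sfreq=1000.0, kind="MEG", meta={"seed": seed})
    empty = Recording(data=er, sfreq=1000.0, kind="empty_room", meta={"seed": seed})
    return meg, empty


def simulate_dataset(scn: Scenario, grid: SourceGrid | None = None,
                     sensors: SensorArray | None = None,
                     leadfield: LeadField | None = None) -> dict:
    """Full dataset for one scenario: EMG, MEG, empty room, and ground truth.

    Geometry and lead field default to :func:`default_geometry` with the
    sphere forward model; pass precomputed objects to amortize the forward
    solution across datasets.
    """
    if grid is None or sensors is None:
        grid, sensors = default_geometry()
    if leadfield is None:
        leadfield = reduce_orientations(sphere_leadfield(grid, sensors), grid, sensors)
    rng = np.random.default_rng(scn.seed)
    emg = simulate_emg(scn, rng)
    activity, truth = simulate_sources(scn, emg, grid, rng)
    meg, empty = simulate_meg(
        activity, leadfield, scn.sensor_noise_rms, scn.target_snr, rng, seed=scn.seed
    )
    for rec in (meg, empty, emg):
        rec.meta["scenario"] = scn.name
    meg.sfreq = empty.sfreq = scn.sfreq
    return {
        "scenario": scn, "grid": grid, "sensors": sensors, "leadfield": leadfield,
        "emg": emg, "meg": meg, "empty_room": empty,
        "activity": activity, "truth": truth,
    }


# ---------------------------------------------------------------------------
# presets

def scenario_presets(seed: int = 0, side: str = "right") -> dict:
    """The five standard study conditions.

    * ``healthy_theta`` — theta-band coupling only, lag −50 ms.
    * ``healthy_multiband`` — delta, theta and beta coupled (lags −60, −50,
      −40 ms); alpha and gamma left uncoupled, matching the positive/negative
      band pattern the method is expected to reproduce.
    * ``irregular_patient`` — erratic movement timing, no movement-frequency
      spectral peak, theta coupling intact.
    * ``deep_source`` — theta coupling at a deep (20 mm radius) node.
    * ``null_no_coupling`` — background and noise only; any localization
      "success" is a false positive.
    """
    mk = lambda band, lag: CouplingSpec(band=band, lag_ms=lag)
    presets = {
        "healthy_theta": Scenario(
            name="healthy_theta", couplings=[mk("theta", -50.0)], seed=seed, side=side,
        ),
        "healthy_multiband": Scenario(
            name="healthy_multiband",
            couplings=[
                CouplingSpec("delta", -60.0, gain=2.5),
                CouplingSpec("theta", -50.0, gain=1.0),
                CouplingSpec("beta", -40.0, gain=0.7, band_hz=(15.0, 24.0)),
            ],
            seed=seed, side=side,
        ),
        "irregular_patient": Scenario(
            name="irregular_patient", irregular=True,
            couplings=[mk("theta", -50.0)], seed=seed, side=side,
        ),
        "deep_source": Scenario(
            name="deep_source", couplings=[mk("theta", -50.0)], seed=seed, side=side,
            target_coord=np.array([0.02, 0.0, 0.01]),
        ),
        "null_no_coupling": Scenario(
            name="null_no_coupling",
            couplings=[CouplingSpec("theta", -50.0, gain=0.0, intrinsic_gain=0.0)],
            seed=seed, side=side,
        ),
    }
    return presets
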