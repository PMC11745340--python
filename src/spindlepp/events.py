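"""Event trains, hypnograms and covariate series on the model time grid.

A recording is reduced to three aligned pieces of information: a spindle
event train (one time point per detected spindle), a 30-s-epoch hypnogram,
and continuous slow-oscillation (SO) covariates — instantaneous phase of the
0.4–1.5 Hz band (0 = up-state peak, cosine convention) and normalized SO
power (SOP), a continuous sleep-depth proxy.  Everything downstream operates
on a common bin grid (default 0.1 s) with binary per-bin event counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: the five scored sleep stages, in canonical order
STAGES = ("N1", "N2", "N3", "REM", "Wake")

#: slow-oscillation band (Hz) used for phase extraction
SO_BAND = (0.4, 1.5)
#: band (Hz) used for SO power
SOP_BAND = (0.3, 1.5)


@dataclass(frozen=True)
class EventTrain:
    """Ordered spindle event times (s from recording start)."""

    times: np.ndarray
    duration_s: float
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("event times must be a 1-D array")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if times.size:
            if np.any(~np.isfinite(times)):
                raise ValueError("event times must be finite")
            if np.any(np.diff(times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration_s:
                raise ValueError("event times must lie in [0, duration_s]")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def rate_per_min(self) -> float:
        return 60.0 * self.n_events / self.duration_s


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch sleep-stage labels (standard 30-s scoring epochs)."""

    stages: tuple
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        bad = sorted({s for s in stages} - set(STAGES))
        if bad:
            raise ValueError(
                f"unknown stage label(s) {bad}; allowed: {list(STAGES)}"
            )

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_s

    def stage_at(self, t: np.ndarray) -> np.ndarray:
        """Stage label at each time (clamped to the last epoch)."""
        idx = np.clip(
            (np.asarray(t, float) // self.epoch_s).astype(int),
            0,
            len(self.stages) - 1,
        )
        arr = np.asarray(self.stages, dtype=object)
        return arr[idx]


@dataclass
class CovariateSeries:
    """Binned stage / SO-phase / SOP traces plus binary event counts.

    All arrays share one half-open bin grid ``[k*dt, (k+1)*dt)``; continuous
    covariates are evaluated at bin centers.  ``event_times`` keeps the exact
    event times so history lags are not quantized to the bin width.
    """

    dt_s: float
    stage: np.ndarray          # per-bin stage label (object array)
    phase: np.ndarray          # per-bin SO phase, (−π, π]
    sop: np.ndarray            # per-bin normalized SO power, [0, 1]
    counts: np.ndarray         # per-bin event count, {0, 1}
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        n = len(self.counts)
        for name in ("stage", "phase", "sop"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"covariate array {name!r} length mismatch")
        if not np.all(np.isin(self.counts, (0, 1))):
            raise ValueError("counts must be binary")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.dt_s

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.dt_s


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (−π, π]."""
    phi = np.asarray(phi, dtype=float)
    out = np.mod(-phi + np.pi, 2.0 * np.pi)
    return np.pi - out


def _so_bandpass(eeg: np.ndarray, fs_hz: float, band) -> np.ndarray:
    """Zero-phase FIR bandpass; no group delay by construction."""
    lo, hi = band
    numtaps = int(4 * fs_hz / lo)  # ~4 cycles of the low edge
    numtaps += (numtaps + 1) % 2   # force odd
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs_hz)
    return signal.filtfilt(taps, [1.0], eeg, padtype="even")


def compute_so_phase(eeg: np.ndarray, fs_hz: float, band=SO_BAND) -> np.ndarray:
    """Instantaneous SO phase per sample, cosine convention.

    The signal is bandpassed (zero-phase FIR) to the SO band and the phase is
    the angle of its analytic signal, so phase 0 falls on band-limited signal
    maxima (up-states), −π/+π on troughs, and negative phase on the rising
    flank.  Output is wrapped to (−π, π].
    """
    eeg = np.asarray(eeg, dtype=float)
    if np.any(~np.isfinite(eeg)):
        raise ValueError("EEG contains non-finite samples")
    if fs_hz < 50:
        raise ValueError("sampling rate must be ≥ 50 Hz")
    if eeg.size < 30 * fs_hz:
        raise ValueError("need at least 30 s of signal")
    so = _so_bandpass(eeg, fs_hz, band)
    return wrap_phase(np.angle(signal.hilbert(so)))


def compute_so_power(
    eeg: np.ndarray,
    fs_hz: float,
    window_s: float = 4.0,
    step_s: float = 1.0,
    band=SOP_BAND,
    normalize: bool = True,
):
    """Sliding-window SO band power in dB, optionally normalized to [0, 1].

    Band power (0.3–1.5 Hz by default) is computed per Hann window via Welch
    on each segment, expressed in dB, then (if ``normalize``) scaled per
    recording by its 5th–95th percentile range and clipped to [0, 1] — a
    robust, recording-relative normalization.

    Returns ``(t_centers, sop)`` where ``sop`` is normalized (or raw dB when
    ``normalize=False``).
    """
    eeg = np.asarray(eeg, dtype=float)
    lo, hi = band
    if window_s < 4.0:  # two cycles of a nominal 0.5-Hz slow oscillation
        raise ValueError("window must span at least 2 SO cycles (4 s)")
    nper = int(window_s * fs_hz)
    step = int(step_s * fs_hz)
    if nper > eeg.size:
        raise ValueError("signal shorter than one analysis window")
    starts = np.arange(0, eeg.size - nper + 1, step)
    t_centers = (starts + nper / 2) / fs_hz
    win = np.hanning(nper)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs_hz)
    band_mask = (freqs >= lo) & (freqs <= hi)
    u = (win ** 2).sum() * fs_hz  # PSD normalization
    power = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        seg = eeg[s0 : s0 + nper]
        spec = np.abs(np.fft.rfft((seg - seg.mean()) * win)) ** 2 / u
        power[i] = spec[band_mask].sum() * (freqs[1] - freqs[0])
    sop_db = 10.0 * np.log10(np.maximum(power, 1e-300))
    if not normalize:
        return t_centers, sop_db
    p5, p95 = np.percentile(sop_db, [5, 95])
    if p95 - p5 < 1e-12:
        return t_centers, np.full_like(sop_db, 0.5)
    return t_centers, np.clip((sop_db - p5) / (p95 - p5), 0.0, 1.0)


def bin_events(train: EventTrain, dt_s: float) -> np.ndarray:
    """Binary per-bin event counts on half-open bins [k·dt, (k+1)·dt).

    Two events in one bin are capped at 1 with a logged warning (the
    discrete-time Bernoulli likelihood needs binary counts).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    n_bins = int(np.ceil(train.duration_s / dt_s))
    counts = np.zeros(n_bins, dtype=int)
    idx = np.minimum((train.times // dt_s).astype(int), n_bins - 1)
    np.add.at(counts, idx, 1)
    n_coll = int((counts[counts > 1] - 1).sum())
    if n_coll:
        logger.warning(
            "%d event collision(s) capped at 1 event/bin (dt=%.3g s)",
            n_coll,
            dt_s,
        )
        counts = np.minimum(counts, 1)
    return counts


def assemble_covariates(
    train: EventTrain,
    hypnogram: Hypnogram,
    phase: np.ndarray,
    sop: np.ndarray,
    dt_s: float = 0.1,
    phase_t: np.ndarray | None = None,
    sop_t: np.ndarray | None = None,
) -> CovariateSeries:
    """Align events, stages and SO covariates on one bin grid.

    ``phase``/``sop`` may be given either already on the target grid (same
    number of bins) or as irregular samples with their own time axes
    (``phase_t``/``sop_t``), in which case they are interpolated to bin
    centers (phase via its cos/sin embedding to avoid wrap artifacts).
    Inputs whose spans differ by more than one epoch raise; smaller
    mismatches truncate to the common span with a warning.
    """
    spans = [train.duration_s, hypnogram.duration_s]
    if max(spans) - min(spans) > hypnogram.epoch_s:
        raise ValueError(
            f"recording spans differ by more than one epoch: {spans}"
        )
    if max(spans) - min(spans) > 1e-9:
        warnings.warn("inputs truncated to common span", stacklevel=2)
    duration = min(spans)
    n_bins = int(np.floor(duration / dt_s + 1e-9))
    centers = (np.arange(n_bins) + 0.5) * dt_s

    def _to_grid(x, t_x, circular):
        x = np.asarray(x, dtype=float)
        if t_x is None:
            if x.size < n_bins:
                raise ValueError("gridded covariate shorter than bin grid")
            return x[:n_bins]
        if circular:
            c = np.interp(centers, t_x, np.cos(x))
            s = np.interp(centers, t_x, np.sin(x))
            return wrap_phase(np.arctan2(s, c))
        return np.interp(centers, t_x, x)

    phase_b = wrap_phase(_to_grid(phase, phase_t, circular=True))
    sop_b = np.clip(_to_grid(sop, sop_t, circular=False), 0.0, 1.0)
    stage_b = hypnogram.stage_at(centers)
    counts = bin_events(train, dt_s)[:n_bins]
    times = train.times[train.times < n_bins * dt_s]
    return CovariateSeries(
        dt_s=dt_s,
        stage=stage_b,
        phase=phase_b,
        sop=sop_b,
        counts=counts,
        event_times=times,
    )


def naive_sigma_detector(
    eeg: np.ndarray,
    fs_hz: float,
    band=(12.0, 16.0),
    threshold_sd: float = 2.0,
    min_duration_s: float = 0.4,
) -> np.ndarray:
    """Toy sigma-band envelope detector (demo plumbing only).

    Bandpasses to the sigma range, takes the smoothed Hilbert envelope, and
    marks each suprathreshold excursion longer than ``min_duration_s`` by its
    envelope-peak time.  This is a fixture for end-to-end demos and carries
    no detection-accuracy claims; production event trains come from an
    upstream detector.
    """
    eeg = np.asarray(eeg, dtype=float)
    sos = signal.butter(4, band, btype="bandpass", fs=fs_hz, output="sos")
    sig = signal.sosfiltfilt(sos, eeg)
    env = np.abs(signal.hilbert(sig))
    smooth_n = max(int(0.2 * fs_hz), 1)
    env = np.convolve(env, np.ones(smooth_n) / smooth_n, mode="same")
    thr = env.mean() + threshold_sd * env.std()
    above = env > thr
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    peaks = [
        s + np.argmax(env[s:e])
        for s, e in zip(starts, ends)
        if (e - s) / fs_hz >= min_duration_s
    ]
    return np.asarray(peaks, dtype=float) / fs_hz
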