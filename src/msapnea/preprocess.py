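"""ECG preprocessing: denoising, R-peak detection, derived signals, segmentation.

Pipeline order: a linear-phase FIR band-pass (3–45 Hz) removes baseline
wander, powerline interference and most EMG noise; a Pan–Tompkins-style
detector (Hamilton-flavoured adaptive thresholds with searchback) locates R
peaks; the RR-interval tachogram and R-peak amplitude series — both
irregularly sampled at the peak times — are resampled to a uniform 5 Hz grid
with a natural cubic spline; finally each annotated minute becomes one
2-channel, 300-sample segment (z-scored per channel) unless it fails the
abnormal-minute rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import fftconvolve, firwin

from .ecg_io import ECGRecord, LABEL_APNEA, LABEL_NORMAL

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec", "RPeakSeries", "DerivedSignals", "SegmentDataset",
    "bandpass", "detect_r_peaks", "derive_series", "resample_uniform",
    "segment_and_filter",
]

#: minimum spacing between accepted R peaks (seconds)
REFRACTORY_S = 0.2
#: half-width of the local-maximum refinement window (seconds)
REFINE_S = 0.05
#: moving-window integration length (seconds), after Pan–Tompkins
MWI_S = 0.15


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR band-pass specification (defaults: 3–45 Hz)."""

    low_cut: float = 3.0
    high_cut: float = 45.0

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")

    def n_taps(self, sampling_rate: float) -> int:
        """Tap count ≈ one second of signal, rounded up to odd."""
        n = int(round(sampling_rate))
        return n + 1 if n % 2 == 0 else n

    def taps(self, sampling_rate: float) -> np.ndarray:
        if self.high_cut >= sampling_rate / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz needs sampling_rate > "
                f"{2 * self.high_cut} Hz, got {sampling_rate}")
        return firwin(self.n_taps(sampling_rate),
                      [self.low_cut, self.high_cut],
                      pass_zero=False, fs=sampling_rate)


@dataclass
class RPeakSeries:
    """R-peak occurrence times (s, strictly increasing) and amplitudes (mV)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DerivedSignals:
    """Uniformly resampled RR and amplitude channels for one window."""

    grid_rate: float
    rr_channel: np.ndarray
    amp_channel: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rr_channel) != len(self.amp_channel):
            raise ValueError("channels must have equal length")


@dataclass
class SegmentDataset:
    """Fixed-length 2-channel derived-signal segments with binary labels.

    ``segments`` has shape (n, 2, samples_per_segment): channel 0 is the
    z-scored RR spline, channel 1 the z-scored amplitude spline. The
    pre-normalization channel mean/std are kept in ``norm_mean``/``norm_std``
    for de-normalization bookkeeping.
    """

    segments: np.ndarray
    labels: np.ndarray          # 0 = N, 1 = AH
    record_ids: np.ndarray
    minute_indices: np.ndarray
    norm_mean: np.ndarray = field(default=None)  # (n, 2)
    norm_std: np.ndarray = field(default=None)   # (n, 2)
    n_rejected: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def concatenate(parts: list["SegmentDataset"]) -> "SegmentDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("no segments to concatenate")
        rejected: dict[str, int] = {}
        for p in parts:
            rejected.update(p.n_rejected)
        return SegmentDataset(
            segments=np.concatenate([p.segments for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            record_ids=np.concatenate([p.record_ids for p in parts]),
            minute_indices=np.concatenate([p.minute_indices for p in parts]),
            norm_mean=np.concatenate([p.norm_mean for p in parts]),
            norm_std=np.concatenate([p.norm_std for p in parts]),
            n_rejected=rejected,
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path, segments=self.segments, labels=self.labels,
            record_ids=self.record_ids.astype(str),
            minute_indices=self.minute_indices,
            norm_mean=self.norm_mean, norm_std=self.norm_std)

    @classmethod
    def load(cls, path) -> "SegmentDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(segments=z["segments"], labels=z["labels"],
                       record_ids=z["record_ids"],
                       minute_indices=z["minute_indices"],
                       norm_mean=z["norm_mean"], norm_std=z["norm_std"])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass(record: ECGRecord, spec: FilterSpec = FilterSpec()) -> ECGRecord:
    """Apply the FIR band-pass with group-delay compensation.

    The filter is linear-phase; convolving in ``same`` mode centres the
    response, so the output is time-aligned with the input and has the
    same length.
    """
    taps = spec.taps(record.sampling_rate)
    filtered = fftconvolve(record.samples, taps, mode="same")
    return ECGRecord(record_id=record.record_id, samples=filtered,
                     sampling_rate=record.sampling_rate,
                     minute_labels=record.minute_labels)


# ---------------------------------------------------------------------------
# R-peak detection (Pan–Tompkins with Hamilton-style adaptive thresholds)
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average (zero-phase, same length)."""
    kernel = np.full(n, 1.0 / n)
    return fftconvolve(x, kernel, mode="same")


def detect_r_peaks(record: ECGRecord) -> RPeakSeries:
    """Locate R peaks on a band-passed record.

    Classic chain: derivative → squaring → 150 ms moving-window integration
    (centred, so no group delay) → adaptive dual thresholds with a 200 ms
    refractory period and searchback at 1.5× the running RR estimate; the
    final peak index is refined to the local maximum of the filtered ECG
    within ±50 ms, where the amplitude is read off.
    """
    fs = record.sampling_rate
    x = record.samples
    if len(x) < 2 * fs:
        raise ValueError("record shorter than 2 s")
    if np.ptp(x) == 0:
        return RPeakSeries(times=np.empty(0), amplitudes=np.empty(0))

    deriv = np.gradient(x)
    mwi = _moving_average(deriv ** 2, max(int(round(MWI_S * fs)), 1))

    refractory = int(round(REFRACTORY_S * fs))
    # candidate peaks: local maxima of the integrated signal
    cand = np.flatnonzero((mwi[1:-1] > mwi[:-2]) & (mwi[1:-1] >= mwi[2:])) + 1
    if cand.size == 0:
        return RPeakSeries(times=np.empty(0), amplitudes=np.empty(0))

    # initial signal/noise estimates from the first two seconds
    init = mwi[: int(2 * fs)]
    spki = float(init.max())
    npki = float(init.mean())

    accepted: list[int] = []
    rr_est = 0.8 * fs  # running RR estimate in samples
    last = -10 * refractory
    pending: list[int] = []  # candidates since the last accepted peak

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        v = mwi[c]
        if v > threshold():
            if accepted and c - last < refractory:
                # within refractory: keep the larger deflection
                if v > mwi[last]:
                    accepted[-1] = c
                    spki = 0.125 * v + 0.875 * spki
                    last = c
                continue
            accepted.append(c)
            spki = 0.125 * v + 0.875 * spki
            if len(accepted) > 1:
                rr_est = 0.875 * rr_est + 0.125 * (c - accepted[-2])
            last = c
            pending = []
        else:
            npki = 0.125 * v + 0.875 * npki
            pending.append(c)
            # searchback: no accepted peak for 1.5x the RR estimate
            if accepted and c - last > 1.5 * rr_est and pending:
                best = max(pending, key=lambda i: mwi[i])
                if mwi[best] > 0.5 * threshold() and best - last >= refractory:
                    accepted.append(best)
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    rr_est = 0.875 * rr_est + 0.125 * (best - last)
                    last = best
                    pending = []

    if not accepted:
        return RPeakSeries(times=np.empty(0), amplitudes=np.empty(0))

    # refine to the local maximum of the filtered ECG within +-50 ms
    win = int(round(REFINE_S * fs))
    refined: list[int] = []
    for c in accepted:
        lo, hi = max(c - win, 0), min(c + win + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    # refinement can merge neighbours: dedupe and re-impose the refractory
    idx: list[int] = []
    for r in sorted(set(refined)):
        if idx and r - idx[-1] < refractory:
            if x[r] > x[idx[-1]]:
                idx[-1] = r
        else:
            idx.append(r)
    idx_arr = np.asarray(idx)
    return RPeakSeries(times=idx_arr / fs, amplitudes=x[idx_arr])


# ---------------------------------------------------------------------------
# Derived signals
# ---------------------------------------------------------------------------

def derive_series(peaks: RPeakSeries) -> tuple[np.ndarray, np.ndarray]:
    """Irregular RR and amplitude point series from detected peaks.

    Returns ``(rr_points, amp_points)`` where ``rr_points`` is an (n-1, 2)
    array of ``(t_i, t_i - t_{i-1})`` — the tachogram — and ``amp_points``
    an (n, 2) array of ``(t_i, a_i)``. The first peak contributes no RR
    point.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to derive an RR series")
    rr = np.diff(peaks.times)
    rr_points = np.column_stack([peaks.times[1:], rr])
    amp_points = np.column_stack([peaks.times, peaks.amplitudes])
    return rr_points, amp_points


def resample_uniform(points: np.ndarray, grid_rate: float,
                     window: tuple[float, float]) -> np.ndarray:
    """Natural-cubic-spline resampling of an irregular series onto a grid.

    Grid times are ``window_start + k / grid_rate`` for
    ``k = 0 .. round((end-start)*grid_rate) - 1``. Query times outside the
    span of the points are clamped to the nearest knot (boundary-value
    extension). Knot ordinates are reproduced exactly.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (t, value)")
    if len(points) < 4:
        raise ValueError("need at least 4 points for cubic spline resampling")
    t, v = points[:, 0], points[:, 1]
    order = np.argsort(t)
    t, v = t[order], v[order]
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate abscissae in point series")
    start, end = window
    n = int(round((end - start) * grid_rate))
    grid = start + np.arange(n) / grid_rate
    spline = CubicSpline(t, v, bc_type="natural")
    return spline(np.clip(grid, t[0], t[-1]))


# ---------------------------------------------------------------------------
# Segmentation + abnormal-minute removal
# ---------------------------------------------------------------------------

#: physiological RR plausibility band (seconds)
RR_MIN_S, RR_MAX_S = 0.3, 2.0
#: minimum detected peaks in the padded minute window
MIN_PEAKS_PER_MINUTE = 20
#: padding around each minute used for peak counting and spline support (s)
MINUTE_PAD_S = 5.0


def segment_and_filter(record: ECGRecord, peaks: RPeakSeries,
                       labels: list[str] | None = None,
                       grid_rate: float = 5.0,
                       rr_min: float = RR_MIN_S,
                       rr_max: float = RR_MAX_S,
                       min_peaks: int = MIN_PEAKS_PER_MINUTE) -> SegmentDataset:
    """Build one 2×(60·grid_rate) segment per labelled minute.

    A minute is rejected as abnormal iff (a) fewer than ``min_peaks``
    detected peaks fall in the ±5 s padded window, (b) any RR interval with
    abscissa inside the minute lies outside ``[rr_min, rr_max]`` s, or
    (c) the spline preconditions fail (too few support points, or a
    zero-variance channel). Each channel is z-scored per segment.
    """
    labels = labels if labels is not None else record.minute_labels
    if labels is None:
        raise ValueError("no per-minute labels available")
    labels = list(labels)
    n_per_seg = int(round(60 * grid_rate))

    if len(peaks) >= 2:
        rr_points, amp_points = derive_series(peaks)
    else:
        rr_points = np.empty((0, 2))
        amp_points = np.empty((0, 2))

    segments, seg_labels, minute_idx = [], [], []
    means, stds = [], []
    rejected = 0
    for k, lab in enumerate(labels):
        start, end = 60.0 * k, 60.0 * (k + 1)
        in_pad = (peaks.times >= start - MINUTE_PAD_S) & \
                 (peaks.times < end + MINUTE_PAD_S) if len(peaks) else \
                 np.empty(0, dtype=bool)
        if int(np.count_nonzero(in_pad)) < min_peaks:
            rejected += 1
            continue
        rr_in_minute = rr_points[(rr_points[:, 0] >= start)
                                 & (rr_points[:, 0] < end), 1]
        if rr_in_minute.size and (
                rr_in_minute.min() < rr_min or rr_in_minute.max() > rr_max):
            rejected += 1
            continue
        rr_sup = rr_points[(rr_points[:, 0] >= start - MINUTE_PAD_S)
                           & (rr_points[:, 0] < end + MINUTE_PAD_S)]
        amp_sup = amp_points[(amp_points[:, 0] >= start - MINUTE_PAD_S)
                             & (amp_points[:, 0] < end + MINUTE_PAD_S)]
        try:
            rr_ch = resample_uniform(rr_sup, grid_rate, (start, end))
            amp_ch = resample_uniform(amp_sup, grid_rate, (start, end))
        except ValueError:
            rejected += 1
            continue
        chans = np.stack([rr_ch, amp_ch])
        mu = chans.mean(axis=1)
        sd = chans.std(axis=1)
        if np.any(sd < 1e-12):
            rejected += 1
            continue
        segments.append((chans - mu[:, None]) / sd[:, None])
        seg_labels.append(1 if lab == LABEL_APNEA else 0)
        minute_idx.append(k)
        means.append(mu)
        stds.append(sd)

    if rejected:
        logger.info("record %s: rejected %d/%d minute(s) as abnormal",
                    record.record_id, rejected, len(labels))
    n = len(segments)
    return SegmentDataset(
        segments=np.asarray(segments, dtype=np.float32).reshape(n, 2, n_per_seg),
        labels=np.asarray(seg_labels, dtype=np.int64),
        record_ids=np.asarray([record.record_id] * n, dtype=object).astype(str),
        minute_indices=np.asarray(minute_idx, dtype=np.int64),
        norm_mean=np.asarray(means, dtype=np.float64).reshape(n, 2),
        norm_std=np.asarray(stds, dtype=np.float64).reshape(n, 2),
        n_rejected={record.record_id: rejected},
    )


def preprocess_record(record: ECGRecord, labels: list[str] | None = None,
                      spec: FilterSpec = FilterSpec(),
                      grid_rate: float = 5.0, **kwargs) -> SegmentDataset:
    """Convenience chain: band-pass → detect peaks → segment."""
    filtered = bandpass(record, spec)
    peaks = detect_r_peaks(filtered)
    return segment_and_filter(filtered, peaks, labels=labels,
                              grid_rate=grid_rate, **kwargs)
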