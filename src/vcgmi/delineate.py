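"""R-peak detection and QRS/T loop segmentation.

Beats are located on the spatial magnitude ``sqrt(x^2 + y^2 + z^2)`` with a
simple adaptive-threshold peak picker, then cut into fixed physiologic
windows: the QRS loop spans +/- 60 ms around the R peak and the T loop the
interval from R + 120 ms to R + min(450 ms, 0.7 * RR). All constants are
exposed in :class:`DelineationConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import find_peaks

from .io import VCGRecord

__all__ = ["DelineationConfig", "BeatLoops", "spatial_magnitude",
           "detect_r_peaks", "segment_beats"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DelineationConfig:
    """Beat-detection and loop-window constants (all durations in ms)."""

    qrs_half_ms: float = 60.0
    t_on_ms: float = 120.0
    t_off_ms_cap: float = 450.0
    t_off_rr_frac: float = 0.7
    refractory_ms: float = 200.0
    threshold_frac: float = 0.5
    rolling_max_s: float = 2.0
    min_rr_ms: float = 300.0


DEFAULT_DELINEATION = DelineationConfig()


@dataclass
class BeatLoops:
    """One beat's QRS and T loop point sets in 3D lead space (mV)."""

    r_index: int
    qrs_points: np.ndarray  # (n_qrs, 3), ordered in time
    t_points: np.ndarray    # (n_t, 3), ordered in time
    rr_prev_ms: float

    def __post_init__(self) -> None:
        self.qrs_points = np.atleast_2d(np.asarray(self.qrs_points, float))
        self.t_points = np.atleast_2d(np.asarray(self.t_points, float))
        if len(self.qrs_points) < 4 or len(self.t_points) < 4:
            raise ValueError("QRS and T loops each need at least 4 points")


def spatial_magnitude(record: VCGRecord) -> np.ndarray:
    """Element-wise spatial vector magnitude of the three leads."""
    return np.sqrt(record.x ** 2 + record.y ** 2 + record.z ** 2)


def detect_r_peaks(magnitude: np.ndarray, fs: float,
                   config: DelineationConfig = DEFAULT_DELINEATION) -> np.ndarray:
    """Detect R peaks on a spatial-magnitude series.

    A sample qualifies when it is a local maximum, exceeds
    ``threshold_frac`` times the rolling maximum over a
    ``rolling_max_s``-second neighborhood, and is separated from stronger
    peaks by at least the refractory period. Returns strictly increasing
    sample indices; an empty array is a valid result.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if len(magnitude) < fs / 2:
        raise ValueError("series too short for beat detection "
                         f"({len(magnitude)} samples at {fs} Hz)")
    distance = max(1, int(round(config.refractory_ms / 1000.0 * fs)))
    peaks, _ = find_peaks(magnitude, distance=distance)
    if len(peaks) == 0:
        return peaks
    size = max(1, int(round(config.rolling_max_s * fs)))
    rolling = maximum_filter1d(magnitude, size=size, mode="nearest")
    keep = magnitude[peaks] >= config.threshold_frac * rolling[peaks]
    return peaks[keep]


def segment_beats(record: VCGRecord, r_peaks: np.ndarray,
                  config: DelineationConfig = DEFAULT_DELINEATION
                  ) -> list[BeatLoops]:
    """Cut each detected beat into QRS and T loop point sets.

    Beats whose QRS or T window would run past either record boundary, or
    whose RR interval to the next beat is shorter than ``min_rr_ms``, are
    dropped (counted in a log line). The RR used for the T-window end is
    the interval to the *next* beat; the last beat uses the median RR of
    the record (or the T cap if the record holds a single beat).
    """
    fs = record.fs
    xyz = record.xyz
    n = len(record)
    r_peaks = np.asarray(r_peaks, dtype=int)

    qrs_half = int(round(config.qrs_half_ms / 1000.0 * fs))
    t_on = int(round(config.t_on_ms / 1000.0 * fs))

    rr_next_ms = np.full(len(r_peaks), np.inf)
    if len(r_peaks) > 1:
        diffs = np.diff(r_peaks) / fs * 1000.0
        rr_next_ms[:-1] = diffs
        rr_next_ms[-1] = float(np.median(diffs))

    beats: list[BeatLoops] = []
    dropped = 0
    for k, r in enumerate(r_peaks):
        rr = rr_next_ms[k]
        if rr < config.min_rr_ms:
            dropped += 1
            continue
        t_off_ms = config.t_off_ms_cap
        if np.isfinite(rr):
            t_off_ms = min(t_off_ms, config.t_off_rr_frac * rr)
        t_off = int(round(t_off_ms / 1000.0 * fs))
        q_lo, q_hi = r - qrs_half, r + qrs_half
        t_lo, t_hi = r + t_on, r + t_off
        if q_lo < 0 or t_hi >= n or t_hi <= t_lo + 3:
            dropped += 1
            continue
        rr_prev = (r - r_peaks[k - 1]) / fs * 1000.0 if k > 0 else rr
        beats.append(BeatLoops(
            r_index=int(r),
            qrs_points=xyz[q_lo : q_hi + 1],
            t_points=xyz[t_lo : t_hi + 1],
            rr_prev_ms=float(rr_prev),
        ))
    if dropped:
        log.info("record %s: dropped %d of %d beats at segmentation",
                 record.record_id, dropped, len(r_peaks))
    return beats
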