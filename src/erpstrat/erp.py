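"""Peak-feature extraction from epoched ERP waveforms.

Turns stimulus-locked epochs into per-subject P1 / N290 / P400 peak
amplitudes (microvolt) and latencies (ms) per stimulus condition, plus the
three condition contrasts (face - noise, direct - averted, toward - away).
The signal of interest is the mean over the designated occipito-temporal
channels of the artifact-cleaned, baseline-corrected epoch average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("FD", "FA", "F", "N", "SD", "SA")

#: contrast name -> (minuend condition, subtrahend condition)
CONTRAST_PARENTS = {
    "face_noise": ("F", "N"),
    "direct_averted": ("FD", "FA"),
    "toward_away": ("SD", "SA"),
}

FLAG_OK = "ok"
FLAG_NO_PEAK = "no-peak"
FLAG_TOO_FEW = "too-few-epochs"


@dataclass
class EpochSet:
    """Epochs for one subject x condition: (epochs, channels, samples) in uV.

    ``times`` is the peristimulus axis in ms (strictly increasing, contains
    0); ``ot_channels`` lists the occipito-temporal channel indices used for
    peak detection.
    """

    subject: str
    condition: str
    data: np.ndarray
    times: np.ndarray
    ot_channels: tuple
    flag: str = FLAG_OK

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match sample count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("time axis must contain 0 (stimulus onset)")
        if len(self.ot_channels) < 1:
            raise ValueError("need at least one occipito-temporal channel")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ComponentWindow:
    """Search window for one component: closed interval [lo, hi] ms and polarity."""

    component: str
    lo: float
    hi: float
    polarity: int  # +1 positive-going, -1 negative-going

    def __post_init__(self):
        if not (0.0 < self.lo < self.hi <= 800.0):
            raise ValueError("window must lie within (0, 800] ms")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


def default_windows() -> dict:
    """Standard infant face-ERP component windows (configurable).

    P1 positive [70, 170] ms, N290 negative [200, 350] ms, P400 positive
    [350, 600] ms; windows are ordered in time.
    """
    return {
        "P1": ComponentWindow("P1", 70.0, 170.0, +1),
        "N290": ComponentWindow("N290", 200.0, 350.0, -1),
        "P400": ComponentWindow("P400", 350.0, 600.0, +1),
    }


@dataclass
class PeakFeature:
    component: str
    condition: str
    amplitude: float
    latency: float
    flag: str = FLAG_OK


def reject_artifacts(epochs: EpochSet, abs_threshold_uv: float = 200.0,
                     min_epochs: int = 10) -> EpochSet:
    """Drop epochs exceeding ``abs_threshold_uv`` on any occipito-temporal channel.

    If fewer than ``min_epochs`` survive, the returned set is flagged
    ``too-few-epochs`` (its surviving epochs are kept for inspection).
    """
    if abs_threshold_uv <= 0:
        raise ValueError("abs_threshold_uv must be positive")
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    ot = np.asarray(epochs.ot_channels, dtype=int)
    bad = np.abs(epochs.data[:, ot, :]).max(axis=(1, 2)) > abs_threshold_uv
    kept = epochs.data[~bad]
    flag = FLAG_TOO_FEW if kept.shape[0] < min_epochs else FLAG_OK
    return replace(epochs, data=kept, flag=flag)


def average_epochs(epochs: EpochSet) -> np.ndarray:
    """Pointwise epoch average, baseline-corrected on the prestimulus window.

    The mean of the -200..0 ms segment is subtracted per channel.
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot average zero epochs")
    avg = epochs.data.mean(axis=0)
    baseline = epochs.times <= 0.0
    avg = avg - avg[:, baseline].mean(axis=1, keepdims=True)
    return avg


def detect_peak(avg: np.ndarray, times: np.ndarray, window: ComponentWindow,
                ot_channels, condition: str = "") -> PeakFeature:
    """Find the component peak in the occipito-temporal channel-group mean.

    The peak is the extremum of the stated polarity inside the closed
    window; its latency is the sample time (ties break to the earliest
    sample).  An extremum sitting on a window edge indicates a monotone run
    rather than a true peak and is flagged ``no-peak``, as is an extremum
    whose sign contradicts the component polarity.
    """
    times = np.asarray(times, dtype=float)
    in_win = (times >= window.lo) & (times <= window.hi)
    if not in_win.any():
        raise ValueError("window lies outside the time axis")
    sig = np.asarray(avg, dtype=float)[np.asarray(ot_channels, dtype=int)].mean(axis=0)
    seg = sig[in_win]
    seg_t = times[in_win]
    i = int(np.argmax(window.polarity * seg))  # argmax -> earliest on ties
    amp = float(seg[i])
    lat = float(seg_t[i])
    flag = FLAG_OK
    if i == 0 or i == seg.size - 1:
        flag = FLAG_NO_PEAK
    elif window.polarity * amp <= 0:
        flag = FLAG_NO_PEAK
    return PeakFeature(window.component, condition, amp, lat, flag)


def extract_features(averages: dict, times: np.ndarray, ot_channels,
                     windows: dict | None = None) -> pd.Series:
    """Build the 54 ERP features (36 averaged + 18 differential) for a subject.

    ``averages`` maps condition -> (channels x samples) array, or None for a
    condition flagged upstream (too few epochs).  Flagged conditions and
    no-peak detections propagate as missing values into every feature that
    depends on them; contrasts are exact differences of the parent features.
    """
    windows = windows or default_windows()
    values: dict = {}
    for comp, win in windows.items():
        for cond in CONDITIONS:
            avg = averages.get(cond)
            if avg is None:
                amp = lat = np.nan
            else:
                pk = detect_peak(avg, times, win, ot_channels, cond)
                if pk.flag == FLAG_OK:
                    amp, lat = pk.amplitude, pk.latency
                else:
                    amp = lat = np.nan
            values[f"{comp}_amp_{cond}"] = amp
            values[f"{comp}_lat_{cond}"] = lat
        for contrast, (a, b) in CONTRAST_PARENTS.items():
            for meas in ("amp", "lat"):
                values[f"{comp}_{meas}_{contrast}"] = (
                    values[f"{comp}_{meas}_{a}"] - values[f"{comp}_{meas}_{b}"]
                )
    # reorder to the canonical inventory layout: averaged block then contrasts
    ordered = {}
    for comp in windows:
        for meas in ("amp", "lat"):
            for cond in CONDITIONS:
                k = f"{comp}_{meas}_{cond}"
                ordered[k] = values[k]
    for comp in windows:
        for meas in ("amp", "lat"):
            for contrast in CONTRAST_PARENTS:
                k = f"{comp}_{meas}_{contrast}"
                ordered[k] = values[k]
    return pd.Series(ordered)


def extract_cohort_features(epoch_sets, windows: dict | None = None,
                            abs_threshold_uv: float = 200.0,
                            min_epochs: int = 10) -> pd.DataFrame:
    """Run reject -> average -> peak extraction for a list of EpochSets.

    Returns one row per subject over the 54 ERP feature columns.
    """
    by_subject: dict = {}
    times = None
    ot = None
    for es in epoch_sets:
        clean = reject_artifacts(es, abs_threshold_uv, min_epochs)
        avg = None
        if clean.flag == FLAG_OK and clean.n_epochs > 0:
            avg = average_epochs(clean)
        by_subject.setdefault(es.subject, {})[es.condition] = avg
        times, ot = es.times, es.ot_channels
    rows = {
        subj: extract_features(avgs, times, ot, windows)
        for subj, avgs in by_subject.items()
    }
    return pd.DataFrame(rows).T
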