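"""Multi-electrode-array activity metrics.

Three per-well features: activity (mean firing rate over electrodes),
synchrony (baseline-normalized cross-correlogram area averaged over
electrode pairs) and oscillation (coefficient of variation of inter-spike
intervals), plus threshold spike detection from raw voltage traces and
activity-based well filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpikeTrainSet


@dataclass
class MEAFeatures:
    well_id: str
    activity_hz: float
    synchrony: float
    oscillation: float
    n_active_electrodes: int
    active_well: bool


# ----------------------------------------------------------- spike detection


def detect_spikes(voltage, sampling_hz: float, threshold_sd: float = 5.5,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Detect spikes as negative threshold crossings of a voltage trace.

    The noise SD is estimated robustly (median absolute deviation /
    0.6745) on the full trace; each downward crossing of
    -threshold_sd x SD is refined to the local minimum within 1 ms, and a
    refractory period is enforced. A flat trace yields no spikes.
    """
    v = np.asarray(voltage, float)
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")
    med = np.median(v)
    sd = np.median(np.abs(v - med)) / 0.6745
    if sd == 0:
        return np.empty(0)
    thr = med - threshold_sd * sd
    below = v < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    win = max(1, int(round(0.001 * sampling_hz)))
    refr = refractory_ms / 1000.0
    times = []
    for i in crossings:
        j = i + int(np.argmin(v[i:i + win]))
        t = j / sampling_hz
        if not times or t - times[-1] >= refr:
            times.append(t)
    return np.asarray(times)


# ----------------------------------------------------------------- features


def mean_firing_rate(trains: SpikeTrainSet) -> float:
    """Activity: spikes / observation time, averaged across electrodes.

    Silent electrodes count as 0 Hz unless filtered upstream.
    """
    if trains.n_electrodes == 0:
        return 0.0
    rates = [t.size / trains.duration_s for t in trains.electrodes.values()]
    return float(np.mean(rates))


def cross_correlogram(a: np.ndarray, b: np.ndarray, duration_s: float,
                      window_ms: float = 20.0, bin_ms: float = 1.0) -> np.ndarray:
    """Normalized cross-correlogram of two spike trains over lags +/-window.

    Bin counts are divided by ``n_a * n_b * bin_s / duration_s`` so that
    two independent homogeneous Poisson trains have expectation 1 in every
    bin.
    """
    w = window_ms / 1000.0
    binw = bin_ms / 1000.0
    nbins = 2 * int(round(window_ms / bin_ms))
    edges = np.linspace(-w, w, nbins + 1)
    counts = np.zeros(nbins)
    if a.size and b.size:
        lo = np.searchsorted(b, a - w, side="left")
        hi = np.searchsorted(b, a + w, side="right")
        lags = np.concatenate([b[l:h] - t for t, l, h in zip(a, lo, hi)]) \
            if np.any(hi > lo) else np.empty(0)
        counts, _ = np.histogram(lags, bins=edges)
    expected = a.size * b.size * binw / duration_s
    if expected == 0:
        return np.zeros(nbins)
    return counts / expected


def synchrony(trains: SpikeTrainSet, window_ms: float = 20.0,
              bin_ms: float = 1.0) -> float:
    """Excess-coincidence synchrony averaged over electrode pairs.

    Per unordered pair: mean normalized correlogram bin minus 1, clipped
    at 0 (independent Poisson trains score ~0); the well value is the sum
    over pairs divided by the number of pairs. NaN when fewer than two
    electrodes spike.
    """
    spiking = [t for t in trains.electrodes.values() if t.size > 0]
    if len(spiking) < 2:
        return float("nan")
    total = 0.0
    npairs = 0
    for i in range(len(spiking)):
        for j in range(i + 1, len(spiking)):
            cc = cross_correlogram(spiking[i], spiking[j], trains.duration_s,
                                   window_ms, bin_ms)
            total += max(float(cc.mean()) - 1.0, 0.0)
            npairs += 1
    return total / npairs


def oscillation(trains: SpikeTrainSet) -> float:
    """Coefficient of variation of inter-spike intervals (sample SD / mean),
    averaged over electrodes with at least 2 ISIs. NaN when none qualify."""
    cvs = []
    for t in trains.electrodes.values():
        isi = np.diff(t)
        if isi.size >= 2 and isi.mean() > 0:
            cvs.append(isi.std(ddof=1) / isi.mean())
    return float(np.mean(cvs)) if cvs else float("nan")


def well_features(trains: SpikeTrainSet, electrode_min_rate_per_min: float = 5.0,
                  min_active_electrode_frac: float = 0.25,
                  window_ms: float = 20.0, bin_ms: float = 1.0) -> MEAFeatures:
    """All three per-well features plus the active-well flag."""
    min_rate_hz = electrode_min_rate_per_min / 60.0
    n_active = sum(1 for t in trains.electrodes.values()
                   if t.size / trains.duration_s >= min_rate_hz)
    frac = n_active / trains.n_electrodes if trains.n_electrodes else 0.0
    return MEAFeatures(
        well_id=trains.well_id,
        activity_hz=mean_firing_rate(trains),
        synchrony=synchrony(trains, window_ms, bin_ms),
        oscillation=oscillation(trains),
        n_active_electrodes=n_active,
        active_well=frac >= min_active_electrode_frac,
    )


def filter_activity(features: list, min_active_wells: int = 3) -> dict:
    """Exclude background-only wells; report the condition only with
    at least ``min_active_wells`` active wells."""
    active = [f for f in features if f.active_well]
    return {
        "active_wells": active,
        "n_active": len(active),
        "sufficient": len(active) >= min_active_wells,
    }
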