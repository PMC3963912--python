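"""Peristaltic wave propagation and luminal flow quantification.

Wave speed comes from the latency of matched contraction events across
transverse stations: the k-th event at each station is assumed to belong
to the k-th contraction wave, event time is regressed on axial position,
and the inverse slope is the propagation speed.  A slope smaller than what
half a frame interval across the station span could resolve is classified
"global" (simultaneous within temporal resolution).

Luminal flow comes from a longitudinal (centerline) kymograph: the
frame-to-frame displacement of the luminal intensity profile is measured
by maximum normalized cross-correlation with parabolic subpixel
refinement, and the cumulative displacement series is split into a net
drift (robust Theil-Sen line fit) and a pendular oscillation amplitude
(SD of the detrended series times sqrt(2), i.e. the amplitude of an
equivalent sinusoid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .contract import ContractionEvent
from .kymo import Kymograph


@dataclass
class WaveEstimate:
    """Propagation of contraction events along the duct axis.

    ``speed_px_per_s`` is signed (positive = toward increasing column) and
    ``None`` for the "global" classification, where the latency is below
    temporal resolution.
    """

    speed_px_per_s: float | None
    latency_slope_s_per_px: float
    latency_slope_se: float
    r_squared: float
    classification: str
    n_stations: int
    n_events: int
    note: str = ""

    def to_dict(self) -> dict:
        d = {
            "speed_px_per_s": self.speed_px_per_s,
            "latency_slope_s_per_px": self.latency_slope_s_per_px,
            "latency_slope_se": self.latency_slope_se,
            "r_squared": self.r_squared,
            "classification": self.classification,
            "n_stations": self.n_stations,
            "n_events": self.n_events,
        }
        if self.note:
            d["note"] = self.note
        return d


@dataclass
class FlowEstimate:
    """Net vs pendular movement of luminal contents.

    classification: "net_transport" when the net drift is resolvable,
    "pendular" when oscillation dominates a negligible drift, "static"
    otherwise (including a featureless lumen).
    """

    net_velocity_px_per_s: float
    net_velocity_se: float
    oscillation_amplitude_px: float
    classification: str
    cumulative_displacement_px: np.ndarray = field(repr=False,
                                                   default=None)

    def to_dict(self) -> dict:
        return {
            "net_velocity_px_per_s": self.net_velocity_px_per_s,
            "net_velocity_se": self.net_velocity_se,
            "oscillation_amplitude_px": self.oscillation_amplitude_px,
            "classification": self.classification,
        }


# ---------------------------------------------------------------------------
# wave estimation
# ---------------------------------------------------------------------------

def _normalize_stations(events_by_station) -> dict[float, np.ndarray]:
    """Accept {station: events/times} or an iterable of event lists."""
    out: dict[float, np.ndarray] = {}
    if isinstance(events_by_station, Mapping):
        items = events_by_station.items()
    else:
        items = []
        for evs in events_by_station:
            evs = list(evs)
            if not evs or not isinstance(evs[0], ContractionEvent):
                raise ValueError(
                    "station columns are unknown: pass a mapping "
                    "{station_col: events} or lists of ContractionEvent"
                )
            items.append((evs[0].axial_station_col, evs))
    for station, evs in items:
        times = np.asarray([
            e.time_s if isinstance(e, ContractionEvent) else float(e)
            for e in evs
        ])
        out[float(station)] = np.sort(times)
    return out


def estimate_wave(events_by_station, frame_interval_s: float,
                  r2_propagating: float = 0.5) -> WaveEstimate:
    """Estimate propagation speed from per-station contraction events.

    Stations whose event count deviates from the majority count are
    excluded (their events cannot be rank-matched); at least 3 usable
    stations are required.  Event times are matched by rank, each wave's
    time-vs-station relation is fitted by least squares, and slopes are
    averaged across waves.
    """
    stations = _normalize_stations(events_by_station)
    if len(stations) < 3:
        raise ValueError(
            f"need >= 3 stations with events, got {len(stations)}"
        )
    counts = {s: len(t) for s, t in stations.items()}
    values, tally = np.unique(list(counts.values()), return_counts=True)
    # majority event count; ties resolved toward the larger count
    best = values[np.lexsort((values, tally))[-1]]
    usable = sorted(s for s, c in counts.items() if c == best)
    if len(usable) < 3 or best == 0:
        raise ValueError(
            "event counts cannot be matched across stations: "
            + ", ".join(f"col {s:g}: {counts[s]}" for s in sorted(counts))
        )

    st = np.asarray(usable)
    T = np.column_stack([stations[s] for s in usable])    # (waves, stations)
    n_waves, n_st = T.shape
    X = np.column_stack([np.ones(n_st), st])
    beta, *_ = np.linalg.lstsq(X, T.T, rcond=None)        # (2, waves)
    slopes = beta[1]
    slope = float(np.mean(slopes))
    slope_se = float(np.std(slopes, ddof=1) / np.sqrt(n_waves)) \
        if n_waves > 1 else float("nan")

    row_means = T.mean(axis=1, keepdims=True)
    pred = row_means + slope * (st - st.mean())[None, :]
    sst = float(np.sum((T - row_means) ** 2))
    sse = float(np.sum((T - pred) ** 2))
    r2 = float(np.clip(1.0 - sse / sst, 0.0, 1.0)) if sst > 1e-12 else 0.0

    span = float(st.max() - st.min())
    resolvable = (frame_interval_s / 2.0) / span
    note = ""
    if abs(slope) < resolvable:
        classification = "global"
        speed = None
    else:
        classification = "propagating" if r2 >= r2_propagating \
            else "incoherent"
        speed = 1.0 / slope
        if abs(slope) * span < 3.0 * frame_interval_s:
            note = ("station lag is within a few frame intervals; consider "
                    "capturing at 7 frames/s for a finer time resolution")

    return WaveEstimate(
        speed_px_per_s=speed,
        latency_slope_s_per_px=slope,
        latency_slope_se=slope_se,
        r_squared=r2,
        classification=classification,
        n_stations=n_st,
        n_events=n_waves,
        note=note,
    )


# ---------------------------------------------------------------------------
# flow estimation
# ---------------------------------------------------------------------------

def _profile_shift(ref: np.ndarray, cur: np.ndarray,
                   max_shift: int) -> float:
    """Displacement of ``cur`` relative to ``ref`` (positive = toward
    larger positions), by maximum cross-correlation of the mean-subtracted
    profiles with parabolic subsample refinement."""
    a = ref - ref.mean()
    b = cur - cur.mean()
    full = np.correlate(b, a, mode="full")
    lags = np.arange(-len(a) + 1, len(b))
    keep = np.abs(lags) <= max_shift
    cc = full[keep]
    ll = lags[keep]
    i = int(np.argmax(cc))
    if 0 < i < len(cc) - 1:
        denom = cc[i - 1] - 2 * cc[i] + cc[i + 1]
        delta = 0.5 * (cc[i - 1] - cc[i + 1]) / denom if denom < 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(ll[i]) + delta


def estimate_flow(kym: Kymograph,
                  net_threshold_px_per_s: float = 0.5,
                  oscillation_threshold_px: float = 1.0,
                  feature_threshold: float = 0.01,
                  max_shift_frac: float = 0.25) -> FlowEstimate:
    """Quantify luminal flow from a longitudinal (centerline) kymograph.

    A featureless lumen (profile variation below ``feature_threshold``
    intensity units) is classified "static" with a warning rather than an
    error.  Net transport requires ``|net| > max(net_threshold, 2 * fit
    SE)``; otherwise oscillation above ``oscillation_threshold_px`` means
    "pendular", else "static".
    """
    m = kym.matrix
    n_pos, n_frames = m.shape
    contrast = float(np.median(np.ptp(m - m.mean(axis=0, keepdims=True),
                                      axis=0)))
    if contrast < feature_threshold:
        warnings.warn("luminal profile is featureless; flow cannot be "
                      "tracked", stacklevel=2)
        return FlowEstimate(0.0, 0.0, 0.0, "static",
                            np.zeros(n_frames))

    max_shift = max(2, int(max_shift_frac * n_pos))
    steps = np.empty(n_frames - 1)
    for j in range(n_frames - 1):
        steps[j] = _profile_shift(m[:, j], m[:, j + 1], max_shift)
    steps *= kym.sample_spacing_px
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    times = kym.times()

    slope, intercept, lo, hi = stats.theilslopes(cum, times, alpha=0.95)
    se = (hi - lo) / (2 * 1.959964) if np.isfinite(hi - lo) else 0.0
    detrended = cum - (intercept + slope * times)
    osc = float(np.std(detrended) * np.sqrt(2.0))

    if abs(slope) > max(net_threshold_px_per_s, 2 * se):
        classification = "net_transport"
    elif osc >= oscillation_threshold_px:
        classification = "pendular"
    else:
        classification = "static"

    return FlowEstimate(
        net_velocity_px_per_s=float(slope),
        net_velocity_se=float(se),
        oscillation_amplitude_px=osc,
        classification=classification,
        cumulative_displacement_px=cum,
    )
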