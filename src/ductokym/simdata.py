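"""Synthetic transillumination movies of a contracting duct, with ground truth.

The simulator emulates what a transmitted-light camera sees when pointed at
a straight tubular duct: a bright background crossed by two dark Gaussian
wall bands whose separation (the duct diameter) undergoes brief phasic
contractions, optionally propagating along the duct axis as a peristaltic
wave, with dark intraluminal particles that drift and/or oscillate
(pendular flow).  Every movie comes with exact ground truth — per-station
contraction onset times, per-epoch true frequencies, wave speed and net
flow — so the whole analysis chain can be validated end to end.

The physical model is continuous in time and sampled at the frame times, so
the same physics simulated at 1 frame/s and 7 frames/s agrees exactly at
common time points.

Model
-----
Diameter at axial column c and time t::

    D(c, t) = D0 * (1 - A * p(t - tau(c)))

where ``p`` is a raised-cosine unit pulse of width ``pulse_width_s``
repeating at the active regime's interval, and ``tau(c) =
(c - wave_origin_col) / wave_speed`` (zero everywhere for "global"
contractions).  Walls are Gaussian absorption bands centered at
``duct_center_row -/+ D(c,t)/2``.  Particle columns follow::

    x(t) = x0 + flow_net * t + flow_osc_amplitude * sin(2*pi*t / period)

Frames are clipped to [0, 1] and quantized to the 16-bit grid before being
returned, so an in-memory stack is bit-identical to one written to TIFF and
read back.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .stackio import MovieStack, TIFF_SCALE

#: sentinel for simultaneous (infinitely fast) contractions
GLOBAL_WAVE = "global"


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Full parameterization of one synthetic movie.

    ``schedule`` is a list of ``(time_s, new_contraction_interval_s, label)``
    regime changes emulating drug additions: the pulse interval switches at
    the first pulse onset at or after the change time, so no pulse is ever
    truncated mid-contraction.
    """

    duration_s: float = 240.0
    frame_interval_s: float = 1.0
    image_shape: tuple[int, int] = (96, 192)      # rows, cols
    duct_center_row: float = 48.0
    resting_diameter_px: float = 40.0
    wall_sigma_px: float = 2.0
    contraction_interval_s: float = 8.0
    contraction_amplitude_frac: float = 0.2
    pulse_width_s: float = 3.0
    wave_speed_px_per_s: float | str = GLOBAL_WAVE
    wave_origin_col: float = 0.0
    n_particles: int = 0
    flow_net_px_per_s: float = 0.0
    flow_osc_amplitude_px: float = 0.0
    flow_osc_period_s: float = 10.0
    noise_sd: float = 0.01
    background_level: float = 0.85
    wall_depth: float = 0.55
    particle_depth: float = 0.25
    particle_sigma_px: float = 1.5
    seed: int = 0
    schedule: list[tuple[float, float, str]] = field(default_factory=list)

    def validate(self) -> None:
        rows, cols = self.image_shape
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be positive")
        if not (0 <= self.contraction_amplitude_frac < 1):
            raise ValueError("contraction_amplitude_frac must be in [0, 1)")
        intervals = [self.contraction_interval_s] + \
            [iv for _, iv, _ in self.schedule]
        if any(iv <= 0 for iv in intervals):
            raise ValueError("contraction intervals must be positive")
        if any(self.pulse_width_s >= iv for iv in intervals):
            raise ValueError(
                "pulse_width_s must be shorter than every contraction "
                "interval (pulses may not overlap)"
            )
        if self.resting_diameter_px + 6 * self.wall_sigma_px >= rows:
            raise ValueError(
                "geometry rejected: resting_diameter_px + 6*wall_sigma_px "
                f"= {self.resting_diameter_px + 6 * self.wall_sigma_px:g} "
                f"must be < image rows ({rows}); enlarge the frame or "
                "shrink the duct"
            )
        margin = 3 * self.wall_sigma_px
        top = self.duct_center_row - self.resting_diameter_px / 2 - margin
        bot = self.duct_center_row + self.resting_diameter_px / 2 + margin
        if top < 0 or bot > rows - 1:
            raise ValueError(
                "geometry rejected: a wall leaves the frame "
                f"(wall band spans rows {top:.1f}..{bot:.1f} of 0..{rows - 1})"
            )
        for t, _, label in self.schedule:
            if not (0 < t < self.duration_s):
                raise ValueError(
                    f"schedule change {label!r} at t={t:g} s lies outside "
                    f"the recording (0, {self.duration_s:g})"
                )
        times = [t for t, _, _ in self.schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if self.wave_speed_px_per_s != GLOBAL_WAVE:
            if not (abs(float(self.wave_speed_px_per_s)) > 0):
                raise ValueError(
                    "wave_speed_px_per_s must be nonzero or 'global'"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["schedule"] = [list(s) for s in self.schedule]
        return d


@dataclass
class GroundTruth:
    """Exact description of what a simulated movie contains.

    ``event_times_by_station`` maps each integer axial column to the
    ordered contraction onset times seen at that column (onsets lag the
    wave origin by ``(col - origin) / wave_speed`` for finite speeds).
    ``epochs`` lists ``(start_s, end_s, interval_s, bpm, label)`` for each
    contraction regime; ``bpm = 60 / interval``.
    """

    event_times_by_station: dict[int, np.ndarray]
    epochs: list[dict]
    wave_speed_px_per_s: float | str
    net_flow_px_per_s: float
    params: SimulationParams
    seed: int

    @property
    def true_frequency_bpm_by_epoch(self) -> list[float]:
        return [e["bpm"] for e in self.epochs]

    def onsets_at(self, col: float) -> np.ndarray:
        """Analytic onset times at an arbitrary (possibly fractional) column."""
        base = _base_onsets(self.params)[0]
        lag = _station_lag(self.params, np.asarray([col], dtype=float))[0]
        t = base + lag
        return t[(t >= 0) & (t < self.params.duration_s)]

    def to_dict(self) -> dict:
        return {
            "frame_interval_s": self.params.frame_interval_s,
            "seed": self.seed,
            "wave_speed_px_per_s": self.wave_speed_px_per_s,
            "net_flow_px_per_s": self.net_flow_px_per_s,
            "epochs": self.epochs,
            "events": {str(c): np.asarray(v).tolist()
                       for c, v in self.event_times_by_station.items()},
            "params": self.params.to_dict(),
        }


# ---------------------------------------------------------------------------
# pulse schedule
# ---------------------------------------------------------------------------

def _base_onsets(params: SimulationParams) -> tuple[np.ndarray, list[dict]]:
    """Pulse onset times at the wave origin, plus the regime epochs.

    The first onset is at t=0; the interval switches at the first onset at
    or after each scheduled change time.
    """
    changes = sorted(params.schedule)
    onsets: list[float] = []
    epochs: list[dict] = []
    interval = params.contraction_interval_s
    label = "Spont"
    epoch_start = 0.0
    applied = 0
    t = 0.0
    while t < params.duration_s - 1e-9:
        while applied < len(changes) and t >= changes[applied][0] - 1e-9:
            epochs.append({"start_s": epoch_start, "end_s": t,
                           "interval_s": interval,
                           "bpm": 60.0 / interval, "label": label})
            _, interval, label = changes[applied]
            epoch_start = t
            applied += 1
        onsets.append(t)
        t += interval
    epochs.append({"start_s": epoch_start, "end_s": params.duration_s,
                   "interval_s": interval, "bpm": 60.0 / interval,
                   "label": label})
    return np.asarray(onsets), epochs


def _station_lag(params: SimulationParams, cols: np.ndarray) -> np.ndarray:
    if params.wave_speed_px_per_s == GLOBAL_WAVE:
        return np.zeros_like(cols, dtype=float)
    speed = float(params.wave_speed_px_per_s)
    return (cols - params.wave_origin_col) / speed


def _pulse_activity(params: SimulationParams, times: np.ndarray,
                    cols: np.ndarray) -> np.ndarray:
    """Unit pulse value p(t - tau(c)) on a (times x cols) grid."""
    onsets, _ = _base_onsets(params)
    lag = _station_lag(params, cols.astype(float))
    s = times[:, None] - lag[None, :]
    idx = np.searchsorted(onsets, s + 1e-12, side="right") - 1
    rel = s - onsets[np.clip(idx, 0, None)]
    active = (idx >= 0) & (rel <= params.pulse_width_s)
    with np.errstate(invalid="ignore"):
        p = 0.5 * (1.0 - np.cos(2 * np.pi * rel / params.pulse_width_s))
    return np.where(active, p, 0.0)


def analytic_diameter(params: SimulationParams, t, col) -> np.ndarray:
    """Closed-form D(c, t) in pixels for scalar or array t / col."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    col = np.atleast_1d(np.asarray(col, dtype=float))
    p = _pulse_activity(params, t, col)
    d = params.resting_diameter_px * \
        (1.0 - params.contraction_amplitude_frac * p)
    return d.squeeze()


def analytic_wall_profile(params: SimulationParams, t: float,
                          col: float) -> np.ndarray:
    """Noise-free, particle-free intensity down one column at time t."""
    rows = np.arange(params.image_shape[0], dtype=float)
    d = float(np.asarray(analytic_diameter(params, t, col)).reshape(-1)[0])
    top = params.duct_center_row - d / 2
    bot = params.duct_center_row + d / 2
    sig2 = 2 * params.wall_sigma_px ** 2
    prof = params.background_level - params.wall_depth * (
        np.exp(-(rows - top) ** 2 / sig2) + np.exp(-(rows - bot) ** 2 / sig2)
    )
    return np.clip(prof, 0.0, 1.0)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def simulate_movie(params: SimulationParams) -> tuple[MovieStack, GroundTruth]:
    """Render a movie and its ground truth.

    Identical parameters (including the seed) give bit-identical pixel
    data: the returned stack is already quantized to the 16-bit intensity
    grid used by the TIFF writer.
    """
    params.validate()
    rows, cols = params.image_shape
    n_frames = int(round(params.duration_s / params.frame_interval_s))
    times = np.arange(n_frames) * params.frame_interval_s
    col_idx = np.arange(cols, dtype=float)

    p = _pulse_activity(params, times, col_idx)            # (F, C)
    diam = params.resting_diameter_px * \
        (1.0 - params.contraction_amplitude_frac * p)
    top = params.duct_center_row - diam / 2                # (F, C)
    bot = params.duct_center_row + diam / 2
    r = np.arange(rows, dtype=float)[None, :, None]
    sig2 = 2 * params.wall_sigma_px ** 2
    frames = params.background_level - params.wall_depth * (
        np.exp(-(r - top[:, None, :]) ** 2 / sig2)
        + np.exp(-(r - bot[:, None, :]) ** 2 / sig2)
    )

    rng = np.random.default_rng(params.seed)
    if params.n_particles > 0:
        _render_particles(params, frames, times, rng)
    if params.noise_sd > 0:
        frames = frames + rng.normal(0.0, params.noise_sd, frames.shape)

    np.clip(frames, 0.0, 1.0, out=frames)
    frames = np.round(frames * TIFF_SCALE) / TIFF_SCALE

    stack = MovieStack(data=frames,
                       frame_interval_s=params.frame_interval_s,
                       origin_label="simulated")

    onsets, epochs = _base_onsets(params)
    lags = _station_lag(params, col_idx)
    events: dict[int, np.ndarray] = {}
    for c in range(cols):
        t = onsets + lags[c]
        events[c] = t[(t >= 0) & (t < params.duration_s)]
    truth = GroundTruth(
        event_times_by_station=events,
        epochs=epochs,
        wave_speed_px_per_s=params.wave_speed_px_per_s,
        net_flow_px_per_s=params.flow_net_px_per_s,
        params=params,
        seed=params.seed,
    )
    return stack, truth


def _render_particles(params: SimulationParams, frames: np.ndarray,
                      times: np.ndarray, rng: np.random.Generator) -> None:
    """Subtract dark Gaussian particles, advected through a periodic lumen."""
    rows, cols = params.image_shape
    n = params.n_particles
    x0 = rng.uniform(0.0, cols, size=n)
    # keep particles inside the lumen even at full contraction
    half_lumen = 0.25 * params.resting_diameter_px * \
        (1.0 - params.contraction_amplitude_frac)
    pr = params.duct_center_row + rng.uniform(-half_lumen, half_lumen, size=n)
    osc = params.flow_osc_amplitude_px * \
        np.sin(2 * np.pi * times / params.flow_osc_period_s)
    sig2 = 2 * params.particle_sigma_px ** 2
    reach = 4 * params.particle_sigma_px
    col_grid = np.arange(cols, dtype=float)
    for i in range(n):
        x = np.mod(x0[i] + params.flow_net_px_per_s * times + osc, cols)
        # wrapped horizontal distance keeps the particle field periodic
        dx = np.mod(col_grid[None, :] - x[:, None] + cols / 2, cols) - cols / 2
        g = np.exp(-dx ** 2 / sig2)                        # (F, C)
        r_lo = max(int(np.floor(pr[i] - reach)), 0)
        r_hi = min(int(np.ceil(pr[i] + reach)) + 1, rows)
        rr = np.arange(r_lo, r_hi, dtype=float)
        h = np.exp(-(rr - pr[i]) ** 2 / sig2)              # (band,)
        frames[:, r_lo:r_hi, :] -= \
            params.particle_depth * h[None, :, None] * g[:, None, :]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _preset_fig1() -> SimulationParams:
    return SimulationParams(duration_s=240.0, frame_interval_s=1.0,
                            contraction_interval_s=8.0,
                            contraction_amplitude_frac=0.2,
                            wave_speed_px_per_s=GLOBAL_WAVE, seed=42)


def _preset_peristaltic() -> SimulationParams:
    return SimulationParams(duration_s=120.0, frame_interval_s=1.0 / 7.0,
                            contraction_interval_s=8.0,
                            contraction_amplitude_frac=0.2,
                            wave_speed_px_per_s=50.0, wave_origin_col=0.0,
                            noise_sd=0.005, seed=7)


def _preset_pendular_flow() -> SimulationParams:
    return SimulationParams(duration_s=120.0, frame_interval_s=1.0,
                            contraction_interval_s=8.0,
                            contraction_amplitude_frac=0.15,
                            n_particles=12, flow_net_px_per_s=0.0,
                            flow_osc_amplitude_px=5.0, flow_osc_period_s=10.0,
                            noise_sd=0.005, seed=11)


def _preset_net_flow() -> SimulationParams:
    return SimulationParams(duration_s=120.0, frame_interval_s=1.0,
                            contraction_interval_s=8.0,
                            contraction_amplitude_frac=0.15,
                            n_particles=12, flow_net_px_per_s=2.0,
                            flow_osc_amplitude_px=0.0,
                            noise_sd=0.005, seed=13)


def _preset_drug_response() -> SimulationParams:
    return SimulationParams(duration_s=600.0, frame_interval_s=1.0,
                            contraction_interval_s=8.0,
                            contraction_amplitude_frac=0.2,
                            schedule=[(300.0, 20.0, "sildenafil 5 uM")],
                            seed=5)


_PRESETS = {
    "fig1": _preset_fig1,
    "peristaltic": _preset_peristaltic,
    "pendular_flow": _preset_pendular_flow,
    "net_flow": _preset_net_flow,
    "drug_response": _preset_drug_response,
}


def preset(name: str) -> SimulationParams:
    """Return one of the documented fixed parameter sets.

    * ``fig1`` — 240 s at 1 frame/s, global contractions every 8 s
      (60/8 = 7.5 beats/min), amplitude 0.2, seed 42.
    * ``peristaltic`` — 120 s at 7 frames/s, wave speed 50 px/s from the
      left edge.
    * ``pendular_flow`` — 12 luminal particles oscillating 5 px with a
      10 s period, zero net drift.
    * ``net_flow`` — 12 particles drifting at 2 px/s.
    * ``drug_response`` — 600 s; interval 8 s switching to 20 s at the
      addition logged at t=300 s (label "sildenafil 5 uM"), i.e. 7.5 ->
      3.0 beats/min.
    """
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
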