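"""Shared helpers for the test suite."""

from __future__ import annotations

from ductokym.simdata import SimulationParams
from ductokym.stackio import AnalysisLine


def small_params(**overrides) -> SimulationParams:
    """A compact movie geometry that keeps simulations fast in tests."""
    base = dict(
        duration_s=240.0,
        frame_interval_s=1.0,
        image_shape=(64, 128),
        duct_center_row=32.0,
        resting_diameter_px=28.0,
        wall_sigma_px=2.0,
        contraction_interval_s=8.0,
        contraction_amplitude_frac=0.2,
        noise_sd=0.01,
        seed=0,
    )
    base.update(overrides)
    return SimulationParams(**base)


def vline(col: float, row_lo: float, row_hi: float,
          line_id: str | None = None, width_px: int = 1) -> AnalysisLine:
    """A vertical transverse line at a given column."""
    return AnalysisLine(
        id=line_id or f"c{col:g}",
        kind="transverse",
        endpoints=((float(col), float(row_lo)), (float(col), float(row_hi))),
        width_px=width_px,
    )
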