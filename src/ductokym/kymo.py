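"""Kymograph extraction: virtual sections through a time stack.

A kymograph resamples every frame along a fixed line and stacks the
resulting 1-D profiles side by side, turning wall motion into visible
spikes: position along the line runs down the rows, time runs across the
columns.  Sampling uses bilinear interpolation at (by default) 1-px steps;
a line of ``width_px`` > 1 averages that many parallel 1-px offsets
perpendicular to the line.  Coordinates that would leave the frame are an
error rather than being clamped — silent clamping would bias wall
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .stackio import AnalysisLine, MovieStack


@dataclass
class Kymograph:
    """Positions-along-line x frames intensity matrix.

    ``matrix[i, j]`` is the intensity at the i-th sample point along the
    line in frame j.  Row 0 corresponds to the line's first endpoint.
    """

    matrix: np.ndarray
    sample_spacing_px: float
    frame_interval_s: float
    line: AnalysisLine

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def positions(self) -> np.ndarray:
        """Distance of each sample from the first endpoint, in pixels."""
        return np.arange(self.n_positions) * self.sample_spacing_px


def extract_kymograph(stack: MovieStack, line: AnalysisLine,
                      sample_spacing_px: float = 1.0) -> Kymograph:
    """Extract the kymograph of ``stack`` along ``line``.

    Sample points are spaced evenly so that the spacing never exceeds
    ``sample_spacing_px`` and both endpoints are sampled exactly; the
    actual spacing is recorded on the result.  Raises ``ValueError`` if
    any sample (after width offsetting) leaves the image.
    """
    if sample_spacing_px <= 0:
        raise ValueError("sample_spacing_px must be positive")
    n_frames, rows, cols = stack.shape
    p0 = np.asarray(line.endpoints[0], dtype=float)   # (col, row)
    p1 = np.asarray(line.endpoints[1], dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n_samples = int(np.ceil(length / sample_spacing_px)) + 1
    ts = np.linspace(0.0, 1.0, n_samples)
    base = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]   # (n, 2) col,row
    u = (p1 - p0) / length
    perp = np.array([-u[1], u[0]])
    offsets = np.arange(line.width_px) - (line.width_px - 1) / 2.0

    pts = base[None, :, :] + offsets[:, None, None] * perp[None, None, :]
    pc, prow = pts[..., 0], pts[..., 1]
    if pc.min() < 0 or pc.max() > cols - 1 or \
            prow.min() < 0 or prow.max() > rows - 1:
        raise ValueError(
            f"line {line.id!r} leaves the image: endpoints "
            f"{line.endpoints[0]} -> {line.endpoints[1]} with width "
            f"{line.width_px} sample cols {pc.min():.1f}..{pc.max():.1f}, "
            f"rows {prow.min():.1f}..{prow.max():.1f} "
            f"(image is {rows} rows x {cols} cols)"
        )

    coords = np.stack([prow.ravel(), pc.ravel()])   # map_coordinates: (row, col)
    out = np.empty((n_samples, n_frames))
    n_off = len(offsets)
    for j in range(n_frames):
        vals = ndimage.map_coordinates(stack.data[j], coords, order=1,
                                       mode="nearest")
        out[:, j] = vals.reshape(n_off, n_samples).mean(axis=0)

    spacing = length / (n_samples - 1)
    return Kymograph(matrix=out, sample_spacing_px=spacing,
                     frame_interval_s=stack.frame_interval_s, line=line)


# ---------------------------------------------------------------------------
# automatic line placement
# ---------------------------------------------------------------------------

def _two_deepest_minima(profile: np.ndarray, min_separation: float = 3.0,
                        min_prominence: float | None = None):
    """Indices of the two deepest separable local minima, or None."""
    span = float(np.ptp(profile))
    if span <= 1e-12:
        return None
    if min_prominence is None:
        min_prominence = 0.1 * span
    minima, _ = signal.find_peaks(-profile, prominence=min_prominence)
    if len(minima) < 2:
        return None
    order = minima[np.argsort(profile[minima], kind="stable")]
    first = order[0]
    for cand in order[1:]:
        if abs(cand - first) >= min_separation:
            return tuple(sorted((int(first), int(cand))))
    return None


def auto_place_lines(stack: MovieStack, n_lines: int = 3,
                     width_px: int = 1) -> list[AnalysisLine]:
    """Place transverse lines plus a luminal centerline automatically.

    The duct axis is estimated from the time-averaged frame: in every
    column the two deepest dark-band minima locate the walls, their
    midpoints are fitted with a straight line, and ``n_lines`` transverse
    lines perpendicular to that axis are placed at evenly spaced axial
    stations.  A longitudinal centerline along the fitted axis is appended
    (id ``"centerline"``).  Raises if no duct-like two-band structure is
    found.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    mean_frame = stack.data.mean(axis=0)
    rows, cols = mean_frame.shape

    centers: dict[int, float] = {}
    separations: list[float] = []
    for c in range(cols):
        hit = _two_deepest_minima(mean_frame[:, c])
        if hit is None:
            continue
        a, b = hit
        centers[c] = 0.5 * (a + b)
        separations.append(float(b - a))
    if len(centers) < max(4, cols // 4):
        raise ValueError(
            "no duct-like structure detected (need two dark wall bands in "
            "most columns); provide analysis lines manually"
        )

    cs = np.array(sorted(centers))
    mids = np.array([centers[c] for c in cs])
    slope, intercept = np.polyfit(cs, mids, 1)
    sep = float(np.median(separations))

    axis_dir = np.array([1.0, slope]) / np.hypot(1.0, slope)
    perp = np.array([-axis_dir[1], axis_dir[0]])
    half = 0.75 * sep + 5.0

    c_lo, c_hi = float(cs.min()), float(cs.max())
    stations = c_lo + (np.arange(n_lines) + 1) / (n_lines + 1) * (c_hi - c_lo)

    lines: list[AnalysisLine] = []
    for i, sc in enumerate(stations):
        center_pt = np.array([sc, intercept + slope * sc])
        h = half
        # shrink symmetric reach so both endpoints stay inside the frame
        for _ in range(50):
            e0 = center_pt - h * perp
            e1 = center_pt + h * perp
            if (0 <= e0[0] <= cols - 1 and 0 <= e0[1] <= rows - 1
                    and 0 <= e1[0] <= cols - 1 and 0 <= e1[1] <= rows - 1):
                break
            h *= 0.9
        line = AnalysisLine(id=f"T{i + 1}", kind="transverse",
                            endpoints=(tuple(e0), tuple(e1)),
                            width_px=width_px, axial_station_col=float(sc))
        _check_crosses_walls(mean_frame, line)
        lines.append(line)

    margin = 2.0
    a0 = np.array([c_lo + margin, intercept + slope * (c_lo + margin)])
    a1 = np.array([c_hi - margin, intercept + slope * (c_hi - margin)])
    lines.append(AnalysisLine(id="centerline", kind="longitudinal",
                              endpoints=(tuple(a0), tuple(a1)),
                              width_px=width_px))
    return lines


def _check_crosses_walls(mean_frame: np.ndarray, line: AnalysisLine) -> None:
    from scipy.ndimage import map_coordinates

    p0 = np.asarray(line.endpoints[0])
    p1 = np.asarray(line.endpoints[1])
    n = int(np.ceil(line.length_px)) + 1
    ts = np.linspace(0, 1, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    prof = map_coordinates(mean_frame, [pts[:, 1], pts[:, 0]], order=1,
                           mode="nearest")
    if _two_deepest_minima(prof) is None:
        raise ValueError(
            f"auto-placed line {line.id!r} does not cross two dark wall "
            "bands; provide analysis lines manually"
        )
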