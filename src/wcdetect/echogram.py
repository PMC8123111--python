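"""Stacked-beam echogram construction and the 2D cleaning chain.

The water-column fans are first collapsed into a 2D ping-by-range "stacked
beams" echogram (per-range maximum over all beams of both transducers).  The
stacked view is then cleaned — bad-ping rejection, 3×3 median and erosion
convolutions, bottom and surface virtual lines, 3×3 dilation — to select the
pings that contain backscatter of interest, before the surviving fans are
smoothed with a 45-sample (3 beams × 5 pings × 3 range bins) mean kernel and
masked around the near field and the seafloor.

Order statistics (median/min/max) are computed in the dB domain, where they
are equivalent to linear-domain order statistics; the 45-cell mean is taken
in linear power and converted back to dB.  Edges are replicate-padded.
No-data samples are NaN and are ignored by every window statistic (a window
of only no-data stays no-data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seafloor import SeafloorTIN
from .simulate import PingFan

__all__ = [
    "StackedEchogram",
    "VirtualLine",
    "stack_max_intensity",
    "reject_bad_pings",
    "median_3x3",
    "erosion_3x3",
    "dilate_3x3",
    "best_bottom_candidate",
    "threshold_offset_line",
    "select_pings_of_interest",
    "smooth_fan_45",
    "exclusion_mask",
]


@dataclass
class StackedEchogram:
    """Ping × range matrix of per-range maxima, in dB (NaN = no data)."""

    values: np.ndarray  # (n_pings, n_range_bins)
    ping_ids: np.ndarray  # strictly increasing ints
    range_axis: np.ndarray  # bin-centre ranges, m, uniform

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ping_ids = np.asarray(self.ping_ids)
        self.range_axis = np.asarray(self.range_axis, dtype=float)
        if np.any(np.diff(self.ping_ids) <= 0):
            raise ValueError("ping_ids must be strictly increasing")

    @property
    def range_bin(self) -> float:
        return float(self.range_axis[1] - self.range_axis[0])

    def with_values(self, values: np.ndarray) -> "StackedEchogram":
        return StackedEchogram(values, self.ping_ids.copy(), self.range_axis.copy())


@dataclass
class VirtualLine:
    """Per-ping range boundary (surface-exclusion or bottom), metres.

    ``ranges`` is NaN where the line is undefined for a ping.
    """

    ping_ids: np.ndarray
    ranges: np.ndarray
    kind: str = "bottom"  # or "surface-exclusion"

    def __post_init__(self) -> None:
        self.ping_ids = np.asarray(self.ping_ids)
        self.ranges = np.asarray(self.ranges, dtype=float)
        if self.kind not in ("bottom", "surface-exclusion"):
            raise ValueError(f"unknown line kind {self.kind!r}")


def stack_max_intensity(pings: Sequence[PingFan]) -> StackedEchogram:
    """Collapse fans to the per-range maximum over transducers and beams."""
    if len(pings) == 0:
        raise ValueError("cannot stack an empty ping sequence")
    geom = pings[0].geometry
    rows = np.empty((len(pings), geom.ranges.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        for i, fan in enumerate(pings):
            rows[i] = np.nanmax(fan.sv.reshape(-1, fan.sv.shape[-1]), axis=0)
    ids = np.array([fan.ping_id for fan in pings])
    return StackedEchogram(rows, ids, geom.ranges.copy())


def reject_bad_pings(
    e: StackedEchogram, frac_threshold: float = 0.9, sv_threshold: float = -70.0
) -> np.ndarray:
    """Drop pings glowing across the full range extent; returns retained ids.

    A ping is removed iff the fraction of its (valid) bins above
    ``sv_threshold`` is at least ``frac_threshold``.
    """
    if not (np.isfinite(frac_threshold) and np.isfinite(sv_threshold)):
        raise ValueError("thresholds must be finite")
    valid = ~np.isnan(e.values)
    n_valid = valid.sum(axis=1)
    n_hot = (np.nan_to_num(e.values, nan=-np.inf) > sv_threshold).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, n_hot / np.maximum(n_valid, 1), 0.0)
    return e.ping_ids[frac < frac_threshold]


def _window_3x3(values: np.ndarray) -> np.ndarray:
    """Replicate-padded 3×3 windows, shape (n, m, 3, 3)."""
    if values.shape[0] < 3 or values.shape[1] < 3:
        raise ValueError("matrix must be at least 3x3")
    padded = np.pad(values, 1, mode="edge")
    return sliding_window_view(padded, (3, 3))


def median_3x3(e: StackedEchogram) -> StackedEchogram:
    """3×3 sliding-window median (centre included), NaN-aware."""
    win = _window_3x3(e.values).reshape(*e.values.shape, 9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(win, axis=-1)
    out[np.isnan(e.values)] = np.nan
    return e.with_values(out)


def erosion_3x3(e: StackedEchogram) -> StackedEchogram:
    """3×3 sliding-window minimum (centre included), NaN-aware."""
    win = _window_3x3(e.values).reshape(*e.values.shape, 9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmin(win, axis=-1)
    out[np.isnan(e.values)] = np.nan
    return e.with_values(out)


def dilate_3x3(e: StackedEchogram) -> StackedEchogram:
    """Replace each cell by the maximum of its eight surrounding samples.

    The centre cell is excluded from the window, so an isolated hot impulse
    spreads to exactly its 8 neighbours and is itself overwritten.
    """
    win = _window_3x3(e.values).reshape(*e.values.shape, 9).copy()
    win[..., 4] = np.nan  # drop the centre
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmax(win, axis=-1)
    out[np.isnan(e.values)] = np.nan
    return e.with_values(out)


def best_bottom_candidate(
    e: StackedEchogram,
    window_pings: int = 5,
    min_peak_sv: float = -55.0,
    min_range: float = 4.0,
) -> VirtualLine:
    """Bottom line pick: per-ping strongest peak + windowed median consensus.

    Per ping the candidate is the range of the strongest sample beyond
    ``min_range``; candidates weaker than ``min_peak_sv`` are discarded, and
    the line value is the median of the candidates inside a centred window of
    ``window_pings`` pings (NaN where the whole window has no candidate).
    """
    n = e.values.shape[0]
    cand = np.full(n, np.nan)
    searchable = e.range_axis >= min_range
    vals = np.where(np.isnan(e.values), -np.inf, e.values)
    vals = np.where(searchable[None, :], vals, -np.inf)
    peak_idx = np.argmax(vals, axis=1)
    peak_val = vals[np.arange(n), peak_idx]
    ok = peak_val >= min_peak_sv
    cand[ok] = e.range_axis[peak_idx[ok]]

    half = window_pings // 2
    line = np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            w = cand[max(0, i - half) : i + half + 1]
            line[i] = np.nanmedian(w)
    return VirtualLine(e.ping_ids.copy(), line, kind="bottom")


def threshold_offset_line(
    e: StackedEchogram,
    reference: VirtualLine,
    sv_threshold: float,
    offset: float,
) -> VirtualLine:
    """Nearest threshold crossing with respect to a nominated line, + offset.

    Scanning away from the reference range towards increasing range, the
    first transition of Sv across ``sv_threshold`` between consecutive bins
    defines the line (the crossing range plus ``offset``); with no crossing
    the line falls back to ``reference + offset``.  Used with the surface as
    reference this tracks the bottom of any near-surface entrained-air layer.
    """
    n, m = e.values.shape
    out = np.full(n, np.nan)
    for i in range(n):
        ref = reference.ranges[i]
        if np.isnan(ref):
            continue
        j0 = int(np.clip(np.searchsorted(e.range_axis, ref), 0, m - 1))
        row = e.values[i]
        above = row > sv_threshold
        crossing = None
        for j in range(j0, m - 1):
            if np.isnan(row[j]) or np.isnan(row[j + 1]):
                break
            if above[j] != above[j + 1]:
                crossing = e.range_axis[j + 1]
                break
        out[i] = (crossing if crossing is not None else ref) + offset
    return VirtualLine(e.ping_ids.copy(), out, kind="surface-exclusion")


def select_pings_of_interest(
    e_cleaned: StackedEchogram,
    surface_line: Optional[VirtualLine],
    bottom_line: Optional[VirtualLine],
    sv_threshold: float,
    bottom_margin: float = 2.0,
) -> np.ndarray:
    """Ids of pings with ≥1 above-threshold sample left in the water column.

    Samples above the surface-exclusion line or within ``bottom_margin`` of
    the bottom line are masked before a 3×3 dilation of the above-threshold
    bitmap; a ping is retained iff any highlighted sample survives.
    """
    masked = e_cleaned.values.copy()
    r = e_cleaned.range_axis[None, :]
    if surface_line is not None:
        s = np.where(np.isnan(surface_line.ranges), -np.inf, surface_line.ranges)
        masked[r <= s[:, None]] = np.nan
    if bottom_line is not None:
        b = np.where(np.isnan(bottom_line.ranges), np.inf, bottom_line.ranges)
        masked[r >= (b - bottom_margin)[:, None]] = np.nan
    hot = np.nan_to_num(masked, nan=-np.inf) > sv_threshold
    dil = dilate_3x3(e_cleaned.with_values(hot.astype(float)))
    highlighted = hot | (np.nan_to_num(dil.values, nan=0.0) > 0)
    highlighted &= ~np.isnan(masked)
    return e_cleaned.ping_ids[highlighted.any(axis=1)]


def smooth_fan_45(fans: Sequence[PingFan], index: int) -> PingFan:
    """Mean over a 3-beam × 5-ping × 3-range-bin (45-sample) neighbourhood.

    The mean is taken in linear power and converted back to dB.  Pings beyond
    the ends of ``fans`` are replicate-padded; NaN samples do not contribute
    (and stay NaN in the output).  Returns a new fan; ``fans`` is unchanged.
    """
    fan = fans[index]
    n = len(fans)
    window = [fans[min(max(index + o, 0), n - 1)] for o in (-2, -1, 0, 1, 2)]
    power = np.stack([10.0 ** (f.sv.astype(float) / 10.0) for f in window])
    valid = ~np.isnan(power)
    power = np.nan_to_num(power, nan=0.0)

    def box(arr: np.ndarray) -> np.ndarray:
        # sum over 5 pings then 3×3 (beam, range) replicate-padded box sum
        s = arr.sum(axis=0)  # (2, beams, bins)
        p = np.pad(s, ((0, 0), (1, 1), (1, 1)), mode="edge")
        w = sliding_window_view(p, (3, 3), axis=(1, 2))
        return w.sum(axis=(-1, -2))

    num = box(power)
    den = box(valid.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_power = np.where(den > 0, num / den, np.nan)
        out = 10.0 * np.log10(mean_power)
    out[np.isnan(fan.sv)] = np.nan
    smoothed = PingFan(
        fan.ping_id,
        fan.time,
        fan.nav,
        fan.geometry,
        out.astype(np.float32),
        fan.ground_truth.copy(),
        fan.seafloor_depth.copy(),
    )
    return smoothed


def exclusion_mask(
    fan: PingFan,
    tin: Optional[SeafloorTIN],
    near_field: float = 4.0,
    tin_offset: float = 1.0,
) -> np.ndarray:
    """True where a sample must be excluded from further processing.

    Excluded: slant range within ``near_field`` metres of the transducer
    face, or deeper than the resampled seafloor TIN minus ``tin_offset`` at
    the sample's horizontal position (conservatively excluded where the TIN
    is undefined), or no-data.
    """
    geom = fan.geometry
    mask = np.broadcast_to(
        (geom.ranges < near_field)[None, None, :], fan.sv.shape
    ).copy()
    if tin is not None:
        x, y = fan.sample_world_xy()
        tin_depth = tin.depth_at(x.ravel(), y.ravel()).reshape(x.shape)
        deep = ~(geom.depth + 0 * tin_depth <= tin_depth - tin_offset)
        mask |= deep  # NaN TIN depth compares False -> excluded
    mask |= np.isnan(fan.sv)
    return mask
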