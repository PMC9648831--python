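"""From spectrograms to CNN input images.

The 0-30 s application span is cut into 3 s windows sliding by 1 s (2 s
overlap, 28 windows).  Each window is averaged over time and over the 1 Hz
frequency bins of four bands -- alpha, beta, low gamma, high gamma -- giving
a 4 x 19 band-power table.  Each band's 19 channel values are arranged on a
5x5 grid mirroring the scalp layout (six gaps filled with neighbour means),
and the four grids are tiled into the 10x10 merged image the classifiers
consume.

Band bins are half-open on 1 Hz bin centres: alpha 7-14, beta 15-32,
low gamma 33-69, high gamma 70-120.  Boundary bins (15, 33, 70) are assigned
upward so the bands partition 7-120 Hz; 1-6 Hz (delta/theta) is excluded
from the feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import LAYOUT_MATRIX
from .errors import BoundsError, ConfigurationError, ShapeError
from .preprocessing import Spectrogram


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, exclusive

    def bin_mask(self, freq_axis: np.ndarray) -> np.ndarray:
        return (freq_axis >= self.lo) & (freq_axis < self.hi)


#: The four analysis bands, in canonical (quadrant) order.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("alpha", 7.0, 15.0),
    BandDefinition("beta", 15.0, 33.0),
    BandDefinition("low_gamma", 33.0, 70.0),
    BandDefinition("high_gamma", 70.0, 121.0),  # top bin 120 Hz inclusive
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

#: Quadrant (row, col) of each band in the 10x10 merged image, reading order.
BAND_QUADRANTS: dict[str, tuple[int, int]] = {
    "alpha": (0, 0), "beta": (0, 1), "low_gamma": (1, 0), "high_gamma": (1, 1),
}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis windows over the application span."""

    length: float = 3.0  # s
    hop: float = 1.0     # s (=> 2 s overlap, 66.7%)
    span: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError("window length must be > 0")
        if not (0 < self.hop <= self.length):
            raise ConfigurationError("hop must satisfy 0 < hop <= length")
        if self.span[1] - self.span[0] < self.length:
            raise ConfigurationError("span must be at least one window long")

    @property
    def n_windows(self) -> int:
        span_len = self.span[1] - self.span[0]
        return int(np.floor((span_len - self.length) / self.hop + 1e-9)) + 1

    def window_bounds(self, i: int) -> tuple[float, float]:
        start = self.span[0] + i * self.hop
        return (start, start + self.length)


@dataclass
class BandPowerWindow:
    """Mean power per band x channel for one window."""

    window_index: int
    values: np.ndarray  # (4, 19)


@dataclass
class LayoutFrame:
    """One band's 5x5 scalp-layout power image."""

    band: str
    grid: np.ndarray  # (5, 5)


@dataclass
class MergedFrame:
    """The 10x10 four-band image fed to the merged-input classifiers."""

    grid: np.ndarray  # (10, 10)
    band_quadrants: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(BAND_QUADRANTS))

    def quadrant(self, band: str) -> np.ndarray:
        r, c = self.band_quadrants[band]
        return self.grid[5 * r:5 * r + 5, 5 * c:5 * c + 5]


def make_windows(spec: Spectrogram, wspec: WindowSpec = WindowSpec()) -> list[Spectrogram]:
    """Cut the spectrogram into sliding windows over ``wspec.span``.

    Window i covers [span0 + i*hop, span0 + i*hop + length); a time bin
    belongs to the window if its centre lies in that half-open interval.
    """
    t = spec.time_axis
    lo, hi = wspec.span
    dt = t[1] - t[0] if t.size > 1 else wspec.length
    if t[0] > lo + 1e-9 or t[-1] < hi - dt - 1e-9:
        raise BoundsError(
            f"spectrogram covers [{t[0]}, {t[-1]}] s; cannot window span {wspec.span}")
    return [spec.crop(*wspec.window_bounds(i)) for i in range(wspec.n_windows)]


def band_average(window: Spectrogram, bands: tuple[BandDefinition, ...] = BANDS,
                 window_index: int = 0) -> BandPowerWindow:
    """Mean power over time bins and in-band frequency bins, per channel."""
    vals = np.empty((len(bands), window.power.shape[0]))
    for b, band in enumerate(bands):
        mask = band.bin_mask(window.freq_axis)
        if not mask.any():
            raise ConfigurationError(f"freq_axis has no bins in band {band.name}")
        vals[b] = window.power[:, mask, :].mean(axis=(1, 2))
    return BandPowerWindow(window_index=window_index, values=vals)


def layout_5x5(channel_values: np.ndarray, band: str = "") -> LayoutFrame:
    """Arrange 19 channel values on the 5x5 scalp grid (gaps = neighbour means)."""
    v = np.asarray(channel_values, dtype=float)
    if v.shape != (19,):
        raise ShapeError(f"expected 19 channel values, got shape {v.shape}")
    if not np.isfinite(v).all():
        raise ValueError("channel values must be finite")
    return LayoutFrame(band=band, grid=(LAYOUT_MATRIX @ v).reshape(5, 5))


def merge_bands(frames: dict[str, LayoutFrame] | list[LayoutFrame]) -> MergedFrame:
    """Tile the four band frames into the 10x10 merged image."""
    if not isinstance(frames, dict):
        frames = {f.band: f for f in frames}
    missing = set(BAND_NAMES) - set(frames)
    if missing:
        raise ConfigurationError(f"missing band frames: {sorted(missing)}")
    grid = np.empty((10, 10))
    for name, (r, c) in BAND_QUADRANTS.items():
        grid[5 * r:5 * r + 5, 5 * c:5 * c + 5] = frames[name].grid
    return MergedFrame(grid=grid)


def frames_from_bandpower(bp: BandPowerWindow) -> tuple[np.ndarray, np.ndarray]:
    """(4,5,5) band frames and (10,10) merged frame from one window's table."""
    per_band = {name: layout_5x5(bp.values[b], band=name)
                for b, name in enumerate(BAND_NAMES)}
    band_stack = np.stack([per_band[n].grid for n in BAND_NAMES])
    return band_stack, merge_bands(per_band).grid


def merge_band_stack(band_frames: np.ndarray) -> np.ndarray:
    """Vectorised merge: (..., 4, 5, 5) band frames -> (..., 10, 10) images."""
    bf = np.asarray(band_frames)
    if bf.shape[-3:] != (4, 5, 5):
        raise ShapeError(f"expected trailing dims (4, 5, 5), got {bf.shape}")
    out = np.empty(bf.shape[:-3] + (10, 10), dtype=bf.dtype)
    for b, name in enumerate(BAND_NAMES):
        r, c = BAND_QUADRANTS[name]
        out[..., 5 * r:5 * r + 5, 5 * c:5 * c + 5] = bf[..., b, :, :]
    return out
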