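"""Channel demultiplexing, B-scan assembly/stitching, and A-scan SNR.

After full-range reconstruction the two channels occupy disjoint depth
windows of the length-N axis: channel 1 at [0, 2d) (positive depths) and
channel 2 at the wrapped negative-depth window, bin j of channel 2 stored at
index (N - j) % N.  Index 0 is the shared zero-path/DC bin and is reported in
both channels; physical phantoms keep it empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ChannelLayout:
    """Depth bookkeeping for the two channels.

    ``offset_bins`` is the pre-introduced path offset d; each channel images
    a 2d-bin window and 2*2d must fit in the N-bin full-range axis
    (2d <= N/2).
    """

    offset_bins: int
    n: int
    bin_size_m: float | None = None

    def __post_init__(self) -> None:
        if self.offset_bins <= 0:
            raise ValueError("offset must be positive")
        if 2 * self.offset_bins > self.n // 2:
            raise ValueError("2d must not exceed N/2 bins")

    @property
    def channel_bins(self) -> int:
        return 2 * self.offset_bins

    @property
    def offset_mm(self) -> float | None:
        if self.bin_size_m is None:
            return None
        return self.offset_bins * self.bin_size_m * 1e3

    @property
    def one_sided_depth_mm(self) -> float | None:
        if self.bin_size_m is None:
            return None
        return (self.n // 2) * self.bin_size_m * 1e3


@dataclass
class BScan:
    """2-D magnitude image: rows = depth bins, cols = lateral positions."""

    image: np.ndarray
    axial_pitch_mm: float = 1.0
    lateral_pitch_mm: float = 1.0
    channel: int | None = None
    mode: int | None = None
    scale: str = "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("B-scan image must be 2-D")
        if self.scale == "linear" and np.any(img < 0):
            raise ValueError("linear-scale magnitudes must be non-negative")
        if self.axial_pitch_mm <= 0 or self.lateral_pitch_mm <= 0:
            raise ValueError("pixel pitches must be positive")
        self.image = img

    @property
    def depth_extent_bins(self) -> int:
        return self.image.shape[0]

    @property
    def width_px(self) -> int:
        return self.image.shape[1]


def demux(u_hat: np.ndarray, layout: ChannelLayout) -> tuple[np.ndarray, np.ndarray]:
    """Split a full-range depth vector into per-channel magnitude A-scans.

    Both returned A-scans have length 2d with bin 0 at the channel's zero
    path and depth increasing into the sample; channel-2 bins are read from
    the wrapped indices (N - j) % N.
    """
    u_hat = np.asarray(u_hat)
    if u_hat.size != layout.n:
        raise ValueError("depth vector length does not match layout")
    w = layout.channel_bins
    ascan1 = np.abs(u_hat[:w]).astype(float)
    idx2 = (layout.n - np.arange(w)) % layout.n
    ascan2 = np.abs(u_hat[idx2]).astype(float)
    return ascan1, ascan2


def assemble_bscan(
    ascans,
    axial_pitch_mm: float = 1.0,
    lateral_pitch_mm: float = 1.0,
    channel: int | None = None,
    mode: int | None = None,
) -> BScan:
    """Stack per-lateral-position A-scans into a B-scan (depth x lateral)."""
    img = np.column_stack([np.asarray(a, dtype=float) for a in ascans])
    return BScan(
        img,
        axial_pitch_mm=axial_pitch_mm,
        lateral_pitch_mm=lateral_pitch_mm,
        channel=channel,
        mode=mode,
    )


def stitch_mode1(b1: BScan, b2: BScan, dead_zone_px: int = 0) -> BScan:
    """Lateral concatenation [channel 1 | dead zone | channel 2].

    The two channels scan laterally adjacent regions; the gap between the
    focusing lenses leaves a dead zone, rendered as zero-filled columns and
    recorded in the metadata.
    """
    if b1.depth_extent_bins != b2.depth_extent_bins:
        raise ValueError("channel B-scans must share the depth extent")
    if dead_zone_px < 0:
        raise ValueError("dead zone must be non-negative")
    gap = np.zeros((b1.depth_extent_bins, dead_zone_px))
    img = np.concatenate([b1.image, gap, b2.image], axis=1)
    out = BScan(
        img,
        axial_pitch_mm=b1.axial_pitch_mm,
        lateral_pitch_mm=b1.lateral_pitch_mm,
        mode=1,
        scale=b1.scale,
    )
    out.meta = {
        "source_columns": {
            "channel1": [0, b1.width_px],
            "dead_zone": [b1.width_px, b1.width_px + dead_zone_px],
            "channel2": [b1.width_px + dead_zone_px, img.shape[1]],
        }
    }
    return out


def stitch_mode2(
    b_upper: BScan, b_deep: BScan, x_shift_px: int = 0, overlap_px: int = 0
) -> BScan:
    """Axial concatenation (upper over deep) with lateral-shift correction.

    The deeper channel's image is shifted right by ``x_shift_px`` to correct
    the instrument's lateral offset, then only the laterally common columns
    are kept.  ``overlap_px`` rows at the seam are blended by maximum (robust
    to the lower channel-2 signal level).  With zero shift and zero overlap
    the stitched depth extent is exactly the sum of the two extents.
    """
    if b_upper.width_px != b_deep.width_px:
        raise ValueError("channel B-scans must share the lateral width")
    w = b_upper.width_px
    if not 0 <= x_shift_px < w:
        raise ValueError("lateral shift must lie in [0, width)")
    if overlap_px < 0 or overlap_px > min(b_upper.depth_extent_bins, b_deep.depth_extent_bins):
        raise ValueError("overlap outside the valid range")
    upper = b_upper.image[:, x_shift_px:]
    deep = b_deep.image[:, : w - x_shift_px]
    rows = upper.shape[0] + deep.shape[0] - overlap_px
    img = np.zeros((rows, upper.shape[1]))
    img[: upper.shape[0]] = upper
    start = upper.shape[0] - overlap_px
    img[start : start + deep.shape[0]] = np.maximum(
        img[start : start + deep.shape[0]], deep
    )
    out = BScan(
        img,
        axial_pitch_mm=b_upper.axial_pitch_mm,
        lateral_pitch_mm=b_upper.lateral_pitch_mm,
        mode=2,
        scale=b_upper.scale,
    )
    out.meta = {"x_shift_px": x_shift_px, "overlap_px": overlap_px}
    return out


def snr_db(ascan: np.ndarray, peak_index: int, noise_window, guard: int = 1) -> float:
    """A-scan SNR: 20*log10(peak height / noise-floor standard deviation).

    ``noise_window`` is a (start, stop) index range on the magnitude A-scan;
    it must hold at least 8 bins and exclude the peak and its +/-guard
    neighbours.  A zero noise std returns +inf as the infinite-SNR sentinel.
    """
    ascan = np.asarray(ascan, dtype=float)
    start, stop = int(noise_window[0]), int(noise_window[1])
    if stop - start < 8:
        raise ValueError("noise window must span at least 8 bins")
    if start <= peak_index + guard and stop > peak_index - guard:
        raise ValueError("noise window must exclude the peak +/- guard bins")
    sigma = float(np.std(ascan[start:stop]))
    if sigma == 0.0:
        return float("inf")
    return 20.0 * np.log10(ascan[peak_index] / sigma)


def to_db_image(b: BScan, floor_db: float = -40.0) -> np.ndarray:
    """8-bit log-compressed image: 20*log10 relative to the image maximum,
    clipped at ``floor_db`` and linearly quantised to 0..255."""
    if floor_db >= 0:
        return np.zeros(b.image.shape, dtype=np.uint8)
    peak = b.image.max()
    if peak <= 0:
        return np.zeros(b.image.shape, dtype=np.uint8)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(b.image / peak)
    db = np.clip(db, floor_db, 0.0)
    return np.round((db - floor_db) / (-floor_db) * 255.0).astype(np.uint8)
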