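"""Encode an RGB bitmap as an array layout of per-channel template truncations.

Each colour channel is carried by one template sequence; brightness shades
are realized by 5' truncations of that sequence (shorter template -> shorter
RNA -> shorter probe duplex -> dimmer feature). A calibration of truncation
length against hybridization intensity selects, per channel, the k
truncations whose intensities best match k evenly spaced targets across the
observed range. A pixel is expanded to a small block of features (one per
channel plus a duplicate of the brightest channel) and the expanded image is
tiled to fill the synthesis grid of the micromirror device.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .design import DesignTable, TemplateSpec, make_template
from .seqcore import DEFAULT_PRIMER, PrimerSpec

__all__ = [
    "CHANNELS",
    "CHANNEL_TEMPLATES",
    "CHANNEL_WAVELENGTHS",
    "CalibrationCurve",
    "LevelMap",
    "ArrayLayout",
    "TilingConfig",
    "GeometryError",
    "InsufficientCalibrationError",
    "quantize_rgb",
    "select_levels",
    "encode_image",
    "DARK_PROBE_ID",
]

CHANNELS = ("red", "green", "blue")

#: Full-length variable regions carrying each colour channel (detected with
#: Cy5-, Cy3- and FAM-labelled complements respectively).
CHANNEL_TEMPLATES: Dict[str, str] = {
    "red": "TCACCGAATCGATTCCATCTGCTTC",
    "green": "TCAACCCAGGTCCAATTTCC",
    "blue": "ACAGTGGATCGTACTCAGGTCTCA",
}

#: Scanner laser line conventionally used per channel fluorophore.
CHANNEL_WAVELENGTHS: Dict[str, int] = {"red": 635, "green": 532, "blue": 488}

DARK_PROBE_ID = "dark"
# TG repeat: no complementarity to any channel probe, never transcribed.
_DARK_VARIABLE = "TG" * 10


class GeometryError(ValueError):
    """Raster, block and grid shapes are inconsistent."""


class InsufficientCalibrationError(ValueError):
    """Fewer calibration points than requested levels."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Measured mean intensity per truncation length for one channel."""

    channel: str
    points: Mapping[int, float]  # truncation length (nt) -> mean intensity (a.u.)

    def __post_init__(self) -> None:
        full_len = len(CHANNEL_TEMPLATES.get(self.channel, "")) or None
        for length, intensity in self.points.items():
            if length <= 0:
                raise ValueError(f"truncation length must be positive, got {length}")
            if full_len is not None and length > full_len:
                raise ValueError(
                    f"truncation length {length} exceeds the {full_len} nt "
                    f"{self.channel} template"
                )
            if intensity < 0:
                raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class LevelMap:
    """Ordered truncation lengths, level 0 (dimmest) .. k-1 (brightest)."""

    channel: str
    lengths: Tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.lengths, self.lengths[1:])):
            raise ValueError("level lengths must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.lengths)


def quantize_rgb(image, k: int = 8) -> np.ndarray:
    """Quantize an 8-bit RGB raster to ``k`` brightness levels per channel.

    Levels use floor binning, ``level = value * k // 256``, mapping 0..255
    onto 0..k-1 (so 0 -> 0 and 255 -> k-1). Accepts an ``(H, W, 3)`` uint8
    array or a PIL image convertible to RGB.
    """
    if not 2 <= k <= 256:
        raise ValueError("k must be in [2, 256]")
    if hasattr(image, "convert"):  # PIL image
        if image.mode != "RGB":
            image = image.convert("RGB")
        image = np.asarray(image)
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise GeometryError(f"expected an (H, W, 3) RGB raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("channel values must be 8-bit (0..255)")
        arr = arr.astype(np.uint8)
    return (arr.astype(np.int64) * k) // 256


def select_levels(curve: CalibrationCurve, k: int = 8) -> LevelMap:
    """Select the ``k`` truncation lengths spanning the intensity range with
    the most uniform spacing.

    Targets are ``k`` intensities evenly spaced from the minimum to the
    maximum observed intensity (both extremes included). With at most 25
    calibration points the optimum is found by exhaustive search over all
    size-k subsets, minimizing the sum of squared deviations between the
    subset's (sorted) intensities and the targets; ties break to the
    lexicographically smallest length tuple. Larger calibrations use a
    greedy nearest-intensity assignment per target.
    """
    items = sorted(curve.points.items())
    n = len(items)
    if n < k:
        raise InsufficientCalibrationError(
            f"{n} calibration points < {k} requested levels for channel {curve.channel}"
        )
    lengths = [length for length, _ in items]
    intens = np.array([i for _, i in items], dtype=float)
    targets = np.linspace(intens.min(), intens.max(), k)
    if n == k:
        order = np.argsort(intens, kind="stable")
        return LevelMap(curve.channel, tuple(lengths[i] for i in order))
    if n <= 25:
        best_sse = np.inf
        best: Optional[Tuple[int, ...]] = None
        for combo in itertools.combinations(range(n), k):
            sel = intens[list(combo)]
            sse = float(np.sum((np.sort(sel) - targets) ** 2))
            if sse < best_sse - 1e-12:
                best_sse = sse
                best = combo
        assert best is not None
        order = sorted(best, key=lambda i: (intens[i], lengths[i]))
        return LevelMap(curve.channel, tuple(lengths[i] for i in order))
    # greedy fallback for dense calibrations
    chosen: List[int] = []
    free = set(range(n))
    for t in targets:
        i = min(free, key=lambda j: (abs(intens[j] - t), lengths[j]))
        chosen.append(i)
        free.discard(i)
    chosen.sort(key=lambda i: (intens[i], lengths[i]))
    return LevelMap(curve.channel, tuple(lengths[i] for i in chosen))


@dataclass
class ArrayLayout:
    """Rectangular feature grid mapping 0-based (row, col) to probe ids.

    ``annotations`` optionally records the image channel and brightness level
    of each feature for downstream bookkeeping.
    """

    n_rows: int
    n_cols: int
    features: Dict[Tuple[int, int], str]
    annotations: Dict[Tuple[int, int], Tuple[Optional[str], Optional[int]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for (r, c) in self.features:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise GeometryError(
                    f"feature ({r}, {c}) outside grid {self.n_rows}x{self.n_cols}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def subgrid(self, n_rows: int, n_cols: int, origin: Tuple[int, int] = (0, 0)) -> "ArrayLayout":
        """Crop to an ``n_rows`` x ``n_cols`` window anchored at ``origin``."""
        r0, c0 = origin
        feats = {
            (r - r0, c - c0): pid
            for (r, c), pid in self.features.items()
            if r0 <= r < r0 + n_rows and c0 <= c < c0 + n_cols
        }
        anns = {
            (r - r0, c - c0): a
            for (r, c), a in self.annotations.items()
            if r0 <= r < r0 + n_rows and c0 <= c < c0 + n_cols
        }
        return ArrayLayout(n_rows, n_cols, feats, anns)

    def to_frame(self):
        import pandas as pd

        rows = []
        for (r, c), pid in sorted(self.features.items()):
            channel, level = self.annotations.get((r, c), (None, None))
            rows.append(
                {"row": r, "col": c, "probe_id": pid, "channel": channel, "level": level}
            )
        return pd.DataFrame(rows, columns=["row", "col", "probe_id", "channel", "level"])

    @classmethod
    def from_frame(cls, frame, n_rows: Optional[int] = None, n_cols: Optional[int] = None):
        features = {}
        annotations = {}
        for rec in frame.itertuples(index=False):
            key = (int(rec.row), int(rec.col))
            features[key] = str(rec.probe_id)
            channel = getattr(rec, "channel", None)
            level = getattr(rec, "level", None)
            if channel is not None or level is not None:
                channel = None if channel in (None, "", "nan") or channel != channel else str(channel)
                level = None if level is None or level != level else int(level)
                annotations[key] = (channel, level)
        if n_rows is None:
            n_rows = max(r for r, _ in features) + 1 if features else 0
        if n_cols is None:
            n_cols = max(c for _, c in features) + 1 if features else 0
        return cls(n_rows, n_cols, features, annotations)


@dataclass(frozen=True)
class TilingConfig:
    """How pixels expand to feature blocks and images tile the grid.

    The default — 2x2 channel blocks per pixel, then 2x2 tiling of the
    expanded image — takes a 256x192 pixel source to exactly the 1024x768
    feature grid of the XGA micromirror device. The fourth block position
    duplicates the pixel's brightest channel.
    """

    block_shape: Tuple[int, int] = (2, 2)
    tile_reps: Tuple[int, int] = (2, 2)

    def expanded_shape(self, raster_shape: Tuple[int, int]) -> Tuple[int, int]:
        h, w = raster_shape
        return (
            h * self.block_shape[0] * self.tile_reps[0],
            w * self.block_shape[1] * self.tile_reps[1],
        )


def _truncation_probe_id(channel: str, length: int) -> str:
    return f"{channel}_L{length:02d}"


def encode_image(
    levels: np.ndarray,
    level_maps: Mapping[str, LevelMap],
    tiling: TilingConfig = TilingConfig(),
    primer: PrimerSpec = DEFAULT_PRIMER,
    grid: Optional[Tuple[int, int]] = None,
    linker_len: int = 5,
) -> Tuple[ArrayLayout, DesignTable]:
    """Expand a quantized level raster into an array layout plus its probes.

    Each pixel becomes a block of features: red, green, blue, and (for 2x2
    blocks) a duplicate of the pixel's brightest channel; the expanded image
    is tiled ``tile_reps`` times to fill the grid. A feature receives the
    channel template truncated (5'-ward) to the length of the pixel's level;
    level-0 features receive the untranscribable dark control. All 3 x k
    truncation templates plus the dark control are emitted as a DesignTable.

    Raises
    ------
    GeometryError
        If ``grid`` is given and the expanded raster does not match it.
    """
    levels = np.asarray(levels)
    if levels.ndim != 3 or levels.shape[2] != 3:
        raise GeometryError(f"expected an (H, W, 3) level raster, got shape {levels.shape}")
    h, w, _ = levels.shape
    expanded = tiling.expanded_shape((h, w))
    if grid is not None and tuple(grid) != expanded:
        raise GeometryError(
            f"expanded raster shape {expanded} does not match target grid {tuple(grid)}"
        )
    n_rows, n_cols = expanded
    bh, bw = tiling.block_shape

    # Emit probes: every (channel, level) truncation, plus the dark control.
    templates: List[TemplateSpec] = []
    probe_of: Dict[Tuple[str, int], str] = {}
    for channel in CHANNELS:
        lm = level_maps[channel]
        full = CHANNEL_TEMPLATES[channel]
        for level, length in enumerate(lm.lengths):
            variable = full[-length:]  # 5' truncation: keep the 3'-most bases
            pid = _truncation_probe_id(channel, length)
            probe_of[(channel, level)] = pid
            if not any(t.probe_id == pid for t in templates):
                templates.append(
                    make_template(
                        variable,
                        linker_len,
                        primer,
                        probe_id=pid,
                        platform="photolithography",
                        channel=channel,
                        level=level,
                        response_len=length,
                    )
                )
    from .design import TemplateSpec as _TS  # dark control has no probe complement

    templates.append(
        _TS(
            probe_id=DARK_PROBE_ID,
            variable=_DARK_VARIABLE,
            linker_len=linker_len,
            role="control",
            primer_name=primer.name,
            response_len=0,
        )
    )
    design = DesignTable(templates, replicate_count=1, metadata={"series": "rgb-image"})

    # block cell -> channel; position (bh-1, bw-1) duplicates the brightest.
    cell_channel: Dict[Tuple[int, int], Optional[str]] = {}
    flat_cells = [(i, j) for i in range(bh) for j in range(bw)]
    for idx, cell in enumerate(flat_cells):
        cell_channel[cell] = CHANNELS[idx] if idx < len(CHANNELS) else None

    features: Dict[Tuple[int, int], str] = {}
    annotations: Dict[Tuple[int, int], Tuple[Optional[str], Optional[int]]] = {}
    lvl = {ch: levels[:, :, i] for i, ch in enumerate(CHANNELS)}
    for py in range(h):
        for px in range(w):
            pix_levels = {ch: int(lvl[ch][py, px]) for ch in CHANNELS}
            brightest = max(CHANNELS, key=lambda ch: pix_levels[ch])
            for (ci, cj), channel in cell_channel.items():
                ch = channel if channel is not None else brightest
                level = pix_levels[ch]
                if level <= 0:
                    pid, ann = DARK_PROBE_ID, (None, 0)
                else:
                    pid, ann = probe_of[(ch, level)], (ch, level)
                base_r, base_c = py * bh + ci, px * bw + cj
                for tr in range(tiling.tile_reps[0]):
                    for tc in range(tiling.tile_reps[1]):
                        r = tr * h * bh + base_r
                        c = tc * w * bw + base_c
                        features[(r, c)] = pid
                        annotations[(r, c)] = ann
    layout = ArrayLayout(n_rows, n_cols, features, annotations)
    return layout, design
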