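"""Frame-stack handling: registration by translation and averaging.

An AO-SLO acquisition of one retinal region is a short stack of frames
(typically 32) of the same patch, displaced relative to each other by eye
motion.  Averaging after rigid-translation registration trades temporal
resolution for signal-to-noise: residual noise falls as 1/sqrt(n_frames)
while the cone mosaic stays sharp.

Coordinates are (row, col) = (y, x), 0-based, pixel-center convention.
A frame's *shift* (dy, dx) is its displacement relative to the reference
frame: frame(y, x) ~ reference(y - dy, x - dx).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage


@dataclass
class FrameStack:
    """A stack of co-located AO-SLO frames plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, H, W), float64, non-negative
    pixel_scale_um: float
    eccentricity_mm: float = 1.0
    region_label: str = "superior"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, H, W) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < 0:
            raise ValueError("frame intensities must be non-negative")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MosaicImage:
    """One averaged mosaic image of a retinal region — the unit of analysis."""

    pixels: np.ndarray  # (H, W) float
    pixel_scale_um: float
    eccentricity_mm: float = 1.0
    region_label: str = "superior"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ShiftEstimate:
    """Per-frame translation estimates with a registration confidence score.

    ``peak_ratio`` is the phase-correlation peak divided by the largest
    secondary peak; values near 1 mean the correlation surface is flat
    (pure noise) and the shift is untrustworthy.
    """

    shifts: np.ndarray        # (n, 2) (dy, dx)
    peak_ratio: np.ndarray    # (n,)
    low_confidence: np.ndarray  # (n,) bool

    def __iter__(self):
        return iter(self.shifts)


def _phase_correlation_surface(ref: np.ndarray, frame: np.ndarray) -> np.ndarray:
    fr = np.fft.fft2(ref)
    ff = np.fft.fft2(frame)
    cross = fr * np.conj(ff)
    denom = np.abs(cross)
    denom[denom == 0] = 1.0
    return np.abs(np.fft.ifft2(cross / denom))


def _wrap_shift(idx: int, n: int) -> int:
    return idx - n if idx > n // 2 else idx


def estimate_shifts(
    stack: FrameStack,
    reference_index: int = 0,
    subpixel: bool = False,
    upsample_factor: int = 4,
    peak_ratio_threshold: float = 3.0,
) -> ShiftEstimate:
    """Estimate each frame's translation relative to the reference frame.

    Uses the cross-power-spectrum (phase correlation) peak.  Integer-pixel
    precision by default; ``subpixel=True`` refines by Fourier upsampling.
    The reference frame's shift is exactly (0, 0).

    A frame whose correlation peak ratio falls below
    ``peak_ratio_threshold`` is flagged low-confidence (a warning is
    logged, processing continues); the flag propagates into downstream QC.
    """
    n = stack.n_frames
    if not 0 <= reference_index < n:
        raise IndexError("reference_index out of range")
    ref = stack.frames[reference_index]
    shifts = np.zeros((n, 2), dtype=float)
    ratios = np.full(n, np.inf)
    h, w = ref.shape
    for i in range(n):
        if i == reference_index:
            continue
        frame = stack.frames[i]
        surface = _phase_correlation_surface(ref, frame)
        peak_flat = int(np.argmax(surface))
        py, px = np.unravel_index(peak_flat, surface.shape)
        # frame(y,x)=ref(y-dy,x-dx) puts the correlation peak at (-dy, -dx)
        dy = -float(_wrap_shift(int(py), h))
        dx = -float(_wrap_shift(int(px), w))
        peak_val = surface[py, px]
        masked = surface.copy()
        yy = (np.arange(h)[:, None] - py + h // 2) % h - h // 2
        xx = (np.arange(w)[None, :] - px + w // 2) % w - w // 2
        masked[(np.abs(yy) <= 5) & (np.abs(xx) <= 5)] = 0.0
        second = masked.max()
        ratios[i] = peak_val / second if second > 0 else np.inf
        if subpixel:
            from skimage.registration import phase_cross_correlation

            # skimage returns the correction to apply to the moving frame,
            # i.e. the negative of the frame's displacement
            corr, _, _ = phase_cross_correlation(
                ref, frame, upsample_factor=upsample_factor, normalization="phase"
            )
            dy, dx = -float(corr[0]), -float(corr[1])
        shifts[i] = (dy, dx)
    low = ratios < peak_ratio_threshold
    if low.any():
        warnings.warn(
            f"{int(low.sum())} frame(s) registered with low confidence "
            f"(peak ratio < {peak_ratio_threshold})",
            stacklevel=2,
        )
    return ShiftEstimate(shifts=shifts, peak_ratio=ratios, low_confidence=low)


def average_frames(
    stack: FrameStack,
    shifts: np.ndarray | ShiftEstimate | None = None,
) -> MosaicImage:
    """Average shift-compensated frames over their common overlap.

    Each frame is translated by the negative of its estimated shift so all
    frames land in the reference frame's coordinate system, then the stack
    is averaged pixel-wise over the region covered by every frame (the
    output is cropped, never padded, so border pixels are true means).
    ``shifts=None`` averages without registration.
    """
    low_confidence = False
    if isinstance(shifts, ShiftEstimate):
        low_confidence = bool(shifts.low_confidence.any())
        shifts = shifts.shifts
    n = stack.n_frames
    if shifts is None:
        shifts = np.zeros((n, 2))
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (n, 2):
        raise ValueError(f"need one (dy, dx) pair per frame, got {shifts.shape}")

    h, w = stack.shape
    integer = np.allclose(shifts, np.round(shifts))
    if integer:
        s = np.round(shifts).astype(int)
        # corrected(y, x) = frame(y + dy, x + dx) lands in reference coords
        y0 = max(0, -int(s[:, 0].min()))
        y1 = h - max(0, int(s[:, 0].max()))
        x0 = max(0, -int(s[:, 1].min()))
        x1 = w - max(0, int(s[:, 1].max()))
        if y1 <= y0 or x1 <= x0:
            raise ValueError("shift-compensated frames have no common overlap")
        # mean computed as base + mean(deviations): exact for identical
        # frames and avoids accumulation error
        base = stack.frames[0, y0 + s[0, 0] : y1 + s[0, 0], x0 + s[0, 1] : x1 + s[0, 1]]
        acc = np.zeros_like(base)
        for i in range(1, n):
            dy, dx = s[i]
            acc += stack.frames[i, y0 + dy : y1 + dy, x0 + dx : x1 + dx] - base
        pixels = base + acc / n
    else:
        y0 = max(0, int(np.ceil(-shifts[:, 0].min())))
        y1 = h - max(0, int(np.ceil(shifts[:, 0].max())))
        x0 = max(0, int(np.ceil(-shifts[:, 1].min())))
        x1 = w - max(0, int(np.ceil(shifts[:, 1].max())))
        if y1 <= y0 or x1 <= x0:
            raise ValueError("shift-compensated frames have no common overlap")
        acc = np.zeros((y1 - y0, x1 - x0))
        for i in range(n):
            corrected = ndimage.shift(
                stack.frames[i], -shifts[i], order=1, mode="nearest"
            )
            acc += corrected[y0:y1, x0:x1]
        pixels = acc / n

    prov = {
        "n_frames": n,
        "shifts": shifts.tolist(),
        "overlap_offset": [int(y0), int(x0)],
        "registered": shifts.any(),
        "low_confidence_registration": low_confidence,
    }
    return MosaicImage(
        pixels=pixels,
        pixel_scale_um=stack.pixel_scale_um,
        eccentricity_mm=stack.eccentricity_mm,
        region_label=stack.region_label,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# I/O — multi-page TIFF or numbered PNG set, with a JSON metadata sidecar.
# 16-bit integer storage with an affine (offset, scale) recorded in the
# sidecar so float intensities round-trip.


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "meta.json"
    return path.with_suffix(".json")


def _quantize(frames: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo = float(frames.min())
    hi = float(frames.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    raw = np.round((frames - lo) / scale).astype(np.uint16)
    return raw, lo, scale


def write_stack(stack: FrameStack, path: str | Path, fmt: str = "tiff") -> Path:
    """Write a frame stack as multi-page 16-bit TIFF (or numbered PNGs).

    Returns the path of the main artifact; a JSON sidecar with
    pixel scale, eccentricity, region label and the intensity affine is
    written alongside.
    """
    path = Path(path)
    raw, offset, scale = _quantize(stack.frames)
    meta = {
        "pixel_scale_um": stack.pixel_scale_um,
        "eccentricity_mm": stack.eccentricity_mm,
        "region_label": stack.region_label,
        "n_frames": stack.n_frames,
        "intensity_offset": offset,
        "intensity_scale": scale,
        "coordinate_convention": "0-based, pixel-center, (y, x)",
        **{k: v for k, v in stack.meta.items() if _json_safe(v)},
    }
    if fmt == "tiff":
        tifffile.imwrite(path, raw, photometric="minisblack")
    elif fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i in range(stack.n_frames):
            iio.imwrite(path / f"frame_{i:04d}.png", raw[i])
    else:
        raise ValueError(f"unsupported format: {fmt!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a frame stack written by :func:`write_stack`.

    Raises if the metadata sidecar is missing or lacks ``pixel_scale_um``
    (spot sizing is meaningless without the pixel scale).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "pixel_scale_um" not in meta:
        raise ValueError("metadata sidecar lacks pixel_scale_um")
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        raw = np.stack([iio.imread(f) for f in files])
    else:
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
    offset = float(meta.get("intensity_offset", 0.0))
    scale = float(meta.get("intensity_scale", 1.0))
    frames = offset + raw.astype(float) * scale
    extra = {
        k: v
        for k, v in meta.items()
        if k
        not in {
            "pixel_scale_um",
            "eccentricity_mm",
            "region_label",
            "n_frames",
            "intensity_offset",
            "intensity_scale",
            "coordinate_convention",
        }
    }
    return FrameStack(
        frames=frames,
        pixel_scale_um=float(meta["pixel_scale_um"]),
        eccentricity_mm=float(meta.get("eccentricity_mm", 1.0)),
        region_label=meta.get("region_label", "superior"),
        meta=extra,
    )


def write_mosaic(image: MosaicImage, path: str | Path) -> Path:
    """Write an averaged mosaic as a float32 single-page TIFF + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    meta = {
        "pixel_scale_um": image.pixel_scale_um,
        "eccentricity_mm": image.eccentricity_mm,
        "region_label": image.region_label,
        "provenance": {k: v for k, v in image.provenance.items() if _json_safe(v)},
        "coordinate_convention": "0-based, pixel-center, (y, x)",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_mosaic(path: str | Path) -> MosaicImage:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "pixel_scale_um" not in meta:
        raise ValueError("metadata sidecar lacks pixel_scale_um")
    pixels = tifffile.imread(path).astype(float)
    return MosaicImage(
        pixels=pixels,
        pixel_scale_um=float(meta["pixel_scale_um"]),
        eccentricity_mm=float(meta.get("eccentricity_mm", 1.0)),
        region_label=meta.get("region_label", "superior"),
        provenance=meta.get("provenance", {}),
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
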