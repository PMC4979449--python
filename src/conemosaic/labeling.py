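"""Automated cone labeling: eccentricity-tuned low-pass filtering followed
by local-maximum detection, with optional merge of manual edits.

The detector follows the classic recipe for confocal AO-SLO cone mosaics:
suppress spatial frequencies above the mosaic's fundamental (set by the
expected cone spacing at the imaged eccentricity) with a smooth frequency-
domain low-pass, then accept local intensity maxima greedily in descending
brightness subject to a minimum separation.  Sub-pixel peak positions come
from a 3×3 quadratic refinement.  Cones the detector misses can be added
(and false positives removed) from manual edit lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .frames import MosaicImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConeLocation:
    """One labeled cone position (0-based, pixel-center convention)."""

    x_px: float
    y_px: float
    source: str = "auto"  # "auto" | "manual"
    peak_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.source not in ("auto", "manual"):
            raise ValueError("source must be 'auto' or 'manual'")


@dataclass
class DetectionParams:
    """Tunable knobs of the cone detector.

    ``cutoff_period_px`` is the low-pass cutoff expressed as a spatial
    period; ``rel_threshold`` is a fraction of the filtered image's robust
    (1st–99th percentile) intensity range.
    """

    cutoff_period_px: float = 4.12
    min_distance_px: float = 4.0
    rel_threshold: float = 0.1
    border_margin_px: int = 2

    def __post_init__(self) -> None:
        if self.cutoff_period_px <= 0 or self.min_distance_px <= 0:
            raise ValueError("cutoff_period_px and min_distance_px must be positive")
        if not 0.0 < self.rel_threshold < 1.0:
            raise ValueError("rel_threshold must be in (0, 1)")
        if self.border_margin_px < 0:
            raise ValueError("border_margin_px must be >= 0")


# Nominal center-to-center cone spacing (μm) vs eccentricity (mm) from the
# foveal center.  Small monotone lookup, linearly interpolated; spacing
# grows away from the fovea as cone density falls.
DEFAULT_SPACING_TABLE_UM: tuple[tuple[float, float], ...] = (
    (0.0, 3.0),
    (0.5, 5.0),
    (1.0, 7.0),
    (2.0, 9.5),
    (3.0, 11.0),
)


def expected_spacing_um(
    eccentricity_mm: float,
    table: tuple[tuple[float, float], ...] = DEFAULT_SPACING_TABLE_UM,
) -> float:
    """Nominal cone spacing at a retinal eccentricity, by interpolation.

    Eccentricities beyond the lookup range are clamped (with a warning).
    """
    if eccentricity_mm < 0:
        raise ValueError("eccentricity_mm must be >= 0")
    knots = np.asarray(table, dtype=float)
    ecc, spacing = knots[:, 0], knots[:, 1]
    if eccentricity_mm > ecc[-1]:
        warnings.warn(
            f"eccentricity {eccentricity_mm} mm beyond lookup range; clamped",
            stacklevel=2,
        )
    return float(np.interp(eccentricity_mm, ecc, spacing))


def derive_detection_params(
    eccentricity_mm: float,
    pixel_scale_um: float,
    k: float = 2.0,
    rel_threshold: float = 0.1,
    border_margin_px: int = 2,
    table: tuple[tuple[float, float], ...] = DEFAULT_SPACING_TABLE_UM,
) -> DetectionParams:
    """DetectionParams tuned to the imaged eccentricity.

    The low-pass cutoff period is spacing/k (k=2 passes the mosaic's
    fundamental frequency and suppresses super-Nyquist noise); the minimum
    peak separation is half the expected spacing.
    """
    spacing_um = expected_spacing_um(eccentricity_mm, table)
    spacing_px = spacing_um / pixel_scale_um
    return DetectionParams(
        cutoff_period_px=max(2.0, spacing_px / k),
        min_distance_px=max(2.0, spacing_px / 2.0),
        rel_threshold=rel_threshold,
        border_margin_px=border_margin_px,
    )


def lowpass(image: MosaicImage | np.ndarray, cutoff_period_px: float) -> np.ndarray:
    """Frequency-domain Gaussian low-pass with half-power at the cutoff.

    The filter gain is exp(-f²/(2 s²)) with s chosen so that
    |H(1/cutoff_period)|² = 1/2.  DC gain is 1, so the image mean is
    preserved exactly.
    """
    if cutoff_period_px < 2.0:
        raise ValueError("cutoff_period_px must be >= 2 (Nyquist)")
    pixels = image.pixels if isinstance(image, MosaicImage) else np.asarray(image, float)
    h, w = pixels.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    f2 = fy * fy + fx * fx
    fc = 1.0 / cutoff_period_px
    s2 = fc * fc / np.log(2.0)  # |H(fc)| = 2^{-1/2}
    gain = np.exp(-f2 / (2.0 * s2))
    return np.fft.irfft2(np.fft.rfft2(pixels) * gain, s=(h, w))


def _quadratic_offset(v_minus: float, v0: float, v_plus: float) -> float:
    denom = 2.0 * v0 - v_minus - v_plus
    if denom <= 0:
        return 0.0
    return float(np.clip((v_plus - v_minus) / (2.0 * denom), -0.5, 0.5))


def detect(
    image: MosaicImage,
    params: DetectionParams | None = None,
) -> list[ConeLocation]:
    """Label cone centers in a mosaic image.

    Low-passes the image, finds local maxima above the relative threshold,
    refines each candidate to sub-pixel precision, then accepts candidates
    greedily in descending filtered intensity subject to the minimum
    separation.  Candidates inside the border margin are excluded.  Ties
    in intensity break by scan order (smaller row, then column), making
    the result fully deterministic.
    """
    if params is None:
        params = derive_detection_params(image.eccentricity_mm, image.pixel_scale_um)
    h, w = image.shape
    m = params.border_margin_px
    if h <= 2 * m or w <= 2 * m:
        raise ValueError("image not larger than twice the border margin")

    filtered = lowpass(image, params.cutoff_period_px)
    p1, p99 = np.percentile(filtered, [1.0, 99.0])
    threshold = p1 + params.rel_threshold * (p99 - p1)

    footprint = np.ones((3, 3), bool)
    is_max = (filtered == ndimage.maximum_filter(filtered, footprint=footprint)) & (
        filtered > threshold
    )
    ys, xs = np.nonzero(is_max)
    if len(ys) == 0:
        warnings.warn("no cone candidates above threshold", stacklevel=2)
        return []

    # sub-pixel refinement of every candidate, then greedy NMS on the
    # refined coordinates so the min-distance invariant holds exactly
    cand = []
    for y, x in zip(ys, xs):
        if not (m <= y < h - m and m <= x < w - m):
            continue
        v0 = filtered[y, x]
        if 0 < y < h - 1 and 0 < x < w - 1:
            dy = _quadratic_offset(filtered[y - 1, x], v0, filtered[y + 1, x])
            dx = _quadratic_offset(filtered[y, x - 1], v0, filtered[y, x + 1])
        else:
            dy = dx = 0.0
        cand.append((v0, y, x, x + dx, y + dy))
    if not cand:
        warnings.warn("no cone candidates outside the border margin", stacklevel=2)
        return []

    return greedy_nms(cand, params.min_distance_px)


def greedy_nms(
    candidates: list[tuple[float, int, int, float, float]], min_distance_px: float
) -> list[ConeLocation]:
    """Greedy non-maximum suppression of (value, row, col, x, y) candidates.

    Candidates are taken in descending value; exact ties break by scan
    order (smaller row, then column).  A candidate is accepted iff its
    refined (x, y) lies at least ``min_distance_px`` from every already
    accepted point, so the pairwise min-distance invariant holds on the
    output by construction.
    """
    ordered = sorted(candidates, key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[ConeLocation] = []
    acc_xy: list[tuple[float, float]] = []
    min_d2 = min_distance_px**2
    for v0, _, _, xr, yr in ordered:
        if all((ax - xr) ** 2 + (ay - yr) ** 2 >= min_d2 for ax, ay in acc_xy):
            accepted.append(
                ConeLocation(x_px=float(xr), y_px=float(yr), source="auto",
                             peak_intensity=float(v0))
            )
            acc_xy.append((xr, yr))
    return accepted


def merge_manual(
    auto: list[ConeLocation],
    add: list[ConeLocation] | list[tuple[float, float]] = (),
    remove: list[tuple[float, float]] = (),
    min_distance_px: float = 4.0,
    match_radius_px: float = 2.0,
) -> list[ConeLocation]:
    """Apply manual edits to an automatic labeling.

    Removals first: each removal point deletes its nearest surviving
    location within ``match_radius_px`` (no match → no-op, logged).  Then
    additions are appended with source="manual"; an addition closer than
    ``min_distance_px`` to any surviving location is rejected and logged.
    """
    out = list(auto)
    for rx, ry in remove:
        if not out:
            logger.info("remove (%.1f, %.1f): no locations left", rx, ry)
            continue
        d2 = [(c.x_px - rx) ** 2 + (c.y_px - ry) ** 2 for c in out]
        i = int(np.argmin(d2))
        if d2[i] <= match_radius_px**2:
            out.pop(i)
        else:
            logger.info("remove (%.1f, %.1f): no auto point within radius", rx, ry)

    min_d2 = min_distance_px**2
    for a in add:
        ax, ay = (a.x_px, a.y_px) if isinstance(a, ConeLocation) else (a[0], a[1])
        if any((c.x_px - ax) ** 2 + (c.y_px - ay) ** 2 < min_d2 for c in out):
            logger.info(
                "add (%.1f, %.1f): rejected, violates min distance %.2f px",
                ax, ay, min_distance_px,
            )
            continue
        out.append(ConeLocation(x_px=float(ax), y_px=float(ay), source="manual"))
    return out


def match_points(
    detected: np.ndarray | list,
    truth: np.ndarray | list,
    radius_px: float = 2.0,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected points to truth points.

    Points are (x, y) pairs.  Pairs are matched nearest-first within
    ``radius_px``.  Returns (true_positives, false_positives,
    false_negatives) for precision/recall scoring against generator truth.
    """
    det = np.atleast_2d(np.asarray([(p.x_px, p.y_px) if hasattr(p, "x_px") else p
                                    for p in detected], dtype=float))
    tru = np.atleast_2d(np.asarray([(p.x_px, p.y_px) if hasattr(p, "x_px") else p
                                    for p in truth], dtype=float))
    if det.size == 0:
        return 0, 0, len(tru)
    if tru.size == 0:
        return 0, len(det), 0
    tree = cKDTree(tru)
    pairs = tree.query_ball_point(det, r=radius_px)
    cand = [
        (float(np.hypot(*(det[i] - tru[j]))), i, j)
        for i, js in enumerate(pairs)
        for j in js
    ]
    cand.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for _, i, j in cand:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    return tp, len(det) - tp, len(tru) - tp


def detection_scores(detected, truth, radius_px: float = 2.0) -> dict:
    """Precision, recall and F1 of a labeling against generator truth."""
    tp, fp, fn = match_points(detected, truth, radius_px)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
            "recall": recall, "f1": f1}


# ---------------------------------------------------------------------------
# CSV I/O (0-based, pixel-center coordinates; stated in the header comment)

_CONE_COLUMNS = ("x_px", "y_px", "source", "peak_intensity")


def write_cones(
    cones: list[ConeLocation], path: str | Path, params: DetectionParams | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# cone locations; coordinates 0-based, pixel-center\n")
        if params is not None:
            fh.write(
                f"# cutoff_period_px={params.cutoff_period_px} "
                f"min_distance_px={params.min_distance_px} "
                f"rel_threshold={params.rel_threshold} "
                f"border_margin_px={params.border_margin_px}\n"
            )
        fh.write(",".join(_CONE_COLUMNS) + "\n")
        for c in cones:
            fh.write(f"{c.x_px:.4f},{c.y_px:.4f},{c.source},{c.peak_intensity:.6g}\n")
    return path


def read_cones(path: str | Path) -> list[ConeLocation]:
    df = pd.read_csv(path, comment="#")
    return [
        ConeLocation(
            x_px=float(r.x_px),
            y_px=float(r.y_px),
            source=str(r.source),
            peak_intensity=float(r.peak_intensity),
        )
        for r in df.itertuples()
    ]


def read_points_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read a manual-edit point list (columns x_px, y_px)."""
    df = pd.read_csv(path, comment="#")
    return [(float(x), float(y)) for x, y in zip(df["x_px"], df["y_px"])]
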