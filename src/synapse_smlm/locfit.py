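"""Frame stack -> localization table.

Temporal-median background subtraction, robust-threshold spot detection,
center-of-mass sub-pixel localization, and intensity/width/asymmetry
filtering.

Coordinate convention: 0-based pixel indices; pixel i spans [i, i+1) pixel
units, so its center is at i + 0.5; nm coordinates are pixel units times the
pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class QCFilter:
    """Quality cutoffs; the defaults are pipeline choices and must be logged."""

    min_intensity: float = 200.0
    max_width_nm: float = 250.0
    max_asymmetry: float = 1.5

    def __post_init__(self) -> None:
        if self.min_intensity <= 0 or self.max_width_nm <= 0:
            raise ValueError("cutoffs must be positive")
        if self.max_asymmetry < 1:
            raise ValueError("max_asymmetry must be >= 1")


def temporal_median_background(
    stack: np.ndarray, window: int = 101, clip_negative: bool = False
) -> np.ndarray:
    """Subtract a running per-pixel temporal median from a (T, H, W) stack.

    The window is centered on each frame and truncated (shrinks) at the ends
    of the stack, so no frames are discarded. Output is float; negative
    residuals are kept unless ``clip_negative``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    n = stack.shape[0]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3 or window > n:
        raise ValueError(f"window must be in [3, {n}]")
    half = (window - 1) // 2

    out = np.empty(stack.shape, dtype=np.float64)
    med = None
    lo_prev = hi_prev = -1
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        if (lo, hi) != (lo_prev, hi_prev):
            med = np.median(stack[lo:hi], axis=0)
            lo_prev, hi_prev = lo, hi
        out[t] = stack[t] - med
    if clip_negative:
        np.clip(out, 0.0, None, out=out)
    return out


def robust_sd(frame: np.ndarray) -> float:
    """1.4826 x median absolute deviation (Gaussian-consistent scale)."""
    med = np.median(frame)
    return 1.4826 * float(np.median(np.abs(frame - med)))


@dataclass(frozen=True)
class SpotCandidate:
    """A detected connected component: bounding-box slice plus pixel values."""

    y0: int
    x0: int
    values: np.ndarray  # 2D crop of the background-corrected frame


def detect_spots(frame: np.ndarray, threshold_k: float = 5.0) -> list[SpotCandidate]:
    """Threshold at ``threshold_k`` x robust noise sd, group pixels into
    8-connected components, pad each bounding box by one pixel, and drop
    components touching the image border."""
    frame = np.asarray(frame, dtype=float)
    sd = robust_sd(frame)
    if sd <= 0:
        # noiseless frame: any strictly positive pixel is signal
        mask = frame > 0
    else:
        mask = frame > threshold_k * sd
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    h, w = frame.shape
    out: list[SpotCandidate] = []
    for sl_y, sl_x in ndimage.find_objects(labels):
        if sl_y.start == 0 or sl_x.start == 0 or sl_y.stop == h or sl_x.stop == w:
            continue
        y0, y1 = sl_y.start - 1, min(sl_y.stop + 1, h)
        x0, x1 = sl_x.start - 1, min(sl_x.stop + 1, w)
        out.append(SpotCandidate(y0=y0, x0=x0, values=frame[y0:y1, x0:x1].copy()))
    return out


def localize_com(
    cand: SpotCandidate, pixel_size_nm: float = 132.0
) -> dict | None:
    """Center-of-mass localization of one candidate region.

    Returns a record dict (x_nm, y_nm, intensity, width_nm, asymmetry) or
    None when the region's total (non-negative) intensity is not positive.
    Width is the RMS spot radius sqrt((l1 + l2) / 2) of the intensity-weighted
    covariance, asymmetry is sqrt(lmax / lmin); a single-pixel region has
    asymmetry 1 by definition.
    """
    vals = np.clip(cand.values, 0.0, None)
    total = float(vals.sum())
    if total <= 0:
        return None
    ny, nx = vals.shape
    ys = cand.y0 + np.arange(ny) + 0.5
    xs = cand.x0 + np.arange(nx) + 0.5
    wy = vals.sum(axis=1) / total
    wx = vals.sum(axis=0) / total
    cy = float(ys @ wy)
    cx = float(xs @ wx)

    dy = ys - cy
    dx = xs - cx
    cov_yy = float((dy**2) @ wy)
    cov_xx = float((dx**2) @ wx)
    cov_xy = float(dy @ (vals / total) @ dx)
    cov = np.array([[cov_xx, cov_xy], [cov_xy, cov_yy]])
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    width_px = float(np.sqrt(lam.mean()))
    if lam[1] <= 0:
        asym = 1.0
    elif lam[0] <= 0:
        asym = np.inf
    else:
        asym = float(np.sqrt(lam[1] / lam[0]))
    return {
        "x_nm": cx * pixel_size_nm,
        "y_nm": cy * pixel_size_nm,
        "intensity": total,
        "width_nm": width_px * pixel_size_nm,
        "asymmetry": asym,
    }


def localize_stack(
    corrected: np.ndarray,
    pixel_size_nm: float = 132.0,
    threshold_k: float = 5.0,
    channel: int = 1,
) -> pd.DataFrame:
    """Run detection + COM localization on every frame of a
    background-corrected stack; returns an unfiltered localization table."""
    records = []
    for t, frame in enumerate(corrected):
        for cand in detect_spots(frame, threshold_k=threshold_k):
            rec = localize_com(cand, pixel_size_nm=pixel_size_nm)
            if rec is not None:
                rec["frame"] = t
                rec["channel"] = channel
                records.append(rec)
    cols = ["frame", "x_nm", "y_nm", "intensity", "width_nm", "asymmetry", "channel"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(records)[cols]


def filter_localizations(
    table: pd.DataFrame, qc: QCFilter = QCFilter()
) -> tuple[pd.DataFrame, dict]:
    """Keep records passing all three QC criteria; preserves row order.

    Returns (filtered table, report) where the report counts how many records
    each criterion rejected (a record can fail several)."""
    if len(table) == 0:
        report = {
            "n_in": 0, "n_kept": 0,
            "fail_intensity": 0, "fail_width": 0, "fail_asymmetry": 0,
            "qc": asdict(qc),
        }
        return table.copy(), report
    ok_i = table["intensity"].to_numpy() >= qc.min_intensity
    ok_w = table["width_nm"].to_numpy() <= qc.max_width_nm
    ok_a = table["asymmetry"].to_numpy() <= qc.max_asymmetry
    keep = ok_i & ok_w & ok_a
    report = {
        "n_in": int(len(table)),
        "n_kept": int(keep.sum()),
        "fail_intensity": int((~ok_i).sum()),
        "fail_width": int((~ok_w).sum()),
        "fail_asymmetry": int((~ok_a).sum()),
        "qc": asdict(qc),
    }
    return table.loc[keep].reset_index(drop=True), report


def process_stack(
    stack: np.ndarray,
    pixel_size_nm: float = 132.0,
    window: int = 101,
    threshold_k: float = 5.0,
    qc: QCFilter = QCFilter(),
    channel: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Full locfit chain: median background -> detect -> COM -> QC filter."""
    corrected = temporal_median_background(stack, window=window)
    table = localize_stack(
        corrected, pixel_size_nm=pixel_size_nm, threshold_k=threshold_k, channel=channel
    )
    return filter_localizations(table, qc)
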