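"""Two-channel registration and drift correction.

Channel 2 is mapped onto channel 1 by an affine (or second-order polynomial)
transform fitted to fiducial beads by least squares. Drift is estimated by
redundant cross-correlation (RCC): all pairwise shifts between temporal
segments of the localization table are measured on 2D histograms and combined
by least squares, anchored at the first segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import fft2, ifft2
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# channel transform
# ---------------------------------------------------------------------------


def _design_matrix(points: np.ndarray, kind: str) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    if kind == "affine":
        return np.stack([x, y, np.ones_like(x)], axis=1)
    if kind == "polynomial":
        return np.stack([np.ones_like(x), x, y, x * x, x * y, y * y], axis=1)
    raise ValueError(f"unknown transform kind {kind!r}")


@dataclass(frozen=True)
class TransformModel:
    """(x, y) -> (x', y') map in nm. Affine stores 6 parameters (rows of the
    2x3 matrix [a b c; d e f]), polynomial-2nd-order stores 12."""

    kind: str
    parameters: np.ndarray
    fit_rms_nm: float = 0.0
    n_beads: int = 0

    def __post_init__(self) -> None:
        params = np.asarray(self.parameters, dtype=float)
        object.__setattr__(self, "parameters", params)
        n_expected = 6 if self.kind == "affine" else 12
        if self.kind not in ("affine", "polynomial"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if params.size != n_expected:
            raise ValueError(f"{self.kind} transform needs {n_expected} parameters")
        if self.fit_rms_nm < 0:
            raise ValueError("fit_rms_nm must be >= 0")

    @staticmethod
    def identity() -> "TransformModel":
        return TransformModel("affine", np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0]))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        A = _design_matrix(pts, self.kind)
        coef = self.parameters.reshape(2, -1)
        return A @ coef.T

    def inverse(self) -> "TransformModel":
        if self.kind != "affine":
            raise ValueError("only affine transforms have a closed-form inverse")
        a, b, c, d, e, f = self.parameters
        M = np.array([[a, b], [d, e]])
        Minv = np.linalg.inv(M)
        tinv = -Minv @ np.array([c, f])
        return TransformModel(
            "affine",
            np.array([Minv[0, 0], Minv[0, 1], tinv[0], Minv[1, 0], Minv[1, 1], tinv[1]]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "parameters": self.parameters.tolist(),
                    "fit_rms_nm": self.fit_rms_nm,
                    "n_beads": self.n_beads,
                },
                fh,
                indent=2,
            )

    @staticmethod
    def from_json(path) -> "TransformModel":
        with open(path) as fh:
            d = json.load(fh)
        return TransformModel(d["kind"], np.asarray(d["parameters"]), d["fit_rms_nm"], d["n_beads"])


def match_beads(
    beads1: np.ndarray, beads2: np.ndarray, gate_nm: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbor bead pairing within a distance gate."""
    b1 = np.atleast_2d(np.asarray(beads1, dtype=float))
    b2 = np.atleast_2d(np.asarray(beads2, dtype=float))
    t1, t2 = cKDTree(b1), cKDTree(b2)
    d12, j12 = t2.query(b1, distance_upper_bound=gate_nm)
    _, j21 = t1.query(b2, distance_upper_bound=gate_nm)
    pairs = [
        (i, j)
        for i, (d, j) in enumerate(zip(d12, j12))
        if np.isfinite(d) and j < len(b2) and j21[j] == i
    ]
    if not pairs:
        return np.empty((0, 2)), np.empty((0, 2))
    idx1, idx2 = zip(*pairs)
    return b1[list(idx1)], b2[list(idx2)]


def fit_channel_transform(
    beads_ch1: np.ndarray,
    beads_ch2: np.ndarray,
    kind: str = "affine",
    matched: bool | None = None,
    gate_nm: float = 500.0,
) -> TransformModel:
    """Least-squares fit of T with T(beads_ch2) ~ beads_ch1.

    If the lists are not already index-matched (``matched=False``, or lengths
    differ), beads are paired by mutual nearest neighbor within ``gate_nm``.
    """
    b1 = np.atleast_2d(np.asarray(beads_ch1, dtype=float))
    b2 = np.atleast_2d(np.asarray(beads_ch2, dtype=float))
    if matched is None:
        matched = len(b1) == len(b2)
    if not matched:
        b1, b2 = match_beads(b1, b2, gate_nm=gate_nm)

    n_min = 3 if kind == "affine" else 6
    if len(b1) < n_min:
        raise ValueError(f"too few matched beads: {len(b1)} < {n_min} required for {kind}")

    A = _design_matrix(b2, kind)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("degenerate bead layout (collinear or coincident beads)")
    coef, *_ = np.linalg.lstsq(A, b1, rcond=None)
    resid = A @ coef - b1
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return TransformModel(kind, coef.T.ravel(), fit_rms_nm=rms, n_beads=len(b1))


def apply_transform(table: pd.DataFrame, t: TransformModel) -> pd.DataFrame:
    """Map a localization table's coordinates through ``t``; every other
    column is untouched and the row count is preserved."""
    out = table.copy()
    if len(out):
        xy = t(out[["x_nm", "y_nm"]].to_numpy())
        out["x_nm"] = xy[:, 0]
        out["y_nm"] = xy[:, 1]
    return out


# ---------------------------------------------------------------------------
# drift (RCC)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftTrace:
    """Per-segment xy drift in nm, linearly interpolated between segment
    center frames (linear extrapolation outside). The first segment is the
    (0, 0) reference."""

    segment_centers: np.ndarray  # (k,) frame indices (float)
    shifts_nm: np.ndarray  # (k, 2)

    def __post_init__(self) -> None:
        c = np.asarray(self.segment_centers, dtype=float)
        s = np.asarray(self.shifts_nm, dtype=float)
        object.__setattr__(self, "segment_centers", c)
        object.__setattr__(self, "shifts_nm", s)
        if not np.all(np.isfinite(s)):
            raise ValueError("shifts must be finite")
        if len(c) != len(s):
            raise ValueError("centers and shifts length mismatch")

    def shift_at(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames, dtype=float)
        c, s = self.segment_centers, self.shifts_nm
        if len(c) == 1:
            return np.tile(s[0], (frames.size, 1)).reshape(frames.shape + (2,))
        out = np.empty(frames.shape + (2,))
        for ax in (0, 1):
            out[..., ax] = np.interp(frames, c, s[:, ax])
            # linear extrapolation beyond the outermost segment centers
            lo = frames < c[0]
            hi = frames > c[-1]
            if lo.any():
                slope = (s[1, ax] - s[0, ax]) / (c[1] - c[0])
                out[lo, ax] = s[0, ax] + slope * (frames[lo] - c[0])
            if hi.any():
                slope = (s[-1, ax] - s[-2, ax]) / (c[-1] - c[-2])
                out[hi, ax] = s[-1, ax] + slope * (frames[hi] - c[-1])
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"segment_centers": self.segment_centers.tolist(), "shifts_nm": self.shifts_nm.tolist()},
                fh,
                indent=2,
            )

    @staticmethod
    def from_json(path) -> "DriftTrace":
        with open(path) as fh:
            d = json.load(fh)
        return DriftTrace(np.asarray(d["segment_centers"]), np.asarray(d["shifts_nm"]))


def _histogram_image(
    x: np.ndarray, y: np.ndarray, bounds: tuple, bin_nm: float
) -> np.ndarray:
    x0, x1, y0, y1 = bounds
    nx = int(np.ceil((x1 - x0) / bin_nm)) + 1
    ny = int(np.ceil((y1 - y0) / bin_nm)) + 1
    ix = np.floor((x - x0) / bin_nm).astype(int)
    iy = np.floor((y - y0) / bin_nm).astype(int)
    img = np.zeros((ny, nx))
    np.add.at(img, (iy, ix), 1.0)
    return img


def _xcorr_shift(img_a: np.ndarray, img_b: np.ndarray) -> tuple[float, float]:
    """Shift (dx, dy) in bins that maps img_b onto img_a, from the argmax of
    the circular cross-correlation with 3-point parabolic refinement."""
    shape = img_a.shape
    corr = np.real(ifft2(fft2(img_a) * np.conj(fft2(img_b))))
    iy, ix = np.unravel_index(np.argmax(corr), shape)

    def parabolic(cm: float, c0: float, cp: float) -> float:
        denom = cm - 2.0 * c0 + cp
        if denom == 0:
            return 0.0
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))

    dx = parabolic(corr[iy, (ix - 1) % shape[1]], corr[iy, ix], corr[iy, (ix + 1) % shape[1]])
    dy = parabolic(corr[(iy - 1) % shape[0], ix], corr[iy, ix], corr[(iy + 1) % shape[0], ix])
    sx = ix + dx
    sy = iy + dy
    if sx > shape[1] / 2:
        sx -= shape[1]
    if sy > shape[0] / 2:
        sy -= shape[0]
    return sx, sy


def estimate_drift_rcc(
    table: pd.DataFrame,
    n_segments: int = 10,
    bin_nm: float = 10.0,
    min_locs_per_segment: int = 100,
) -> DriftTrace:
    """Redundant cross-correlation drift estimation on a localization table.

    Splits the frame range into equal temporal segments, renders each as a
    2D histogram at ``bin_nm``, measures all pairwise shifts, and solves the
    overdetermined system d_j - d_i = shift_ij by least squares with
    segment 1 anchored at (0, 0).
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    frames = table["frame"].to_numpy()
    f0, f1 = frames.min(), frames.max() + 1
    edges = np.linspace(f0, f1, n_segments + 1)
    seg_idx = np.clip(np.searchsorted(edges, frames, side="right") - 1, 0, n_segments - 1)

    x = table["x_nm"].to_numpy()
    y = table["y_nm"].to_numpy()
    pad = bin_nm  # margin so drifted positions stay in range
    bounds = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)

    imgs, centers = [], []
    for s in range(n_segments):
        m = seg_idx == s
        n_in = int(m.sum())
        if n_in == 0:
            raise ValueError(f"segment {s} contains no localizations")
        if n_in < min_locs_per_segment:
            import warnings

            warnings.warn(f"segment {s} has only {n_in} localizations", stacklevel=2)
        imgs.append(_histogram_image(x[m], y[m], bounds, bin_nm))
        centers.append(0.5 * (edges[s] + edges[s + 1]))

    # all pairwise shifts d_j - d_i
    pairwise = []
    for i in range(n_segments):
        for j in range(i + 1, n_segments):
            sx, sy = _xcorr_shift(imgs[j], imgs[i])  # maps segment i onto j
            pairwise.append((i, j, sx * bin_nm, sy * bin_nm))

    shifts = solve_pairwise_shifts(pairwise, n_segments)
    return DriftTrace(np.asarray(centers), shifts)


def solve_pairwise_shifts(pairwise, n_segments: int) -> np.ndarray:
    """Least-squares solution of d_j - d_i = s_ij for per-segment shifts,
    anchored at segment 0 = (0, 0). ``pairwise`` holds (i, j, sx_nm, sy_nm)
    tuples; a self-consistent set of pairwise shifts is reproduced exactly."""
    rows, rhs = [], []
    for i, j, sx, sy in pairwise:
        row = np.zeros(n_segments)
        row[j], row[i] = 1.0, -1.0
        rows.append(row)
        rhs.append((sx, sy))
    anchor = np.zeros(n_segments)
    anchor[0] = 1.0
    A = np.vstack([np.asarray(rows), anchor])
    b = np.vstack([np.asarray(rhs), [0.0, 0.0]])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol - sol[0]


def correct_drift(table: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Subtract the interpolated per-frame drift from each record."""
    out = table.copy()
    if len(out):
        shift = trace.shift_at(out["frame"].to_numpy())
        out["x_nm"] = out["x_nm"].to_numpy() - shift[:, 0]
        out["y_nm"] = out["y_nm"].to_numpy() - shift[:, 1]
    return out
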