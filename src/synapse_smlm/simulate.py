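"""Synthetic two-color synapse data: ground-truth geometry, immunolabel
sampling, fast-path localization tables, and full blinking-emitter movies.

All randomness is driven by explicit integer seeds; there is no module-level
RNG state. Coordinates are in nm, the optical axis is z, and images are
projections onto the xy plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

TABLE_COLUMNS = ["frame", "x_nm", "y_nm", "intensity", "width_nm", "asymmetry", "channel"]

TRUTH_COLUMNS = [
    "synapse_id",
    "channel",
    "true_com_x_nm",
    "true_com_y_nm",
    "axis_x",
    "axis_y",
    "axis_z",
    "separation_nm",
]


# ---------------------------------------------------------------------------
# shape and geometry types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeSpec:
    """Label-population support.

    ``bar``: box of length x width (in the cleft plane) x thickness (along
    the transsynaptic axis). ``disc``: cylinder of given radius and thickness.
    ``cloud``: isotropic Gaussian of the given sd.
    """

    kind: str  # "bar" | "disc" | "cloud"
    length_nm: float = 0.0
    width_nm: float = 0.0
    thickness_nm: float = 0.0
    radius_nm: float = 0.0
    sd_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("bar", "disc", "cloud"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind == "bar" and min(self.length_nm, self.width_nm, self.thickness_nm) <= 0:
            raise ValueError("bar dimensions must be > 0")
        if self.kind == "disc" and min(self.radius_nm, self.thickness_nm) <= 0:
            raise ValueError("disc dimensions must be > 0")
        if self.kind == "cloud" and self.sd_nm < 0:
            raise ValueError("cloud sd must be >= 0")

    @property
    def max_extent_nm(self) -> float:
        if self.kind == "bar":
            return max(self.length_nm, self.width_nm, self.thickness_nm)
        if self.kind == "disc":
            return max(2.0 * self.radius_nm, self.thickness_nm)
        return 4.0 * self.sd_nm

    @staticmethod
    def bar(length_nm: float, width_nm: float, thickness_nm: float) -> "ShapeSpec":
        return ShapeSpec("bar", length_nm=length_nm, width_nm=width_nm, thickness_nm=thickness_nm)

    @staticmethod
    def disc(radius_nm: float, thickness_nm: float) -> "ShapeSpec":
        return ShapeSpec("disc", radius_nm=radius_nm, thickness_nm=thickness_nm)

    @staticmethod
    def cloud(sd_nm: float) -> "ShapeSpec":
        return ShapeSpec("cloud", sd_nm=sd_nm)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "bar":
            d.update(length_nm=self.length_nm, width_nm=self.width_nm, thickness_nm=self.thickness_nm)
        elif self.kind == "disc":
            d.update(radius_nm=self.radius_nm, thickness_nm=self.thickness_nm)
        else:
            d.update(sd_nm=self.sd_nm)
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "ShapeSpec":
        return ShapeSpec(**dict(d))


# Default population shapes: thin bars for scaffold proteins, an isotropic
# cloud for the vesicle-associated population.
DEFAULT_SHAPE_POST = ShapeSpec.bar(300.0, 300.0, 40.0)
DEFAULT_SHAPE_PRE = ShapeSpec.bar(300.0, 300.0, 60.0)
DEFAULT_SHAPE_VESICLE = ShapeSpec.cloud(120.0)


@dataclass(frozen=True)
class SynapseGroundTruth:
    """One simulated synapse: two label populations whose centers sit
    ``separation_nm`` apart along a 3D unit ``axis`` through ``center``."""

    center: np.ndarray  # (3,) nm
    axis: np.ndarray  # (3,) unit vector
    separation_nm: float
    shape_a: ShapeSpec
    shape_b: ShapeSpec
    n_labels_a: int
    n_labels_b: int
    linkage_sd_nm: float = 0.0
    synapse_id: int = 0

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "axis", axis)
        if center.shape != (3,) or axis.shape != (3,):
            raise ValueError("center and axis must be 3-vectors")
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("axis must have unit norm (within 1e-9)")
        if self.separation_nm < 0:
            raise ValueError("separation_nm must be >= 0")
        if self.n_labels_a < 1 or self.n_labels_b < 1:
            raise ValueError("label counts must be >= 1")
        if self.linkage_sd_nm < 0:
            raise ValueError("linkage_sd_nm must be >= 0")

    @property
    def com_a(self) -> np.ndarray:
        return self.center - 0.5 * self.separation_nm * self.axis

    @property
    def com_b(self) -> np.ndarray:
        return self.center + 0.5 * self.separation_nm * self.axis


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters shared by every synapse of a simulated population."""

    separation_nm: float = 100.0
    shape_a: ShapeSpec = DEFAULT_SHAPE_PRE
    shape_b: ShapeSpec = DEFAULT_SHAPE_POST
    n_labels_a: int = 50
    n_labels_b: int = 50
    linkage_sd_nm: float = 0.0
    field_size_nm: tuple[float, float] = (20000.0, 20000.0)
    z_nm: float = 0.0
    fixed_axis: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.separation_nm < 0:
            raise ValueError("separation_nm must be >= 0")
        if self.n_labels_a < 1 or self.n_labels_b < 1:
            raise ValueError("label counts must be >= 1")


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera geometry and noise parameters."""

    pixel_size_nm: float = 132.0
    frame_rate_hz: float = 46.0
    n_frames_per_channel: int = 30000
    width_px: int = 128
    height_px: int = 128
    em_gain: float = 1.0
    read_noise_e: float = 0.0
    background_rate: float = 0.0  # photons / pixel / frame
    psf_sd_nm: float = 150.0
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.n_frames_per_channel < 1:
            raise ValueError("n_frames_per_channel must be >= 1")
        if self.psf_sd_nm <= 0:
            raise ValueError("psf_sd_nm must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


@dataclass(frozen=True)
class EmitterSet:
    """Blinking point emitters for the movie forward model."""

    positions_nm: np.ndarray  # (n, 2) or (n, 3); z is ignored in rendering
    photon_rate: float = 500.0  # photons / frame while ON
    k_on: float = 0.002
    k_off: float = 0.5
    bleach_prob: float = 0.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions_nm, dtype=float))
        object.__setattr__(self, "positions_nm", pos)
        for name in ("k_on", "k_off", "bleach_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.photon_rate <= 0:
            raise ValueError("photon_rate must be > 0")


@dataclass(frozen=True)
class DriftProgram:
    """Per-frame xy drift in nm. Either a linear slope or a piecewise-linear
    table of (frame, dx, dy) knots; drift at frame 0 is always (0, 0)."""

    slope_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    table: np.ndarray | None = None  # (k, 3): frame, dx_nm, dy_nm

    def shift_at(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames, dtype=float)
        if self.table is not None:
            tab = np.asarray(self.table, dtype=float)
            dx = np.interp(frames, tab[:, 0], tab[:, 1])
            dy = np.interp(frames, tab[:, 0], tab[:, 2])
            return np.stack([dx, dy], axis=-1)
        sx, sy = self.slope_nm_per_frame
        return np.stack([frames * sx, frames * sy], axis=-1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _unit_hemisphere_axes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Axes uniform on the unit hemisphere (z >= 0)."""
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1)
    # resample the (measure-zero) degenerate draws
    while np.any(norms < 1e-12):
        bad = norms < 1e-12
        v[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    v /= norms[:, None]
    v[:, 2] = np.abs(v[:, 2])
    return v


def make_synapse_population(
    config: PopulationConfig, n_synapses: int, rng_seed: int
) -> list[SynapseGroundTruth]:
    """Place ``n_synapses`` on a jittered grid with axes drawn uniformly on
    the hemisphere (or a fixed axis if the config supplies one)."""
    if n_synapses < 1:
        raise ValueError("n_synapses must be >= 1")
    rng = np.random.default_rng(rng_seed)

    max_dim = max(config.shape_a.max_extent_nm, config.shape_b.max_extent_nm, config.separation_nm)
    min_spacing = 4.0 * max_dim
    fx, fy = config.field_size_nm
    k = math.ceil(math.sqrt(n_synapses))
    cell_x, cell_y = fx / k, fy / k
    if cell_x < min_spacing or cell_y < min_spacing:
        need = k * min_spacing
        raise ValueError(
            f"field size {config.field_size_nm} nm too small for {n_synapses} synapses "
            f"at minimum spacing {min_spacing:.0f} nm; need at least {need:.0f} nm per side"
        )

    if config.fixed_axis is not None:
        ax = np.asarray(config.fixed_axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        axes = np.tile(ax, (n_synapses, 1))
    else:
        axes = _unit_hemisphere_axes(n_synapses, rng)

    jit_x = (cell_x - min_spacing) / 2.0
    jit_y = (cell_y - min_spacing) / 2.0
    synapses: list[SynapseGroundTruth] = []
    for i in range(n_synapses):
        gx, gy = i % k, i // k
        cx = (gx + 0.5) * cell_x + rng.uniform(-jit_x, jit_x)
        cy = (gy + 0.5) * cell_y + rng.uniform(-jit_y, jit_y)
        synapses.append(
            SynapseGroundTruth(
                center=np.array([cx, cy, config.z_nm]),
                axis=axes[i],
                separation_nm=config.separation_nm,
                shape_a=config.shape_a,
                shape_b=config.shape_b,
                n_labels_a=config.n_labels_a,
                n_labels_b=config.n_labels_b,
                linkage_sd_nm=config.linkage_sd_nm,
                synapse_id=i,
            )
        )
    return synapses


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``axis``."""
    helper = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _sample_shape(shape: ShapeSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample points inside a shape in its local frame: columns are
    (in-plane 1, in-plane 2, along-axis)."""
    if shape.kind == "bar":
        u = rng.uniform(-0.5, 0.5, size=(n, 3))
        return u * np.array([shape.length_nm, shape.width_nm, shape.thickness_nm])
    if shape.kind == "disc":
        r = shape.radius_nm * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        z = rng.uniform(-0.5, 0.5, size=n) * shape.thickness_nm
        return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return rng.normal(scale=shape.sd_nm, size=(n, 3)) if shape.sd_nm > 0 else np.zeros((n, 3))


def sample_labels(
    truth: SynapseGroundTruth, rng_seed: int
) -> dict[int, np.ndarray]:
    """Draw labeled fluorophore positions (3D, nm) for both populations.

    Channel 1 carries population A, channel 2 population B. Each label is
    displaced by an isotropic Gaussian of sd ``linkage_sd_nm`` (antibody
    linkage error). The expected per-channel COM equals the population COM.
    """
    rng = np.random.default_rng(rng_seed)
    e1, e2 = _orthonormal_frame(truth.axis)
    basis = np.stack([e1, e2, truth.axis], axis=1)  # local -> world

    out: dict[int, np.ndarray] = {}
    for ch, (shape, n, com) in {
        1: (truth.shape_a, truth.n_labels_a, truth.com_a),
        2: (truth.shape_b, truth.n_labels_b, truth.com_b),
    }.items():
        local = _sample_shape(shape, n, rng)
        world = local @ basis.T + com
        if truth.linkage_sd_nm > 0:
            world = world + rng.normal(scale=truth.linkage_sd_nm, size=world.shape)
        out[ch] = world
    return out


@dataclass(frozen=True)
class IntensityModel:
    """Lognormal single-molecule photon counts (log-photon units)."""

    log_mean: float = 6.0
    log_sd: float = 0.5

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.log_mean, self.log_sd, size=n)


def emit_localization_table(
    labels: Mapping[int, np.ndarray],
    loc_precision_sd_nm: float,
    mean_locs_per_label: float,
    rng_seed: int,
    n_frames: int = 30000,
    intensity_model: IntensityModel = IntensityModel(),
) -> pd.DataFrame:
    """Fast path: turn 3D label positions directly into a localization table,
    bypassing movie rendering.

    Projects to 2D by dropping z, draws Poisson(mean_locs_per_label)
    localization events per label, each jittered by the localization
    precision. The ``label_id`` column maps every record back to its
    generating label (sidecar round-trip).
    """
    if loc_precision_sd_nm < 0:
        raise ValueError("loc_precision_sd_nm must be >= 0")
    rng = np.random.default_rng(rng_seed)
    parts = []
    for ch in sorted(labels):
        pos = np.atleast_2d(np.asarray(labels[ch], dtype=float))[:, :2]
        if mean_locs_per_label == round(mean_locs_per_label) and loc_precision_sd_nm == 0:
            counts = np.full(len(pos), int(mean_locs_per_label))
        else:
            counts = rng.poisson(mean_locs_per_label, size=len(pos))
        total = int(counts.sum())
        if total == 0:
            continue
        xy = np.repeat(pos, counts, axis=0)
        label_id = np.repeat(np.arange(len(pos)), counts)
        if loc_precision_sd_nm > 0:
            xy = xy + rng.normal(scale=loc_precision_sd_nm, size=xy.shape)
        widths = np.clip(rng.normal(150.0, 15.0, size=total), 100.0, 220.0)
        asym = 1.0 + np.abs(rng.normal(0.0, 0.1, size=total)).clip(max=0.45)
        parts.append(
            pd.DataFrame(
                {
                    "frame": rng.integers(0, n_frames, size=total),
                    "x_nm": xy[:, 0],
                    "y_nm": xy[:, 1],
                    "intensity": intensity_model.draw(total, rng),
                    "width_nm": widths,
                    "asymmetry": asym,
                    "channel": ch,
                    "label_id": label_id,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TABLE_COLUMNS + ["label_id"])
    return pd.concat(parts, ignore_index=True)


def population_localization_table(
    synapses: Sequence[SynapseGroundTruth],
    loc_precision_sd_nm: float,
    mean_locs_per_label: float,
    rng_seed: int,
    n_frames: int = 30000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast-path tables for a whole population, plus the ground-truth sidecar
    (one row per synapse and channel, schema ``TRUTH_COLUMNS``)."""
    rng = np.random.default_rng(rng_seed)
    tables, truth_rows = [], []
    for syn in synapses:
        labels = sample_labels(syn, int(rng.integers(0, 2**63 - 1)))
        tab = emit_localization_table(
            labels, loc_precision_sd_nm, mean_locs_per_label,
            int(rng.integers(0, 2**63 - 1)), n_frames=n_frames,
        )
        tab["synapse_id"] = syn.synapse_id
        tables.append(tab)
        for ch, com in ((1, syn.com_a), (2, syn.com_b)):
            truth_rows.append(
                {
                    "synapse_id": syn.synapse_id,
                    "channel": ch,
                    "true_com_x_nm": com[0],
                    "true_com_y_nm": com[1],
                    "axis_x": syn.axis[0],
                    "axis_y": syn.axis[1],
                    "axis_z": syn.axis[2],
                    "separation_nm": syn.separation_nm,
                }
            )
    table = pd.concat(tables, ignore_index=True)
    return table, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def inject_drift(table: pd.DataFrame, drift: DriftProgram) -> pd.DataFrame:
    """Add per-frame drift to a localization table (simulation side; the
    register module subtracts)."""
    out = table.copy()
    shift = drift.shift_at(out["frame"].to_numpy())
    out["x_nm"] = out["x_nm"].to_numpy() + shift[:, 0]
    out["y_nm"] = out["y_nm"].to_numpy() + shift[:, 1]
    return out


# ---------------------------------------------------------------------------
# movie forward model
# ---------------------------------------------------------------------------


def _render_emitters(
    frame: np.ndarray,
    xy_px: np.ndarray,
    photons: np.ndarray,
    psf_sd_px: float,
) -> None:
    """Accumulate integrated-Gaussian PSFs into ``frame`` in place.

    Pixel i integrates the Gaussian over [i, i+1); total flux equals
    ``photons`` up to the tail truncated at +-4 sd outside the patch.
    """
    h, w = frame.shape
    half = int(np.ceil(4.0 * psf_sd_px)) + 1
    s = psf_sd_px * math.sqrt(2.0)
    for (x, y), p in zip(xy_px, photons):
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        ex = np.arange(x0c, x1c + 1, dtype=float)
        ey = np.arange(y0c, y1c + 1, dtype=float)
        fx = 0.5 * (erf((ex - x) / s))
        fy = 0.5 * (erf((ey - y) / s))
        frame[y0c:y1c, x0c:x1c] += p * np.outer(np.diff(fy), np.diff(fx))


def render_movie(
    emitters: EmitterSet | Mapping[int, np.ndarray],
    camera: CameraModel,
    drift: DriftProgram | None = None,
    beads_nm: np.ndarray | None = None,
    rng_seed: int = 0,
    n_frames: int | None = None,
    bead_photons: float = 2000.0,
    apply_noise: bool = True,
    emitter_kwargs: Mapping | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a camera frame stack from blinking emitters.

    Returns ``(stack, sidecar)`` where stack is (T, H, W) — uint16 counts if
    noise is applied, float photons otherwise — and the sidecar lists each
    emitter's true position and on-frame count.

    ``emitters`` may be an EmitterSet or a per-channel label mapping (3D
    positions; z is dropped); in the latter case a single channel must be
    selected upstream, so pass one channel's labels at a time.
    """
    if isinstance(emitters, Mapping):
        if len(emitters) != 1:
            raise ValueError("pass one channel's labels at a time to render_movie")
        (positions,) = emitters.values()
        emitters = EmitterSet(np.asarray(positions)[:, :2], **dict(emitter_kwargs or {}))

    rng = np.random.default_rng(rng_seed)
    n_frames = camera.n_frames_per_channel if n_frames is None else n_frames
    pos_px = emitters.positions_nm[:, :2] / camera.pixel_size_nm
    h, w = camera.height_px, camera.width_px
    if np.any(pos_px < 0) or np.any(pos_px[:, 0] >= w) or np.any(pos_px[:, 1] >= h):
        raise ValueError("emitter outside the camera field of view")
    if beads_nm is not None:
        beads_px = np.atleast_2d(np.asarray(beads_nm, dtype=float)) / camera.pixel_size_nm
        if np.any(beads_px < 0) or np.any(beads_px[:, 0] >= w) or np.any(beads_px[:, 1] >= h):
            raise ValueError("bead outside the camera field of view")
    else:
        beads_px = np.empty((0, 2))

    n_em = len(pos_px)
    p_on = emitters.k_on / (emitters.k_on + emitters.k_off) if (emitters.k_on + emitters.k_off) > 0 else 0.0
    state = rng.uniform(size=n_em) < p_on  # ON mask
    bleached = np.zeros(n_em, dtype=bool)
    on_count = np.zeros(n_em, dtype=int)

    psf_sd_px = camera.psf_sd_nm / camera.pixel_size_nm
    drift = drift or DriftProgram()
    shifts_px = drift.shift_at(np.arange(n_frames)) / camera.pixel_size_nm

    stack = np.empty((n_frames, h, w), dtype=(np.uint16 if apply_noise else np.float64))
    for t in range(n_frames):
        frame = np.zeros((h, w), dtype=float)
        active = state & ~bleached
        on_count += active
        if active.any():
            _render_emitters(
                frame,
                pos_px[active] + shifts_px[t],
                np.full(int(active.sum()), emitters.photon_rate),
                psf_sd_px,
            )
        if len(beads_px):
            _render_emitters(
                frame, beads_px + shifts_px[t], np.full(len(beads_px), bead_photons), psf_sd_px
            )
        frame += camera.background_rate
        if apply_noise:
            counts = rng.poisson(frame).astype(float) * camera.em_gain
            if camera.read_noise_e > 0:
                counts += rng.normal(scale=camera.read_noise_e, size=counts.shape)
            stack[t] = np.clip(counts + camera.baseline, 0, 65535).astype(np.uint16)
        else:
            stack[t] = frame

        # on/off Markov chain for the next frame
        to_off = state & (rng.uniform(size=n_em) < emitters.k_off)
        to_on = ~state & (rng.uniform(size=n_em) < emitters.k_on)
        if emitters.bleach_prob > 0:
            bleached |= state & (rng.uniform(size=n_em) < emitters.bleach_prob)
        state = (state & ~to_off) | to_on

    sidecar = pd.DataFrame(
        {
            "emitter_id": np.arange(n_em),
            "true_x_nm": emitters.positions_nm[:, 0],
            "true_y_nm": emitters.positions_nm[:, 1],
            "n_on_frames": on_count,
        }
    )
    return stack, sidecar
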