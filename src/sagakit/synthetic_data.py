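"""Synthetic ground-truth generators for the spheroid-invasion pipeline.

Three generators emulate the three data streams the analysis consumes:

* :func:`generate_spheroid_stack` — a 4D (t, z, y, x) image phantom of a
  spheroid with a bright core and radial invasive branches that elongate
  over time.  Foreground voxels carry a linear intensity ramp across z so
  that the standard-deviation z-projection separates them from the flat
  background; the geometric ground truth (area, invasive radius, branch
  count, invasive area) is computed analytically per frame.
* :func:`generate_tracks` — persistent-random-walk trajectories of invasive
  chains, optionally with a speed change at a leader-detachment frame.
* :func:`generate_expression` — a genes x 12-sample expression matrix over
  the four-group design (leader, follower, photoconverted control,
  non-photoconverted control) with planted null, leader-up, follower-up and
  photoconversion-artifact genes.

All randomness flows through one :func:`numpy.random.default_rng` seeded
from the spec; fixed seed implies bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

GROUPS = ("leader", "follower", "ctrl_photo", "ctrl_nonphoto")

GENE_LABELS = ("null", "leader_up", "follower_up", "artifact")


# ---------------------------------------------------------------------------
# Spheroid phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpheroidPhantomSpec:
    """Geometry and photometry of a synthetic invading spheroid.

    The phantom is a bright core disk of radius ``core_radius`` centred in
    the frame, plus ``n_branches`` radial rays whose tips sit at radius
    ``core_radius + branch_growth_rate * t`` at frame ``t``.  Each ray is a
    capsule (rectangle of width ``branch_width`` capped by a half-disk) so
    its area has a closed form.
    """

    image_shape: tuple[int, int, int, int]  # (T, Z, Y, X)
    core_radius: float = 20.0
    n_branches: int = 5
    branch_growth_rate: float = 2.0  # px / frame
    branch_width: float = 6.0
    fg_intensity: float = 100.0
    bg_intensity: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t, z, y, x = self.image_shape
        if t < 1 or z < 2 or y < 4 or x < 4:
            raise ValueError(f"image_shape {self.image_shape} too small (need T>=1, Z>=2)")
        if self.core_radius < 1:
            raise ValueError("core_radius must be >= 1 px")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.branch_width <= 0:
            raise ValueError("branch_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # all geometry must fit inside (Y, X) at the final frame
        for frame in range(t):
            r = self.core_radius + self.branch_growth_rate * frame
            if r + 1 > min(y, x) / 2:
                raise ValueError(
                    f"phantom geometry exceeds image bounds at frame {frame}: "
                    f"radius {r:.1f} px does not fit in ({y}, {x})"
                )

    @property
    def projected_contrast(self) -> float:
        """Foreground-minus-background amplitude of the noiseless z-std projection."""
        _, z, _, _ = self.image_shape
        ramp = _z_ramp(z, self.fg_intensity)
        return float(np.std(ramp, ddof=1))


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic per-frame ground truth for a phantom."""

    frame: np.ndarray              # (T,)
    true_area: np.ndarray          # px^2, core + rays
    true_invasive_radius: np.ndarray
    true_branch_count: np.ndarray
    true_invasive_area: np.ndarray  # ray area outside the core
    branch_angles: np.ndarray       # radians
    core_center: tuple[float, float]  # (y, x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "area": self.true_area,
                "invasive_radius": self.true_invasive_radius,
                "branch_count": self.true_branch_count,
                "invasive_area": self.true_invasive_area,
            }
        )


def _z_ramp(n_z: int, fg_intensity: float) -> np.ndarray:
    """Linear intensity ramp across z for foreground voxels.

    Ranges from 0.5*fg to 1.5*fg so that the mean stays at fg_intensity
    while the z-variance is strictly positive.
    """
    return fg_intensity * (0.5 + np.arange(n_z) / (n_z - 1))


def _branch_angles(n_branches: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct ray directions: even spacing with a random global rotation.

    Even spacing keeps the phantom's centre of mass at the core centre at
    every frame (the ray first moments cancel), so the analytic invasive
    radius (core + growth * t, measured from the centre) coincides with the
    centroid-based definition used by the feature extractor.
    """
    if n_branches == 0:
        return np.empty(0)
    base = rng.uniform(0, 2 * np.pi)
    spacing = 2 * np.pi / n_branches
    return (base + np.arange(n_branches) * spacing) % (2 * np.pi)


def _capsule_mask(yy: np.ndarray, xx: np.ndarray, center: tuple[float, float],
                  angle: float, tip_radius: float, width: float) -> np.ndarray:
    """Pixels within width/2 of the segment from the centre towards `angle`.

    The segment ends at radius ``tip_radius - width/2`` so that the half-disk
    cap reaches exactly ``tip_radius`` — the phantom's true invasive radius.
    """
    half = width / 2.0
    seg_len = max(tip_radius - half, 0.0)
    cy, cx = center
    dy, dx = math.sin(angle), math.cos(angle)
    ry, rx = yy - cy, xx - cx
    proj = np.clip(ry * dy + rx * dx, 0.0, seg_len)
    dist2 = (ry - proj * dy) ** 2 + (rx - proj * dx) ** 2
    return dist2 <= half ** 2


def rasterize_phantom_frame(spec: SpheroidPhantomSpec, frame: int,
                            angles: np.ndarray) -> np.ndarray:
    """Binary (Y, X) foreground mask of the phantom at one frame."""
    _, _, ny, nx = spec.image_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.core_radius ** 2
    tip = spec.core_radius + spec.branch_growth_rate * frame
    for ang in angles:
        mask |= _capsule_mask(yy, xx, (cy, cx), ang, tip, spec.branch_width)
    return mask


def _analytic_ray_area_outside_core(spec: SpheroidPhantomSpec, frame: int) -> float:
    """Closed-form area of one ray capsule beyond the core disk.

    Approximated as the rectangle portion outside the core plus the half-disk
    cap; the small curvature correction at the core boundary is within the
    per-boundary-pixel discretisation bound.
    """
    half = spec.branch_width / 2.0
    length = spec.branch_growth_rate * frame  # protrusion beyond the core
    if length <= 0:
        return 0.0
    rect = spec.branch_width * max(length - half, 0.0)
    cap = math.pi * half ** 2 / 2.0
    return rect + cap


def generate_spheroid_stack(spec: SpheroidPhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render the 4D phantom stack and its analytic truth table.

    Returns
    -------
    stack : ndarray, shape (T, Z, Y, X)
        Foreground voxels follow a linear intensity ramp across z (mean
        ``fg_intensity``); background is flat at ``bg_intensity``; additive
        Gaussian noise of sd ``noise_sd`` everywhere.
    truth : PhantomTruth
    """
    rng = np.random.default_rng(spec.seed)
    nt, nz, ny, nx = spec.image_shape
    angles = _branch_angles(spec.n_branches, rng)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0

    stack = np.full((nt, nz, ny, nx), spec.bg_intensity, dtype=np.float64)
    ramp = _z_ramp(nz, spec.fg_intensity)

    areas = np.empty(nt)
    radii = np.empty(nt)
    inv_areas = np.empty(nt)
    for t in range(nt):
        mask = rasterize_phantom_frame(spec, t, angles)
        stack[t][:, mask] = ramp[:, None]  # ramp down each foreground column
        core_area = math.pi * spec.core_radius ** 2
        ray_area = spec.n_branches * _analytic_ray_area_outside_core(spec, t)
        areas[t] = core_area + ray_area
        radii[t] = spec.core_radius + (spec.branch_growth_rate * t if spec.n_branches else 0.0)
        inv_areas[t] = ray_area

    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)

    truth = PhantomTruth(
        frame=np.arange(nt),
        true_area=areas,
        true_invasive_radius=radii,
        true_branch_count=np.full(nt, spec.n_branches, dtype=int),
        true_invasive_area=inv_areas,
        branch_angles=angles,
        core_center=(cy, cx),
    )
    return stack, truth


def rasterized_truth_mask(spec: SpheroidPhantomSpec, truth: PhantomTruth) -> np.ndarray:
    """(T, Y, X) boolean foreground truth, for segmentation overlap checks."""
    nt = spec.image_shape[0]
    return np.stack([rasterize_phantom_frame(spec, t, truth.branch_angles)
                     for t in range(nt)])


# ---------------------------------------------------------------------------
# Chain tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackSimSpec:
    """Persistent-random-walk model of invasive-chain motion.

    ``persistence`` interpolates between an isotropic random walk (0) and
    ballistic motion (1).  If ``detachment_frame`` is set, the step length
    switches from ``speed_pre`` to ``speed_post`` at that frame, emulating
    chain slow-down after leader-cell loss.
    """

    n_frames: int = 120
    frame_interval: float = 10.0  # minutes, matching 10-min live imaging
    speed_pre: float = 2.0        # px / frame
    speed_post: float = 0.5
    detachment_frame: int | None = None
    persistence: float = 0.8
    noise_sd: float = 0.0         # positional jitter, px
    n_tracks: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if self.detachment_frame is not None and not (
                0 < self.detachment_frame < self.n_frames):
            raise ValueError("detachment_frame must lie strictly inside the track")
        if self.noise_sd < 0 or self.speed_pre < 0 or self.speed_post < 0:
            raise ValueError("speeds and noise_sd must be >= 0")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass(frozen=True)
class TrackSet:
    """Simulated trajectories plus the generating spec (the ground truth)."""

    tracks: pd.DataFrame  # columns: track_id, frame, x, y
    spec: TrackSimSpec

    def coordinates(self, track_id: int) -> np.ndarray:
        sub = self.tracks[self.tracks.track_id == track_id]
        return sub[["x", "y"]].to_numpy()


def generate_tracks(spec: TrackSimSpec) -> TrackSet:
    """Simulate persistent random walks with an optional detachment slow-down."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for tid in range(spec.n_tracks):
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        pos = rng.uniform(0, 50, size=2)
        positions = [pos.copy()]
        for t in range(1, spec.n_frames):
            speed = spec.speed_pre
            if spec.detachment_frame is not None and t > spec.detachment_frame:
                speed = spec.speed_post
            if spec.persistence < 1.0:
                phi = rng.uniform(0, 2 * np.pi)
                rand_dir = np.array([math.cos(phi), math.sin(phi)])
                mixed = spec.persistence * direction + (1 - spec.persistence) * rand_dir
                norm = np.linalg.norm(mixed)
                direction = mixed / norm if norm > 0 else rand_dir
            pos = pos + speed * direction
            positions.append(pos.copy())
        arr = np.asarray(positions)
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
        for t, (x, y) in enumerate(arr):
            rows.append((tid, t, x, y))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    return TrackSet(tracks=df, spec=spec)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimSpec:
    """Planted-effect model for the four-group microarray design.

    Effects are additive on the log2 scale: leader-up genes gain ``delta``
    in the leader samples, follower-up genes in the follower samples, and
    photoconversion-artifact genes in BOTH the leader and the photoconverted
    control samples, so that the leader-vs-follower and the control
    (photoconverted vs non-photoconverted) contrasts shift comparably.
    """

    n_genes: int = 1000
    n_reps: int = 3
    baseline_mean: float = 8.0   # log2 a.u., typical array scale
    baseline_sd: float = 0.25
    delta: float = 1.0           # log2 effect size
    f_null: float = 0.85
    f_leader_up: float = 0.05
    f_follower_up: float = 0.05
    f_artifact: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.f_null, self.f_leader_up, self.f_follower_up, self.f_artifact)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("gene fractions must be non-negative and sum to 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")


def make_design(n_reps: int = 3) -> pd.DataFrame:
    """Sample design table: sample_id, group, replicate."""
    rows = [
        (f"{grp}_{rep + 1}", grp, rep + 1)
        for grp in GROUPS
        for rep in range(n_reps)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "replicate"])


def generate_expression(spec: ExpressionSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate the genes x (4 * n_reps) matrix with planted effects.

    Returns ``(matrix, design, truth)`` where ``truth`` labels each gene as
    one of ``null | leader_up | follower_up | artifact``.
    """
    rng = np.random.default_rng(spec.seed)
    design = make_design(spec.n_reps)
    n_samples = len(design)

    counts = _label_counts(spec)
    labels = np.repeat(GENE_LABELS, [counts[k] for k in GENE_LABELS])

    values = rng.normal(spec.baseline_mean, spec.baseline_sd,
                        size=(spec.n_genes, n_samples))
    col_group = design.group.to_numpy()
    leader_cols = col_group == "leader"
    follower_cols = col_group == "follower"
    photo_cols = col_group == "ctrl_photo"

    values[np.ix_(labels == "leader_up", leader_cols)] += spec.delta
    values[np.ix_(labels == "follower_up", follower_cols)] += spec.delta
    values[np.ix_(labels == "artifact", leader_cols)] += spec.delta
    values[np.ix_(labels == "artifact", photo_cols)] += spec.delta

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    matrix = pd.DataFrame(values, index=gene_ids, columns=design.sample_id)
    matrix.index.name = "gene_id"
    truth = pd.Series(labels, index=gene_ids, name="truth")
    return matrix, design, truth


def _label_counts(spec: ExpressionSimSpec) -> dict[str, int]:
    raw = {
        "leader_up": spec.f_leader_up,
        "follower_up": spec.f_follower_up,
        "artifact": spec.f_artifact,
    }
    counts = {k: int(round(v * spec.n_genes)) for k, v in raw.items()}
    counts["null"] = spec.n_genes - sum(counts.values())
    if counts["null"] < 0:
        raise ValueError("fractions leave no room for null genes at this n_genes")
    return counts


# ---------------------------------------------------------------------------
# On-disk interchange
# ---------------------------------------------------------------------------

def write_phantom(stack: np.ndarray, truth: PhantomTruth, out_dir: str | Path,
                  stem: str = "phantom") -> dict[str, Path]:
    """Write the stack as a multi-page TIFF (axes TZYX) and the truth as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{stem}.tif"
    csv_path = out_dir / f"{stem}_truth.csv"
    tifffile.imwrite(tiff_path, stack.astype(np.float32), metadata={"axes": "TZYX"})
    truth.to_frame().to_csv(csv_path, index=False)
    return {"stack": tiff_path, "truth": csv_path}


def read_stack(path: str | Path, axes: str = "TZYX") -> np.ndarray:
    """Read a multi-page TIFF into (t, z, y, x) order."""
    data = tifffile.imread(path)
    axes = axes.upper()
    if data.ndim != len(axes):
        raise ValueError(f"stack has {data.ndim} axes, expected '{axes}'")
    order = [axes.index(a) for a in "TZYX" if a in axes]
    return np.transpose(data, order)


def write_tracks(trackset: TrackSet, out_dir: str | Path,
                 stem: str = "tracks") -> dict[str, Path]:
    """Write tracks CSV (track_id, frame, x, y) with a YAML spec sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    yaml_path = out_dir / f"{stem}_spec.yaml"
    trackset.tracks.to_csv(csv_path, index=False)
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(trackset.spec), fh)
    return {"tracks": csv_path, "spec": yaml_path}


def write_expression(matrix: pd.DataFrame, design: pd.DataFrame,
                     out_dir: str | Path, stem: str = "expression",
                     truth: pd.Series | None = None) -> dict[str, Path]:
    """Write the expression TSV (gene_id + sample columns) and design CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{stem}.tsv",
        "design": out_dir / f"{stem}_design.csv",
    }
    matrix.to_csv(paths["matrix"], sep="\t")
    design.to_csv(paths["design"], index=False)
    if truth is not None:
        paths["truth"] = out_dir / f"{stem}_truth.csv"
        truth.to_csv(paths["truth"])
    return paths
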