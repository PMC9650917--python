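"""Synthetic breast-ultrasound-like video clips and the on-disk dataset format.

Real breast-ultrasound cine sequences show a speckle-textured echogenic
background with a hypoechoic (dark) lesion whose boundary morphology carries
the diagnostic signal: benign lesions tend to present smooth, near-elliptic
margins while malignant ones are irregular and spiculated. During acquisition
the operator slowly translates the probe, re-scales and re-adjusts brightness.
This module emulates exactly those properties — multiplicative speckle,
a star-convex lesion whose radial roughness is class-dependent, and slow
inter-frame drift/zoom/brightness changes — so that the full pipeline is
exercisable and learnable without any proprietary data.

Dataset-on-disk layout::

    <root>/index.csv                 # video_id,label,n_frames,relative_path
    <root>/splits.json               # video_id -> "train" | "test"
    <root>/<video_id>/frame_0000.png # 8-bit grayscale frames
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "LABELS",
    "ClipParams",
    "VideoSequence",
    "IndexRecord",
    "DatasetIndex",
    "generate_clip",
    "generate_clip_population",
    "generate_dataset",
    "read_dataset",
    "read_clip_dir",
]

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)

#: default boundary-perturbation amplitude per class (dimensionless, fraction
#: of the local lesion radius): low for smooth benign margins, high for
#: spiculated malignant ones
DEFAULT_IRREGULARITY = {BENIGN: 0.05, MALIGNANT: 0.35}

_BACKGROUND_LEVEL = 0.60  # mean echogenic background intensity
_LESION_CONTRAST = 0.40  # lesion interior multiplies background by this
_N_BOUNDARY_VERTICES = 16
_EDGE_SOFTNESS_PX = 1.5


@dataclass(frozen=True)
class ClipParams:
    """Parameters of one synthetic clip.

    ``irregularity`` defaults (None) to a class-dependent amplitude:
    0.05 for benign, 0.35 for malignant.
    """

    T: int = 16
    H: int = 64
    W: int = 64
    class_label: str = BENIGN
    lesion_radius_frac: float = 0.25
    irregularity: float | None = None
    speckle_scale: float = 0.15
    drift_px_per_frame: float = 1.0
    brightness_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.H < 8 or self.W < 8:
            raise ValueError(f"H and W must be >= 8, got H={self.H}, W={self.W}")
        if self.class_label not in LABELS:
            raise ValueError(f"class_label must be one of {LABELS}, got {self.class_label!r}")
        if not 0.0 < self.lesion_radius_frac < 0.5:
            raise ValueError(f"lesion_radius_frac must lie in (0, 0.5), got {self.lesion_radius_frac}")
        if self.irregularity is not None and self.irregularity < 0:
            raise ValueError(f"irregularity must be >= 0, got {self.irregularity}")
        if self.speckle_scale <= 0:
            raise ValueError(f"speckle_scale must be > 0, got {self.speckle_scale}")
        if self.drift_px_per_frame < 0:
            raise ValueError(f"drift_px_per_frame must be >= 0, got {self.drift_px_per_frame}")
        if self.brightness_jitter < 0:
            raise ValueError(f"brightness_jitter must be >= 0, got {self.brightness_jitter}")

    @property
    def effective_irregularity(self) -> float:
        if self.irregularity is not None:
            return self.irregularity
        return DEFAULT_IRREGULARITY[self.class_label]


@dataclass
class VideoSequence:
    """A labeled clip: ordered grayscale frames in [0, 1]."""

    id: str
    frames: np.ndarray  # (T, H, W) float32 in [0, 1]
    label: str

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class IndexRecord:
    video_id: str
    label: str
    n_frames: int
    relative_path: str


@dataclass
class DatasetIndex:
    records: list[IndexRecord]
    split_assignment: dict[str, str] = field(default_factory=dict)
    root: Path | None = None

    def ids(self, split: str | None = None) -> list[str]:
        if split is None:
            return [r.video_id for r in self.records]
        return [r.video_id for r in self.records if self.split_assignment.get(r.video_id) == split]

    def label_of(self, video_id: str) -> str:
        for r in self.records:
            if r.video_id == video_id:
                return r.label
        raise KeyError(video_id)


# --------------------------------------------------------------------- clips


def _radial_profile(params: ClipParams, rng: np.random.Generator) -> tuple[np.ndarray, float, float, float]:
    """Per-vertex lesion radius multipliers plus ellipse axes/rotation."""
    # mild random ellipticity shared by both classes
    a = 1.0 + rng.uniform(0.0, 0.20)
    b = 1.0 - rng.uniform(0.0, 0.20)
    phi = rng.uniform(0.0, math.pi)
    pert = rng.uniform(-1.0, 1.0, size=_N_BOUNDARY_VERTICES)
    mult = 1.0 + params.effective_irregularity * pert
    return np.clip(mult, 0.25, None), a, b, phi


def _render_clean(
    params: ClipParams,
    background: np.ndarray,
    mult: np.ndarray,
    a: float,
    b: float,
    phi: float,
    center: tuple[float, float],
    zoom: float,
) -> np.ndarray:
    """Anti-aliased star-convex lesion on the background (no speckle yet)."""
    h, w = params.H, params.W
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    dy, dx = yy - center[0], xx - center[1]
    d = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # base ellipse radius along each direction
    r0 = params.lesion_radius_frac * min(h, w) * zoom
    ct, st = np.cos(theta - phi), np.sin(theta - phi)
    r_ell = r0 * a * b / np.sqrt((b * ct) ** 2 + (a * st) ** 2)
    # piecewise-linear per-vertex perturbation (star-convex polygon boundary)
    v = (theta + math.pi) / (2 * math.pi) * _N_BOUNDARY_VERTICES
    i0 = np.floor(v).astype(int) % _N_BOUNDARY_VERTICES
    i1 = (i0 + 1) % _N_BOUNDARY_VERTICES
    frac = v - np.floor(v)
    r_bound = r_ell * (mult[i0] * (1 - frac) + mult[i1] * frac)
    # smoothstep anti-aliasing of the lesion edge
    s = np.clip((d - r_bound) / _EDGE_SOFTNESS_PX + 0.5, 0.0, 1.0)
    inside = 1.0 - s * s * (3.0 - 2.0 * s)
    return background * (1.0 - (1.0 - _LESION_CONTRAST) * inside)


def generate_clip(params: ClipParams) -> VideoSequence:
    """Render one synthetic clip, fully determined by ``params`` (incl. seed).

    The lesion geometry is fixed per clip; consecutive frames differ by a
    bounded random-walk translation, slow zoom in [0.97, 1.03], per-frame
    brightness offsets within ±``brightness_jitter``, and independent
    multiplicative speckle smoothed with a 1-px Gaussian.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.H, params.W

    base = np.full((h, w), _BACKGROUND_LEVEL, dtype=np.float32)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 8.0)
    background = base + 0.08 * texture.astype(np.float32)

    mult, a, b, phi = _radial_profile(params, rng)
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w

    max_drift = 0.12 * min(h, w)  # keep the lesion in frame
    frames = np.empty((params.T, h, w), dtype=np.float32)
    off_y = off_x = 0.0
    zoom = 1.0
    for t in range(params.T):
        if t > 0 and params.drift_px_per_frame > 0:
            off_y = float(np.clip(off_y + rng.uniform(-1, 1) * params.drift_px_per_frame, -max_drift, max_drift))
            off_x = float(np.clip(off_x + rng.uniform(-1, 1) * params.drift_px_per_frame, -max_drift, max_drift))
        if t > 0:
            zoom = float(np.clip(zoom + rng.uniform(-0.01, 0.01), 0.97, 1.03))
        brightness = rng.uniform(-1, 1) * params.brightness_jitter
        clean = _render_clean(params, background, mult, a, b, phi, (cy + off_y, cx + off_x), zoom)
        speckle = 1.0 + params.speckle_scale * rng.standard_normal((h, w)).astype(np.float32)
        frame = gaussian_filter(clean * speckle, sigma=1.0) + brightness
        frames[t] = np.clip(frame, 0.0, 1.0)

    return VideoSequence(id=f"{params.class_label}_{params.seed}", frames=frames, label=params.class_label)


def generate_clip_population(
    n_per_class: int,
    T: int,
    H: int = 64,
    W: int = 64,
    radius_range: tuple[float, float] = (0.15, 0.35),
    seed: int = 0,
) -> list[VideoSequence]:
    """In-memory balanced clip population with per-clip lesion-size diversity
    (uniform radius fraction in ``radius_range``), emulating the spread of
    lesion sizes in a clinical cohort. Useful for experiments that do not
    need the on-disk format."""
    rng = np.random.default_rng(seed)
    clips: list[VideoSequence] = []
    for label in LABELS:
        for i in range(n_per_class):
            params = ClipParams(
                T=T,
                H=H,
                W=W,
                class_label=label,
                lesion_radius_frac=float(rng.uniform(*radius_range)),
                seed=int(rng.integers(0, 2**31)),
            )
            clip = generate_clip(params)
            clip.id = f"{label}_{i:04d}"
            clips.append(clip)
    return clips


# ------------------------------------------------------------------- dataset


def _stratified_split(
    ids_by_class: dict[str, list[str]], test_fraction: float, rng: np.random.Generator
) -> dict[str, str]:
    """Seeded stratified split; per-class test count is round(fraction * n)."""
    assignment: dict[str, str] = {}
    for label in sorted(ids_by_class):
        ids = sorted(ids_by_class[label])
        n_test = int(math.floor(test_fraction * len(ids) + 0.5))
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            assignment[ids[idx]] = "test" if rank < n_test else "train"
    return assignment


def generate_dataset(
    n_benign: int,
    n_malignant: int,
    params_template: ClipParams,
    test_fraction: float,
    seed: int,
    out_dir: str | Path,
    variable_length: bool = True,
) -> DatasetIndex:
    """Write a labeled synthetic dataset (PNG frames + CSV index + split file).

    Clip lengths vary uniformly in [ceil(0.75 T), ceil(1.25 T)] around the
    template's T when ``variable_length`` is set, mirroring free-hand cine
    acquisitions of uneven duration.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    clip_seeds = np.random.SeedSequence(seed).generate_state(n_benign + n_malignant)

    records: list[IndexRecord] = []
    ids_by_class: dict[str, list[str]] = {BENIGN: [], MALIGNANT: []}
    counts = {BENIGN: n_benign, MALIGNANT: n_malignant}
    k = 0
    for label in (BENIGN, MALIGNANT):
        for i in range(counts[label]):
            video_id = f"{label}_{i:04d}"
            t = params_template.T
            if variable_length:
                lo, hi = math.ceil(0.75 * t), math.ceil(1.25 * t)
                t = int(rng.integers(lo, hi + 1))
            params = replace(
                params_template, T=t, class_label=label, seed=int(clip_seeds[k]) % (2**31)
            )
            clip = generate_clip(params)
            clip_dir = out_dir / video_id
            clip_dir.mkdir(exist_ok=True)
            for f_idx in range(len(clip)):
                frame8 = np.round(clip.frames[f_idx] * 255.0).astype(np.uint8)
                iio.imwrite(clip_dir / f"frame_{f_idx:04d}.png", frame8)
            records.append(IndexRecord(video_id, label, len(clip), video_id))
            ids_by_class[label].append(video_id)
            k += 1

    assignment = _stratified_split(ids_by_class, test_fraction, rng)

    frame = pd.DataFrame(
        [(r.video_id, r.label, r.n_frames, r.relative_path) for r in records],
        columns=["video_id", "label", "n_frames", "relative_path"],
    )
    frame.to_csv(out_dir / "index.csv", index=False)
    with open(out_dir / "splits.json", "w") as fh:
        json.dump(assignment, fh, indent=1, sort_keys=True)
    return DatasetIndex(records=records, split_assignment=assignment, root=out_dir)


def read_clip_dir(clip_dir: str | Path, video_id: str, label: str, n_frames: int | None = None) -> VideoSequence:
    """Load one clip directory of ``frame_####.png`` files."""
    clip_dir = Path(clip_dir)
    paths = sorted(clip_dir.glob("frame_*.png"))
    if n_frames is not None and len(paths) != n_frames:
        raise IOError(
            f"video {video_id!r}: expected {n_frames} frames under {clip_dir}, found {len(paths)}"
        )
    if not paths:
        raise IOError(f"video {video_id!r}: no frames found under {clip_dir}")
    frames = np.stack([iio.imread(p).astype(np.float32) / 255.0 for p in paths])
    return VideoSequence(id=video_id, frames=frames, label=label)


def read_dataset(index_path: str | Path) -> tuple[list[VideoSequence], DatasetIndex]:
    """Read a dataset written by :func:`generate_dataset` (or hand-assembled
    in the same layout). Pixels round-trip exactly at 8-bit quantization."""
    index_path = Path(index_path)
    if index_path.is_dir():
        index_path = index_path / "index.csv"
    if not index_path.exists():
        raise IOError(f"index file not found: {index_path}")
    root = index_path.parent
    try:
        table = pd.read_csv(index_path, dtype={"video_id": str, "label": str})
    except pd.errors.EmptyDataError:
        return [], DatasetIndex(records=[], split_assignment={}, root=root)
    records, clips = [], []
    for row in table.itertuples(index=False):
        if row.label not in LABELS:
            raise ValueError(
                f"video {row.video_id!r}: unknown label {row.label!r} (expected one of {LABELS})"
            )
        rec = IndexRecord(str(row.video_id), row.label, int(row.n_frames), str(row.relative_path))
        clip = read_clip_dir(root / rec.relative_path, rec.video_id, rec.label, rec.n_frames)
        records.append(rec)
        clips.append(clip)
    split_file = root / "splits.json"
    assignment = {}
    if split_file.exists():
        with open(split_file) as fh:
            assignment = json.load(fh)
    return clips, DatasetIndex(records=records, split_assignment=assignment, root=root)
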