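"""Synthetic time-lapse sequences of a moving fish-like blob.

Renders a dark elongated ellipse moving over a light background at a known
per-frame displacement, emulating bright-field imaging of a larva on a flat
light box.  Every rendered sequence carries its ground truth (sub-pixel
centroid track and realized per-step travel lengths), so the downstream
activity pipeline can be validated without recorded data.

The renderer anti-aliases the ellipse boundary with a signed-distance
approximation, which makes the rendered image — and hence every activity
statistic computed from it — a continuous function of sub-pixel position.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .frames import Frame, FrameSequence

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "simulate_sequence",
    "simulate_death_trace",
    "write_sequence",
]


class SpecError(ValueError):
    """Raised when a synthetic spec cannot be rendered."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic sequence.

    Intensities follow the 8-bit bright-field convention: dark animal
    (default 40/255) on a light background (default 220/255).  With
    ``float_mode`` the same levels are emitted on a [0, 1] scale.

    ``step_lengths`` holds the requested per-frame displacement in pixels;
    it must have length ``n_frames - 1``.  ``heading_policy`` is ``"fixed"``
    (constant heading ``heading_deg``) or ``"random-walk"`` (initial heading
    drawn uniformly, per-step Gaussian turns of scale ``turn_sd_deg``).
    """

    image_height: int = 480
    image_width: int = 640
    blob_major_axis: float = 20.0
    blob_minor_axis: float = 6.0
    blob_intensity: float = 40.0
    background_intensity: float = 220.0
    noise_sd: float = 0.0
    n_frames: int = 2
    step_lengths: Sequence[float] = field(default_factory=lambda: (5.0,))
    heading_policy: str = "fixed"
    heading_deg: float = 0.0
    turn_sd_deg: float = 30.0
    seed: int = 0
    capture_interval: float = 1.0
    float_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if len(self.step_lengths) != self.n_frames - 1:
            raise SpecError(
                f"step_lengths must have length n_frames-1 = {self.n_frames - 1}, "
                f"got {len(self.step_lengths)}"
            )
        if any(s < 0 for s in self.step_lengths):
            raise SpecError("step_lengths must all be >= 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.blob_major_axis < 1 or self.blob_minor_axis < 1:
            raise SpecError("blob axes must be >= 1 pixel")
        if self.blob_minor_axis > self.blob_major_axis:
            raise SpecError("blob_minor_axis must not exceed blob_major_axis")
        if self.heading_policy not in ("fixed", "random-walk"):
            raise SpecError(f"unknown heading_policy {self.heading_policy!r}")
        # the blob (any orientation) must fit inside the frame with margin
        margin = 2 * self._margin()
        if margin >= self.image_height or margin >= self.image_width:
            raise SpecError(
                f"blob of major axis {self.blob_major_axis} cannot fit in a "
                f"{self.image_height}x{self.image_width} image"
            )

    def _margin(self) -> float:
        return self.blob_major_axis / 2.0 + 1.5

    @property
    def intensity_range(self) -> tuple[float, float]:
        return (0.0, 1.0) if self.float_mode else (0.0, 255.0)


@dataclass(frozen=True)
class GroundTruth:
    """True trajectory behind one rendered sequence.

    ``travel_lengths[i]`` is the realized (post border reflection) Euclidean
    displacement between centroids of frames ``i`` and ``i+1``.
    ``death_frame`` is set by :func:`simulate_death_trace` only.
    """

    centroid_positions: np.ndarray  # (n_frames, 2) of (row, col)
    travel_lengths: np.ndarray  # (n_frames - 1,)
    cumulative_path_length: float
    death_frame: int | None = None


def _render_frame(spec: SyntheticSpec, pos: np.ndarray, heading: float) -> np.ndarray:
    """Render one anti-aliased ellipse at (row, col) = pos with given heading."""
    a = spec.blob_major_axis / 2.0
    b = spec.blob_minor_axis / 2.0
    r0, c0 = float(pos[0]), float(pos[1])
    img = np.full((spec.image_height, spec.image_width),
                  spec.background_intensity, dtype=np.float64)

    # restrict work to the blob bounding box
    pad = int(math.ceil(a)) + 2
    rlo = max(0, int(math.floor(r0)) - pad)
    rhi = min(spec.image_height, int(math.ceil(r0)) + pad + 1)
    clo = max(0, int(math.floor(c0)) - pad)
    chi = min(spec.image_width, int(math.ceil(c0)) + pad + 1)
    rr, cc = np.meshgrid(np.arange(rlo, rhi, dtype=np.float64),
                         np.arange(clo, chi, dtype=np.float64), indexing="ij")
    dy = rr - r0
    dx = cc - c0
    ct, st = math.cos(heading), math.sin(heading)
    u = dx * ct + dy * st      # along major axis
    v = -dx * st + dy * ct     # along minor axis

    # elliptical radius f = sqrt((u/a)^2 + (v/b)^2); signed distance to the
    # f = 1 contour approximated as (f - 1) / |grad f|, a standard SDF trick
    f = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = np.sqrt((u / a**2) ** 2 + (v / b**2) ** 2) / f
        sd = np.where(f > 0, (f - 1.0) / np.maximum(grad, 1e-12), -min(a, b))
    coverage = np.clip(0.5 - sd, 0.0, 1.0)
    img[rlo:rhi, clo:chi] += (spec.blob_intensity - spec.background_intensity) * coverage
    return img


def _trajectory(spec: SyntheticSpec, rng: np.random.Generator,
                step_lengths: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Positions (n,2) and per-frame headings (n,), with border reflection."""
    m = spec._margin()
    lo = np.array([m, m])
    hi = np.array([spec.image_height - 1 - m, spec.image_width - 1 - m])
    pos = np.empty((spec.n_frames, 2), dtype=np.float64)
    headings = np.empty(spec.n_frames, dtype=np.float64)
    pos[0] = (spec.image_height - 1) / 2.0, (spec.image_width - 1) / 2.0

    if spec.heading_policy == "fixed":
        heading = math.radians(spec.heading_deg)
        turns = np.zeros(max(spec.n_frames - 1, 0))
    else:
        heading = rng.uniform(0.0, 2.0 * math.pi)
        turns = rng.normal(0.0, math.radians(spec.turn_sd_deg),
                           size=max(spec.n_frames - 1, 0))
    headings[0] = heading

    for i, step in enumerate(step_lengths):
        # turns apply only to actual movement: a stationary animal neither
        # advances nor re-orients (turns are pre-drawn, so the RNG stream is
        # identical whether or not steps are later zeroed)
        if step > 0:
            heading = heading + turns[i]
        nxt = pos[i] + step * np.array([math.sin(heading), math.cos(heading)])
        # reflect across the margin boundary until inside (clamp-and-reflect)
        for ax in range(2):
            for _ in range(8):
                if nxt[ax] < lo[ax]:
                    nxt[ax] = 2 * lo[ax] - nxt[ax]
                elif nxt[ax] > hi[ax]:
                    nxt[ax] = 2 * hi[ax] - nxt[ax]
                else:
                    break
            nxt[ax] = min(max(nxt[ax], lo[ax]), hi[ax])
        pos[i + 1] = nxt
        # keep the previous heading through zero-length steps so the blob
        # orientation does not jump while the animal is still
        if step > 0:
            d = nxt - pos[i]
            if np.hypot(d[0], d[1]) > 0:
                heading = math.atan2(d[0], d[1])
        headings[i + 1] = heading
    return pos, headings


def simulate_sequence(spec: SyntheticSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render a sequence and return it with its ground truth.

    The per-sequence RNG (seeded by ``spec.seed``) is consumed in a fixed
    order — trajectory first, then per-frame noise — so identical specs give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    pos, headings = _trajectory(spec, rng, spec.step_lengths)
    return _render(spec, rng, pos, headings, death_frame=None)


def simulate_death_trace(spec: SyntheticSpec,
                         death_frame: int) -> tuple[FrameSequence, GroundTruth]:
    """Like :func:`simulate_sequence` but motion ceases at ``death_frame``.

    Step lengths are forced to zero from ``death_frame`` onward, emulating an
    animal that dies partway through the recording; the true cessation index
    is recorded in the ground truth.
    """
    if not 0 <= death_frame < spec.n_frames:
        raise SpecError(f"death_frame {death_frame} out of range [0, {spec.n_frames})")
    steps = list(spec.step_lengths)
    for i in range(death_frame, len(steps)):
        steps[i] = 0.0
    rng = np.random.default_rng(spec.seed)
    pos, headings = _trajectory(spec, rng, steps)
    return _render(spec, rng, pos, headings, death_frame=death_frame)


def _render(spec: SyntheticSpec, rng: np.random.Generator, pos: np.ndarray,
            headings: np.ndarray, death_frame: int | None) -> tuple[FrameSequence, GroundTruth]:
    scale = 1.0 / 255.0 if spec.float_mode else 1.0
    lo, hi = spec.intensity_range
    frames = []
    for i in range(spec.n_frames):
        img = _render_frame(spec, pos[i], headings[i])
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(img * scale, lo, hi)
        if not spec.float_mode:
            img = np.round(img).astype(np.uint8)
        frames.append(Frame(pixels=img, timestamp=i * spec.capture_interval))
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1) if spec.n_frames > 1 \
        else np.empty(0)
    gt = GroundTruth(
        centroid_positions=pos,
        travel_lengths=steps,
        cumulative_path_length=float(steps.sum()),
        death_frame=death_frame,
    )
    return FrameSequence(frames=frames, capture_interval=spec.capture_interval), gt


def write_sequence(out_dir: str | Path, seq: FrameSequence, gt: GroundTruth,
                   fmt: str = "png") -> Path:
    """Write frames as zero-padded numbered images plus a ground-truth CSV.

    Returns the path of the sidecar ``ground_truth.csv`` (columns:
    frame_index, row, col, step_length — step_length of frame i is the
    displacement from frame i-1, empty for frame 0).
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(seq.frames))))
    for i, frame in enumerate(seq.frames):
        px = frame.pixels
        if px.dtype != np.uint8:
            px = np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(out / f"frame_{i:0{width}d}.{fmt}", px)
    gt_path = out / "ground_truth.csv"
    with open(gt_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "row", "col", "step_length"])
        for i, (r, c) in enumerate(gt.centroid_positions):
            step = "" if i == 0 else f"{gt.travel_lengths[i - 1]:.9g}"
            w.writerow([i, f"{r:.9g}", f"{c:.9g}", step])
    return gt_path


def spec_from_json(path: str | Path) -> SyntheticSpec:
    """Load a SyntheticSpec from a JSON file mirroring its field names."""
    import json

    with open(path) as fh:
        data = json.load(fh)
    if "step_lengths" in data:
        data["step_lengths"] = tuple(float(s) for s in data["step_lengths"])
    return SyntheticSpec(**data)
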