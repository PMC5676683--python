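"""Seeded synthetic scenes of textured moving animals with exact ground truth.

Each animal is an ellipse carrying a rigid intensity texture (a mix of
band-limited sinusoids in body coordinates, rotated with the heading, the way
real markings rotate with the body).  Animals perform a bounce-off-walls
random walk with soft mutual repulsion; scripted *crossings* steer a pair of
animals so that their centres coincide at a scheduled frame, after which they
continue through each other and separate.  Dark animals move on a bright
background and Gaussian pixel noise is added after compositing.

``texture_distinctness`` interpolates between identical textures for all
animals (0) and disjoint intensity bands plus independent patterns (1).

Everything is deterministic given ``SceneConfig.seed``; the generator records
every animal's true centre per frame and, for each scheduled crossing, the
first frame at which the two body masks actually overlap (the frame the
occlusion physically begins, used as the crossing's reference frame).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict

import imageio.v3 as iio
import numpy as np

from .blob_detection import GrayFrame
from .evaluation import GroundTruth


class ScheduleError(ValueError):
    """Raised when a crossing schedule cannot be realised."""


@dataclass
class SceneConfig:
    n_animals: int = 2
    frame_size: tuple[int, int] = (320, 320)      # (height, width) pixels
    n_frames: int = 600
    fps: float = 25.0
    axes: tuple[float, float] = (12.0, 7.0)       # ellipse semi-axes, pixels
    texture_distinctness: float = 1.0
    speed: float = 3.0                            # px / frame
    turn_sd: float = 0.25                         # heading noise, radians
    crossing_schedule: tuple = ()                 # ((frame, (i, j)), ...)
    background_intensity: float = 240.0
    noise_sd: float = 2.0
    approach_frames: int = 40
    separate_frames: int = 15
    min_separation: float | None = None           # default 4 x semi-major axis
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_size
        a, b = self.axes
        if a < b:
            raise ValueError("axes must be (semi-major, semi-minor)")
        if 2 * (a + 4) >= min(h, w):
            raise ValueError("animals do not fit in the frame")
        if not 0.0 <= self.texture_distinctness <= 1.0:
            raise ValueError("texture_distinctness must lie in [0, 1]")
        if self.n_animals < 1 or self.n_frames < 1 or self.fps <= 0:
            raise ValueError("invalid scene dimensions")

    @property
    def margin(self) -> float:
        return self.axes[0] + 4.0

    @property
    def min_sep(self) -> float:
        return self.min_separation if self.min_separation is not None else 4.0 * self.axes[0]


class _Texture:
    """Rigid body-frame intensity pattern inside an intensity band."""

    def __init__(self, rng: np.random.Generator, lo: float, hi: float) -> None:
        self.lo, self.hi = lo, hi
        self.freq = rng.uniform(0.10, 0.30, size=3)       # cycles / pixel
        self.orient = rng.uniform(0.0, 2 * np.pi, size=3)
        self.phase = rng.uniform(0.0, 2 * np.pi, size=3)

    def __call__(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        s = np.zeros_like(u, dtype=np.float64)
        for f, o, p in zip(self.freq, self.orient, self.phase):
            s += np.sin(2 * np.pi * f * (u * np.cos(o) + v * np.sin(o)) + p)
        p01 = np.clip(0.5 + s / 6.0, 0.0, 1.0)
        return self.lo + p01 * (self.hi - self.lo)


def _bands(n: int, t: float) -> list[tuple[float, float]]:
    """Per-animal intensity bands: identical at t=0, disjoint at t=1."""
    lo_full, hi_full = 20.0, 170.0
    width = hi_full - lo_full
    common_c, common_hw = (lo_full + hi_full) / 2.0, width / 2.0
    out = []
    for i in range(n):
        ci = lo_full + (i + 0.5) * width / n
        c = (1 - t) * common_c + t * ci
        hw = (1 - t) * common_hw + t * width / (2 * n)
        out.append((c - hw, c + hw))
    return out


def _ellipse_pixels(
    x: float, y: float, theta: float, a: float, b: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pixel coordinates inside the rotated ellipse, plus body coordinates."""
    h, w = shape
    r0, r1 = max(int(y - a - 1), 0), min(int(y + a + 1), h - 1)
    c0, c1 = max(int(x - a - 1), 0), min(int(x + a + 1), w - 1)
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    dx, dy = cols - x, rows - y
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rows[inside], cols[inside], u[inside], v[inside]


@dataclass
class _Motion:
    """Per-frame positions and headings, plus realised crossing windows."""

    pos: np.ndarray        # (n_frames, n_animals, 2) of (x, y)
    heading: np.ndarray    # (n_frames, n_animals)
    events: list[dict]


def _validate_schedule(cfg: SceneConfig) -> list[dict]:
    events = []
    busy: dict[int, list[tuple[int, int]]] = {i: [] for i in range(cfg.n_animals)}
    for frame, pair in cfg.crossing_schedule:
        i, j = pair
        if not (0 <= i < cfg.n_animals and 0 <= j < cfg.n_animals and i != j):
            raise ScheduleError(f"invalid crossing pair {pair}")
        start = frame - cfg.approach_frames
        stop = frame + cfg.separate_frames
        if start < 1 or stop >= cfg.n_frames:
            raise ScheduleError(f"crossing at frame {frame} does not fit in the video")
        for k in (i, j):
            for s, e in busy[k]:
                if start <= e and s <= stop:
                    raise ScheduleError(f"overlapping crossing windows for animal {k}")
            busy[k].append((start, stop))
        events.append({"pair": (min(i, j), max(i, j)), "scheduled_frame": int(frame),
                       "start": start, "stop": stop})
    return sorted(events, key=lambda e: e["scheduled_frame"])


def _simulate(cfg: SceneConfig, rng: np.random.Generator) -> _Motion:
    h, w = cfg.frame_size
    n = cfg.n_animals
    m = cfg.margin
    events = _validate_schedule(cfg)

    # initial placement with pairwise separation
    pos = np.zeros((cfg.n_frames, n, 2))
    heading = np.zeros((cfg.n_frames, n))
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(10_000):
            p = rng.uniform([m, m], [w - 1 - m, h - 1 - m])
            if all(np.hypot(*(p - q)) >= cfg.min_sep for q in placed):
                placed.append(p)
                break
        else:
            raise ValueError("could not place animals with the requested separation")
    pos[0] = np.array(placed)
    heading[0] = rng.uniform(0, 2 * np.pi, size=n)

    # per-frame steering directives: mode[frame][animal] = ("approach", event) etc.
    steer: dict[int, dict[int, tuple[str, dict]]] = {}
    for ev in events:
        for k in range(ev["start"], ev["scheduled_frame"] + 1):
            for animal in ev["pair"]:
                steer.setdefault(k, {})[animal] = ("approach", ev)
        for k in range(ev["scheduled_frame"] + 1, ev["stop"] + 1):
            for animal in ev["pair"]:
                steer.setdefault(k, {})[animal] = ("separate", ev)

    for k in range(1, cfg.n_frames):
        prev = pos[k - 1]
        directives = steer.get(k, {})
        new_heading = heading[k - 1].copy()
        vel = np.zeros((n, 2))
        for i in range(n):
            mode, ev = directives.get(i, ("free", None))
            if mode == "approach":
                if "target" not in ev:
                    a, b = ev["pair"]
                    ev["target"] = (prev[a] + prev[b]) / 2.0
                    for s in ev["pair"]:
                        need = np.hypot(*(ev["target"] - prev[s]))
                        frames_left = ev["scheduled_frame"] - k + 1
                        if need / frames_left > 3.0 * cfg.speed:
                            raise ScheduleError(
                                f"crossing at frame {ev['scheduled_frame']}: animal {s} "
                                f"cannot reach the meeting point in time"
                            )
                frames_left = ev["scheduled_frame"] - k + 1
                v = (ev["target"] - prev[i]) / frames_left
                vel[i] = v
                if np.hypot(*v) > 1e-9:
                    new_heading[i] = math.atan2(v[1], v[0])
            elif mode == "separate":
                # continue along the approach heading: the pair crossed moving
                # in roughly opposite directions, so they separate naturally
                th = new_heading[i]
                vel[i] = cfg.speed * np.array([math.cos(th), math.sin(th)])
            else:
                th = new_heading[i] + rng.normal(0.0, cfg.turn_sd)
                # soft repulsion from the nearest too-close free neighbour
                d = np.hypot(prev[:, 0] - prev[i, 0], prev[:, 1] - prev[i, 1])
                d[i] = np.inf
                nearest = int(d.argmin())
                if d[nearest] < cfg.min_sep:
                    away = prev[i] - prev[nearest]
                    if np.hypot(*away) > 1e-9:
                        th = math.atan2(away[1], away[0])
                new_heading[i] = th
                vel[i] = cfg.speed * np.array([math.cos(th), math.sin(th)])
        nxt = prev + vel
        # wall reflection
        for i in range(n):
            vx, vy = vel[i]
            x, y = nxt[i]
            if x < m:
                x, vx = 2 * m - x, -vx
            elif x > w - 1 - m:
                x, vx = 2 * (w - 1 - m) - x, -vx
            if y < m:
                y, vy = 2 * m - y, -vy
            elif y > h - 1 - m:
                y, vy = 2 * (h - 1 - m) - y, -vy
            nxt[i] = (x, y)
            if (vx, vy) != tuple(vel[i]) and math.hypot(vx, vy) > 1e-9:
                new_heading[i] = math.atan2(vy, vx)
        pos[k] = nxt
        heading[k] = new_heading

    for ev in events:
        ev.pop("target", None)
    return _Motion(pos, heading, events)


def _overlap_log(cfg: SceneConfig, motion: _Motion) -> list[dict]:
    """Per scheduled crossing: first frame and count of actual mask overlap."""
    a, b = cfg.axes
    log = []
    for ev in motion.events:
        i, j = ev["pair"]
        first, count = None, 0
        for k in range(ev["start"], ev["stop"] + 1):
            ri, ci, _, _ = _ellipse_pixels(
                motion.pos[k, i, 0], motion.pos[k, i, 1], motion.heading[k, i], a, b, cfg.frame_size
            )
            rj, cj, _, _ = _ellipse_pixels(
                motion.pos[k, j, 0], motion.pos[k, j, 1], motion.heading[k, j], a, b, cfg.frame_size
            )
            w = cfg.frame_size[1]
            if np.intersect1d(ri * w + ci, rj * w + cj, assume_unique=True).size:
                count += 1
                if first is None:
                    first = k
        if first is None:
            raise ScheduleError(
                f"crossing scheduled at frame {ev['scheduled_frame']} produced no overlap"
            )
        log.append({
            "pair": (i, j),
            "scheduled_frame": ev["scheduled_frame"],
            "first_overlap_frame": int(first),
            "overlap_frames": int(count),
        })
    return log


def _make_textures(cfg: SceneConfig, rng: np.random.Generator) -> list[_Texture]:
    bands = _bands(cfg.n_animals, cfg.texture_distinctness)
    if cfg.texture_distinctness == 0.0:
        shared = _Texture(rng, *bands[0])
        return [shared] * cfg.n_animals
    return [_Texture(rng, lo, hi) for lo, hi in bands]


def generate_scene(cfg: SceneConfig) -> tuple[list[GrayFrame], GroundTruth, list[dict]]:
    """Render a full scene; returns (frames, ground truth, crossing log)."""
    rng = np.random.default_rng(cfg.seed)
    textures = _make_textures(cfg, rng)
    motion = _simulate(cfg, rng)
    crossing_log = _overlap_log(cfg, motion)

    a, b = cfg.axes
    frames: list[GrayFrame] = []
    for k in range(cfg.n_frames):
        canvas = np.full(cfg.frame_size, cfg.background_intensity, dtype=np.float64)
        for i in range(cfg.n_animals):
            rows, cols, u, v = _ellipse_pixels(
                motion.pos[k, i, 0], motion.pos[k, i, 1], motion.heading[k, i],
                a, b, cfg.frame_size,
            )
            canvas[rows, cols] = textures[i](u, v)
        canvas += rng.normal(0.0, cfg.noise_sd, size=cfg.frame_size)
        frames.append(GrayFrame(np.clip(canvas, 0, 255).round().astype(np.uint8), k))

    centers = {k: motion.pos[k].copy() for k in range(cfg.n_frames)}
    ids = {k: np.arange(1, cfg.n_animals + 1) for k in range(cfg.n_frames)}
    truth = GroundTruth(
        centers=centers,
        ids=ids,
        n_animals=cfg.n_animals,
        fps=cfg.fps,
        duration_minutes=cfg.n_frames / cfg.fps / 60.0,
    )
    return frames, truth, crossing_log


def texture_intensity_histograms(cfg: SceneConfig, n_sample_frames: int = 20) -> np.ndarray:
    """Raw painted body-intensity histograms per animal (generator diagnostic).

    Samples frames evenly, accumulates each animal's own (pre-noise) texture
    values over its body mask, and returns one 32-bin histogram over [0, 255]
    per animal.  Used to verify what ``texture_distinctness`` controls.
    """
    rng = np.random.default_rng(cfg.seed)
    textures = _make_textures(cfg, rng)
    motion = _simulate(cfg, rng)
    hists = np.zeros((cfg.n_animals, 32))
    a, b = cfg.axes
    for k in np.linspace(0, cfg.n_frames - 1, n_sample_frames).astype(int):
        for i in range(cfg.n_animals):
            _, _, u, v = _ellipse_pixels(
                motion.pos[k, i, 0], motion.pos[k, i, 1], motion.heading[k, i],
                a, b, cfg.frame_size,
            )
            vals = textures[i](u, v)
            hists[i] += np.histogram(vals, bins=32, range=(0, 255))[0]
    return hists


def default_detection_config(cfg: SceneConfig):
    """Segmentation settings matched to a scene's rendering parameters.

    Threshold midway between the brightest body intensity and the
    background; size limits scaled to the ellipse area (lower bound filters
    noise specks, upper bound still admits merged blobs during occlusions).
    """
    from .blob_detection import DetectionConfig

    area = math.pi * cfg.axes[0] * cfg.axes[1]
    return DetectionConfig(
        threshold=0.5 * (170.0 + cfg.background_intensity),
        min_size=max(10, int(0.2 * area)),
        max_size=int(8.0 * area) * max(1, cfg.n_animals // 2 + 1),
        fps=cfg.fps,
    )


def canonical_scene_configs(base_seed: int = 0) -> dict[str, SceneConfig]:
    """The four packaged test scenes (all parameters fixed, seeds derived)."""
    ten_crossings = tuple(
        (150 + 180 * k, pair)
        for k, pair in enumerate(
            [(0, 1), (2, 3), (1, 2), (3, 4), (0, 2), (1, 3), (2, 4), (0, 3), (1, 4), (0, 4)]
        )
    )
    return {
        "one_animal": SceneConfig(
            n_animals=1, frame_size=(240, 240), n_frames=300, seed=base_seed + 11
        ),
        "two_cross": SceneConfig(
            n_animals=2, frame_size=(320, 320), n_frames=600,
            crossing_schedule=((300, (0, 1)),), seed=base_seed + 22,
        ),
        "five_distinct": SceneConfig(
            n_animals=5, frame_size=(400, 400), n_frames=2000,
            texture_distinctness=1.0, crossing_schedule=ten_crossings,
            seed=base_seed + 33,
        ),
        "five_identical": SceneConfig(
            n_animals=5, frame_size=(400, 400), n_frames=1000,
            texture_distinctness=0.0,
            crossing_schedule=tuple((150 + 180 * k, p) for k, p in
                                    [(0, (0, 1)), (1, (2, 3)), (2, (1, 2)), (3, (3, 4)), (4, (0, 4))]),
            seed=base_seed + 44,
        ),
    }


def render_fixture_suite(
    out_dir: str | os.PathLike,
    scenes: dict[str, SceneConfig] | None = None,
    base_seed: int = 0,
) -> dict:
    """Write scenes as PNG sequences + truth CSV; returns the manifest.

    Defaults to the canonical four-scene suite.  Layout per scene:
    ``<out_dir>/<name>/frames/frame_%06d.png`` and ``<out_dir>/<name>/truth.csv``;
    the manifest (also written as ``manifest.json``) records configs and the
    crossing log.
    """
    from .io import write_truth  # local import to avoid a cycle

    scenes = scenes if scenes is not None else canonical_scene_configs(base_seed)
    manifest: dict = {"scenes": {}}
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for name, cfg in scenes.items():
        frames, truth, crossing_log = generate_scene(cfg)
        scene_dir = os.path.join(out_dir, name)
        frame_dir = os.path.join(scene_dir, "frames")
        os.makedirs(frame_dir, exist_ok=True)
        for fr in frames:
            iio.imwrite(os.path.join(frame_dir, f"frame_{fr.index:06d}.png"), fr.pixels)
        write_truth(os.path.join(scene_dir, "truth.csv"), truth)
        manifest["scenes"][name] = {
            "dir": name,
            "seed": cfg.seed,
            "config": asdict(cfg),
            "crossing_log": crossing_log,
        }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
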