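"""Online trajectory-fragment creation.

Detections are assigned frame by frame to open trajectory fragments by
minimising, with the Hungarian algorithm, the Euclidean distance between each
detection and each fragment's Kalman-predicted next position.  Fragments are
*cut* (marked inactive) whenever continued tracking would risk an identity
error:

``cost_gate``    assigned distance exceeds ``cost_limit``;
``size_gate``    symmetric relative size change exceeds ``size_change_limit``;
``lost``         unmatched for more than ``max_missed_frames`` frames;
``proximity``    two fragments predict within ``proximity_limit`` of the same
                 nearest detection — the occlusion cut: both are closed and
                 the ambiguous detection starts a fresh fragment.

The resulting fragments are pure (one animal each, up to segmentation noise)
and are re-linked into identities by :mod:`toxid.fragment_assignment`.
Processing is strictly online: frame ``k`` is handled using frames ``<= k``
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .blob_detection import Detection, DetectionConfig, detect_frame, GrayFrame

INACTIVE_REASONS = ("cost_gate", "size_gate", "lost", "proximity", "end_of_video", "none")

#: sentinel cost used to pad rectangular assignment matrices to square
_PAD_COST = 1e9


@dataclass
class TrackingConfig:
    """Gating limits and motion-filter tuning.

    ``cost_limit`` / ``proximity_limit`` may be left ``None``: they are then
    derived online from the first frame that contains detections, as
    ``4 x`` / ``1.5 x`` the median blob diameter estimate
    ``2 sqrt(S / pi)``, and frozen for the rest of the run.
    """

    cost_limit: Optional[float] = None
    size_change_limit: float = 1.0
    max_missed_frames: int = 10
    proximity_limit: Optional[float] = None
    process_noise: float = 1e-2
    measurement_noise: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cost_limit", "size_change_limit", "max_missed_frames",
                     "proximity_limit", "process_noise", "measurement_noise"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")

    def resolved(self, median_diameter: float) -> "TrackingConfig":
        """Return a copy with ``None`` limits filled from a diameter estimate."""
        return TrackingConfig(
            cost_limit=self.cost_limit if self.cost_limit is not None else 4.0 * median_diameter,
            size_change_limit=self.size_change_limit,
            max_missed_frames=self.max_missed_frames,
            proximity_limit=(
                self.proximity_limit
                if self.proximity_limit is not None
                else 1.5 * median_diameter
            ),
            process_noise=self.process_noise,
            measurement_noise=self.measurement_noise,
        )


class KalmanCV:
    """Constant-velocity Kalman filter, state ``(x, y, vx, vy)``.

    Position-only measurements; time step is one frame.  Initialised on the
    first measurement with zero velocity and a diffuse velocity covariance so
    that the second measurement essentially fixes the velocity.
    """

    _F = np.array([[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]])
    _H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])

    def __init__(self, xy: tuple[float, float], q: float, r: float) -> None:
        self.q = q
        self.r = r
        self.x = np.array([xy[0], xy[1], 0.0, 0.0])
        self.P = np.diag([r, r, 1e6, 1e6])

    def predict(self) -> None:
        F = self._F
        self.x = F @ self.x
        self.P = F @ self.P @ F.T + self.q * np.eye(4)

    def update(self, xy: tuple[float, float]) -> None:
        H = self._H
        z = np.asarray(xy, dtype=np.float64)
        S = H @ self.P @ H.T + self.r * np.eye(2)
        K = self.P @ H.T @ np.linalg.inv(S)
        self.x = self.x + K @ (z - H @ self.x)
        self.P = (np.eye(4) - K @ H) @ self.P

    def next_position(self) -> tuple[float, float]:
        """One-step-ahead position without advancing the filter."""
        x = self._F @ self.x
        return float(x[0]), float(x[1])


@dataclass
class Fragment:
    """An ordered run of detections believed to belong to one animal."""

    id: int
    detections: list[Detection] = field(default_factory=list)
    kalman: Optional[KalmanCV] = None
    active: bool = True
    inactive_reason: str = "none"
    missed_frames: int = 0
    inactive_frame: Optional[int] = None  # frame at which the fragment was closed

    @property
    def n_samples(self) -> int:
        return len(self.detections)

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame

    @property
    def last(self) -> Detection:
        return self.detections[-1]

    def append(self, det: Detection, cfg: TrackingConfig) -> None:
        if self.detections and det.frame <= self.end_frame:
            raise ValueError("detections must have strictly increasing frame numbers")
        if self.kalman is None:
            self.kalman = KalmanCV(det.cm, cfg.process_noise, cfg.measurement_noise)
        else:
            self.kalman.predict()
            self.kalman.update(det.cm)
        self.detections.append(det)
        self.missed_frames = 0

    def coast(self) -> None:
        """Advance the motion filter through a frame with no assignment."""
        if self.kalman is not None:
            self.kalman.predict()
        self.missed_frames += 1

    def deactivate(self, reason: str, frame: Optional[int] = None) -> None:
        if reason not in INACTIVE_REASONS or reason == "none":
            raise ValueError(f"invalid inactivation reason {reason!r}")
        self.active = False
        self.inactive_reason = reason
        self.inactive_frame = frame


def predict_position(fragment: Fragment) -> tuple[float, float]:
    """Kalman one-step-ahead position of a fragment.

    With a single detection (no velocity evidence) this is that detection's
    centre of mass.
    """
    if not fragment.detections:
        raise ValueError("cannot predict from an empty fragment")
    if fragment.kalman is None:
        return fragment.last.cm
    return fragment.kalman.next_position()


def size_change(s_i: float, s_jn: float) -> float:
    """Symmetric relative size change between two blob sizes.

    ``(s_i - s_jn)/s_jn`` when the new blob is larger, ``(s_jn - s_i)/s_i``
    otherwise; zero iff equal.
    """
    if s_i <= 0 or s_jn <= 0:
        raise ValueError("blob sizes must be positive")
    if s_jn < s_i:
        return (s_i - s_jn) / s_jn
    return (s_jn - s_i) / s_i


def assignment_cost(fragment: Fragment, detection: Detection) -> float:
    """Euclidean distance from the predicted fragment position to a detection."""
    px, py = predict_position(fragment)
    dx, dy = detection.cm
    return math.hypot(px - dx, py - dy)


def solve_assignment(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost row/column matching of a (possibly rectangular) matrix.

    The matrix is padded square with a large sentinel; pairs matched to
    padding are dropped.  Returns ``(row, col)`` pairs sorted by row.
    """
    cost = np.asarray(cost, dtype=np.float64)
    n = max(cost.shape) if cost.size else 0
    if n == 0:
        return []
    padded = np.full((n, n), _PAD_COST)
    padded[: cost.shape[0], : cost.shape[1]] = cost
    rows, cols = linear_sum_assignment(padded)
    return sorted(
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < cost.shape[0] and c < cost.shape[1]
    )


@dataclass
class AssignmentStep:
    """Outcome of one frame of online assignment."""

    matches: dict[int, int]                 # fragment id -> detection index
    new_fragments: list[Fragment]
    deactivated: list[tuple[int, str]]      # (fragment id, reason)
    proximity_events: list[tuple[int, tuple[int, ...]]]  # (detection idx, fragment ids)


def assign_detections(
    fragments: list[Fragment],
    detections: list[Detection],
    cfg: TrackingConfig,
    frame_index: Optional[int] = None,
    next_id: int = 0,
) -> AssignmentStep:
    """Assign one frame's detections to the active fragments (in place).

    Order of rules: the proximity (occlusion) cut first, then global
    Hungarian assignment, then the cost and size gates on matched pairs,
    then the lost rule for unmatched fragments.  Every detection ends up in
    exactly one fragment (matched, or the seed of a new one).
    """
    if cfg.cost_limit is None or cfg.proximity_limit is None:
        raise ValueError("tracking limits unresolved; call cfg.resolved(...) first")
    if frame_index is None and detections:
        frame_index = detections[0].frame

    active = sorted((f for f in fragments if f.active), key=lambda f: f.id)
    preds = {f.id: predict_position(f) for f in active}
    step = AssignmentStep({}, [], [], [])
    consumed: set[int] = set()

    # --- occlusion cut: >= 2 fragments share a nearest detection, both close
    if detections and active:
        dist = np.array(
            [
                [math.hypot(preds[f.id][0] - d.cm[0], preds[f.id][1] - d.cm[1]) for d in detections]
                for f in active
            ]
        )
        nearest = dist.argmin(axis=1)
        cut_frags: set[int] = set()
        for d_idx in range(len(detections)):
            sharing = [
                i
                for i, f in enumerate(active)
                if nearest[i] == d_idx and dist[i, d_idx] <= cfg.proximity_limit
            ]
            if len(sharing) >= 2:
                ids = tuple(active[i].id for i in sharing)
                for i in sharing:
                    active[i].deactivate("proximity", frame_index)
                    step.deactivated.append((active[i].id, "proximity"))
                    cut_frags.add(i)
                step.proximity_events.append((d_idx, ids))
                consumed.add(d_idx)
        active = [f for i, f in enumerate(active) if i not in cut_frags]

    # --- global assignment over the surviving fragments x detections
    open_dets = [i for i in range(len(detections)) if i not in consumed]
    matched_frag_ids: set[int] = set()
    matched_det_idx: set[int] = set()
    if active and open_dets:
        cost = np.array(
            [
                [
                    math.hypot(
                        preds[f.id][0] - detections[j].cm[0],
                        preds[f.id][1] - detections[j].cm[1],
                    )
                    for j in open_dets
                ]
                for f in active
            ]
        )
        for r, c in solve_assignment(cost):
            frag, d_idx = active[r], open_dets[c]
            det = detections[d_idx]
            if cost[r, c] > cfg.cost_limit:
                frag.deactivate("cost_gate", frame_index)
                step.deactivated.append((frag.id, "cost_gate"))
                continue
            if size_change(det.size, frag.last.size) > cfg.size_change_limit:
                frag.deactivate("size_gate", frame_index)
                step.deactivated.append((frag.id, "size_gate"))
                continue
            frag.append(det, cfg)
            step.matches[frag.id] = d_idx
            matched_frag_ids.add(frag.id)
            matched_det_idx.add(d_idx)

    # --- unmatched fragments coast; too many misses closes them
    for frag in active:
        if frag.id in matched_frag_ids or not frag.active:
            continue
        frag.coast()
        if frag.missed_frames > cfg.max_missed_frames:
            frag.deactivate("lost", frame_index)
            step.deactivated.append((frag.id, "lost"))

    # --- every unclaimed detection seeds a new fragment
    for d_idx, det in enumerate(detections):
        if d_idx in matched_det_idx:
            continue
        frag = Fragment(id=next_id)
        next_id += 1
        frag.append(det, cfg)
        step.new_fragments.append(frag)
        fragments.append(frag)

    return step


def track_sequence(
    frames: Iterable[GrayFrame],
    det_cfg: DetectionConfig,
    trk_cfg: TrackingConfig,
) -> list[Fragment]:
    """Run detection + online assignment over a frame sequence.

    Returns every fragment created (all inactive on return; fragments still
    open when the sequence ends are closed with reason ``end_of_video``).
    Frames are consumed strictly in order and never read ahead, so streaming
    a generator and passing a list give identical results.
    """
    fragments: list[Fragment] = []
    next_id = 0
    resolved: Optional[TrackingConfig] = None
    for frame in frames:
        try:
            detections = detect_frame(frame, det_cfg)
        except Exception as exc:  # noqa: BLE001 - annotate with frame index
            raise RuntimeError(f"failed to process frame {frame.index}") from exc
        if resolved is None and detections:
            diam = float(np.median([2.0 * math.sqrt(d.size / math.pi) for d in detections]))
            resolved = trk_cfg.resolved(diam)
        if resolved is None:  # nothing detected yet
            continue
        step = assign_detections(fragments, detections, resolved, frame.index, next_id)
        next_id += len(step.new_fragments)
    for frag in fragments:
        if frag.active:
            frag.deactivate("end_of_video")
    return fragments


def proximity_cut_frames(fragments: Iterable[Fragment]) -> list[int]:
    """Frames at which occlusion cuts occurred (one entry per cut event)."""
    frames = sorted(
        {f.inactive_frame for f in fragments if f.inactive_reason == "proximity"}
        - {None}
    )
    return [int(f) for f in frames]
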