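"""Readers and writers for frames and CSV/JSON trajectory artifacts.

All trajectory artifacts are plain CSV (inspectable and diff-able); floats
are written with 17 significant digits so round-trips are lossless.
"""

from __future__ import annotations

import csv
import glob
import json
import os
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .blob_detection import Detection, GrayFrame
from .evaluation import GroundTruth, MetricsReport
from .fragment_assignment import IdentityAssignment, UNASSIGNED
from .fragment_tracking import Fragment

_FRAME_PATTERNS = ("*.png", "*.tif", "*.tiff", "*.jpg", "*.jpeg", "*.bmp")

#: ITU-R BT.601 luminance weights used to collapse colour frames
LUMA = (0.299, 0.587, 0.114)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """8-bit grayscale via BT.601 luminance for colour inputs."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].astype(np.float64) @ np.array(LUMA)
        img = np.clip(img.round(), 0, 255)
    return img.astype(np.uint8)


def read_frames(path: str | os.PathLike) -> Iterator[GrayFrame]:
    """Yield grayscale frames from an image directory or a video file.

    A directory is read as a sorted, zero-padded image sequence; anything
    else is handed to imageio as a video container.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        files: list[str] = []
        for pat in _FRAME_PATTERNS:
            files.extend(glob.glob(os.path.join(path, pat)))
        if not files:
            raise FileNotFoundError(f"no frames found in {path!r}")
        for index, fname in enumerate(sorted(files)):
            yield GrayFrame(to_grayscale(iio.imread(fname)), index)
    elif os.path.exists(path):
        for index, img in enumerate(iio.imiter(path)):
            yield GrayFrame(to_grayscale(img), index)
    else:
        raise FileNotFoundError(f"no frames found at {path!r}")


# ---------------------------------------------------------------------------
# fragments CSV: fragment_id,frame,t,x,y,size,hu1..hu7,hist0..hist{kn-1}

def _fragment_columns(kn: int) -> list[str]:
    return (
        ["fragment_id", "frame", "t", "x", "y", "size"]
        + [f"hu{i}" for i in range(1, 8)]
        + [f"hist{i}" for i in range(kn)]
    )


def fragments_to_frame(fragments: Iterable[Fragment]) -> pd.DataFrame:
    rows = []
    kn = None
    for frag in fragments:
        for det in frag.detections:
            kn = len(det.hist)
            rows.append(
                [frag.id, det.frame, det.t, det.cm[0], det.cm[1], det.size]
                + list(det.hu)
                + list(det.hist)
            )
    if kn is None:
        raise ValueError("no detections to serialise")
    return pd.DataFrame(rows, columns=_fragment_columns(kn))


def write_fragments(path, fragments: Iterable[Fragment]) -> None:
    fragments_to_frame(fragments).to_csv(path, index=False, float_format="%.17g")


def read_fragments(path) -> list[Fragment]:
    """Rebuild fragments (detections only, no motion-filter state)."""
    df = pd.read_csv(path, float_precision="round_trip")
    hu_cols = [f"hu{i}" for i in range(1, 8)]
    hist_cols = [c for c in df.columns if c.startswith("hist")]
    fragments: list[Fragment] = []
    for fid, grp in df.groupby("fragment_id", sort=True):
        frag = Fragment(id=int(fid), active=False, inactive_reason="end_of_video")
        for _, row in grp.sort_values("frame").iterrows():
            det = Detection(
                cm=(float(row["x"]), float(row["y"])),
                size=int(row["size"]),
                hist=row[hist_cols].to_numpy(dtype=np.int64),
                hu=row[hu_cols].to_numpy(dtype=np.float64),
                t=float(row["t"]),
                frame=int(row["frame"]),
                bbox=(0, 0, 0, 0),
            )
            frag.detections.append(det)
        fragments.append(frag)
    return fragments


def write_detections(path, fragments: Iterable[Fragment]) -> None:
    """Per-frame detections CSV (same schema minus the fragment id)."""
    df = fragments_to_frame(fragments).drop(columns=["fragment_id"])
    df.sort_values(["frame", "x", "y"]).to_csv(path, index=False, float_format="%.17g")


def write_identities(path, assignment: IdentityAssignment, fragments: Iterable[Fragment]) -> None:
    """Trajectories CSV: identity,fragment_id,frame,t,x,y,size."""
    rows = []
    for frag in fragments:
        identity = assignment.labels.get(frag.id, UNASSIGNED)
        for det in frag.detections:
            rows.append(
                [identity, frag.id, det.frame, det.t, det.cm[0], det.cm[1], det.size]
            )
    df = pd.DataFrame(rows, columns=["identity", "fragment_id", "frame", "t", "x", "y", "size"])
    df.sort_values(["identity", "fragment_id", "frame"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_assignment(path, assignment: IdentityAssignment, stopping_value: float | None = None) -> None:
    payload = {
        "n_animals": assignment.n_animals,
        "labels": {str(k): v for k, v in sorted(assignment.labels.items())},
        "unassigned": assignment.unassigned_ids,
    }
    if stopping_value is not None:
        payload["stopping_value"] = stopping_value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def write_metrics(path, report: MetricsReport) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# ground truth CSV: frame,x,y,animal_id

def write_truth(path, truth: GroundTruth) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "x", "y", "animal_id"])
        for frame in sorted(truth.centers):
            pts, ids = truth.centers[frame], truth.ids[frame]
            for (x, y), animal in zip(pts, ids):
                writer.writerow([frame, f"{x:.17g}", f"{y:.17g}", int(animal)])


def read_truth(path, fps: float, n_animals: int | None = None) -> GroundTruth:
    """Parse a ground-truth CSV; malformed rows fail with their line number."""
    centers: dict[int, list] = {}
    ids: dict[int, list] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != ["frame", "x", "y", "animal_id"]:
            raise ValueError(f"{path}: expected header frame,x,y,animal_id")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                frame, x, y, animal = int(row[0]), float(row[1]), float(row[2]), int(row[3])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
            centers.setdefault(frame, []).append((x, y))
            ids.setdefault(frame, []).append(animal)
    if not centers:
        raise ValueError(f"{path}: no ground-truth rows")
    all_ids = {a for frame_ids in ids.values() for a in frame_ids}
    n = n_animals if n_animals is not None else max(all_ids)
    n_frames = max(centers) + 1
    return GroundTruth(
        centers={k: np.asarray(v, dtype=np.float64) for k, v in centers.items()},
        ids={k: np.asarray(v, dtype=np.int64) for k, v in ids.items()},
        n_animals=n,
        fps=fps,
        duration_minutes=n_frames / fps / 60.0,
    )
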