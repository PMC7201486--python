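"""Reading and writing pose-keypoint files.

Handles the OpenPose per-frame JSON dialect (one file per video frame, each
holding a ``people`` list whose entries carry a flat ``pose_keypoints_2d``
list of 75 numbers: x0, y0, c0, ..., x24, y24, c24), the 90-degree rotation
convention used when the detector is run on rotated video, and the CSV
serialization of derived per-trial indices.

The canonical internal orientation is the *original* video orientation
(participant horizontal, image origin top-left, y increasing downward); all
downstream index computation assumes coordinates in that frame.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .body25 import N_KEYPOINTS, Side
from .errors import EmptyTrialError, FormatError, MissingPersonError

logger = logging.getLogger(__name__)

#: Filename pattern for per-frame files: ``<trial>_<%012d>_keypoints.json``.
_FRAME_RE = re.compile(r"(\d+)_keypoints\.json$")

#: Column order of the indices CSV.
INDICES_COLUMNS = ("participant_id", "side", "DT_s", "D_prime", "a_raw", "SPB", "AG")


@dataclass(frozen=True)
class Keypoint:
    """One 2D landmark: pixel position plus detector confidence in [0, 1].

    An undetected landmark is encoded by the (0, 0, 0) sentinel, which merges
    naturally into confidence-threshold masking downstream.
    """

    x: float
    y: float
    confidence: float

    @property
    def is_detected(self) -> bool:
        return not (self.x == 0.0 and self.y == 0.0 and self.confidence == 0.0)


@dataclass(frozen=True)
class KeypointFrame:
    """One video frame's 25 BODY_25 keypoints, in convention order."""

    index: int
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if len(self.keypoints) != N_KEYPOINTS:
            raise FormatError(
                f"frame {self.index}: expected {N_KEYPOINTS} keypoints, got {len(self.keypoints)}"
            )


@dataclass
class TrialRecording:
    """An ordered frame sequence plus trial metadata.

    Coordinates are stored as (n_frames, 25) arrays for vectorized access;
    :meth:`frame` reconstructs individual :class:`KeypointFrame` views.
    """

    participant_id: str
    side: Side
    fps: float
    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray
    image_width: int = 1280
    image_height: int = 720
    annotated_start_frame: int | None = None
    annotated_fall_frame: int | None = None

    def __post_init__(self) -> None:
        self.side = Side.parse(self.side)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.x.shape != self.y.shape or self.x.shape != self.confidence.shape:
            raise FormatError("x, y and confidence arrays must share shape")
        if self.x.ndim != 2 or self.x.shape[1] != N_KEYPOINTS:
            raise FormatError(f"expected (n, {N_KEYPOINTS}) coordinate arrays, got {self.x.shape}")
        if self.n_frames < 2:
            raise FormatError(f"trial needs at least 2 frames, got {self.n_frames}")
        if not self.fps > 0:
            raise FormatError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def frame(self, i: int) -> KeypointFrame:
        kps = tuple(
            Keypoint(float(self.x[i, k]), float(self.y[i, k]), float(self.confidence[i, k]))
            for k in range(N_KEYPOINTS)
        )
        return KeypointFrame(index=i, keypoints=kps)

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[KeypointFrame],
        *,
        participant_id: str,
        side: Side | str,
        fps: float,
        **kwargs,
    ) -> "TrialRecording":
        n = len(frames)
        x = np.zeros((n, N_KEYPOINTS))
        y = np.zeros((n, N_KEYPOINTS))
        c = np.zeros((n, N_KEYPOINTS))
        for i, fr in enumerate(frames):
            for k, kp in enumerate(fr.keypoints):
                x[i, k], y[i, k], c[i, k] = kp.x, kp.y, kp.confidence
        return cls(
            participant_id=participant_id, side=Side.parse(side), fps=fps,
            x=x, y=y, confidence=c, **kwargs,
        )


@dataclass
class TrialIndices:
    """Per-trial scores: duration time plus the raw and standardized CV indices.

    ``spb``/``ag`` are cohort z-scores and are only defined after
    standardization across trials; the four per-keypoint moving distances are
    kept for inspection but are not part of the CSV interface.
    """

    participant_id: str
    side: Side
    dt_s: float
    d_prime: float
    a_raw: float
    spb: float = float("nan")
    ag: float = float("nan")
    d_w: float | None = None
    d_e: float | None = None
    d_a: float | None = None
    d_k: float | None = None


# ---------------------------------------------------------------------------
# OpenPose JSON dialect
# ---------------------------------------------------------------------------

def parse_openpose_frame(json_text: str, frame_index: int = 0) -> KeypointFrame:
    """Parse one OpenPose per-frame JSON document into a :class:`KeypointFrame`.

    If several people were detected, the person with the highest summed
    confidence is selected (the task records a single child; the rule keeps
    plumbing deterministic).

    Raises
    ------
    MissingPersonError
        If the ``people`` list is empty.
    FormatError
        If the document is not valid JSON or a ``pose_keypoints_2d`` list
        does not hold exactly 75 numbers.
    """
    try:
        obj = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"frame {frame_index}: invalid JSON ({exc})") from exc
    if not isinstance(obj, dict) or "people" not in obj:
        raise FormatError(f"frame {frame_index}: missing 'people' key")
    people = obj["people"]
    if not people:
        raise MissingPersonError(f"frame {frame_index}: no person detected")

    best_flat: list[float] | None = None
    best_score = -np.inf
    for person in people:
        flat = person.get("pose_keypoints_2d")
        if flat is None or len(flat) != 3 * N_KEYPOINTS:
            n = "missing" if flat is None else len(flat)
            raise FormatError(
                f"frame {frame_index}: pose_keypoints_2d must hold {3 * N_KEYPOINTS} numbers, got {n}"
            )
        score = float(sum(flat[2::3]))
        if score > best_score:
            best_score = score
            best_flat = flat

    assert best_flat is not None
    kps = tuple(
        Keypoint(float(best_flat[3 * k]), float(best_flat[3 * k + 1]), float(best_flat[3 * k + 2]))
        for k in range(N_KEYPOINTS)
    )
    return KeypointFrame(index=frame_index, keypoints=kps)


def frame_to_openpose_json(frame: KeypointFrame) -> str:
    """Serialize a frame back into the OpenPose per-frame dialect."""
    flat: list[float] = []
    for kp in frame.keypoints:
        flat.extend((kp.x, kp.y, kp.confidence))
    return json.dumps({"version": 1.4, "people": [{"pose_keypoints_2d": flat}]})


def _undetected_frame(index: int) -> KeypointFrame:
    zero = Keypoint(0.0, 0.0, 0.0)
    return KeypointFrame(index=index, keypoints=(zero,) * N_KEYPOINTS)


def load_trial(
    directory: str | Path,
    *,
    participant_id: str,
    side: Side | str,
    fps: float,
    image_width: int = 1280,
    image_height: int = 720,
    annotated_start_frame: int | None = None,
    annotated_fall_frame: int | None = None,
) -> TrialRecording:
    """Load a trial directory of per-frame OpenPose JSON files.

    Files are ordered by the zero-padded frame number embedded in the file
    name (falling back to lexicographic order), then reindexed 0..n-1 so the
    loaded frame sequence is gapless.  Frames in which no person was detected
    are retained as fully undetected frames (all confidences 0) so that
    downstream masking/interpolation treats them as gaps.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.json"))

    def sort_key(p: Path):
        m = _FRAME_RE.search(p.name)
        return (int(m.group(1)), p.name) if m else (float("inf"), p.name)

    paths = sorted(paths, key=sort_key)
    if not paths:
        raise EmptyTrialError(f"no keypoint JSON files in {directory}")

    frames: list[KeypointFrame] = []
    for i, path in enumerate(paths):
        try:
            frames.append(parse_openpose_frame(path.read_text(), frame_index=i))
        except MissingPersonError:
            frames.append(_undetected_frame(i))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc

    return TrialRecording.from_frames(
        frames,
        participant_id=participant_id,
        side=side,
        fps=fps,
        image_width=image_width,
        image_height=image_height,
        annotated_start_frame=annotated_start_frame,
        annotated_fall_frame=annotated_fall_frame,
    )


def write_trial(recording: TrialRecording, directory: str | Path, trial_name: str | None = None) -> list[Path]:
    """Write a recording as one OpenPose-dialect JSON file per frame."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = trial_name or f"{recording.participant_id}_{recording.side.value}"
    paths = []
    for i in range(recording.n_frames):
        path = directory / f"{name}_{i:012d}_keypoints.json"
        path.write_text(frame_to_openpose_json(recording.frame(i)))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# 90-degree rotation convention
# ---------------------------------------------------------------------------

def rotate_frame(
    frame: KeypointFrame,
    direction: Literal["cw90", "ccw90"],
    image_width: int,
    image_height: int,
) -> KeypointFrame:
    """Rotate keypoints by 90 degrees within the image.

    The detector performs best with the head up, so horizontal-posture video
    is rotated before detection and the keypoints rotated back afterwards.
    ``cw90`` maps (x, y) -> (H - 1 - y, x); ``ccw90`` maps
    (x, y) -> (y, W - 1 - x), where W, H are the dimensions of the image the
    coordinates *currently* live in.  The two are mutual inverses (apply
    ``ccw90`` with the rotated image's dimensions, i.e. swapped).  The
    undetected sentinel (0, 0, 0) passes through unchanged; out-of-bounds
    coordinates are passed through with a warning.
    """
    if direction not in ("cw90", "ccw90"):
        raise ValueError(f"direction must be 'cw90' or 'ccw90', got {direction!r}")
    out: list[Keypoint] = []
    for k, kp in enumerate(frame.keypoints):
        if not kp.is_detected:
            out.append(kp)
            continue
        if not (0 <= kp.x < image_width and 0 <= kp.y < image_height):
            logger.warning(
                "frame %d keypoint %d at (%g, %g) outside [0,%d)x[0,%d); passing through",
                frame.index, k, kp.x, kp.y, image_width, image_height,
            )
        if direction == "cw90":
            out.append(Keypoint(image_height - 1 - kp.y, kp.x, kp.confidence))
        else:
            out.append(Keypoint(kp.y, image_width - 1 - kp.x, kp.confidence))
    return KeypointFrame(index=frame.index, keypoints=tuple(out))


# ---------------------------------------------------------------------------
# Indices CSV
# ---------------------------------------------------------------------------

def write_indices_table(rows: Iterable[TrialIndices], path: str | Path) -> None:
    """Write per-trial indices as UTF-8 comma-separated CSV with the standard header."""
    df = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "side": r.side.value,
                "DT_s": r.dt_s,
                "D_prime": r.d_prime,
                "a_raw": r.a_raw,
                "SPB": r.spb,
                "AG": r.ag,
            }
            for r in rows
        ],
        columns=list(INDICES_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_indices_table(path: str | Path) -> list[TrialIndices]:
    """Read an indices CSV written by :func:`write_indices_table`."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if tuple(df.columns) != INDICES_COLUMNS:
        raise FormatError(
            f"{path}: malformed header {tuple(df.columns)}, expected {INDICES_COLUMNS}"
        )
    rows: list[TrialIndices] = []
    for i, rec in df.iterrows():
        try:
            rows.append(
                TrialIndices(
                    participant_id=str(rec["participant_id"]),
                    side=Side.parse(rec["side"]),
                    dt_s=float(rec["DT_s"]),
                    d_prime=float(rec["D_prime"]),
                    a_raw=float(rec["a_raw"]),
                    spb=float(rec["SPB"]),
                    ag=float(rec["AG"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return rows


def indices_to_frame(rows: Iterable[TrialIndices]) -> pd.DataFrame:
    """Tabulate indices (including the four per-keypoint distances) for analysis."""
    return pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "side": r.side.value,
            "DT": r.dt_s,
            "D_w": r.d_w,
            "D_e": r.d_e,
            "D_a": r.d_a,
            "D_k": r.d_k,
            "D_prime": r.d_prime,
            "a_raw": r.a_raw,
            "SPB": r.spb,
            "AG": r.ag,
        }
        for r in rows
    )
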