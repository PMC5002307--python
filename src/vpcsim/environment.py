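"""Arena geometry and landmark fields.

The simulated world is a rectangular arena with the origin at the
south-west corner (x east, y north). Landmarks are fixed point objects,
each carrying a recognition label (an integer id standing in for the
"what" information), a position, and a saliency value that later weights
the landmark's contribution to place-cell firing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "Landmark",
    "LandmarkField",
    "LandmarkFormatError",
    "generate_landmark_field",
    "read_landmark_csv",
    "write_landmark_csv",
]


class LandmarkFormatError(ValueError):
    """A landmark CSV violates the format or a field invariant."""


@dataclass(frozen=True)
class Arena:
    """Rectangular arena, dimensions in metres.

    Coordinate frame: origin at the south-west corner, x increases
    eastward, y increases northward. Valid positions lie in
    ``[0, width] x [0, height]`` (boundaries included).
    """

    width: float = 40.0
    height: float = 40.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"arena dimensions must be positive, got {self.width} x {self.height}"
            )

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Landmark:
    """A fixed world landmark: recognition id, position, saliency."""

    id: int
    x: float
    y: float
    saliency: float = 1.0

    def __post_init__(self) -> None:
        if not self.saliency > 0:
            raise ValueError(f"landmark {self.id}: saliency must be > 0, got {self.saliency}")


class LandmarkField:
    """An ordered collection of landmarks with distinct ids.

    Positions and saliencies are mirrored into numpy arrays for fast
    vectorised perception queries.
    """

    def __init__(self, landmarks: Sequence[Landmark] = ()):
        landmarks = tuple(landmarks)
        ids = [lm.id for lm in landmarks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate landmark ids: {dupes}")
        self.landmarks = landmarks
        self.ids = np.asarray(ids, dtype=np.int64)
        self.xs = np.asarray([lm.x for lm in landmarks], dtype=float)
        self.ys = np.asarray([lm.y for lm in landmarks], dtype=float)
        self.saliencies = np.asarray([lm.saliency for lm in landmarks], dtype=float)

    def __len__(self) -> int:
        return len(self.landmarks)

    def __iter__(self) -> Iterator[Landmark]:
        return iter(self.landmarks)

    def __getitem__(self, index: int) -> Landmark:
        return self.landmarks[index]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkField):
            return NotImplemented
        return self.landmarks == other.landmarks

    def __repr__(self) -> str:
        return f"LandmarkField(n={len(self)})"


def generate_landmark_field(
    arena: Arena,
    n: int,
    saliency_mode: str = "equal",
    seed: int | np.random.SeedSequence | None = None,
) -> LandmarkField:
    """Sample ``n`` landmarks uniformly over the arena.

    Parameters
    ----------
    arena
        The arena to populate.
    n
        Number of landmarks (>= 0).
    saliency_mode
        ``"equal"`` gives every landmark saliency 1 (the baseline study
        condition); ``"uniform_random"`` draws saliencies i.i.d. uniform
        on (0, 1] to exercise the saliency weighting nontrivially.
    seed
        Seed for the position (and saliency) sampler; identical seeds
        yield identical fields.

    Ids are assigned 0..n-1 in generation order and serve as the
    recognition labels.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if saliency_mode not in ("equal", "uniform_random"):
        raise ValueError(f"unknown saliency_mode {saliency_mode!r}")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(0.0, arena.width, size=n)
    ys = rng.uniform(0.0, arena.height, size=n)
    if saliency_mode == "equal":
        sal = np.ones(n)
    else:
        # 1 - U[0,1) lies in (0, 1]; saliency must be strictly positive
        sal = 1.0 - rng.random(n)
    return LandmarkField(
        [Landmark(i, float(xs[i]), float(ys[i]), float(sal[i])) for i in range(n)]
    )


_CSV_COLUMNS = ["id", "x", "y", "saliency"]


def write_landmark_csv(field: LandmarkField, path: str | Path) -> None:
    """Write a landmark field as CSV with header ``id,x,y,saliency``."""
    df = pd.DataFrame(
        {
            "id": field.ids,
            "x": field.xs,
            "y": field.ys,
            "saliency": field.saliencies,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_landmark_csv(path: str | Path, arena: Arena | None = None) -> LandmarkField:
    """Read a landmark field from CSV (header ``id,x,y,saliency``).

    Raises :class:`LandmarkFormatError` naming the offending row on
    duplicate ids, non-positive saliency, malformed values, or (when an
    ``arena`` is given) out-of-arena coordinates.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise LandmarkFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(df.columns) != _CSV_COLUMNS:
        raise LandmarkFormatError(
            f"{path}: expected header {','.join(_CSV_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    landmarks: list[Landmark] = []
    seen: set[int] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            lid = int(row.id)
            x, y, sal = float(row.x), float(row.y), float(row.saliency)
        except (TypeError, ValueError) as exc:
            raise LandmarkFormatError(f"{path}: row {row_no}: malformed value ({exc})") from exc
        if not np.isfinite([x, y, sal]).all():
            raise LandmarkFormatError(f"{path}: row {row_no}: non-finite value")
        if lid in seen:
            raise LandmarkFormatError(f"{path}: row {row_no}: duplicate id {lid}")
        if not sal > 0:
            raise LandmarkFormatError(f"{path}: row {row_no}: saliency must be > 0, got {sal}")
        if arena is not None and not arena.contains(x, y):
            raise LandmarkFormatError(
                f"{path}: row {row_no}: position ({x}, {y}) outside arena "
                f"[0,{arena.width}] x [0,{arena.height}]"
            )
        seen.add(lid)
        landmarks.append(Landmark(lid, x, y, sal))
    return LandmarkField(landmarks)
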