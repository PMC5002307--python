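"""Landmark perception: from vehicle pose to the current place code.

A perceived landmark carries the recognition id, saliency, allocentric
bearing (degrees clockwise from north — an absolute reference so the
place code does not depend on the vehicle's running direction), and
Euclidean distance. The place code at a time step is the set of all
landmarks currently perceived; here perception is a recognition-distance
annulus: a landmark is perceived iff its distance lies in
``[d_min, d_max]`` (closed at both ends).

The annulus rule is one provider of place codes; anything that yields a
:class:`PlaceCode` per step (e.g. an image-based landmark extractor) can
feed the downstream place-cell model unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import LandmarkField

__all__ = ["PerceivedLandmark", "PlaceCode", "bearing_to", "perceive"]


@dataclass(frozen=True)
class PerceivedLandmark:
    """One landmark as seen from the vehicle at one step."""

    id: int
    saliency: float
    bearing: float  # degrees CW from north, in [0, 360)
    distance: float  # metres


@dataclass(frozen=True)
class PlaceCode:
    """The set of perceived landmarks defining the current location.

    ``n`` (the number of perceived landmarks) and the id-keyed view are
    derived; ids are unique within a code. An empty place code is valid —
    it simply carries no location information.
    """

    entries: tuple[PerceivedLandmark, ...]
    step: int = 0
    by_id: dict[int, PerceivedLandmark] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_id = {e.id: e for e in self.entries}
        if len(by_id) != len(self.entries):
            raise ValueError("duplicate landmark ids in place code")
        object.__setattr__(self, "by_id", by_id)

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> frozenset[int]:
        return frozenset(self.by_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def bearing_to(vehicle: tuple[float, float], landmark: tuple[float, float]) -> float:
    """Bearing of the vector vehicle -> landmark, degrees CW from north.

    North (+y) is 0 deg, east (+x) is 90 deg. Raises ``ValueError`` for
    coincident positions, where the bearing is undefined.
    """
    dx = landmark[0] - vehicle[0]
    dy = landmark[1] - vehicle[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("bearing undefined: vehicle and landmark coincide")
    return math.degrees(math.atan2(dx, dy)) % 360.0


def perceive(
    vehicle: tuple[float, float],
    field: LandmarkField,
    d_min: float = 10.0,
    d_max: float = 15.0,
    step: int = 0,
) -> PlaceCode:
    """Perceive all landmarks whose distance lies in ``[d_min, d_max]``.

    Both annulus endpoints are included. Returns an (possibly empty)
    :class:`PlaceCode` with one entry per recognised landmark.
    """
    if not 0 <= d_min < d_max:
        raise ValueError(f"need 0 <= d_min < d_max, got [{d_min}, {d_max}]")
    if len(field) == 0:
        return PlaceCode((), step)
    dx = field.xs - vehicle[0]
    dy = field.ys - vehicle[1]
    dist = np.hypot(dx, dy)
    mask = (dist >= d_min) & (dist <= d_max)
    idx = np.nonzero(mask)[0]
    bearings = np.degrees(np.arctan2(dx[idx], dy[idx])) % 360.0
    entries = tuple(
        PerceivedLandmark(
            int(field.ids[i]),
            float(field.saliencies[i]),
            float(b),
            float(dist[i]),
        )
        for i, b in zip(idx, bearings)
    )
    return PlaceCode(entries, step)
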