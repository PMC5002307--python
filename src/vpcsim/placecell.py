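"""The visual-place-cell model core: firing rates and recruitment.

Each recruited place cell memorizes the place code perceived at its
recruitment step. Its firing rate at a later percept is a similarity
measure between the memorized and current codes,

    f_k = sum over matched landmarks i of
          w_i * exp(-( w_d * (d_i - d_i^k)^2 / sigma_d^2
                     + w_th * wrap(th_i - th_i^k)^2 / sigma_th^2 )),

where d_i, th_i are the landmark's current distance/bearing, d_i^k,
th_i^k the values memorized by cell k, and a landmark is "matched" when
its recognition id appears in both codes. The saliency weights

    w_i = s_i / sum_j s_j

are normalized over the *current* percept, so landmarks present now but
unknown to the cell dilute the weights and depress the rate — scene
change is penalized even when the matched landmarks line up perfectly.
(A ``matched``-only normalization is available for sensitivity
analysis.) Bearing differences are wrapped to [-180, 180] degrees before
squaring, so a small physical rotation across north stays small.

sigma_d^2 (m^2) and sigma_th^2 (deg^2) set how fast the rate decays with
distance and bearing mismatch — larger values widen the firing fields.
The binary indicators w_d, w_th switch either term off entirely.

Recruitment: at each percept all cells fire, the winner (maximal rate,
ties to the lowest cell id) is compared with the firing-rate threshold
(FRT); if the winner is strictly below FRT — or no cell exists yet — the
current place code is memorized by a new cell. Empty percepts never
recruit. A freshly recruited cell fires at exactly 1 on its own percept,
so after every processed nonempty percept the winner rate is >= FRT:
recruitment closes every coverage gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .perception import PlaceCode

__all__ = [
    "FiringParams",
    "PlaceCell",
    "Population",
    "WEIGHT_NORMALIZATIONS",
    "wrap_angle_deg",
    "landmark_weights",
    "match_landmarks",
    "firing_rate",
    "evaluate_population",
    "maybe_recruit",
]

WEIGHT_NORMALIZATIONS = ("current", "matched")


@dataclass(frozen=True)
class FiringParams:
    """Similarity-measure parameters.

    sigma_d2
        Distance adjustment factor of the firing field, m^2 (> 0).
    sigma_theta2
        Bearing adjustment factor, squared degrees (> 0). 100 deg^2
        corresponds to a 10-degree angular tuning width.
    w_d, w_theta
        {0,1} indicators selecting whether distance / bearing enter the
        similarity measure.
    frt
        Firing-rate threshold in [0, 1]: a new cell is recruited when the
        winning rate falls strictly below it.
    """

    sigma_d2: float = 25.0
    sigma_theta2: float = 100.0
    w_d: int = 1
    w_theta: int = 1
    frt: float = 0.2

    def __post_init__(self) -> None:
        if not self.sigma_d2 > 0:
            raise ValueError(f"sigma_d2 must be > 0, got {self.sigma_d2}")
        if not self.sigma_theta2 > 0:
            raise ValueError(f"sigma_theta2 must be > 0, got {self.sigma_theta2}")
        if self.w_d not in (0, 1) or self.w_theta not in (0, 1):
            raise ValueError(f"w_d and w_theta must be 0 or 1, got {self.w_d}, {self.w_theta}")
        if not 0.0 <= self.frt <= 1.0:
            raise ValueError(f"frt must be in [0, 1], got {self.frt}")


@dataclass(frozen=True)
class PlaceCell:
    """A recruited cell: the place code memorized at recruitment."""

    cell_id: int
    code: PlaceCode
    recruited_at: int


def wrap_angle_deg(delta: float) -> float:
    """Wrap an angle difference (degrees) into [-180, 180]."""
    return (delta + 180.0) % 360.0 - 180.0


def landmark_weights(code: PlaceCode) -> dict[int, float]:
    """Saliency weights w_i = s_i / sum(s_j) over all landmarks in ``code``.

    An empty code yields an empty map. Weights are positive and sum to 1.
    """
    if code.n == 0:
        return {}
    total = sum(e.saliency for e in code)
    if not total > 0:
        raise ValueError("total saliency must be > 0")
    return {e.id: e.saliency / total for e in code}


def match_landmarks(cell: PlaceCell, current: PlaceCode) -> frozenset[int]:
    """Ids present in both the memorized and the current place code."""
    return cell.code.ids & current.ids


def firing_rate(
    cell: PlaceCell,
    current: PlaceCode,
    params: FiringParams,
    weight_normalization: str = "current",
) -> float:
    """Evaluate the similarity-measure firing rate of one cell.

    The sum runs over matched landmarks only; with no match the rate is
    0. Rates lie in [0, 1]: the weights over the matched subset sum to at
    most 1 and each Gaussian factor is at most 1.
    """
    if weight_normalization not in WEIGHT_NORMALIZATIONS:
        raise ValueError(f"unknown weight_normalization {weight_normalization!r}")
    stored = cell.code.by_id
    matched = [e for e in current if e.id in stored]
    if not matched:
        return 0.0
    if weight_normalization == "current":
        total = sum(e.saliency for e in current)
    else:
        total = sum(e.saliency for e in matched)
    rate = 0.0
    for e in matched:
        mem = stored[e.id]
        expo = 0.0
        if params.w_d:
            dd = e.distance - mem.distance
            expo += dd * dd / params.sigma_d2
        if params.w_theta:
            dth = wrap_angle_deg(e.bearing - mem.bearing)
            expo += dth * dth / params.sigma_theta2
        rate += (e.saliency / total) * math.exp(-expo)
    return rate


@dataclass
class Population:
    """The ordered collection of recruited cells plus firing parameters."""

    params: FiringParams = field(default_factory=FiringParams)
    weight_normalization: str = "current"
    cells: list[PlaceCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.weight_normalization not in WEIGHT_NORMALIZATIONS:
            raise ValueError(f"unknown weight_normalization {self.weight_normalization!r}")

    def __len__(self) -> int:
        return len(self.cells)

    def recruit(self, code: PlaceCode, step: int) -> PlaceCell:
        """Append a new cell memorizing ``code`` (ids in recruitment order)."""
        cell = PlaceCell(len(self.cells), code, step)
        self.cells.append(cell)
        return cell


def evaluate_population(
    pop: Population, current: PlaceCode
) -> tuple[np.ndarray, int | None]:
    """Firing rates of every cell at the current percept, and the winner.

    The winner is the cell with the maximal rate (ties broken toward the
    lowest cell id, which is how ``argmax`` resolves them); ``None`` for
    an empty population.
    """
    rates = np.array(
        [firing_rate(c, current, pop.params, pop.weight_normalization) for c in pop.cells]
    )
    if rates.size == 0:
        return rates, None
    return rates, int(np.argmax(rates))


def maybe_recruit(pop: Population, current: PlaceCode) -> tuple[bool, float]:
    """Apply the winner-take-all / threshold recruitment rule in place.

    Returns ``(recruited, winner_rate)`` where ``winner_rate`` is the
    best rate *before* any recruitment (0.0 for an empty population).
    Recruitment happens when the percept is nonempty and either no cell
    exists or the winner is strictly below FRT.
    """
    rates, winner = evaluate_population(pop, current)
    winner_rate = float(rates[winner]) if winner is not None else 0.0
    if current.n == 0:
        return False, winner_rate
    if winner is None or winner_rate < pop.params.frt:
        pop.recruit(current, current.step)
        return True, winner_rate
    return False, winner_rate
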