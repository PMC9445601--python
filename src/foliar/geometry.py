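"""Leaf and shoot geometry: domain types and the foliage-dimension mapping.

A *shoot* is a single current-year stem with all its leaves (for
single-stemmed herbs, the whole above-ground ramet).  Its *foliage* is the
set of leaf laminas conceptually detached and laid side by side, which gives
two collective dimensions that do not depend on the 3-D arrangement:

* foliage length ``L_f`` — the sum of individual lamina widths, and
* foliage width ``W_f`` — the maximum individual lamina length.

Total shoot leaf area ``A_shoot`` is the sum of individual lamina areas.
Individual lamina area, when not measured directly, is estimated from the
Montgomery relation ``A_leaf = c * L_leaf * W_leaf`` with a species-specific
coefficient ``c``.

All lengths are in cm and areas in cm²; there is no unit-conversion layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "Leaf",
    "Shoot",
    "FoliageDims",
    "AreaPolicy",
    "MEASURED",
    "montgomery_area",
    "foliage_dims",
]


def _require_positive(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise InvalidInputError(f"{name} must be a positive finite number, got {value!r}")
    return value


def montgomery_area(length: float, width: float, coefficient: float) -> float:
    """Individual lamina area from the Montgomery relation ``c * L * W``.

    Parameters
    ----------
    length, width : float
        Lamina length and maximum lamina width, cm.  Length runs from the
        lamina tip to the petiole junction; width is measured perpendicular
        to the midvein.  There is no requirement that length >= width.
    coefficient : float
        Dimensionless species-specific proportionality constant, e.g.
        0.7169 for *Cardiocrinum cordatum*.

    Returns
    -------
    float
        One-sided lamina area, cm².
    """
    length = _require_positive(length, "length")
    width = _require_positive(width, "width")
    coefficient = _require_positive(coefficient, "coefficient")
    return coefficient * length * width


@dataclass(frozen=True, slots=True)
class Leaf:
    """One lamina: length (cm), width (cm) and optional one-sided area (cm²)."""

    length: float
    width: float
    area: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive(self.length, "length")
        _require_positive(self.width, "width")
        if self.area is not None:
            _require_positive(self.area, "area")


@dataclass(frozen=True)
class Shoot:
    """An identified collection of >= 1 leaves from one species."""

    shoot_id: str
    species: str
    leaves: tuple[Leaf, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        if len(self.leaves) < 1:
            raise InvalidInputError(
                f"shoot {self.shoot_id!r}: a shoot must carry at least one leaf"
            )

    @property
    def n(self) -> int:
        return len(self.leaves)


@dataclass(frozen=True)
class AreaPolicy:
    """How individual leaf areas are obtained.

    ``measured`` uses each leaf's recorded area (all leaves must carry one);
    ``montgomery(c)`` estimates every leaf's area as ``c * length * width``,
    the workflow used for species whose leaves are measured in situ rather
    than scanned.
    """

    kind: str = "measured"
    coefficient: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("measured", "montgomery"):
            raise InvalidInputError(f"unknown area policy kind {self.kind!r}")
        if self.kind == "montgomery":
            if self.coefficient is None:
                raise InvalidInputError("montgomery policy requires a coefficient")
            _require_positive(self.coefficient, "coefficient")
        elif self.coefficient is not None:
            raise InvalidInputError("measured policy takes no coefficient")

    @classmethod
    def measured(cls) -> "AreaPolicy":
        return cls("measured")

    @classmethod
    def montgomery(cls, coefficient: float) -> "AreaPolicy":
        return cls("montgomery", float(coefficient))


MEASURED = AreaPolicy.measured()


@dataclass(frozen=True)
class FoliageDims:
    """Per-shoot derived quantities.

    ``l_f``
        Foliage length, the sum of lamina widths (cm).
    ``w_f``
        Foliage width, the maximum lamina length (cm).
    ``a_shoot``
        Total leaf area, the sum of lamina areas (cm²).
    ``n``
        Leaf count.
    ``a_leaf_min``, ``a_leaf_max``
        Smallest and largest individual lamina area on the shoot (cm²).
    ``w_leaf_max``
        Maximum lamina width on the shoot (cm).

    For a single-leaf shoot the foliage dimensions collapse onto the leaf's
    own: ``l_f`` equals that leaf's width and ``w_f`` its length.
    """

    l_f: float
    w_f: float
    a_shoot: float
    n: int
    a_leaf_min: float
    a_leaf_max: float
    w_leaf_max: float
    shoot_id: str = field(default="", compare=False)


def _leaf_areas(shoot: Shoot, area_policy: AreaPolicy) -> np.ndarray:
    if area_policy.kind == "montgomery":
        c = float(area_policy.coefficient)  # type: ignore[arg-type]
        return np.array([c * lf.length * lf.width for lf in shoot.leaves])
    missing = [i for i, lf in enumerate(shoot.leaves) if lf.area is None]
    if missing:
        raise InvalidInputError(
            f"shoot {shoot.shoot_id!r}: measured area policy but leaves at "
            f"indices {missing} have no recorded area"
        )
    return np.array([lf.area for lf in shoot.leaves], dtype=float)


def foliage_dims(shoot: Shoot, area_policy: AreaPolicy = MEASURED) -> FoliageDims:
    """Collapse a shoot's leaves into its foliage dimensions.

    The result is invariant to leaf order; ties for the longest leaf are
    resolved on values (which leaf attains the maximum is never needed).
    """
    lengths = np.array([lf.length for lf in shoot.leaves])
    widths = np.array([lf.width for lf in shoot.leaves])
    areas = _leaf_areas(shoot, area_policy)
    return FoliageDims(
        l_f=float(widths.sum()),
        w_f=float(lengths.max()),
        a_shoot=float(areas.sum()),
        n=shoot.n,
        a_leaf_min=float(areas.min()),
        a_leaf_max=float(areas.max()),
        w_leaf_max=float(widths.max()),
        shoot_id=shoot.shoot_id,
    )


def fill_areas(shoot: Shoot, area_policy: AreaPolicy = MEASURED) -> Shoot:
    """Return a shoot whose every leaf carries an area, per the policy.

    Under the measured policy this validates that areas are present; under
    the Montgomery policy every area is (re)computed from the leaf's own
    length and width.
    """
    areas = _leaf_areas(shoot, area_policy)
    leaves = tuple(
        Leaf(lf.length, lf.width, float(a)) for lf, a in zip(shoot.leaves, areas)
    )
    return Shoot(shoot.shoot_id, shoot.species, leaves)
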