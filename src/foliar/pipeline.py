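"""Per-species analysis: leaf table -> foliage dimensions -> all line fits.

The relationships fitted per species, with the scale and method set each is
conventionally reported with:

====================  ===========================================  ======  =========
relation              y ~ x                                        scale   methods
====================  ===========================================  ======  =========
R_LW_AREA             A_shoot ~ L_f * W_f                          linear  OLS
R_WF                  A_shoot ~ W_f                                log10   OLS, SMA
R_MAXW                A_shoot ~ max leaf width                     log10   OLS, SMA
R_BETA                L_f ~ W_f  (slope is β)                      log10   SMA
R_ALPHA               A_shoot ~ N  (SMA slope is α)                log10   OLS, SMA
R_SUN                 A_shoot ~ N * max leaf area                  linear  OLS
R_GAMMA               A_shoot / W_f ~ N  (SMA slope is γ)          log10   OLS, SMA
R_LOPES               A_shoot ~ N * (min + max leaf area)/2        linear  OLS
R_MONTGOMERY          A_leaf ~ L_leaf * W_leaf  (leaf level)       linear  OLS
====================  ===========================================  ======  =========

``min_n_filter`` optionally drops shoots with few leaves from the
shoot-level fits: shoots in the N <= 3 region are dominated by one or a few
leaves and deviate visibly from the size–number regression line.  The
default keeps every shoot.  The leaf-level Montgomery fit always uses all
leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .allometry import FitResult, log10_pairs, ols_fit, sma_fit
from .exceptions import InsufficientDataError, InvalidInputError
from .geometry import (
    MEASURED,
    AreaPolicy,
    FoliageDims,
    Leaf,
    Shoot,
    fill_areas,
    foliage_dims,
)
from .relations import ConsistencyReport, ExponentSet, exponent_consistency

__all__ = [
    "RelationId",
    "RelationResult",
    "SpeciesReport",
    "compute_dataset",
    "fit_all_relations",
    "analyze_species",
    "SpeciesAllometry",
]


class RelationId(str, Enum):
    R_LW_AREA = "R_LW_AREA"
    R_WF = "R_WF"
    R_MAXW = "R_MAXW"
    R_BETA = "R_BETA"
    R_ALPHA = "R_ALPHA"
    R_SUN = "R_SUN"
    R_GAMMA = "R_GAMMA"
    R_LOPES = "R_LOPES"
    R_MONTGOMERY = "R_MONTGOMERY"


# method set, scale and variable construction for each relation
_SPEC = {
    RelationId.R_LW_AREA: (("OLS",), "linear", "L_f * W_f", "A_shoot"),
    RelationId.R_WF: (("OLS", "SMA"), "log10", "log10(W_f)", "log10(A_shoot)"),
    RelationId.R_MAXW: (("OLS", "SMA"), "log10", "log10(max W_leaf)", "log10(A_shoot)"),
    RelationId.R_BETA: (("SMA",), "log10", "log10(W_f)", "log10(L_f)"),
    RelationId.R_ALPHA: (("OLS", "SMA"), "log10", "log10(N)", "log10(A_shoot)"),
    RelationId.R_SUN: (("OLS",), "linear", "N * max A_leaf", "A_shoot"),
    RelationId.R_GAMMA: (("OLS", "SMA"), "log10", "log10(N)", "log10(A_shoot / W_f)"),
    RelationId.R_LOPES: (("OLS",), "linear", "N * (min A_leaf + max A_leaf)/2", "A_shoot"),
    RelationId.R_MONTGOMERY: (("OLS",), "linear", "L_leaf * W_leaf", "A_leaf"),
}


@dataclass(frozen=True)
class RelationResult:
    """OLS and/or SMA fit of one relationship, with its own sample size."""

    relation: RelationId
    ols: Optional[FitResult]
    sma: Optional[FitResult]
    x_desc: str
    y_desc: str
    n: int

    def fits(self) -> Dict[str, FitResult]:
        out = {}
        if self.ols is not None:
            out["OLS"] = self.ols
        if self.sma is not None:
            out["SMA"] = self.sma
        return out


@dataclass(frozen=True)
class SpeciesReport:
    """Everything the per-species analysis produces."""

    species: str
    relations: Dict[RelationId, RelationResult]
    lambda_fit: FitResult
    exponents: ExponentSet
    consistency: ConsistencyReport
    a_shoot_range: tuple
    n_range: tuple
    n_shoots: int


def compute_dataset(
    shoots: Sequence[Shoot], area_policy: AreaPolicy = MEASURED
) -> List[FoliageDims]:
    """Foliage dimensions for each shoot of one species, order preserved."""
    shoots = list(shoots)
    if not shoots:
        raise InvalidInputError("empty shoot collection")
    species = {s.species for s in shoots}
    if len(species) > 1:
        raise InvalidInputError(
            f"shoots must share one species, got {sorted(species)}"
        )
    return [foliage_dims(s, area_policy) for s in shoots]


def _fit_relation(rel: RelationId, x: np.ndarray, y: np.ndarray, n: int) -> RelationResult:
    methods, scale, x_desc, y_desc = _SPEC[rel]
    if n < 3:
        raise InsufficientDataError(
            f"relation {rel.value}: need at least 3 usable observations, got {n}"
        )
    if scale == "log10":
        x, y = log10_pairs(x, y)
    ols = ols_fit(x, y, scale=scale) if "OLS" in methods else None
    sma = sma_fit(x, y, scale=scale) if "SMA" in methods else None
    return RelationResult(rel, ols, sma, x_desc, y_desc, n)


def fit_all_relations(
    dims: Sequence[FoliageDims],
    leaves: Sequence[Leaf],
    min_n_filter: int = 1,
) -> Dict[RelationId, RelationResult]:
    """Fit every relationship on one species' shoots and leaves.

    Shoots with fewer than ``min_n_filter`` leaves are excluded from the
    shoot-level fits only; the leaf-level Montgomery fit always uses every
    leaf (leaves must carry areas — apply an area policy upstream).
    """
    if min_n_filter < 1:
        raise InvalidInputError(f"min_n_filter must be >= 1, got {min_n_filter}")
    dims = list(dims)
    kept = [d for d in dims if d.n >= min_n_filter]
    l_f = np.array([d.l_f for d in kept])
    w_f = np.array([d.w_f for d in kept])
    a = np.array([d.a_shoot for d in kept])
    n_leaves = np.array([d.n for d in kept], dtype=float)
    w_leaf_max = np.array([d.w_leaf_max for d in kept])
    a_min = np.array([d.a_leaf_min for d in kept])
    a_max = np.array([d.a_leaf_max for d in kept])
    ns = len(kept)

    leaves = list(leaves)
    missing = [i for i, lf in enumerate(leaves) if lf.area is None]
    if missing:
        raise InvalidInputError(
            f"leaf-level fit needs areas; leaves at indices {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''} have none"
        )
    leaf_lw = np.array([lf.length * lf.width for lf in leaves])
    leaf_a = np.array([lf.area for lf in leaves])

    results = {}
    shoot_xy = {
        RelationId.R_LW_AREA: (l_f * w_f, a),
        RelationId.R_WF: (w_f, a),
        RelationId.R_MAXW: (w_leaf_max, a),
        RelationId.R_BETA: (w_f, l_f),
        RelationId.R_ALPHA: (n_leaves, a),
        RelationId.R_SUN: (n_leaves * a_max, a),
        RelationId.R_GAMMA: (n_leaves, a / w_f),
        RelationId.R_LOPES: (n_leaves * (a_min + a_max) / 2.0, a),
    }
    for rel, (x, y) in shoot_xy.items():
        results[rel] = _fit_relation(rel, x, y, ns)
    results[RelationId.R_MONTGOMERY] = _fit_relation(
        RelationId.R_MONTGOMERY, leaf_lw, leaf_a, len(leaves)
    )
    return results


def analyze_species(
    shoots: Sequence[Shoot],
    area_policy: AreaPolicy = MEASURED,
    min_n_filter: int = 1,
) -> SpeciesReport:
    """Full per-species analysis.

    Composes :func:`compute_dataset`, :func:`fit_all_relations`, the
    mean-leaf-area fit (SMA of log10(A_shoot/N) on log10(A_shoot), whose
    slope is λ) and the exponent-consistency report.  The fitted exponent
    set takes β from the foliage length–width SMA slope, α from the
    size–number SMA slope, γ from the Heerema–Spann–Teobaldelli SMA slope
    and k from the Lopes–Pinto OLS slope.
    """
    shoots = [fill_areas(s, area_policy) for s in shoots]
    dims = compute_dataset(shoots, MEASURED)
    leaves = [lf for s in shoots for lf in s.leaves]
    relations = fit_all_relations(dims, leaves, min_n_filter=min_n_filter)

    kept = [d for d in dims if d.n >= min_n_filter]
    a = np.array([d.a_shoot for d in kept])
    n_leaves = np.array([d.n for d in kept], dtype=float)
    lx, ly = log10_pairs(a, a / n_leaves)
    lambda_fit = sma_fit(lx, ly, scale="log10")

    beta_fit = relations[RelationId.R_BETA].sma
    alpha_fit = relations[RelationId.R_ALPHA].sma
    gamma_fit = relations[RelationId.R_GAMMA].sma
    k_fit = relations[RelationId.R_LOPES].ols
    exponents = ExponentSet(
        beta=beta_fit.slope,
        alpha=alpha_fit.slope,
        gamma=gamma_fit.slope,
        lambda_=lambda_fit.slope,
        k=k_fit.slope,
        provenance={f: "fitted" for f in ("beta", "alpha", "gamma", "lambda_", "k")},
    )
    consistency = exponent_consistency(beta_fit, alpha_fit, gamma_fit, lambda_fit)

    a_all = [d.a_shoot for d in dims]
    n_all = [d.n for d in dims]
    return SpeciesReport(
        species=shoots[0].species,
        relations=relations,
        lambda_fit=lambda_fit,
        exponents=exponents,
        consistency=consistency,
        a_shoot_range=(min(a_all), max(a_all)),
        n_range=(min(n_all), max(n_all)),
        n_shoots=len(dims),
    )


class SpeciesAllometry(BaseEstimator):
    """Per-species shoot-allometry analysis as an sklearn-style estimator.

    Parameters
    ----------
    area_policy : AreaPolicy
        How leaf areas are obtained (measured, or Montgomery with a
        coefficient).
    min_n_filter : int
        Minimum leaf count for a shoot to enter the shoot-level fits.

    After :meth:`fit`, the report is available as ``report_`` and its parts
    as ``dims_``, ``relations_``, ``exponents_`` and ``consistency_``.
    """

    def __init__(self, area_policy: AreaPolicy = MEASURED, min_n_filter: int = 1):
        self.area_policy = area_policy
        self.min_n_filter = min_n_filter

    def fit(self, shoots: Sequence[Shoot], y=None) -> "SpeciesAllometry":
        report = analyze_species(
            shoots, area_policy=self.area_policy, min_n_filter=self.min_n_filter
        )
        self.report_ = report
        self.dims_ = compute_dataset(
            [fill_areas(s, self.area_policy) for s in shoots], MEASURED
        )
        self.relations_ = report.relations
        self.exponents_ = report.exponents
        self.consistency_ = report.consistency
        return self
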