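"""Leaf-table CSV reading/writing and species-report serialization.

The leaf table is a flat CSV with the fixed header
``species,shoot_id,leaf_id,length_cm,width_cm,area_cm2`` (UTF-8, '.'
decimal separator).  One row per leaf; ``area_cm2`` may be blank only when
the analysis will fill areas from the Montgomery relation.  Units are
embedded in the column names to prevent silent unit errors.

Reports are written either as JSON (the full nested report, including the
exponent-consistency checks) or as a flat CSV with one row per
(relation, method) — the conventional regression-table layout.  Numbers in
reports are serialized with 6 significant digits.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .allometry import FitResult
from .exceptions import FormatError, InvalidInputError
from .geometry import MEASURED, AreaPolicy, Leaf, Shoot
from .pipeline import RelationId, SpeciesReport

__all__ = [
    "LEAF_TABLE_HEADER",
    "read_leaf_table",
    "write_leaf_table",
    "write_species_report",
    "report_to_dict",
]

LEAF_TABLE_HEADER = ["species", "shoot_id", "leaf_id", "length_cm", "width_cm", "area_cm2"]


def _sig6(value: float) -> float:
    return float(f"{value:.6g}")


def _parse_positive(raw: str, column: str, line_no: int) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise FormatError(
            f"line {line_no}: column {column!r} is not numeric: {raw!r}"
        ) from None
    if not math.isfinite(value) or value <= 0.0:
        raise FormatError(
            f"line {line_no}: column {column!r} must be positive, got {raw!r}"
        )
    return value


def read_leaf_table(path, area_policy: AreaPolicy = MEASURED) -> List[Shoot]:
    """Read a leaf table, grouping rows into shoots by (species, shoot_id).

    Row order is preserved within shoots and shoot order follows first
    appearance.  Blank ``area_cm2`` cells are permitted only under a
    Montgomery area policy.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != LEAF_TABLE_HEADER:
        raise FormatError(
            f"unexpected header {list(df.columns)}; expected exactly "
            f"{LEAF_TABLE_HEADER}"
        )
    if df.empty:
        raise FormatError("leaf table contains no data rows")

    seen: set = set()
    groups: Dict[Tuple[str, str], List[Leaf]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        species, shoot_id, leaf_id, length_s, width_s, area_s = row
        key = (species, shoot_id, leaf_id)
        if key in seen:
            raise FormatError(
                f"line {line_no}: duplicate (species, shoot_id, leaf_id) = {key}"
            )
        seen.add(key)
        length = _parse_positive(length_s, "length_cm", line_no)
        width = _parse_positive(width_s, "width_cm", line_no)
        area: Optional[float]
        if area_s.strip() == "":
            if area_policy.kind != "montgomery":
                raise FormatError(
                    f"line {line_no}: blank area_cm2 requires a montgomery area policy"
                )
            area = None
        else:
            area = _parse_positive(area_s, "area_cm2", line_no)
        groups.setdefault((species, shoot_id), []).append(Leaf(length, width, area))

    return [
        Shoot(shoot_id=shoot_id, species=species, leaves=tuple(leaves))
        for (species, shoot_id), leaves in groups.items()
    ]


def write_leaf_table(shoots: Sequence[Shoot], path) -> None:
    """Write shoots to the leaf-table CSV.

    Floats are written with ``repr`` (shortest round-tripping form), so a
    read-back reproduces every numeric field exactly.
    """
    shoots = list(shoots)
    if not shoots:
        raise InvalidInputError("refusing to write an empty leaf table")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LEAF_TABLE_HEADER)
        for shoot in shoots:
            for j, leaf in enumerate(shoot.leaves):
                writer.writerow(
                    [
                        shoot.species,
                        shoot.shoot_id,
                        f"L{j:03d}",
                        repr(float(leaf.length)),
                        repr(float(leaf.width)),
                        "" if leaf.area is None else repr(float(leaf.area)),
                    ]
                )


def _fit_to_dict(fit: FitResult) -> dict:
    return {
        "slope": _sig6(fit.slope),
        "intercept": _sig6(fit.intercept),
        "r2": _sig6(fit.r2),
        "n": fit.n,
        "method": fit.method,
        "scale": fit.scale,
        "slope_ci": [_sig6(fit.slope_ci[0]), _sig6(fit.slope_ci[1])],
        "p_value": _sig6(fit.p_value),
    }


def report_to_dict(report: SpeciesReport) -> dict:
    """Full nested report as plain JSON-serializable data."""
    relations = {}
    for rel, res in report.relations.items():
        relations[rel.value] = {
            "x": res.x_desc,
            "y": res.y_desc,
            "n": res.n,
            "fits": {m: _fit_to_dict(f) for m, f in res.fits().items()},
        }
    exps = report.exponents
    consistency = {
        "beta_fitted": _sig6(report.consistency.beta_fitted),
        "overall_pass": report.consistency.overall_pass,
        "checks": {
            name: {
                "fitted": _sig6(c.fitted),
                "ci": [_sig6(c.ci[0]), _sig6(c.ci[1])],
                "predicted": None if c.predicted is None else _sig6(c.predicted),
                "inside_ci": c.inside_ci,
            }
            for name, c in report.consistency.checks.items()
        },
    }
    return {
        "species": report.species,
        "n_shoots": report.n_shoots,
        "a_shoot_range_cm2": [_sig6(v) for v in report.a_shoot_range],
        "n_range": list(report.n_range),
        "relations": relations,
        "lambda_fit": _fit_to_dict(report.lambda_fit),
        "exponents": {
            "beta": _sig6(exps.beta),
            "alpha": _sig6(exps.alpha),
            "gamma": _sig6(exps.gamma),
            "lambda": _sig6(exps.lambda_),
            "k": None if exps.k is None else _sig6(exps.k),
            "provenance": exps.provenance,
        },
        "consistency": consistency,
    }


def write_species_report(report: SpeciesReport, path, format: str = "json") -> None:
    """Serialize a species report.

    ``json`` nests the full report; ``csv`` emits one row per
    (relation, method) with columns
    ``relation,method,scale,a,b,r2,n,ci_low,ci_high``.
    """
    if report is None or not report.relations:
        raise InvalidInputError("empty report")
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(
                ["relation", "method", "scale", "a", "b", "r2", "n", "ci_low", "ci_high"]
            )
            for rel in RelationId:
                res = report.relations.get(rel)
                if res is None:
                    continue
                for method, fit in res.fits().items():
                    writer.writerow(
                        [
                            rel.value,
                            method,
                            fit.scale,
                            f"{fit.intercept:.6g}",
                            f"{fit.slope:.6g}",
                            f"{fit.r2:.6g}",
                            fit.n,
                            f"{fit.slope_ci[0]:.6g}",
                            f"{fit.slope_ci[1]:.6g}",
                        ]
                    )
    else:
        raise InvalidInputError(f"unknown report format {format!r}")
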