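"""Closed-form algebra linking the within-species scaling exponents.

If foliage length scales as foliage width to the power β (> 1), the model
fixes every other exponent:

* size–number allometry:      A_shoot ∝ N**α   with  α = (β + 1)/(β − 1)
* Heerema–Spann–Teobaldelli:  A_shoot/W_f ∝ N**γ  with  γ = β/(β − 1)
* mean-leaf-area scaling:     A_shoot/N ∝ A_shoot**λ  with  λ = 2/(β + 1)

so α = 2γ − 1 and λ = 1 − 1/α, and all three are strictly decreasing in β.
The map β ↦ α is an involution: applying it twice returns β.

:func:`exponent_consistency` turns these identities into a report comparing
exponents fitted from data against the values predicted from the fitted β,
using confidence-interval inclusion.  It is a report, not an assertion —
field data may well place a fitted exponent outside the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .allometry import FitResult
from .exceptions import InvalidInputError

__all__ = [
    "alpha_from_beta",
    "gamma_from_beta",
    "lambda_from_beta",
    "predicted_exponents",
    "ExponentSet",
    "ExponentCheck",
    "ConsistencyReport",
    "exponent_consistency",
]


def _check_beta(beta: float) -> float:
    beta = float(beta)
    if not beta > 1.0:
        raise InvalidInputError(f"beta must exceed 1 (got {beta}); the exponent algebra diverges at beta = 1")
    return beta


def alpha_from_beta(beta: float) -> float:
    """Size–number exponent α = (β + 1)/(β − 1); > 1 whenever β > 1."""
    beta = _check_beta(beta)
    return (beta + 1.0) / (beta - 1.0)


def gamma_from_beta(beta: float) -> float:
    """Heerema–Spann–Teobaldelli exponent γ = β/(β − 1); > 1 whenever β > 1."""
    beta = _check_beta(beta)
    return beta / (beta - 1.0)


def lambda_from_beta(beta: float) -> float:
    """Mean-leaf-area exponent λ = 2/(β + 1), strictly in (0, 1) for β > 1."""
    beta = _check_beta(beta)
    return 2.0 / (beta + 1.0)


@dataclass(frozen=True)
class ExponentSet:
    """The scaling exponents β, α, γ, λ and the Lopes–Pinto constant k.

    ``provenance`` maps each field name to either ``"fitted"`` or
    ``"predicted_from_beta"``.
    """

    beta: float
    alpha: float
    gamma: float
    lambda_: float
    k: Optional[float] = None
    provenance: Dict[str, str] = field(default_factory=dict)


def predicted_exponents(beta: float) -> ExponentSet:
    """All exponents implied by a common β > 1."""
    beta = _check_beta(beta)
    return ExponentSet(
        beta=beta,
        alpha=alpha_from_beta(beta),
        gamma=gamma_from_beta(beta),
        lambda_=lambda_from_beta(beta),
        k=None,
        provenance={
            "beta": "fitted",
            "alpha": "predicted_from_beta",
            "gamma": "predicted_from_beta",
            "lambda_": "predicted_from_beta",
        },
    )


@dataclass(frozen=True)
class ExponentCheck:
    """One fitted-vs-predicted comparison."""

    name: str
    fitted: float
    ci: tuple
    predicted: Optional[float]
    inside_ci: bool


@dataclass(frozen=True)
class ConsistencyReport:
    """Fitted exponents against the predictions from the fitted β.

    ``overall_pass`` is true only if every predicted value lies inside the
    corresponding fitted 95 % confidence interval.  When the fitted β does
    not exceed 1 the predictions are undefined and the report fails.
    """

    beta_fitted: float
    checks: Dict[str, ExponentCheck]
    overall_pass: bool


def exponent_consistency(
    beta_fit: FitResult,
    alpha_fit: FitResult,
    gamma_fit: FitResult,
    lambda_fit: Optional[FitResult] = None,
) -> ConsistencyReport:
    """Compare fitted α, γ (and optionally λ) with predictions from fitted β.

    A predicted value counts as consistent when it falls inside the fitted
    exponent's 95 % confidence interval.
    """
    beta = float(beta_fit.slope)
    fits = {"alpha": alpha_fit, "gamma": gamma_fit}
    if lambda_fit is not None:
        fits["lambda_"] = lambda_fit

    if beta <= 1.0:
        checks = {
            name: ExponentCheck(name, float(f.slope), tuple(f.slope_ci), None, False)
            for name, f in fits.items()
        }
        return ConsistencyReport(beta_fitted=beta, checks=checks, overall_pass=False)

    predictors = {
        "alpha": alpha_from_beta,
        "gamma": gamma_from_beta,
        "lambda_": lambda_from_beta,
    }
    checks = {}
    for name, f in fits.items():
        predicted = predictors[name](beta)
        lo, hi = f.slope_ci
        checks[name] = ExponentCheck(
            name=name,
            fitted=float(f.slope),
            ci=(float(lo), float(hi)),
            predicted=predicted,
            inside_ci=bool(lo <= predicted <= hi),
        )
    return ConsistencyReport(
        beta_fitted=beta,
        checks=checks,
        overall_pass=all(c.inside_ci for c in checks.values()),
    )
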