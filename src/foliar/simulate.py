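"""Synthetic shoot generator under the affine foliage model.

No field measurements accompany the model, so validation is by parameter
recovery: shoots are simulated under the model's own assumptions with known
exponents, the analysis pipeline is run, and the fitted exponents are
compared with the ground truth.

Construction for shoot *i*:

1. Draw a size scale ``W*_i`` (the largest leaf's length, cm) from a
   log-normal: ``log10 W* ~ Normal(wf_log10_mean, wf_log10_sd)``.
2. Leaf count ``N_i = max(1, round(n0 * W*_i**(beta_true - 1)))`` — leafing
   intensity ``n0`` sets how many leaves a shoot of given size carries, and
   the exponent makes the foliage length–width power law hold by design.
3. Within-shoot size profile: leaf *j* (largest first) has a relative size
   from a linear ramp down to a floor — either linear in length
   (``linear_length(f_min)``) or linear in area (``linear_area(g_min)``).
4. Leaf lengths ``L_j = W* * profile_j * noise``; widths ``W_j = L_j /
   aspect_ratio * noise`` (a species-constant length-to-width ratio); areas
   from the Montgomery relation ``A_j = c * L_j * W_j``.  Noise is
   multiplicative log-normal (``10**Normal(0, noise_sigma_log10)`` per
   dimension), keeping every dimension positive.

Foliage dimensions are then computed from the *realized* leaves, so their
defining identities hold exactly even under noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

from .exceptions import InvalidInputError
from .geometry import Leaf, Shoot
from .relations import alpha_from_beta, gamma_from_beta, lambda_from_beta

__all__ = [
    "LeafProfile",
    "linear_length",
    "linear_area",
    "profile_values",
    "k_from_relative_areas",
    "theoretical_k",
    "SyntheticConfig",
    "GroundTruth",
    "generate_shoots",
    "default_config",
]


@dataclass(frozen=True)
class LeafProfile:
    """Within-shoot relative-size profile.

    ``linear_length``: relative lamina lengths fall linearly from 1 to
    ``floor``; ``linear_area``: relative lamina areas fall linearly from 1
    to ``floor`` (so lengths fall with the square root).
    """

    kind: str
    floor: float

    def __post_init__(self) -> None:
        if self.kind not in ("linear_length", "linear_area"):
            raise InvalidInputError(f"unknown profile kind {self.kind!r}")
        if not 0.0 < self.floor <= 1.0:
            raise InvalidInputError(f"profile floor must lie in (0, 1], got {self.floor}")

    def values(self, n: int) -> np.ndarray:
        """Native profile values (lengths or areas, by kind), first exactly 1."""
        if n < 1:
            raise InvalidInputError(f"leaf count must be >= 1, got {n}")
        t = np.arange(n) / max(n - 1, 1)
        return 1.0 - (1.0 - self.floor) * t

    def length_factors(self, n: int) -> np.ndarray:
        v = self.values(n)
        return v if self.kind == "linear_length" else np.sqrt(v)

    def relative_areas(self, n: int) -> np.ndarray:
        v = self.values(n)
        return v**2 if self.kind == "linear_length" else v


def linear_length(f_min: float) -> LeafProfile:
    return LeafProfile("linear_length", float(f_min))


def linear_area(g_min: float) -> LeafProfile:
    return LeafProfile("linear_area", float(g_min))


def profile_values(profile: LeafProfile, n: int) -> np.ndarray:
    """Relative sizes for ``n`` leaves (lengths or areas per profile kind)."""
    return profile.values(n)


def k_from_relative_areas(areas) -> float:
    """Lopes–Pinto constant of one shoot: mean leaf area over midrange."""
    areas = np.asarray(areas, dtype=float)
    if areas.size < 1 or not (areas > 0).all():
        raise InvalidInputError("need at least one positive relative area")
    return float(areas.mean() / ((areas.min() + areas.max()) / 2.0))


def theoretical_k(profile: LeafProfile, n: int) -> float:
    """Lopes–Pinto constant implied by a profile at leaf count ``n``.

    k = mean(relative areas) / midrange(relative areas).  Equals 1 for the
    linear_area profile (an arithmetic progression's mean is its midrange)
    and for any profile at n <= 2.
    """
    return k_from_relative_areas(profile.relative_areas(n))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the package's standard conditions."""

    beta_true: float = 2.0
    n_shoots: int = 200
    wf_log10_mean: float = 0.9
    wf_log10_sd: float = 0.25
    n0: float = 10.0  # leaves per cm**(beta-1): leafing intensity
    aspect_ratio: float = 2.5  # lamina length / width, constant within species
    montgomery_c: float = 0.7
    profile: LeafProfile = field(default_factory=lambda: linear_length(0.3))
    noise_sigma_log10: float = 0.01
    seed: int = 20220330

    def __post_init__(self) -> None:
        if not self.beta_true > 1.0:
            raise InvalidInputError(f"beta_true must exceed 1, got {self.beta_true}")
        if self.n_shoots < 3:
            raise InvalidInputError(f"n_shoots must be >= 3, got {self.n_shoots}")
        for name in ("n0", "aspect_ratio"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0.0 < self.montgomery_c <= 1.0:
            raise InvalidInputError(
                f"montgomery_c must lie in (0, 1], got {self.montgomery_c}"
            )
        if self.noise_sigma_log10 < 0.0:
            raise InvalidInputError("noise_sigma_log10 must be >= 0")
        if not np.isfinite(self.wf_log10_sd) or self.wf_log10_sd < 0:
            raise InvalidInputError("wf_log10_sd must be a finite non-negative number")


@dataclass(frozen=True)
class GroundTruth:
    """True exponents behind a synthetic dataset.

    ``k_theoretical`` is the many-leaved (continuum) limit of the
    Lopes–Pinto constant for the configured profile; for the linear_area
    profile it is exactly 1 at every leaf count.
    """

    beta_true: float
    alpha: float
    gamma: float
    lambda_: float
    k_theoretical: float


def default_config(**overrides) -> SyntheticConfig:
    """The standard synthetic conditions, optionally with fields overridden."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def generate_shoots(config: SyntheticConfig) -> Tuple[List[Shoot], GroundTruth]:
    """Simulate one species' shoot collection; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    log_w = rng.normal(config.wf_log10_mean, config.wf_log10_sd, config.n_shoots)
    w_star = 10.0**log_w
    shoots: List[Shoot] = []
    for i, w in enumerate(w_star):
        n = max(1, round(config.n0 * w ** (config.beta_true - 1.0)))
        factors = config.profile.length_factors(n)
        if config.noise_sigma_log10 > 0.0:
            noise_l = 10.0 ** rng.normal(0.0, config.noise_sigma_log10, n)
            noise_w = 10.0 ** rng.normal(0.0, config.noise_sigma_log10, n)
        else:
            noise_l = noise_w = np.ones(n)
        lengths = w * factors * noise_l
        widths = lengths / config.aspect_ratio * noise_w
        areas = config.montgomery_c * lengths * widths
        leaves = tuple(
            Leaf(float(l), float(wd), float(a))
            for l, wd, a in zip(lengths, widths, areas)
        )
        shoots.append(Shoot(shoot_id=f"S{i:04d}", species="synthetic", leaves=leaves))
    truth = GroundTruth(
        beta_true=config.beta_true,
        alpha=alpha_from_beta(config.beta_true),
        gamma=gamma_from_beta(config.beta_true),
        lambda_=lambda_from_beta(config.beta_true),
        k_theoretical=theoretical_k(config.profile, 10001),
    )
    return shoots, truth
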