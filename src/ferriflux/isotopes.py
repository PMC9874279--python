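"""Stable iron isotope (56Fe/54Fe) bookkeeping.

Bulk iron is treated as the sum of the two major isotopes only
(54Fe + 56Fe); each Fe-bearing species therefore carries a paired 56Fe
state field.  Every Fe-transfer reaction with bulk rate R has an
isotope-specific rate 56R tied to R through an effective fractionation
factor alpha_eff = 1 + eps_eff/1000 applied to the isotope ratio of the
reaction's Fe-bearing *source* pool:

    56R = alpha * r / (1 + alpha * r) * R,      r = 56C / (C - 56C)

Below a fractionation limit C_lim on the bulk source concentration the
reaction transfers isotopes at the pool's own ratio (no fractionation),
which prevents runaway delta values in nearly empty pools.

delta56Fe values are reported against IRMM-014 (ratio 15.697861); an
optional reporting offset of -0.09 permil expresses values against average
igneous rocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 56Fe/54Fe of the IRMM-014 reference standard
IRMM014_RATIO = 15.697861

#: bulk concentration below which reactions stop fractionating, umol cm^-3
C_LIM = 1.0e-9

#: delta56Fe of IRMM-014 on the igneous-rock scale, permil
IGNEOUS_OFFSET = -0.09

#: sentinel rendered where a delta is undefined (empty pool)
DELTA_UNDEFINED = np.nan

#: calibrated effective fractionations, permil, per Fe-transfer process
DEFAULT_EPS = {
    "reduction": -1.3,    # dissimilatory + sulfide-mediated FeOOH reduction
    "oxidation": +0.4,    # DFe, FeS and FeS2 oxidation alike
    "sorption": +0.4,
    "fes_precipitation": +0.5,
    "fes_dissolution": -0.5,
    "pyrite_precipitation": -0.7,
}


@dataclass(frozen=True)
class IsotopeParams:
    reference_ratio: float = IRMM014_RATIO
    c_lim: float = C_LIM
    eps_eff: dict = field(default_factory=lambda: dict(DEFAULT_EPS))

    def __post_init__(self) -> None:
        if self.reference_ratio <= 0.0 or self.c_lim <= 0.0:
            raise ValueError("reference_ratio and c_lim must be positive")
        for name, eps in self.eps_eff.items():
            alpha = eps_to_alpha(eps)
            if not (0.9 < alpha < 1.1):
                raise ValueError(f"eps_eff[{name!r}]={eps} permil is out of range")

    def alpha(self, reaction: str) -> float:
        return eps_to_alpha(self.eps_eff[reaction])


@dataclass(frozen=True)
class IsotopePool:
    """A bulk concentration and its heavy (56Fe) sub-pool, same units."""

    bulk: np.ndarray | float
    heavy: np.ndarray | float


def eps_to_alpha(eps: float) -> float:
    """Effective fractionation factor alpha = 1 + eps/1000 (eps in permil)."""
    return 1.0 + eps / 1000.0


def alpha_to_eps(alpha: float) -> float:
    return 1000.0 * (alpha - 1.0)


def isotope_ratio(bulk, heavy):
    """56Fe/54Fe ratio r = 56C / (C - 56C); nan where undefined."""
    bulk = np.asarray(bulk, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    light = bulk - heavy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(light > 0.0, heavy / np.where(light > 0.0, light, 1.0), np.nan)
    return r


def delta56(pool: IsotopePool, params: IsotopeParams = IsotopeParams(),
            igneous_scale: bool = False):
    """delta56Fe in permil versus IRMM-014 (or igneous rocks).

    Undefined for empty pools: returns nan there rather than raising, so
    whole-profile output stays total.
    """
    bulk = np.asarray(pool.bulk, dtype=float)
    heavy = np.asarray(pool.heavy, dtype=float)
    r = isotope_ratio(bulk, heavy)
    delta = (r / params.reference_ratio - 1.0) * 1000.0
    delta = np.where((bulk > 0.0) & (heavy > 0.0) & (heavy < bulk), delta,
                     DELTA_UNDEFINED)
    if igneous_scale:
        delta = delta + IGNEOUS_OFFSET
    if delta.ndim == 0:
        return float(delta)
    return delta


def delta_to_heavy(bulk, delta, params: IsotopeParams = IsotopeParams()):
    """Heavy (56Fe) concentration of a pool with given bulk and delta56Fe."""
    bulk = np.asarray(bulk, dtype=float)
    r = params.reference_ratio * (1.0 + np.asarray(delta, dtype=float) / 1000.0)
    heavy = bulk * r / (1.0 + r)
    if heavy.ndim == 0:
        return float(heavy)
    return heavy


def heavy_rate_fraction(bulk, heavy, alpha, params: IsotopeParams = IsotopeParams(),
                        clip: bool = True):
    """Fraction 56R/R of a reaction rate carried by the heavy isotope.

    The ratio form ``alpha r / (1 + alpha r)`` with ``r = h / (C - h)`` is
    evaluated through its algebraic continuation ``alpha h / (C + (alpha-1) h)``,
    which is identical on valid pools (0 <= h <= C), stays smooth if a
    solver iterate momentarily pushes h past C, and exceeds 1 there — so
    the excess heavy drains back (self-correcting).  Below the ``c_lim``
    bulk concentration the transfer is unfractionated (56R/R = h/C).  Safe
    on empty pools (returns 0 there).

    With ``clip`` the result is restricted to [0, 1], the physical range
    for valid pools.
    """
    bulk = np.asarray(bulk, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    safe_bulk = np.where(bulk > 0.0, bulk, 1.0)
    plain = np.where(bulk > 0.0, heavy / safe_bulk, 0.0)
    denom = bulk + (alpha - 1.0) * heavy
    frac = np.where(
        (bulk > 0.0) & (denom > 0.0),
        alpha * heavy / np.where(denom > 0.0, denom, 1.0),
        plain,
    )
    out = np.where(bulk < params.c_lim, plain, frac)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def isotope_rate(bulk_rate, pool: IsotopePool, alpha_eff: float,
                 params: IsotopeParams = IsotopeParams()):
    """Isotope-specific reaction rate 56R for a bulk rate R drawing on
    ``pool`` (source-pool convention).  0 <= 56R <= R always."""
    bulk = np.asarray(pool.bulk, dtype=float)
    rate = np.asarray(bulk_rate, dtype=float)
    if np.any((bulk <= 0.0) & (rate > 0.0)):
        raise ValueError("nonzero bulk rate drawn from an empty pool")
    out = rate * heavy_rate_fraction(bulk, pool.heavy, alpha_eff, params)
    if out.ndim == 0:
        return float(out)
    return out


def sorbed_isotope_pool(dissolved: IsotopePool, k_ads: float, alpha_sorption: float,
                        params: IsotopeParams = IsotopeParams()):
    """Adsorbed 56Fe in equilibrium with a dissolved pool.

    X56 = k_ads * alpha/(1 + alpha*r) * (1 + r) * 56Fe_dissolved evaluated
    through the ratio form; with alpha = 1 this collapses to
    k_ads * 56Fe_dissolved.
    """
    bulk = np.asarray(dissolved.bulk, dtype=float)
    heavy = np.asarray(dissolved.heavy, dtype=float)
    r = isotope_ratio(bulk, heavy)
    # X56 = k_ads * alpha (1 + r) / (1 + alpha r) * 56Fe; the adsorbed pool
    # then carries exactly the ratio alpha * r
    out = np.where(
        np.isfinite(r),
        k_ads * alpha_sorption * (1.0 + r) / (1.0 + alpha_sorption * r) * heavy,
        k_ads * heavy,
    )
    if out.ndim == 0:
        return float(out)
    return out
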