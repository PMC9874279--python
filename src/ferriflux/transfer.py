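"""Predictive transfer functions for the benthic dissolved-iron flux and
its delta56Fe signature, and the Rayleigh-distillation diagnostic.

Two regimes are covered, each with a flux function and an isotope
function of the depth-integrated carbon oxidation rate Cox
(mmol m^-2 d^-1), the bottom-water oxygen concentration [O2]_BW (uM) and
the total iron-oxide rain J_FeOOH,T (umol m^-2 d^-1):

modern (bioturbated) seafloor
    J_DFe      = 0.153 J_FeOOH,T tanh(Cox / [O2]BW)
    d56Fe_JDFe = 1.65 x / (2.09 + x) - 1.67,        x = Cox^2 / [O2]BW

unbioturbated seafloor
    J_DFe      = (0.161 - 0.161 e^(-3.67 Cox/[O2]BW)) J_FeOOH,T
    d56Fe_JDFe = (1.60 - 1.34 e^(-3.67 (Cox/[O2]BW)^2)) - 1.67

The isotope functions are expressed relative to the delta56Fe of the
deposited iron oxides; their bounds (-1.67 to -0.02 permil modern,
-1.41 to -0.07 unbioturbated) are the maximum and minimum expressed
overall fractionation of the benthic flux.

``fit_surface`` re-derives the coefficients of any of the four forms from
model-generated (Cox, O2, J_FeOOH, response) samples by nonlinear least
squares, which is how the published coefficients were obtained from the
sensitivity grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class DomainError(ValueError):
    pass


#: published coefficient defaults per functional form
DEFAULT_COEFFICIENTS = {
    "tanh_ratio": (0.153,),
    "saturating_ratio": (1.65, 2.09, -1.67),
    "exp_saturation_flux": (0.161, 3.67),
    "exp_saturation_delta": (1.60, 1.34, 3.67),
}

#: fixed lower baseline of the delta transfer functions, permil
DELTA_FLOOR = -1.67


@dataclass(frozen=True)
class TransferCoefficients:
    form_id: str
    coefficients: tuple
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 or np.isnan(self.r_squared)):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class RayleighParams:
    d0: float = 0.0            # delta56Fe of the deposited oxides, permil
    alpha_reac: float = 0.9987  # effective fractionation factor of reduction
    j_max: float = 170.0       # maximum potential benthic flux, umol m^-2 d^-1

    def __post_init__(self) -> None:
        if self.j_max <= 0.0:
            raise ValueError("j_max must be > 0")


def _check_domain(cox, o2) -> tuple[np.ndarray, np.ndarray]:
    cox = np.asarray(cox, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    if np.any(cox < 0.0):
        raise DomainError("Cox must be >= 0")
    if np.any(o2 <= 0.0):
        raise DomainError("[O2]BW must be > 0")
    return cox, o2


def _maybe_scalar(x: np.ndarray):
    return float(x) if x.ndim == 0 else x


def jdfe_modern(cox, o2, j_feooh=1110.0, a: float = 0.153):
    """Benthic DFe flux (umol m^-2 d^-1) for the modern seafloor."""
    cox, o2 = _check_domain(cox, o2)
    return _maybe_scalar(a * np.asarray(j_feooh, float) * np.tanh(cox / o2))


def delta_modern(cox, o2, coefficients=(1.65, 2.09), floor: float = DELTA_FLOOR):
    """delta56Fe of the benthic DFe flux (permil, relative to the deposited
    oxides) for the modern seafloor."""
    cox, o2 = _check_domain(cox, o2)
    a, b = coefficients
    x = cox**2 / o2
    return _maybe_scalar(a * x / (b + x) + floor)


def jdfe_unbioturbated(cox, o2, j_feooh=1110.0, coefficients=(0.161, 3.67)):
    """Benthic DFe flux (umol m^-2 d^-1) for an unbioturbated seafloor."""
    cox, o2 = _check_domain(cox, o2)
    a, b = coefficients
    return _maybe_scalar(
        a * (1.0 - np.exp(-b * cox / o2)) * np.asarray(j_feooh, float))


def delta_unbioturbated(cox, o2, coefficients=(1.60, 1.34, 3.67),
                        floor: float = DELTA_FLOOR):
    """delta56Fe of the benthic DFe flux (permil) for an unbioturbated
    seafloor; plateaus near floor + (a - b) = -1.41 at high oxygen."""
    cox, o2 = _check_domain(cox, o2)
    a, b, c = coefficients
    return _maybe_scalar(a - b * np.exp(-c * (cox / o2) ** 2) + floor)


def rayleigh_delta(j_dfe, params: RayleighParams = RayleighParams()):
    """Expected delta56Fe of the benthic flux if it behaved as a Rayleigh
    distillation of the finite oxide input.

    The remaining-reactant fraction is ``fr = (j_max - j_dfe) / j_max`` so
    that a vanishing flux leaves the reservoir untouched (fr -> 1) and the
    delta tends to ``d0 + 1000 (alpha - 1) + d0 (alpha - 1)`` — the single-
    step fractionation — by the analytic limit of the Rayleigh expression.
    """
    j = np.asarray(j_dfe, dtype=float)
    if np.any(j < 0.0) or np.any(j >= params.j_max):
        raise DomainError(f"j_dfe must lie in [0, {params.j_max})")
    x = j / params.j_max                       # 1 - fr, exact
    a = params.alpha_reac
    d0 = params.d0
    # (1 - fr^a)/(1 - fr) = -expm1(a log1p(-x))/x, -> a as x -> 0; the
    # expm1/log1p route stays accurate through the vanishing-flux limit
    safe_x = np.where(x > 0.0, x, 1.0)
    ratio = np.where(
        x > 0.0, -np.expm1(a * np.log1p(-np.minimum(x, 1.0 - 1e-300)))
        / safe_x, a)
    out = (1000.0 + d0) * ratio - 1000.0
    return _maybe_scalar(out)


# ---------------------------------------------------------------------------
# coefficient re-derivation
# ---------------------------------------------------------------------------

def _form_model(form_id: str):
    if form_id == "tanh_ratio":
        def f(x, a):
            cox, o2, jf = x
            return a * jf * np.tanh(cox / o2)
        return f, DEFAULT_COEFFICIENTS[form_id]
    if form_id == "saturating_ratio":
        def f(x, a, b, c):
            cox, o2, _jf = x
            r = cox**2 / o2
            return a * r / (b + r) + c
        return f, DEFAULT_COEFFICIENTS[form_id]
    if form_id == "exp_saturation_flux":
        def f(x, a, b):
            cox, o2, jf = x
            return a * (1.0 - np.exp(-b * cox / o2)) * jf
        return f, DEFAULT_COEFFICIENTS[form_id]
    if form_id == "exp_saturation_delta":
        def f(x, a, b, c):
            cox, o2, _jf = x
            return a - b * np.exp(-c * (cox / o2) ** 2) + DELTA_FLOOR
        return f, DEFAULT_COEFFICIENTS[form_id]
    raise DomainError(f"unknown functional form {form_id!r}")


def fit_surface(samples, form_id: str) -> TransferCoefficients:
    """Least-squares fit of one transfer-function form.

    ``samples`` is an iterable of (cox, o2, j_feooh, response) tuples.  The
    fit is deterministic: it multi-starts from the published coefficients
    and a small set of fixed perturbations and keeps the best sum of
    squares.  R^2 is reported on the untransformed response.
    """
    arr = np.asarray(list(samples), dtype=float)
    model, p0 = _form_model(form_id)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise DomainError("need samples of (cox, o2, j_feooh, response)")
    # an undefined response (e.g. the delta of a vanishing flux) carries no
    # information for the fit
    arr = arr[np.isfinite(arr[:, 3])]
    if arr.shape[0] < len(p0):
        raise DomainError("need >= n_coefficients finite samples")
    x = (arr[:, 0], arr[:, 1], arr[:, 2])
    y = arr[:, 3]
    if np.allclose(y, y[0]):
        raise DomainError("degenerate design: constant responses")

    best = None
    starts = [np.asarray(p0, float)]
    for fac in (0.5, 2.0):
        starts.append(np.asarray(p0, float) * fac)
    for p_start in starts:
        try:
            popt, _ = curve_fit(model, x, y, p0=p_start, maxfev=20000)
        except RuntimeError:
            continue
        ss_res = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
    if best is None:
        raise DomainError("fit did not converge from any start")
    popt, ss_res = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return TransferCoefficients(form_id, tuple(float(v) for v in popt),
                                max(min(r2, 1.0), 0.0))
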