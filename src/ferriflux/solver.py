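"""Steady-state solution of the discretized reaction-transport system.

The stationary state is found in two phases.  A damped Newton iteration on
the banded Jacobian is attempted first — it converges immediately when a
good starting point is available (warm starts, the nearly linear isotope
stage).  If Newton stalls, the transient system is integrated with the
stiff BDF method (``scipy.integrate.solve_ivp``) over a pseudo-time window
long enough to exhaust the slowest physical timescale (solid burial
through the domain), after which Newton polishes the residual far below
the physical tendencies (default: max |dC/dt| under 1e-8 of each species'
field scale).

Species are interleaved within each cell, so transport couples entries
exactly one species-block apart and reactions couple entries within a
block; the Jacobian is banded with bandwidth equal to the block size and
is factorized with LAPACK's banded LU.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.sparse import dia_matrix


class SteadyStateError(RuntimeError):
    """Non-convergence within budget; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


def banded_to_sparse(ab: np.ndarray, bandwidth: int) -> dia_matrix:
    """LAPACK banded storage -> scipy sparse diagonal matrix."""
    n = ab.shape[1]
    offsets = np.arange(bandwidth, -bandwidth - 1, -1)
    return dia_matrix((ab, offsets), shape=(n, n)).tocsc()


def _scale_from(y: np.ndarray, floors: np.ndarray) -> np.ndarray:
    nb = floors.size
    per = np.maximum(np.abs(y.reshape(-1, nb)).max(axis=0), floors)
    return np.tile(per, y.size // nb)


def newton_solve(
    rhs,
    jacobian_banded,
    y0: np.ndarray,
    bandwidth: int,
    floors: np.ndarray,
    tol: float,
    max_iter: int = 50,
    nonnegative_rhs: bool = True,
) -> tuple[np.ndarray, bool, list[float]]:
    """Damped Newton with a simple halving line search.

    Returns (y, converged, residual history).  Small negative excursions
    are tolerated during iteration (rate laws clip internally); the caller
    clips the converged state.
    """
    def norms(yy, rr):
        scaled = np.abs(rr) / _scale_from(yy, floors)
        return float(np.max(scaled)), float(
            np.sqrt(np.mean(scaled * scaled)))

    y = np.array(y0, dtype=float)
    r = rhs(y)
    norm, rms = norms(y, r)
    history = [norm]
    for _ in range(max_iter):
        if norm < tol:
            return y, True, history
        ab = -jacobian_banded(y)
        try:
            dy = solve_banded((bandwidth, bandwidth), ab, r)
        except np.linalg.LinAlgError:
            return y, False, history
        lam = 1.0
        improved = False
        while lam > 1.0e-4:
            y_new = y + lam * dy
            r_new = rhs(y_new)
            norm_new, rms_new = norms(y_new, r_new)
            # accept on the smoother RMS norm: a single chattering
            # component must not block an otherwise good step
            if np.isfinite(rms_new) and rms_new < rms:
                y, r, norm, rms = y_new, r_new, norm_new, rms_new
                history.append(norm)
                improved = True
                break
            lam *= 0.5
        if not improved:
            return y, False, history
    return y, norm < tol, history


def _march(
    rhs,
    jacobian_banded,
    y: np.ndarray,
    bandwidth: int,
    floors: np.ndarray,
    tol: float,
    max_steps: int = 4000,
    dt0: float = 1.0e-5,
    dt_max: float = 1.0e6,
    newton_gate: float = 5.0e-2,
):
    """Semi-implicit (linearly implicit Euler) pseudo-time marching.

    Each step solves ``(I/dt - J) dy = f(y)`` once with a fresh Jacobian;
    step acceptance is governed by the relative state change, not the
    residual, so slow monotone transients (e.g. sulfide-mineral build-up)
    march through at large dt instead of throttling the iteration.  Newton
    finishes the job once the scaled residual drops through
    ``newton_gate``.
    """
    dt = dt0
    history: list[float] = []
    since_newton = 0
    last_attempt = np.inf
    for _ in range(max_steps):
        r = rhs(y)
        norm = float(np.max(np.abs(r) / _scale_from(y, floors)))
        history.append(norm)
        since_newton += 1
        # attempt the endgame either when the residual is small or
        # periodically — fronts sometimes plateau the march at a modest
        # residual from which Newton converges directly; after a failed
        # attempt, back off until the march has made real progress
        if (norm < newton_gate and norm < 0.25 * last_attempt) \
                or since_newton >= 150:
            since_newton = 0
            last_attempt = norm
            y_n, ok, h = newton_solve(
                rhs, jacobian_banded, y, bandwidth, floors, tol, max_iter=25)
            history += h
            if ok:
                return y_n, True, history
        ab = -jacobian_banded(y)
        ab[bandwidth, :] += 1.0 / dt
        try:
            dy = solve_banded((bandwidth, bandwidth), ab, r)
        except np.linalg.LinAlgError:
            dt *= 0.4
            continue
        rel = float(np.max(np.abs(dy) / _scale_from(y, floors)))
        if not np.isfinite(rel) or rel > 1.0:
            dt *= 0.4
            if dt < 1.0e-14:
                raise SteadyStateError("pseudo-time step collapsed", history)
            continue
        y = np.maximum(y + dy, 0.0)
        if rel < 0.3:
            dt = min(dt * 2.0, dt_max)
    return y, False, history


def steady_state_solve(
    rhs,
    jacobian_banded,
    y0: np.ndarray,
    bandwidth: int,
    floors: np.ndarray,
    tol: float = 1.0e-8,
    t_integrate: float = 2.0e4,
    newton_iter: int = 50,
) -> np.ndarray:
    """Drive ``rhs`` to zero: Newton, then pseudo-time marching, with a
    stiff BDF integration as the final fallback.

    ``t_integrate`` (years) should exceed the slowest physical timescale of
    the configuration — for a sediment column this is the solid residence
    time, domain depth / burial velocity.
    """
    # brief Newton probe: succeeds immediately on warm starts
    y, ok, history = newton_solve(
        rhs, jacobian_banded, y0, bandwidth, floors, tol, max_iter=15)
    if ok:
        return y
    # march from the *original* state: a half-converged Newton iterate can
    # sit outside the physical basin and poison the continuation
    y, ok, h2 = _march(rhs, jacobian_banded, np.array(y0, float),
                       bandwidth, floors, tol)
    history += h2
    if ok:
        return y
    # last resort: error-controlled stiff integration over a bounded window
    sol = solve_ivp(
        lambda _t, yy: rhs(yy),
        (0.0, t_integrate),
        y,
        method="BDF",
        jac=lambda _t, yy: banded_to_sparse(jacobian_banded(yy), bandwidth),
        rtol=1.0e-4,
        atol=np.tile(floors * 1.0e-4, y.size // floors.size),
    )
    if sol.success:
        y, ok, h3 = newton_solve(
            rhs, jacobian_banded, sol.y[:, -1], bandwidth, floors, tol,
            max_iter=newton_iter)
        history += h3
        if ok:
            return y
        y2, ok, h4 = _march(rhs, jacobian_banded, y, bandwidth, floors, tol)
        history += h4
        if ok:
            return y2
    raise SteadyStateError(
        f"not converged; residual {history[-1]:.3e} (tolerance {tol:.1e})",
        history,
    )
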