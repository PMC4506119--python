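"""Pseudo arc-length continuation core shared by the DCPB and coarse solvers.

Traces solution branches of F(u, p) = 0 through folds.  The corrector solves
the bordered system [F(u, p); t . (v - v_pred) ] = 0 with a finite-difference
Jacobian; the predictor is the secant through the two previous points.
Callers continue in a transformed parameter (log rho) for step-size
uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["ContinuationError", "ContinuationResult", "Fold", "newton_solve",
           "trace_branch"]


class ContinuationError(RuntimeError):
    """Newton or continuation failure (with partial results attached)."""

    def __init__(self, msg: str, result: "ContinuationResult | None" = None):
        super().__init__(msg)
        self.result = result


@dataclass
class Fold:
    """A turning point: extremum of the parameter along the arc."""

    p: float                  # parameter value at the fold (internal scale)
    index: int                # branch-point index nearest to the fold
    u: np.ndarray             # solution at that branch point


@dataclass
class ContinuationResult:
    points: list[tuple[np.ndarray, float]] = field(default_factory=list)
    folds: list[Fold] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array([p for _, p in self.points])


def _safe(F, u, p):
    """Evaluate F, mapping domain violations to an infinite residual."""
    try:
        out = np.asarray(F(u, p), dtype=float)
    except (ValueError, FloatingPointError):
        return None
    if not np.all(np.isfinite(out)):
        return None
    return out


def _fd_col(F, u, p, f0, h_vec, h_p):
    """One forward-difference column with a backward-difference fallback."""
    f1 = _safe(F, u + h_vec if h_vec is not None else u,
               p + h_p)
    if f1 is not None:
        return (f1 - f0) / (h_p if h_vec is None else np.sum(h_vec))
    f1 = _safe(F, u - h_vec if h_vec is not None else u, p - h_p)
    if f1 is None:
        raise ContinuationError("finite-difference stencil left the domain")
    return (f0 - f1) / (h_p if h_vec is None else np.sum(h_vec))


def _fd_jacobian(F, u, p, f0, eps_u, eps_p, with_p: bool):
    n = u.size
    if callable(eps_u):
        h_all = np.asarray(eps_u(u), dtype=float)
    elif np.isscalar(eps_u):
        h_all = eps_u * np.maximum(np.abs(u), 1.0)
    else:
        h_all = np.asarray(eps_u, dtype=float)
    cols = n + (1 if with_p else 0)
    J = np.empty((f0.size, cols))
    for i in range(n):
        hv = np.zeros(n)
        hv[i] = h_all[i]
        J[:, i] = _fd_col(F, u, p, f0, hv, 0.0)
    if with_p:
        J[:, n] = _fd_col(F, u, p, f0, None, eps_p)
    return J


def newton_solve(
    F: Callable[[np.ndarray, float], np.ndarray],
    u0: np.ndarray,
    p: float,
    *,
    tol: float | Callable[[], float] = 1e-9,
    max_iter: int = 25,
    eps_u: float | np.ndarray = 1e-7,
    damping: bool = True,
    chord: bool = False,
) -> np.ndarray:
    """Damped Newton for F(u, p) = 0 at fixed parameter.

    ``chord=True`` freezes the Jacobian after the first iteration (useful
    when residual evaluations are expensive and noisy).
    """
    u = np.asarray(u0, dtype=float).copy()
    f = _safe(F, u, p)
    if f is None:
        raise ContinuationError("invalid initial iterate")
    J = None
    u_best, f_best = u.copy(), np.max(np.abs(f))

    def soft_exit():
        # noise-limited residuals: accept the best iterate near tolerance
        if f_best < 2.5 * (tol() if callable(tol) else tol):
            return u_best
        raise ContinuationError(
            f"Newton did not converge: residual {f_best:.3e}"
        )

    for it in range(max_iter):
        res = np.max(np.abs(f))
        if res < f_best:
            u_best, f_best = u.copy(), res
        if res < (tol() if callable(tol) else tol):
            return u
        if J is None or not chord:
            J = _fd_jacobian(F, u, p, f, eps_u, 0.0, with_p=False)
        try:
            du = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise ContinuationError(f"singular Jacobian at iteration {it}") from exc
        lam, best, best_lam, best_res = 1.0, None, 1.0, np.inf
        for _ in range(9):
            f_new = _safe(F, u + lam * du, p)
            if f_new is not None:
                r_new = np.max(np.abs(f_new))
                if r_new < best_res:
                    best, best_lam, best_res = f_new, lam, r_new
                if r_new < res:
                    break
            lam *= 0.5
        if best is None or best_res > 2.0 * res:
            return soft_exit()
        u = u + best_lam * du
        f = best
    res = np.max(np.abs(f))
    if res < f_best:
        u_best, f_best = u.copy(), res
    if res < (tol() if callable(tol) else tol):
        return u
    return soft_exit()


def _corrector(F, v_pred, tangent, tol, max_iter, eps_u, eps_p, chord,
               soft: float = 2.5, min_iter: int = 0):
    """Bordered Newton corrector.

    Converges to ``tol`` when the residual is smooth; when iterations stall
    inside the band ``soft * tol`` (the signature of a noise-limited
    residual) the best iterate is accepted instead of failing.
    """
    n = v_pred.size - 1
    v = v_pred.copy()

    def ext(vv):
        base = _safe(F, vv[:n], vv[n])
        if base is None:
            return None
        return np.concatenate([base, [tangent @ (vv - v_pred)]])

    f = ext(v)
    if f is None:
        raise ContinuationError("invalid predictor state")
    J = None
    v_best, f_best = v.copy(), np.max(np.abs(f))

    def soft_exit(it):
        if f_best < soft * (tol() if callable(tol) else tol):
            return v_best, it, J
        raise ContinuationError(
            f"corrector stalled (best residual {f_best:.3e})"
        )

    for it in range(max_iter):
        res = np.max(np.abs(f))
        if res < f_best:
            v_best, f_best = v.copy(), res
        if it >= min_iter and res < (tol() if callable(tol) else tol):
            return v, it, J
        if J is None or not chord:
            Jf = _fd_jacobian(F, v[:n], v[n], f[:-1], eps_u, eps_p, with_p=True)
            J = np.vstack([Jf, tangent])
        try:
            dv = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            raise ContinuationError("singular bordered Jacobian")
        lam, best, best_lam, best_res = 1.0, None, 1.0, np.inf
        for _ in range(5):
            f_new = ext(v + lam * dv)
            if f_new is not None:
                r_new = np.max(np.abs(f_new))
                if r_new < best_res:
                    best, best_lam, best_res = f_new, lam, r_new
                if r_new < res:
                    break
            lam *= 0.5
        if best is None or best_res > 2.0 * res:
            if it >= min_iter:
                return soft_exit(it)
            v, f = v_best.copy(), None
            f = ext(v)
            if f is None:
                return soft_exit(it)
            continue
        v = v + best_lam * dv
        f = best
    res = np.max(np.abs(f))
    if res < f_best:
        v_best, f_best = v.copy(), res
    if res < (tol() if callable(tol) else tol):
        return v, max_iter, J
    return soft_exit(max_iter)


def refine_fold(result: ContinuationResult, fold: Fold) -> float:
    """Quadratic fit of p against arc length through the fold neighbourhood."""
    k = fold.index
    pts = result.params
    lo, hi = max(k - 2, 0), min(k + 2, pts.size)
    if hi - lo < 3:
        return fold.p
    # arc coordinate from cumulative solution distances (p included)
    s = [0.0]
    for i in range(lo + 1, hi):
        du = result.points[i][0] - result.points[i - 1][0]
        s.append(s[-1] + np.sqrt(du @ du + (pts[i] - pts[i - 1]) ** 2))
    s = np.asarray(s)
    coef = np.polyfit(s, pts[lo:hi], 2)
    if coef[0] == 0:
        return fold.p
    s_star = -coef[1] / (2 * coef[0])
    if not s[0] - (s[1] - s[0]) <= s_star <= s[-1] + (s[-1] - s[-2]):
        return fold.p
    return float(np.polyval(coef, s_star))


def trace_branch(
    F: Callable[[np.ndarray, float], np.ndarray],
    u0: np.ndarray,
    p0: float,
    *,
    direction: int = -1,
    ds: float = 0.05,
    ds_min: float = 1e-4,
    ds_max: float = 0.2,
    max_steps: int = 200,
    p_range: tuple[float, float] = (-np.inf, np.inf),
    newton_tol: float | Callable[[], float] = 1e-9,
    max_newton: int = 20,
    eps_u: float | np.ndarray = 1e-7,
    eps_p: float = 1e-6,
    p_weight: float = 1.0,
    stop_after_folds: int | None = None,
    chord: bool = False,
    fold_on_stall: bool = True,
    min_corrector_iter: int = 0,
    validate: Callable[[np.ndarray, float], bool] | None = None,
    on_point: Callable[[np.ndarray, float], None] | None = None,
) -> ContinuationResult:
    """Trace a branch of F(u, p) = 0 by pseudo arc-length continuation.

    The first two points come from natural continuation (fixed-parameter
    Newton solves); thereafter a secant predictor and bordered corrector
    advance along the arc with adaptive step control, rounding folds.  Folds
    are flagged where the parameter direction along the arc changes sign and
    refined by a quadratic fit.

    ``p_weight`` scales the parameter component in the arc-length metric.
    ``on_point`` is invoked for every accepted branch point.
    """
    result = ContinuationResult()
    u = newton_solve(F, u0, p0, tol=newton_tol, max_iter=max_newton,
                     eps_u=eps_u, chord=chord)
    result.points.append((u.copy(), p0))
    if on_point:
        on_point(u, p0)

    p1 = p0 + direction * ds
    u1 = newton_solve(F, u, p1, tol=newton_tol, max_iter=max_newton,
                      eps_u=eps_u, chord=chord)
    result.points.append((u1.copy(), p1))
    if on_point:
        on_point(u1, p1)

    # initial tangent: secant through the two natural-continuation points
    dv = np.concatenate([u1 - u, [p_weight * (p1 - p0)]])
    tangent = dv / np.linalg.norm(dv)
    tangent_prev_p = tangent[-1]

    step = ds
    n_folds = 0
    for _ in range(max_steps):
        u_cur, p_cur = result.points[-1]
        accepted = False
        while step >= ds_min:
            v_pred = np.concatenate([u_cur, [p_cur]]) + step * np.concatenate(
                [tangent[:-1], [tangent[-1] / p_weight]]
            )
            try:
                v_new, iters, J = _corrector(
                    F, v_pred, tangent, newton_tol, max_newton, eps_u, eps_p,
                    chord, min_iter=min_corrector_iter,
                )
                # trust-region guard: a corrector that lands far outside the
                # predicted step has jumped branches or wandered into the
                # low-residual ghost corridor behind a fold
                dv_acc = v_new - np.concatenate([u_cur, [p_cur]])
                dist = np.sqrt(
                    np.sum(dv_acc[:-1] ** 2) + (p_weight * dv_acc[-1]) ** 2
                )
                if dist > 3.0 * step:
                    raise ContinuationError(
                        f"corrector left the trust region ({dist:.3g} vs "
                        f"step {step:.3g})"
                    )
                if validate is not None and not validate(v_new[:-1],
                                                         float(v_new[-1])):
                    raise ContinuationError("point failed validation")
                accepted = True
                break
            except ContinuationError:
                step *= 0.5
        if not accepted:
            # a step-size underflow while the parameter stalls is the
            # signature of an unrounded fold: the branch is locally a
            # parabola p = a xi^2 + b xi + c whose vertex extrapolates the
            # fold location from the approach points
            if fold_on_stall and len(result.points) >= 3:
                pts = result.points[-3:]
                t_ref = pts[-1][0] - pts[0][0]
                nrm = np.linalg.norm(t_ref)
                if nrm > 0:
                    t_ref = t_ref / nrm
                    xi = np.array([t_ref @ (u_i - pts[0][0]) for u_i, _ in pts])
                    th = np.array([p_i for _, p_i in pts])
                    coef = np.polyfit(xi, th, 2)
                    if coef[0] != 0:
                        xi_star = -coef[1] / (2 * coef[0])
                        span = xi[-1] - xi[0]
                        if -1.0 <= (xi_star - xi[-1]) / span <= 3.0:
                            p_star = float(np.polyval(coef, xi_star))
                            result.folds.append(
                                Fold(p=p_star, index=len(result.points) - 1,
                                     u=result.points[-1][0].copy())
                            )
                            return result
            raise ContinuationError("continuation step-size underflow", result)
        u_new, p_new = v_new[:-1], float(v_new[-1])
        result.points.append((u_new.copy(), p_new))
        if on_point:
            on_point(u_new, p_new)
        if iters <= 3:
            step = min(step * 1.4, ds_max)
        if J is None:
            # the corrector accepted the predictor without iterating; build
            # the bordered Jacobian anyway so the Keller tangent can rotate
            f_here = _safe(F, u_new, p_new)
            if f_here is not None:
                Jf = _fd_jacobian(F, u_new, p_new, f_here, eps_u, eps_p,
                                  with_p=True)
                J = np.vstack([Jf, tangent])
        # Keller tangent: null direction of the bordered Jacobian, oriented
        # along the previous tangent; rotates properly around folds where a
        # stale secant would point off the branch
        t_new = None
        if J is not None:
            rhs = np.zeros(J.shape[0])
            rhs[-1] = 1.0
            try:
                t_new = np.linalg.solve(J, rhs)
            except np.linalg.LinAlgError:
                t_new = None
        if t_new is None:
            u_prev, p_prev = result.points[-2]
            t_new = np.concatenate([u_new - u_prev,
                                    [p_weight * (p_new - p_prev)]])
        else:
            t_new = np.concatenate([t_new[:-1], [p_weight * t_new[-1]]])
        norm = np.linalg.norm(t_new)
        if norm == 0:
            raise ContinuationError("degenerate tangent", result)
        t_new = t_new / norm
        if t_new @ tangent < 0:
            t_new = -t_new
        tangent = t_new
        # fold: the parameter component of the tangent changes sign
        if tangent[-1] * tangent_prev_p < 0:
            fold = Fold(p=p_new, index=len(result.points) - 1, u=u_new.copy())
            fold.p = refine_fold(result, fold)
            result.folds.append(fold)
            n_folds += 1
            if stop_after_folds is not None and n_folds >= stop_after_folds:
                return result
        if abs(tangent[-1]) > 1e-12:
            tangent_prev_p = tangent[-1]
        if not p_range[0] <= p_new <= p_range[1]:
            return result
    return result
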