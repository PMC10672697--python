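"""Identification of adaptation parameters theta = {a, b} from two binaries.

Given co-registered baseline and follow-up bone volumes and the elapsed days,
the inverse solver minimizes a cost on the non-overlapping (XOR) region of
the forward-predicted and observed bone volumes,

    J(theta) = |predict(theta) XOR target| / |target bone|,

starting from a linear least-squares initialization and refining with Adam
gradient descent on normalized parameters.  Gradients are central finite
differences on the 2-parameter space (four forward simulations per gradient,
one more for the cost trace).

Normalization uses the natural scales s_a = spacing/duration (um/day) and
s_b = spacing^2/duration (um^2/day), making the learning rate, tolerance and
finite-difference step dimensionless and transferable across voxel sizes and
scan intervals.

Two practical notes about the voxel-count cost:

* It is piecewise constant (a staircase): parameter changes too small to
  move any voxel across the zero level cannot change it.  Cost evaluations
  are therefore memoized on a fine quantized parameter grid, which is
  lossless at the resolution the optimizer can sense.
* Adam's step size does not vanish in a limit cycle around a staircase
  minimum, so the parameter-step norm criterion alone can fail to fire even
  at a perfectly identified optimum.  A fit is therefore also declared
  converged when the best cost has stopped improving (by at least one
  target-voxel equivalent) over a trailing window: the iterate is trapped on
  a plateau around a stationary point.  Fits that are still descending when
  the iteration cap is reached are reported as non-converged — a tabulated
  outcome, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_geometry import (
    DegenerateInputError,
    Volume3D,
    mean_curvature,
    signed_distance,
)
from .forward_solver import EvolutionConfig, ModelParams, simulate
from .morphometry import symmetric_distance


@dataclass(frozen=True)
class FitConfig:
    """Optimizer hyper-parameters.

    eta: Adam learning rate on normalized parameters.
    gamma: gradient scaling factor applied to the b-component.
    tol: convergence threshold on the normalized parameter-step L2 norm.
    max_iter: iteration cap; fits exceeding it are reported non-converged.
    fd_rel_step: central finite-difference step, as a fraction of each
        parameter scale (large enough to straddle staircase plateaus).
    plateau_window: trailing window (iterations) for the stationarity
        criterion; plateau_min_improve voxels of improvement reset it.
    staged_init: refine the linear least-squares start by a coarse grid over
        the curvature constant with nested secant solves for the advection
        constant (see ``staged_initialize``) before Adam.  Adam's step
        budget (eta x max_iter) can only correct the advection constant by
        ~0.2 normalized units, so the start must already be close; the
        single-step linearization alone degrades badly once the surface
        moves more than a voxel or thin struts vanish within the interval.
    b_grid: curvature-constant nodes for the staged search, um^2/day.
    """

    eta: float = 5e-5
    gamma: float = 5e-4
    tol: float = 1e-8
    max_iter: int = 4000
    fd_rel_step: float = 0.05
    plateau_window: int = 100
    plateau_min_improve: float = 1.0
    staged_init: bool = True
    b_grid: tuple = (0.0, 80.0, 200.0, 400.0, 660.0)

    def __post_init__(self) -> None:
        if not (self.eta > 0 and self.gamma > 0 and self.tol > 0 and self.max_iter >= 1):
            raise ValueError("invalid FitConfig: eta, gamma, tol must be > 0 and max_iter >= 1")


@dataclass
class FitResult:
    params: ModelParams
    converged: bool
    iterations: int
    final_cost: float
    cost_trace: np.ndarray
    accepted: bool
    symmetric_distance_at_fit: float
    init_params: ModelParams | None = None
    staged_params: ModelParams | None = None
    predicted: Volume3D | None = None
    curvature_variance: float = np.nan  # identifiability diagnostic for b
    flags: set = field(default_factory=set)


# --------------------------------------------------------------------------
# Cost
# --------------------------------------------------------------------------

def cost(
    params: ModelParams,
    binary0: Volume3D,
    binary_target: Volume3D,
    duration: float,
    config: EvolutionConfig = EvolutionConfig(),
) -> float:
    """Non-overlap cost J = |predict XOR target| / |target bone|."""
    n_target = binary_target.bone_voxels()
    if n_target == 0:
        raise DegenerateInputError("target volume has zero bone voxels")
    predicted, _ = simulate(binary0, params, duration, config)
    xor = np.count_nonzero(predicted.data.astype(bool) ^ binary_target.data.astype(bool))
    return xor / n_target


# --------------------------------------------------------------------------
# Linear least-squares initialization
# --------------------------------------------------------------------------

def lls_initialize(
    binary0: Volume3D,
    binary_target: Volume3D,
    duration: float,
) -> ModelParams:
    """Initialize theta by regressing the observed normal speed on curvature.

    Both volumes are embedded as signed distance fields; because both are
    (approximately) unit-gradient, the per-voxel observed normal speed on
    the baseline surface band |phi0| <= 2h is F_hat = -(phi1 - phi0)/T.
    Ordinary least squares of F_hat on [1, -kappa(phi0)] yields (a0, b0).

    The voxel-center distance convention places the zero level half a voxel
    beyond the last voxel center on either side, so |phi| overestimates the
    distance to the surface by h/2; for voxels that change phase between the
    two scans the two offsets add instead of cancelling, biasing the speed
    by a full voxel there.  Both embeddings are therefore corrected by
    phi - sign(phi) h/2 before differencing.
    """
    f0 = signed_distance(binary0)
    f1 = signed_distance(binary_target)
    h = binary0.spacing
    band = np.abs(f0.phi) <= 2.0 * h
    if band.sum() < 10:
        raise DegenerateInputError(f"only {int(band.sum())} band voxels; need >= 10")

    def corrected(phi: np.ndarray) -> np.ndarray:
        p = phi.astype(np.float64)
        return p - np.sign(p) * h / 2.0

    fhat = -(corrected(f1.phi)[band] - corrected(f0.phi)[band]) / duration
    kappa = mean_curvature(f0)[band]
    X = np.column_stack([np.ones(kappa.size), -kappa])
    coef, *_ = np.linalg.lstsq(X, fhat, rcond=None)
    return ModelParams(a=float(coef[0]), b=float(coef[1]))


def band_curvature_variance(binary0: Volume3D) -> float:
    """Variance of mean curvature over the baseline surface band.

    Low curvature variance makes b weakly identified (the curvature term is
    then nearly collinear with the advection constant)."""
    f0 = signed_distance(binary0)
    band = np.abs(f0.phi) <= 2.0 * binary0.spacing
    return float(np.var(mean_curvature(f0)[band]))


# --------------------------------------------------------------------------
# Staged initialization
# --------------------------------------------------------------------------

def _half_voxel_corrected(phi: np.ndarray, h: float) -> np.ndarray:
    p = phi.astype(np.float64)
    return p - np.sign(p) * h / 2.0


class _BandResidual:
    """Sub-voxel mismatch between predicted and observed embeddings.

    Evaluated on the union of the two scans' surface bands (|phi| <= 2h of
    either), so the residual stays sensitive even when the surface moves
    far from the baseline band within the interval.
    """

    def __init__(self, binary0, binary_target, duration, evo_config):
        self.binary0 = binary0
        self.duration = duration
        self.evo_config = evo_config
        h = binary0.spacing
        f0 = signed_distance(binary0)
        f1 = signed_distance(binary_target)
        self.band = (np.abs(f0.phi) <= 2 * h) | (np.abs(f1.phi) <= 2 * h)
        self.phi1c = _half_voxel_corrected(f1.phi, h)[self.band]
        self.h = h
        self.n_sim = 0

    def __call__(self, a: float, b: float) -> np.ndarray | None:
        """Residual vector (um), or None if the prediction lost a phase."""
        self.n_sim += 1
        pred, _ = simulate(
            self.binary0, ModelParams(float(a), float(max(b, 0.0))),
            self.duration, self.evo_config,
        )
        n = pred.bone_voxels()
        if n == 0 or n == pred.data.size:
            return None
        fp = signed_distance(pred)
        return _half_voxel_corrected(fp.phi, self.h)[self.band] - self.phi1c

    def rms(self, r: np.ndarray | None) -> float:
        return np.inf if r is None else float(np.sqrt((r**2).mean()))


def _solve_advection(res: _BandResidual, b: float, a0: float,
                     tol_a: float = 0.01, max_it: int = 6):
    """Secant solve of mean-band-residual(a) = 0 at fixed b.

    The mean signed residual is monotone in the advection constant (uniform
    normal speed translates every band value), making a 1D root solve
    robust where the joint problem has a curved valley.
    """
    a1 = float(np.clip(a0, -5.0, 5.0))
    r = res(a1, b)
    tries = 0
    while r is None and tries < 4:
        a1 = a1 / 2.0 if abs(a1) > 0.05 else a1 + 0.2
        r = res(a1, b)
        tries += 1
    if r is None:
        return a1, np.inf
    m1 = float(r.mean())
    best = (res.rms(r), a1)
    a2 = a1 + (0.1 if m1 > 0 else -0.1)
    for _ in range(max_it):
        r2 = res(a2, b)
        if r2 is None:
            a2 = (a1 + a2) / 2.0
            continue
        m2 = float(r2.mean())
        rms2 = res.rms(r2)
        if rms2 < best[0]:
            best = (rms2, a2)
        if abs(m2) < 1.0 or abs(a2 - a1) < tol_a:
            break
        if m2 == m1:
            break
        a_new = a2 - m2 * (a2 - a1) / (m2 - m1)
        a_new = float(np.clip(a_new, a2 - 1.0, a2 + 1.0))
        a1, m1, a2 = a2, m2, a_new
    return best[1], best[0]


def staged_initialize(
    binary0: Volume3D,
    binary_target: Volume3D,
    duration: float,
    init: ModelParams,
    evo_config: EvolutionConfig = EvolutionConfig(),
    b_grid: tuple = (0.0, 80.0, 200.0, 400.0, 660.0),
) -> ModelParams:
    """Refine a linear least-squares start on the band-embedding residual.

    The curvature constant is searched on a coarse grid (it is the weakly
    identified, strongly nonlinear direction), with the advection constant
    solved by a nested secant at each node; the best node is then narrowed
    by two bisection rounds and a parabolic step on rms^2(b).  Each stage
    is a sequence of one-dimensional linear solves, robust to the thin-strut
    runaway that breaks the single-step linearization.
    """
    res = _BandResidual(binary0, binary_target, duration, evo_config)
    evaluated: list[tuple[float, float, float]] = []  # (rms, a, b)
    a_ws = init.a
    worse_streak = 0
    for b in sorted(b_grid):
        a_sol, rms = _solve_advection(res, b, a_ws)
        evaluated.append((rms, a_sol, float(b)))
        if np.isfinite(rms):
            a_ws = a_sol
        best_rms = min(e[0] for e in evaluated)
        # rms(b) is unimodal in practice: once we are clearly past the
        # minimum, higher (and costlier) nodes cannot win
        worse_streak = worse_streak + 1 if rms > 1.5 * best_rms else 0
        if worse_streak >= 2:
            break
    for _ in range(2):  # bisection rounds around the current best node
        evaluated.sort()
        best = evaluated[0]
        bs = sorted({e[2] for e in evaluated})
        i = bs.index(best[2])
        for b_new in ([(bs[i - 1] + bs[i]) / 2] if i > 0 else []) + (
            [(bs[i] + bs[i + 1]) / 2] if i < len(bs) - 1 else []
        ):
            a_sol, rms = _solve_advection(res, b_new, best[1])
            evaluated.append((rms, a_sol, b_new))
    evaluated.sort()
    finite = [e for e in evaluated if np.isfinite(e[0])]
    if len(finite) >= 3:
        # parabolic vertex through the three lowest rms^2 points
        pts = sorted(finite[:3], key=lambda e: e[2])
        bb = np.array([p[2] for p in pts])
        yy = np.array([p[0] ** 2 for p in pts])
        if len(set(bb)) == 3:
            coef = np.polyfit(bb, yy, 2)
            if coef[0] > 0:
                b_v = float(np.clip(-coef[1] / (2 * coef[0]), bb.min(), bb.max()))
                a_sol, rms = _solve_advection(res, b_v, finite[0][1])
                finite.append((rms, a_sol, b_v))
                finite.sort()
    if not finite:
        return init
    best = finite[0]
    return ModelParams(a=best[1], b=best[2])


# --------------------------------------------------------------------------
# Adam fit
# --------------------------------------------------------------------------

_BETA1, _BETA2, _EPS = 0.9, 0.999, 1e-8
_Q_CENTER = 0.002  # cost-trace quantum, fraction of parameter scale
_Q_PROBE = 0.01    # finite-difference probe quantum


def adam_fit(
    binary0: Volume3D,
    binary_target: Volume3D,
    duration: float,
    fit_config: FitConfig = FitConfig(),
    evo_config: EvolutionConfig = EvolutionConfig(),
) -> FitResult:
    """Fit theta = {a, b} by LLS initialization plus Adam gradient descent.

    The fitted parameters are the best (lowest-cost) iterate encountered.
    After the fit, the forward model is run at theta_hat and the mean
    symmetric surface distance to the target decides acceptance
    (converged AND distance <= voxel spacing).
    """
    h = binary0.spacing
    n_target = binary_target.bone_voxels()
    if n_target == 0:
        raise DegenerateInputError("target volume has zero bone voxels")
    s_a = h / duration
    s_b = h * h / duration
    scales = np.array([s_a, s_b])

    memo: dict[tuple[float, float], float] = {}

    def j_eval(theta_n: np.ndarray, quantum: float) -> float:
        q = np.round(theta_n / quantum) * quantum
        key = (float(q[0]), float(q[1]))
        if key not in memo:
            # project b onto the physical (non-negative) half-space for
            # evaluation: negative b is backward diffusion and unstable
            p = ModelParams(a=key[0] * s_a, b=max(key[1], 0.0) * s_b)
            memo[key] = cost(p, binary0, binary_target, duration, evo_config)
        return memo[key]

    init = lls_initialize(binary0, binary_target, duration)
    start = init
    if fit_config.staged_init:
        j_init = j_eval(np.array([init.a, init.b]) / scales, _Q_CENTER)
        if j_init > 0:  # an exact LLS start needs no refinement
            start = staged_initialize(
                binary0, binary_target, duration, init, evo_config,
                b_grid=fit_config.b_grid,
            )
    theta = np.array([start.a, start.b]) / scales
    m = np.zeros(2)
    v = np.zeros(2)
    delta = fit_config.fd_rel_step

    cost_trace: list[float] = []
    best_cost = np.inf
    best_theta = theta.copy()
    best_iter = 0
    converged = False
    k = 0
    min_improve = fit_config.plateau_min_improve / n_target

    while k < fit_config.max_iter:
        k += 1
        jc = j_eval(theta, _Q_CENTER)
        cost_trace.append(jc)
        if jc < best_cost - 1e-15:
            if jc < best_cost - min_improve:
                best_iter = k
            best_cost = jc
            best_theta = theta.copy()

        # stationarity: best cost stopped improving over the trailing window
        if k - best_iter >= fit_config.plateau_window:
            converged = True
            break

        grad = np.empty(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = delta
            jp = j_eval(theta + e, _Q_PROBE)
            jm = j_eval(theta - e, _Q_PROBE)
            grad[i] = (jp - jm) / (2.0 * delta)
        if not np.isfinite(grad).all():
            raise FloatingPointError(f"non-finite gradient at theta={theta * scales}")
        grad[1] *= fit_config.gamma

        m = _BETA1 * m + (1 - _BETA1) * grad
        v = _BETA2 * v + (1 - _BETA2) * grad**2
        m_hat = m / (1 - _BETA1**k)
        v_hat = v / (1 - _BETA2**k)
        step_vec = fit_config.eta * m_hat / (np.sqrt(v_hat) + _EPS)
        theta = theta - step_vec
        if np.linalg.norm(step_vec) < fit_config.tol:
            converged = True
            cost_trace.append(j_eval(theta, _Q_CENTER))
            break

    params = ModelParams(a=float(best_theta[0] * s_a), b=float(best_theta[1] * s_b))
    flags: set = set()
    if params.b < 0:
        flags.add("b_negative")
    predicted, _ = simulate(
        binary0, ModelParams(a=params.a, b=max(params.b, 0.0)), duration, evo_config
    )
    final_cost = (
        np.count_nonzero(predicted.data.astype(bool) ^ binary_target.data.astype(bool))
        / n_target
    )
    try:
        sd = symmetric_distance(predicted, binary_target)
    except DegenerateInputError:
        sd = np.inf
        flags.add("degenerate_prediction")
    result = FitResult(
        params=params,
        converged=converged,
        iterations=k,
        final_cost=float(final_cost),
        cost_trace=np.asarray(cost_trace),
        accepted=False,
        symmetric_distance_at_fit=float(sd),
        init_params=init,
        staged_params=start if fit_config.staged_init else None,
        predicted=predicted,
        curvature_variance=band_curvature_variance(binary0),
        flags=flags,
    )
    result.accepted = accept_fit(result, h)
    return result


def accept_fit(result: FitResult, spacing: float) -> bool:
    """A fit is accepted iff it converged and the fitted prediction lies
    within one voxel (mean symmetric surface distance <= spacing) of the
    observed follow-up."""
    return bool(result.converged and result.symmetric_distance_at_fit <= spacing)
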