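"""Dwell-time optimization: quadratic penalty model and robust extension.

The planning problem penalizes, per dose point i in structure s and
scenario r, the shortfall below a lower bound L_s and the excess above an
upper bound U_s, with linear weights (w^l, w^u) and quadratic weights
(q^l, q^u).  The robust model minimizes

    lambda * z_w  +  (mean_weight / |R|) * sum_r z_r

where z_r is the scenario-r penalty and z_w >= max_r z_r the worst-case
penalty, subject to nonnegative dwell times.  With the penalty variables
eliminated as positive parts,

    g_r(t) = sum_i w^l x + q^l x^2 + w^u y + q^u y^2,
    x = (L - d_r . t)_+ ,  y = (d_r . t - U)_+ ,

each g_r is a convex piecewise-quadratic function of t, and the full
quadratic program is exactly equivalent to

    min_{t >= 0}  lambda * max_r g_r(t) + (mean_weight/|R|) sum_r g_r(t).

The non-robust model is the singleton-nominal-scenario special case and
shares the same code path.  Smooth weighted-sum problems are solved with
L-BFGS-B plus a projected-Newton polish; the minimax term is handled by
the epigraph formulation with trust-constr.  Dose bookkeeping is in Gy
(matrices are cGy/s; dwell times in seconds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import optimize as sciopt

from .dose import DoseMatrix, ScenarioSpec

log = logging.getLogger("shieldplan.optimize")

CGY_PER_GY = 100.0


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructurePenalty:
    """Penalty parameters of one structure (doses in Gy)."""

    lower: float = 0.0            # L_s
    upper: float = np.inf         # U_s (inf = unbounded)
    w_low: float = 0.0            # linear shortfall weight
    w_high: float = 0.0           # linear excess weight
    q_low: float = 0.0            # quadratic shortfall weight
    q_high: float = 0.0           # quadratic excess weight

    def __post_init__(self) -> None:
        if np.isfinite(self.upper) and self.lower > self.upper:
            raise ValueError(f"lower bound {self.lower} exceeds upper bound {self.upper}")
        if min(self.w_low, self.w_high, self.q_low, self.q_high) < 0:
            raise ValueError("penalty weights must be nonnegative")

    def scaled(self, low_factor: float, high_factor: float | None = None
               ) -> "StructurePenalty":
        """Shortfall weights scaled by ``low_factor``, excess weights by
        ``high_factor`` (defaults to ``low_factor``); bounds unchanged."""
        hf = low_factor if high_factor is None else high_factor
        return replace(self, w_low=self.w_low * low_factor, w_high=self.w_high * hf,
                       q_low=self.q_low * low_factor, q_high=self.q_high * hf)


@dataclass(frozen=True)
class PenaltyConfig:
    """Per-structure penalty table; the CTV must carry a finite
    prescription (lower bound)."""

    structures: Mapping[str, StructurePenalty]

    def __post_init__(self) -> None:
        ctv = self.structures.get("ctv")
        if ctv is None or not np.isfinite(ctv.lower) or ctv.lower <= 0:
            raise ValueError("the CTV requires a finite positive prescription (lower bound)")
        object.__setattr__(self, "structures", dict(self.structures))

    def __getitem__(self, role: str) -> StructurePenalty:
        return self.structures[role]

    def scaled(self, target_factor: float, oar_factor: float,
               target_roles: Iterable[str] = ("ctv",)) -> "PenaltyConfig":
        """Coverage-vs-sparing rebalancing: shortfall weights of target
        structures scale by ``target_factor``; every overdose weight (OAR
        structures and the targets' own excess side) scales by
        ``oar_factor``."""
        targets = set(target_roles)
        return PenaltyConfig({
            role: (pen.scaled(target_factor, oar_factor) if role in targets
                   else pen.scaled(oar_factor))
            for role, pen in self.structures.items()
        })


def default_penalties(prescription: float = 10.0) -> PenaltyConfig:
    """Default planning template.

    CTV: prescription as lower bound, 1.5x prescription as upper bound,
    unit quadratic shortfall weight.  OARs: quadratic overdose penalties
    above 5 Gy, the contralateral wall weighted hardest.  These weights
    are package defaults for the synthetic phantoms, not published
    clinical values.
    """
    return PenaltyConfig({
        "ctv": StructurePenalty(lower=prescription, upper=1.5 * prescription,
                                q_low=1.0, q_high=0.1),
        "contra": StructurePenalty(upper=5.0, q_high=1.0),
        "sup": StructurePenalty(upper=5.0, q_high=0.5),
        "inf": StructurePenalty(upper=5.0, q_high=0.5),
    })


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

@dataclass
class RobustProblem:
    """Assembled robust instance: per-scenario dose matrices (Gy/s) with
    per-row penalty parameter vectors."""

    matrices: List[DoseMatrix]
    penalties: PenaltyConfig
    lambda_worst: float = 1.0
    mean_weight: float = 1.0
    # derived, filled by assemble_problem
    d_gy: List[np.ndarray] = field(default_factory=list, repr=False)
    lower: np.ndarray = field(default=None, repr=False)
    upper: np.ndarray = field(default=None, repr=False)
    w_low: np.ndarray = field(default=None, repr=False)
    w_high: np.ndarray = field(default=None, repr=False)
    q_low: np.ndarray = field(default=None, repr=False)
    q_high: np.ndarray = field(default=None, repr=False)

    @property
    def n_scenarios(self) -> int:
        return len(self.matrices)

    @property
    def n_combos(self) -> int:
        return self.matrices[0].n_combos

    @property
    def scenario_labels(self) -> List[str]:
        return [m.scenario.label for m in self.matrices]

    # -- penalty evaluation ------------------------------------------------

    def scenario_penalties(self, t: np.ndarray) -> np.ndarray:
        """g_r(t) for every scenario, recomputed from positive parts."""
        t = np.asarray(t, float)
        out = np.empty(self.n_scenarios)
        for r, D in enumerate(self.d_gy):
            dose = D @ t
            short = np.maximum(self.lower - dose, 0.0)
            over = np.maximum(dose - self.upper, 0.0)
            out[r] = (self.w_low @ short + self.q_low @ short ** 2
                      + self.w_high @ over + self.q_high @ over ** 2)
        return out

    def _penalty_and_grad(self, t: np.ndarray, r: int) -> Tuple[float, np.ndarray]:
        D = self.d_gy[r]
        dose = D @ t
        short = np.maximum(self.lower - dose, 0.0)
        over = np.maximum(dose - self.upper, 0.0)
        g = (self.w_low @ short + self.q_low @ short ** 2
             + self.w_high @ over + self.q_high @ over ** 2)
        coeff = (-(self.w_low * (short > 0)) - 2.0 * self.q_low * short
                 + self.w_high * (over > 0) + 2.0 * self.q_high * over)
        return float(g), D.T @ coeff

    def _penalty_hessian(self, t: np.ndarray, r: int) -> np.ndarray:
        """Hessian of g_r on the current smooth piece (active-set curvature)."""
        D = self.d_gy[r]
        dose = D @ t
        curv = (2.0 * self.q_low * (dose < self.lower)
                + 2.0 * self.q_high * (dose > self.upper))
        active = curv > 0
        Da = D[active]
        return (Da * curv[active][:, None]).T @ Da

    def constraint_counts(self) -> Dict[str, int]:
        """Constraint counts of the explicit quadratic program
        (shortfall/excess inequalities, scenario penalty and worst-case
        rows); structures with unbounded U contribute no excess rows."""
        n_r = self.n_scenarios
        n_lower = int(len(self.lower))
        n_upper = int(np.count_nonzero(np.isfinite(self.upper)))
        return {
            "lower": n_r * n_lower,
            "upper": n_r * n_upper,
            "scenario_penalty": n_r,
            "worst_case": n_r,
            "total": n_r * (n_lower + n_upper) + 2 * n_r,
        }


def assemble_problem(
    matrices: Sequence[DoseMatrix],
    penalties: PenaltyConfig,
    lambda_worst: float = 1.0,
    mean_weight: float = 1.0,
) -> RobustProblem:
    """Build the robust problem from per-scenario dose matrices.

    All matrices must share the dose-point indexing (same rows in the
    same order); every structure present must appear in the penalty
    table.
    """
    if not matrices:
        raise ValueError("at least one scenario matrix is required")
    if lambda_worst < 0 or mean_weight < 0:
        raise ValueError("objective weights must be nonnegative")
    if lambda_worst == 0 and mean_weight == 0:
        raise ValueError("objective weights must not both be zero")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != ref.values.shape or not np.array_equal(m.row_role, ref.row_role):
            raise ValueError("scenario matrices must share dose-point and combination indexing")
    roles = ref.role_order
    missing = [r for r in roles if r not in penalties.structures]
    if missing:
        raise ValueError(f"penalty table missing structures: {missing}")

    n = ref.n_points
    lower = np.zeros(n); upper = np.full(n, np.inf)
    wl = np.zeros(n); wh = np.zeros(n); ql = np.zeros(n); qh = np.zeros(n)
    for role in roles:
        rows = ref.rows_for(role)
        pen = penalties[role]
        lower[rows], upper[rows] = pen.lower, pen.upper
        wl[rows], wh[rows] = pen.w_low, pen.w_high
        ql[rows], qh[rows] = pen.q_low, pen.q_high

    prob = RobustProblem(
        matrices=list(matrices), penalties=penalties,
        lambda_worst=float(lambda_worst), mean_weight=float(mean_weight),
    )
    prob.d_gy = [m.values / CGY_PER_GY for m in matrices]
    prob.lower, prob.upper = lower, upper
    prob.w_low, prob.w_high, prob.q_low, prob.q_high = wl, wh, ql, qh
    return prob


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

@dataclass
class RobustSolution:
    """Optimum of a robust instance.

    Shortfall/excess variables are reported as the positive parts of
    (L - Dt) and (Dt - U) per scenario — their values in any optimal
    vertex of the explicit quadratic program.
    """

    dwell_times: np.ndarray                # seconds per combination
    shortfalls: List[np.ndarray]           # Gy, per scenario
    excesses: List[np.ndarray]             # Gy, per scenario
    scenario_penalties: np.ndarray         # z_r
    worst_penalty: float                   # z_w
    objective: float
    solver_status: str
    kkt_residual: float = np.nan
    n_iterations: int = 0

    @property
    def t(self) -> np.ndarray:
        return self.dwell_times


def objective_value(t: np.ndarray, problem: RobustProblem) -> Tuple[float, np.ndarray, float]:
    """Recompute (objective, z_r per scenario, z_w) from dwell times alone."""
    t = np.asarray(t, float)
    if np.any(t < -1e-12):
        raise ValueError("dwell times must be nonnegative")
    z = problem.scenario_penalties(np.maximum(t, 0.0))
    z_w = float(z.max())
    obj = problem.lambda_worst * z_w + problem.mean_weight * float(z.mean())
    return obj, z, z_w


def _weighted_objective(problem: RobustProblem, weights: np.ndarray):
    """Closure for sum_r c_r g_r(t) with gradient."""
    def fun(t):
        g_total, grad = 0.0, np.zeros(problem.n_combos)
        for r, c in enumerate(weights):
            if c == 0:
                continue
            g, gr = problem._penalty_and_grad(t, r)
            g_total += c * g
            grad += c * gr
        return g_total, grad
    return fun


def _projected_newton(problem: RobustProblem, weights: np.ndarray, t0: np.ndarray,
                      tol: float, max_iter: int = 60) -> np.ndarray:
    """Polish a weighted-sum minimizer to tight KKT residuals.

    Newton steps on the locally-active smooth quadratic piece, projected
    onto t >= 0 with backtracking; the piecewise-quadratic structure makes
    the active set stabilize after a few steps.
    """
    fun = _weighted_objective(problem, weights)
    t = np.maximum(np.asarray(t0, float), 0.0)
    f, grad = fun(t)
    for _ in range(max_iter):
        kkt = np.where(t > 0, np.abs(grad), np.maximum(-grad, 0.0))
        if kkt.max() <= tol:
            break
        free = (t > 0) | (grad < 0)
        if not free.any():
            break
        H = np.zeros((problem.n_combos, problem.n_combos))
        for r, c in enumerate(weights):
            if c:
                H += c * problem._penalty_hessian(t, r)
        Hf = H[np.ix_(free, free)]
        jitter = 1e-12 * max(np.trace(Hf) / max(Hf.shape[0], 1), 1.0)
        try:
            step = np.linalg.solve(Hf + jitter * np.eye(Hf.shape[0]), -grad[free])
        except np.linalg.LinAlgError:
            step = -grad[free]
        direction = np.zeros_like(t)
        direction[free] = step
        alpha, improved = 1.0, False
        for _ in range(30):
            t_new = np.maximum(t + alpha * direction, 0.0)
            f_new, grad_new = fun(t_new)
            if f_new <= f - 1e-16:
                t, f, grad = t_new, f_new, grad_new
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    return t


def _kkt_residual(problem: RobustProblem, weights: np.ndarray, t: np.ndarray) -> float:
    grad = np.zeros(problem.n_combos)
    for r, c in enumerate(weights):
        if c:
            grad += c * problem._penalty_and_grad(t, r)[1]
    return float(np.where(t > 0, np.abs(grad), np.maximum(-grad, 0.0)).max())


def _solve_weighted(problem: RobustProblem, weights: np.ndarray,
                    t0: np.ndarray | None, tol: float
                    ) -> Tuple[np.ndarray, str, int, float]:
    # normalize so the iterate sequence is invariant to objective scaling
    # (argmin is; this keeps ties resolved identically across scalings)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    fun = _weighted_objective(problem, weights)
    x0 = np.zeros(problem.n_combos) if t0 is None else np.asarray(t0, float)
    res = sciopt.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * problem.n_combos,
        options={"maxiter": 4000, "ftol": 1e-16, "gtol": 1e-12, "maxcor": 30},
    )
    t = _projected_newton(problem, weights, res.x, tol=min(tol, 1e-10))
    kkt = _kkt_residual(problem, weights, t)
    # the Newton polish is the authority on optimality, not L-BFGS-B's status
    scale = 1.0 + abs(fun(t)[0])
    status = "optimal" if kkt <= max(tol, 1e-8) * scale else f"stalled(kkt={kkt:.2e})"
    return t, status, res.nit, kkt


def _solve_minimax(problem: RobustProblem, tol: float
                   ) -> Tuple[np.ndarray, str, int, float]:
    """Epigraph formulation min lambda*z + mean-term s.t. g_r(t) <= z."""
    n, R = problem.n_combos, problem.n_scenarios
    lam, mw = problem.lambda_worst, problem.mean_weight
    mean_w = np.full(R, mw / R)

    t_init, _, _, _ = _solve_weighted(problem, mean_w + lam / R, None, tol)
    z_init = problem.scenario_penalties(t_init).max()
    x0 = np.append(t_init, z_init * (1 + 1e-9) + 1e-12)

    def f(u):
        g = 0.0
        grad = np.zeros(n + 1)
        for r in range(R):
            gr, grr = problem._penalty_and_grad(u[:n], r)
            g += mean_w[r] * gr
            grad[:n] += mean_w[r] * grr
        grad[n] = lam
        return g + lam * u[n], grad

    def f_hess(u):
        H = np.zeros((n + 1, n + 1))
        for r in range(R):
            if mean_w[r]:
                H[:n, :n] += mean_w[r] * problem._penalty_hessian(u[:n], r)
        return H

    def c_fun(u):
        return problem.scenario_penalties(u[:n]) - u[n]

    def c_jac(u):
        J = np.empty((R, n + 1))
        for r in range(R):
            _, gr = problem._penalty_and_grad(u[:n], r)
            J[r, :n] = gr
        J[:, n] = -1.0
        return J

    def c_hess(u, v):
        H = np.zeros((n + 1, n + 1))
        for r in range(R):
            if v[r]:
                H[:n, :n] += v[r] * problem._penalty_hessian(u[:n], r)
        return H

    constr = sciopt.NonlinearConstraint(c_fun, -np.inf, 0.0, jac=c_jac, hess=c_hess)
    bounds = sciopt.Bounds(
        np.append(np.zeros(n), -np.inf), np.full(n + 1, np.inf)
    )
    res = sciopt.minimize(
        f, x0, jac=True, hess=f_hess, method="trust-constr",
        constraints=[constr], bounds=bounds,
        options={"gtol": 1e-10, "xtol": 1e-14, "maxiter": 2000, "verbose": 0},
    )
    t = np.maximum(res.x[:n], 0.0)
    # KKT-based polish: at a minimax optimum the solution minimizes the
    # weighted sum with the epigraph constraints' multipliers (which sum
    # to lambda) added to the mean weights
    candidates = [t, t_init]
    try:
        mult = np.clip(np.asarray(res.v[0], float).ravel(), 0.0, None)
        if mult.shape == (R,) and mult.sum() > 0:
            w_kkt = mean_w + lam * mult / mult.sum()
            candidates.append(_projected_newton(problem, w_kkt, t, tol=1e-12))
    except (IndexError, AttributeError, TypeError):
        pass
    objs = [objective_value(c, problem)[0] for c in candidates]
    t = candidates[int(np.argmin(objs))]
    status = "optimal" if res.status in (1, 2) else f"trust-constr:{res.status}"
    return t, status, res.nit, float(res.optimality)


def solve(problem: RobustProblem, tol: float = 1e-8) -> RobustSolution:
    """Solve the robust instance to (convex) global optimality.

    ``tol`` is the absolute KKT/objective tolerance; repeated solves with
    fixed settings are bit-deterministic.
    """
    lam, mw, R = problem.lambda_worst, problem.mean_weight, problem.n_scenarios
    if R == 1 or lam == 0:
        weights = np.full(R, mw / R) + (lam if R == 1 else 0.0)
        t, status, nit, kkt = _solve_weighted(problem, weights, None, tol)
    else:
        t, status, nit, kkt = _solve_minimax(problem, tol)

    obj, z, z_w = objective_value(t, problem)
    shortfalls, excesses = [], []
    for D in problem.d_gy:
        dose = D @ t
        shortfalls.append(np.maximum(problem.lower - dose, 0.0))
        excesses.append(np.where(np.isfinite(problem.upper),
                                 np.maximum(dose - problem.upper, 0.0), 0.0))
    if "optimal" not in status:
        log.warning("solver finished with status %s (kkt residual %.3e)", status, kkt)
    return RobustSolution(
        dwell_times=t, shortfalls=shortfalls, excesses=excesses,
        scenario_penalties=z, worst_penalty=z_w, objective=obj,
        solver_status=status, kkt_residual=kkt, n_iterations=nit,
    )


# ---------------------------------------------------------------------------
# voxel-wise worst case
# ---------------------------------------------------------------------------

def voxelwise_worstcase(
    matrices: Sequence[DoseMatrix],
    roles: Mapping[str, str] | None = None,
) -> DoseMatrix:
    """Composite single-scenario matrix: per dose point, the minimum
    dose-rate contribution over scenarios for target rows and the maximum
    for OAR rows.

    ``roles`` maps structure role -> "target" | "oar"; by default the CTV
    is the target and every other structure an OAR.
    """
    if len(matrices) < 2:
        raise ValueError("voxel-wise worst case needs at least two scenarios")
    ref = matrices[0]
    if roles is None:
        roles = {r: ("target" if r == "ctv" else "oar") for r in ref.role_order}
    missing = [r for r in ref.role_order if r not in roles]
    if missing:
        raise ValueError(f"role classification missing for structures: {missing}")

    stack = np.stack([m.values for m in matrices])
    lo, hi = stack.min(axis=0), stack.max(axis=0)
    target_rows = np.isin(ref.row_role.astype(str),
                          [r for r, kind in roles.items() if kind == "target"])
    values = np.where(target_rows[:, None], lo, hi)
    return DoseMatrix(
        values=values, row_role=ref.row_role, row_voxel=ref.row_voxel,
        voxel_volume_cc=ref.voxel_volume_cc,
        scenario=ScenarioSpec(label="voxelwise-worst-case"),
        clamped_points=max(m.clamped_points for m in matrices),
    )


# ---------------------------------------------------------------------------
# penalty-weight tuning
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    penalties: PenaltyConfig
    trajectory: List[Tuple[float, float]]   # (ctv D90 Gy, target factor) per iteration
    converged: bool
    warning: str = ""


def tune_target_weight(
    problem: RobustProblem,
    eval_matrix: DoseMatrix,
    prescription: float = 10.0,
    max_iter: int = 15,
    tol: float = 0.02,
) -> TuneResult:
    """Automated analogue of manual penalty-weight fine-tuning.

    Target weights are increased and OAR weights decreased while the
    (un-rescaled) CTV D90 falls short of the prescription, and vice
    versa, multiplicatively, until the D90 is within ``tol`` (relative)
    of the prescription or ``max_iter`` is reached.
    """
    from .evaluate import cumulative_dvh, dose_at_volume_percent

    if prescription <= 0:
        raise ValueError("prescription must be positive")
    trajectory: List[Tuple[float, float]] = []
    current = problem
    best = (np.inf, problem.penalties)
    log_ratio = 0.0                      # cumulative log target/OAR weight ratio
    prev: Tuple[float, float] | None = None   # (log_ratio, log d90)
    for _ in range(max(int(max_iter), 1)):
        sol = solve(current)
        ctv_dose = eval_matrix.values[eval_matrix.rows_for("ctv")] @ sol.dwell_times / CGY_PER_GY
        d90 = dose_at_volume_percent(
            cumulative_dvh(ctv_dose, eval_matrix.voxel_volume_cc), 90.0)
        err = abs(d90 - prescription) / prescription
        trajectory.append((float(d90), 1.0))
        if err < best[0]:
            best = (err, current.penalties)
        if err <= tol or not np.isfinite(tol):
            return TuneResult(current.penalties, trajectory, True)
        if d90 <= 0:
            return TuneResult(best[1], trajectory, False, warning="CTV receives no dose")
        # secant step in log space on the monotone weight-ratio -> D90 map
        gap = math.log(prescription) - math.log(d90)
        if prev is not None and abs(math.log(d90) - prev[1]) > 1e-12:
            slope = (log_ratio - prev[0]) / (math.log(d90) - prev[1])
            step = float(np.clip(gap * slope, -6.0, 6.0))
        else:
            step = float(np.clip(gap, -1.5, 1.5))
        prev = (log_ratio, math.log(d90))
        log_ratio += step
        factor = math.exp(step / 2.0)     # split between target-up and OAR-down
        penalties = current.penalties.scaled(factor, 1.0 / factor)
        trajectory[-1] = (float(d90), factor)
        current = assemble_problem(current.matrices, penalties,
                                   current.lambda_worst, current.mean_weight)
    return TuneResult(best[1], trajectory, False,
                      warning=f"not converged after {max_iter} iterations")
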