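"""Growing and optimizing transition paths on a free energy surface.

The growing method starts from the reactant alone and appends snapshots one
at a time.  Each new snapshot is placed a fixed arc step s_g along a
direction blending the downhill free-energy force at the current end with a
unit pull toward the product,

    P_g = -dF/dchi(end) + w * unit(product - end),

normalized to unit length so that s_g is the geometric step (the raw,
unnormalized direction is available behind ``raw_direction``).  When the end
comes within s_g of the product, the product itself is appended and the path
is complete.  After every growth event the path is reparametrized to even
arc-length spacing and the existing snapshots are relaxed by a configurable
number of optimization sweeps.

Path optimization moves every non-anchor snapshot along the component of the
downhill force perpendicular to the path tangent,

    P_op = -dF/dchi + (dF/dchi . s) s,

by plain steepest descent (fixed or variable step), or by a limited-memory
quasi-Newton proposal damped by a step-control fraction s_step and followed
by an angle-based smoothing descent.  Convergence is monitored by the RMS
perpendicular gradient per CV dimension,

    sigma_perp = sqrt( sum_i |P_op(i)|^2 / (n m) ).

A budget ledger reproduces the simulation-time accounting of constrained-MD
runs: full-path optimization costs iterations x m snapshot-simulations,
growth with k sweeps per event costs k * sum_{i=1..m} i.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .exceptions import DegenerateDirectionError, GrowthStallError
from .path_model import Path, reparametrize, tangents
from .surfaces import CountingField

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GrowConfig:
    """Growth-phase settings: arc step s_g, product-pull weight w, and the
    number of relaxation sweeps applied after each new snapshot."""

    s_g: float = 0.1
    w: float = 10.0
    sweeps: int = 2
    s_op: float = 0.002          # step size of the growth-phase sweeps
    max_snapshots: int = 1000
    raw_direction: bool = False  # literal unnormalized P_g

    def __post_init__(self):
        if self.s_g <= 0 or self.w < 0 or self.sweeps < 0 or self.s_op <= 0:
            raise ValueError("GrowConfig requires s_g > 0, w >= 0, sweeps >= 0, s_op > 0")


@dataclass
class OptimizeConfig:
    """Full-path optimization settings.

    ``method`` is one of ``sd_fixed``, ``sd_variable``, ``quasi_newton``.
    The variable-step rule follows the published prescription literally —
    halve the step when the free-energy sum improves, reset it otherwise —
    with ``variable_inverted`` providing the conventional alternative.
    Smoothing defaults (1000 steps, step size 1e-4) apply to the
    quasi-Newton method only.
    """

    method: str = "sd_fixed"
    s_op: float = 0.002
    s_op_initial: float = 0.004   # starting/reset value for sd_variable
    s_step: float = 0.2           # quasi-Newton step-size control, (0, 1]
    memory: int = 5               # limited-memory depth
    smooth_steps: int = 1000
    smooth_step_size: float = 1e-4
    max_iter: int = 200
    sigma_threshold: float | None = None    # absolute sigma_perp stop
    sigma_rel_threshold: float = 0.05       # stop at 5% of initial sigma_perp
    variable_inverted: bool = False
    sigma_squared: bool = False   # alternative reading: mean squared norm, no root

    def __post_init__(self):
        if self.method not in ("sd_fixed", "sd_variable", "quasi_newton"):
            raise ValueError(f"unknown optimizer {self.method!r}")
        if not 0 < self.s_step <= 1:
            raise ValueError("s_step must be in (0, 1]")
        if min(self.s_op, self.s_op_initial, self.smooth_step_size) <= 0:
            raise ValueError("step sizes must be positive")


@dataclass(frozen=True)
class BudgetLedger:
    """Pure arithmetic on a simulation schedule; totals are recomputable."""

    simulations: int            # snapshot-simulations performed
    sampling_ps: Fraction       # constrained-MD sampling per simulation
    timestep_fs: Fraction
    m: int                      # snapshots on the finished path

    @property
    def total_ns(self) -> Fraction:
        return self.simulations * self.sampling_ps / 1000

    @property
    def steps_per_snapshot(self) -> Fraction:
        total_fs = self.simulations * self.sampling_ps * 1000
        return total_fs / (self.m * self.timestep_fs)


def budget(m: int, *, protocol: str, iterations: int | None = None,
           sweeps: int | None = None, sampling_ps, timestep_fs=1) -> BudgetLedger:
    """Simulation-budget accounting.

    ``protocol="full_path"``: ``iterations`` full-path sweeps cost
    iterations * m simulations.  ``protocol="growing"``: ``sweeps``
    relaxation sweeps after each growth event touch all current snapshots
    including the newest, so the total is sweeps * sum_{i=1..m} i.
    """
    sampling = Fraction(str(sampling_ps))
    step = Fraction(str(timestep_fs))
    if protocol == "full_path":
        if iterations is None:
            raise ValueError("full_path budget needs iterations")
        sims = iterations * m
    elif protocol == "growing":
        if sweeps is None:
            raise ValueError("growing budget needs sweeps")
        sims = sweeps * m * (m + 1) // 2
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return BudgetLedger(simulations=sims, sampling_ps=sampling,
                        timestep_fs=step, m=m)


# ---------------------------------------------------------------------------
# Elementary directions
# ---------------------------------------------------------------------------

def growth_direction(grad_at_end: np.ndarray, end, product, w: float,
                     space=None, raw: bool = False) -> np.ndarray:
    """Unit growing direction at the path end.

    -dF/dchi plus w times the unit vector toward the product, normalized to
    unit length (``raw=True`` returns the literal unnormalized blend)."""
    end_vals = np.asarray(getattr(end, "values", end), dtype=float)
    prod_vals = np.asarray(getattr(product, "values", product), dtype=float)
    if space is None:
        space = getattr(end, "space", None)
    to_prod = (space.displacement(end_vals, prod_vals) if space is not None
               else prod_vals - end_vals)
    dist = np.linalg.norm(to_prod)
    if dist < 1e-14:
        raise DegenerateDirectionError("path end coincides with the product")
    p = -np.asarray(grad_at_end, dtype=float) + w * to_prod / dist
    norm = np.linalg.norm(p)
    if norm < 1e-12:
        raise DegenerateDirectionError(
            "growth direction vanished: the gradient exactly cancels the product pull"
        )
    return p if raw else p / norm


def perp_component(grad: np.ndarray, tangent_vec: np.ndarray) -> np.ndarray:
    """P_op = -dF + (dF . s) s; exactly orthogonal to the unit tangent s."""
    t = np.asarray(tangent_vec, dtype=float)
    if abs(np.linalg.norm(t) - 1.0) > 1e-9:
        raise ValueError("tangent must be a unit vector")
    g = np.asarray(grad, dtype=float)
    p = -g + np.dot(g, t) * t
    return p - np.dot(p, t) * t  # second projection kills round-off along s


def perp_components(path: Path, grads: np.ndarray) -> np.ndarray:
    ts = tangents(path)
    g = np.asarray(grads, dtype=float)
    dots = np.sum(g * ts, axis=1, keepdims=True)
    p = -g + dots * ts
    p -= np.sum(p * ts, axis=1, keepdims=True) * ts
    return p


def sigma_perp_from_components(p_op: np.ndarray, n: int, m: int,
                               squared: bool = False) -> float:
    """The convergence metric straight from perpendicular components:
    sqrt(sum_i |P_op(i)|^2 / (n m))."""
    ms = float(np.sum(np.asarray(p_op, dtype=float) ** 2)) / (n * m)
    return ms if squared else float(np.sqrt(ms))


def sigma_perp(path: Path, grads, squared: bool = False) -> float:
    """RMS perpendicular gradient per CV dimension over the whole path.

    ``squared=True`` gives the alternative reading (mean squared norm,
    no square root)."""
    p = perp_components(path, np.asarray(grads, dtype=float))
    return sigma_perp_from_components(p, path.n, path.m, squared=squared)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _evaluate_gradients(path: Path, field) -> np.ndarray:
    return np.stack([np.asarray(field.gradient(path.points[i]), dtype=float)
                     for i in range(path.m)])


def sd_sweep(path: Path, field, s_op: float, grads: np.ndarray | None = None) -> Path:
    """One steepest-descent sweep: move every non-anchor snapshot by
    s_op * P_op, then reparametrize.  Gradients are evaluated once per
    snapshot per sweep unless supplied."""
    if s_op <= 0:
        raise ValueError("s_op must be positive")
    if grads is None:
        grads = _evaluate_gradients(path, field)
    p = perp_components(path, grads)
    pts = path.points.copy()
    mask = path.movable()
    pts[mask] += s_op * p[mask]
    newpath = Path(path.space.wrap(pts), path.space, complete=path.complete)
    return reparametrize(newpath)


def variable_step_controller(f_sum_history, s_op_current: float,
                             s_op_initial: float, inverted: bool = False) -> float:
    """Step-size rule of the variable-step steepest descent.

    As published: if the latest sum of snapshot free energies decreased,
    halve the step; otherwise reset it to the initial value.  ``inverted``
    applies the conventional rule (halve on increase) instead."""
    hist = list(f_sum_history)
    if len(hist) < 2:
        return s_op_current
    improved = hist[-1] < hist[-2]
    if inverted:
        improved = not improved
    return s_op_current * 0.5 if improved else s_op_initial


# ---------------------------------------------------------------------------
# Smoothing (angle objective)
# ---------------------------------------------------------------------------

def _bend_objective(points: np.ndarray, space) -> tuple[float, np.ndarray]:
    """f = sum_i (theta_i - pi)^2 over interior vertices, with its gradient.

    theta_i is the bending angle between chi^(i-1)-chi^(i) and
    chi^(i+1)-chi^(i).  Degenerate terms (folded vertices with undefined
    angle derivative) are skipped."""
    m, n = points.shape
    grad = np.zeros_like(points)
    if m < 3:
        return 0.0, grad
    u = space.wrap(points[:-2] - points[1:-1])
    v = space.wrap(points[2:] - points[1:-1])
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 1e-12) & (nv > 1e-12)
    cosang = np.zeros(m - 2)
    cosang[ok] = np.sum(u[ok] * v[ok], axis=1) / (nu[ok] * nv[ok])
    cosang = np.clip(cosang, -1.0, 1.0)
    theta = np.arccos(cosang)
    sin = np.sqrt(np.maximum(1.0 - cosang * cosang, 0.0))
    use = ok & (sin > 1e-10)
    f = float(np.sum((theta[ok] - np.pi) ** 2))
    if not np.any(use):
        return f, grad
    uhat = u[use] / nu[use][:, None]
    vhat = v[use] / nv[use][:, None]
    c = cosang[use][:, None]
    s = sin[use][:, None]
    # d theta / d u = -(vhat - cos uhat) / (|u| sin); same with u<->v
    dth_du = -(vhat - c * uhat) / (nu[use][:, None] * s)
    dth_dv = -(uhat - c * vhat) / (nv[use][:, None] * s)
    coeff = 2.0 * (theta[use] - np.pi)[:, None]
    idx = np.nonzero(use)[0] + 1  # interior vertex index
    np.add.at(grad, idx - 1, coeff * dth_du)
    np.add.at(grad, idx + 1, coeff * dth_dv)
    np.add.at(grad, idx, -coeff * (dth_du + dth_dv))
    return f, grad


def smooth_path(path: Path, steps: int = 1000, step_size: float = 1e-4) -> Path:
    """Steepest descent on the bending-angle objective over the movable
    snapshots; the objective never increases across the descent and the
    anchors stay fixed."""
    if path.m < 3:
        raise ValueError("smoothing needs m >= 3")
    pts = path.points.copy()
    mask = path.movable()
    f, grad = _bend_objective(pts, path.space)
    step = step_size
    for _ in range(steps):
        if f == 0.0 or not np.any(np.abs(grad[mask]) > 0):
            break
        trial = pts.copy()
        trial[mask] -= step * grad[mask]
        trial = path.space.wrap(trial)
        f_new, grad_new = _bend_objective(trial, path.space)
        if f_new > f:
            step *= 0.5
            if step < 1e-12 * step_size:
                break
            continue
        pts, f, grad = trial, f_new, grad_new
    return Path(pts, path.space, complete=path.complete)


def bend_objective_value(path: Path) -> float:
    return _bend_objective(path.points, path.space)[0]


# ---------------------------------------------------------------------------
# Quasi-Newton sweep
# ---------------------------------------------------------------------------

class QuasiNewtonOptimizer:
    """Limited-memory quasi-Newton updates of the whole path.

    All snapshots are stacked into one n*m vector; the quantity -P_op plays
    the role of the objective gradient.  The two-loop recursion builds a
    proposal chi_bfgs; the path moves only the fraction s_step of the way
    there, then is smoothed and reparametrized.  On the first iteration the
    recursion reduces to a scaled steepest-descent step.  A proposal that is
    not a descent direction triggers a fallback to one plain sd sweep.

    The angle smoothing guards against kinks while the quasi-Newton proposal
    is still taking aggressive steps; once the path nears convergence it is
    already smooth, and holding the smoothing at full strength would balance
    the perpendicular force and hold the path off the true minimum path in
    curved regions.  The smoothing step size is therefore tapered with the
    convergence metric: full strength while sigma_perp exceeds
    SMOOTH_TAPER_AT times its initial value, proportionally weaker below.
    """

    #: sigma_perp fraction of its initial value below which smoothing tapers
    SMOOTH_TAPER_AT = 0.25

    def __init__(self, cfg: OptimizeConfig):
        self.cfg = cfg
        self.pairs: deque[tuple[np.ndarray, np.ndarray]] = deque(maxlen=cfg.memory)
        self._prev_x: np.ndarray | None = None
        self._prev_g: np.ndarray | None = None
        self._sigma0: float | None = None
        self.fallbacks = 0

    def _two_loop(self, g: np.ndarray) -> np.ndarray:
        q = g.copy()
        alphas = []
        for s, y in reversed(self.pairs):
            rho = 1.0 / float(np.dot(y, s))
            a = rho * float(np.dot(s, q))
            alphas.append((a, rho, s, y))
            q -= a * y
        if self.pairs:
            s, y = self.pairs[-1]
            q *= float(np.dot(s, y) / np.dot(y, y))
        for a, rho, s, y in reversed(alphas):
            b = rho * float(np.dot(y, q))
            q += (a - b) * s
        return q  # approx H g

    def sweep(self, path: Path, field, grads: np.ndarray | None = None) -> Path:
        cfg = self.cfg
        if grads is None:
            grads = _evaluate_gradients(path, field)
        sigma = sigma_perp(path, grads)
        if self._sigma0 is None:
            self._sigma0 = sigma
        p = perp_components(path, grads)
        mask = path.movable()
        p[~mask] = 0.0
        g = -p.ravel()
        x = path.unwrapped().ravel()
        if self._prev_x is not None:
            s = x - self._prev_x
            y = g - self._prev_g
            if float(np.dot(s, y)) > 1e-12:
                self.pairs.append((s, y))
        d = -self._two_loop(g)
        if not np.all(np.isfinite(d)) or float(np.dot(d, g)) >= 0.0:
            self.fallbacks += 1
            log.warning("quasi-Newton proposal rejected; falling back to one sd sweep")
            self._prev_x, self._prev_g = x, g
            return sd_sweep(path, field, cfg.s_op, grads=grads)
        self._prev_x, self._prev_g = x, g
        move = cfg.s_step * d.reshape(path.points.shape)
        move[~mask] = 0.0
        pts = path.space.wrap(path.points + move)
        newpath = Path(pts, path.space, complete=path.complete)
        if newpath.m >= 3 and cfg.smooth_steps > 0:
            taper = min(1.0, sigma / (self.SMOOTH_TAPER_AT * self._sigma0))
            if taper > 0:
                newpath = smooth_path(newpath, cfg.smooth_steps,
                                      cfg.smooth_step_size * taper)
        return reparametrize(newpath)


def quasi_newton_sweep(path: Path, field, cfg: OptimizeConfig,
                       state: QuasiNewtonOptimizer | None = None) -> Path:
    """One quasi-Newton sweep (a fresh optimizer state unless one is passed)."""
    opt = state or QuasiNewtonOptimizer(cfg)
    return opt.sweep(path, field)


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

@dataclass
class OptimizeResult:
    path: Path
    sigma_trace: list[float]
    gradient_evaluations: int
    f_sum_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def optimize_path(path: Path, field_in, cfg: OptimizeConfig) -> OptimizeResult:
    """Iterate sweeps of the chosen optimizer until sigma_perp falls below
    the threshold (absolute if given, else the relative fraction of its
    initial value) or max_iter is reached."""
    field_cnt = CountingField(field_in)
    qn = QuasiNewtonOptimizer(cfg) if cfg.method == "quasi_newton" else None
    s_op = cfg.s_op_initial if cfg.method == "sd_variable" else cfg.s_op
    sigma_trace: list[float] = []
    f_sums: list[float] = []
    threshold = cfg.sigma_threshold
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        grads = _evaluate_gradients(path, field_cnt)
        sigma = sigma_perp(path, grads, squared=cfg.sigma_squared)
        sigma_trace.append(sigma)
        if threshold is None and cfg.sigma_rel_threshold is not None:
            threshold = cfg.sigma_rel_threshold * sigma_trace[0]
        if threshold is not None and sigma < threshold:
            converged = True
            break
        if cfg.method == "quasi_newton":
            path = qn.sweep(path, field_cnt, grads=grads)
        else:
            path = sd_sweep(path, field_cnt, s_op, grads=grads)
            if cfg.method == "sd_variable":
                if not field_cnt.has_value:
                    raise ValueError("sd_variable needs a field with values "
                                     "(the rule watches the free-energy sum)")
                f_sums.append(float(sum(field_cnt.value(p) for p in path.points)))
                s_op = variable_step_controller(
                    f_sums, s_op, cfg.s_op_initial, inverted=cfg.variable_inverted
                )
    return OptimizeResult(path=path, sigma_trace=sigma_trace,
                          gradient_evaluations=field_cnt.gradient_calls,
                          f_sum_trace=f_sums, iterations=it, converged=converged)


@dataclass
class GrowResult:
    path: Path
    gradient_evaluations: int
    growth_events: int
    sweep_simulations: int


def grow_step(path: Path, field, cfg: GrowConfig, product,
              grad_at_end: np.ndarray | None = None) -> tuple[Path, bool, np.ndarray | None]:
    """One growth event.

    If the end is within s_g of the product the product is appended and the
    path is complete.  Otherwise a new snapshot is placed s_g along the
    growing direction; the path is then reparametrized and relaxed by
    cfg.sweeps fixed-step sd sweeps over all current snapshots (the newest
    included).  Returns (path, finished, gradient at the new end from the
    last sweep, None if no sweep ran)."""
    space = path.space
    prod_vals = np.asarray(getattr(product, "values", product), dtype=float)
    end = path.points[-1]
    dist = np.linalg.norm(space.displacement(end, prod_vals))
    # the tiny slack keeps an exact multiple of s_g from landing a snapshot
    # on the product itself
    if dist < cfg.s_g * (1.0 + 1e-9):
        newpath = path.appended(prod_vals, complete=True)
        return reparametrize(newpath) if newpath.m >= 3 else newpath, True, None
    if grad_at_end is None:
        grad_at_end = np.asarray(field.gradient(end), dtype=float)
    direction = growth_direction(grad_at_end, end, prod_vals, cfg.w,
                                 space=space, raw=cfg.raw_direction)
    newpath = path.appended(end + cfg.s_g * direction, complete=False)
    if newpath.m > cfg.max_snapshots:
        raise GrowthStallError(
            f"growth exceeded {cfg.max_snapshots} snapshots before reaching the "
            "product (the gradient term is overwhelming w)"
        )
    if newpath.m >= 3:
        newpath = reparametrize(newpath)
    end_grad = None
    for _ in range(cfg.sweeps):
        grads = _evaluate_gradients(newpath, field)
        end_grad = grads[-1]
        newpath = sd_sweep(newpath, field, cfg.s_op, grads=grads)
    return newpath, False, end_grad


def grow_path(reactant, product, field_in, cfg: GrowConfig, space=None) -> GrowResult:
    """Grow a complete path from the reactant toward the product.

    The gradient at the growing end is reused from the last relaxation
    sweep, so the number of gradient evaluations matches the growing
    budget's accounting."""
    field_cnt = CountingField(field_in)
    if space is None:
        space = getattr(reactant, "space", None)
    r = np.asarray(getattr(reactant, "values", reactant), dtype=float)
    path = Path(r[None, :], space, complete=False)
    grad_end = None
    events = 0
    sweep_sims = 0
    while True:
        path, finished, grad_end = grow_step(path, field_cnt, cfg, product,
                                             grad_at_end=grad_end)
        if finished:
            break
        events += 1
        sweep_sims += cfg.sweeps * path.m
    # relax the now-complete path once more (the product end is anchored);
    # this is the final growth event's share of the sweep accounting
    for _ in range(cfg.sweeps):
        grads = _evaluate_gradients(path, field_cnt)
        path = sd_sweep(path, field_cnt, cfg.s_op, grads=grads)
        sweep_sims += path.m
    return GrowResult(path=path, gradient_evaluations=field_cnt.gradient_calls,
                      growth_events=events, sweep_simulations=sweep_sims)
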