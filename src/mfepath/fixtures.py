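"""Synthetic fixtures: the study conditions every test and example runs on.

``ala_like_2d`` emulates the qualitative geometry of an alanine-dipeptide
(Phi, Psi) free energy surface: two Gaussian wells of unequal depth (so the
end-to-end free energy difference is about 2 kcal/mol), a Gaussian barrier
offset from the straight line between them so that the linearly interpolated
path crosses the barrier while the optimal path curves around it through a
shallow intermediate valley, and a weak quartic confinement bowl.  The two
minima are separated by about 3.7 in CV units, so the published growth
protocol (s_g = 0.102, w = 10) yields a path of about 40 snapshots.  Nothing
about these parameters is claimed to match a real molecular surface.

Toy particle systems pair the constrained-dynamics estimator with closed
forms: a separable harmonic particle (exact mean force k (chi - chi0)) and
an anharmonically coupled variant whose multiplier fluctuates thermally with
a known analytic mean.

The module also hosts the independent steepest-descent-path oracle: dense
downhill integration of dchi/dt = -dF/dchi from the numerically located
saddle, in both directions, by an adaptive Runge-Kutta integrator.  It
shares no code with the string optimizers it validates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize, root

from .cv_model import CVSpace, CVSpec, CVVector
from .surfaces import AnalyticSurface, GridAxis, GridSurface
from .toy_md import HarmonicWell, QuadraticCoupling, SumPotential, ToySystem

# ---------------------------------------------------------------------------
# The 2-D double-well study surface
# ---------------------------------------------------------------------------

#: Fixed fixture parameters (CV units ~ radians, energies kcal/mol).
ALA_LIKE_PARAMS = dict(
    centers=[(-1.45, 1.47),   # reactant well (C7eq-like corner)
             (1.27, -1.00),   # product well (C7ax-like corner), shallower
             (0.10, 0.45),    # barrier, offset above the straight line
             (-0.25, -0.65)], # shallow intermediate valley below the line
    heights=[-6.0, -4.0, 9.0, -1.5],
    widths=[0.85, 0.85, 0.95, 0.70],
    confinement=dict(center=(0.0, 0.2), amp=1.0, radius=3.0),
)


def ala_like_surface() -> AnalyticSurface:
    """The bundled double-well surface used as the 2-D study fixture."""
    return AnalyticSurface("gaussian_wells", **ALA_LIKE_PARAMS)


def _refine_minimum(surface: AnalyticSurface, guess) -> np.ndarray:
    res = minimize(surface.value, np.asarray(guess, dtype=float),
                   jac=surface.gradient, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    return res.x


@dataclass(frozen=True)
class Scenario:
    """A surface together with its reactant/product minima and CV space."""

    surface: AnalyticSurface
    space: CVSpace
    reactant: np.ndarray
    product: np.ndarray

    @property
    def reactant_vec(self) -> CVVector:
        return CVVector(self.reactant, self.space)

    @property
    def product_vec(self) -> CVVector:
        return CVVector(self.product, self.space)


def ala_like_2d() -> Scenario:
    """The 2-D curved-valley scenario: surface plus refined minima."""
    surf = ala_like_surface()
    space = CVSpace.euclidean(2)
    r = _refine_minimum(surf, ALA_LIKE_PARAMS["centers"][0])
    p = _refine_minimum(surf, ALA_LIKE_PARAMS["centers"][1])
    return Scenario(surf, space, r, p)


def saddle_quadratic() -> Scenario:
    """F = x^2 - y^2: endpoints on the x-axis straddling the saddle."""

    class _Quad:
        has_value = True
        n = 2

        def value(self, chi):
            chi = np.asarray(getattr(chi, "values", chi), dtype=float)
            return float(chi[0] ** 2 - chi[1] ** 2)

        def gradient(self, chi):
            chi = np.asarray(getattr(chi, "values", chi), dtype=float)
            return np.array([2.0 * chi[0], -2.0 * chi[1]])

    return Scenario(_Quad(), CVSpace.euclidean(2),
                    np.array([-1.0, 0.0]), np.array([1.0, 0.0]))


def harmonic_nd(n: int = 2, k: float = 2.0) -> Scenario:
    surf = AnalyticSurface("harmonic", k=k, center=np.zeros(n))
    r = np.zeros(n)
    r[0] = -1.0
    p = np.zeros(n)
    p[0] = 1.0
    return Scenario(surf, CVSpace.euclidean(n), r, p)


def ala_like_grid(step: float = 0.05, order: str = "cubic",
                  lo: float = -3.2, hi: float = 3.2) -> GridSurface:
    """The study surface sampled on a regular grid (the precomputed-surface
    optimization route)."""
    surf = ala_like_surface()
    ax = GridAxis(lo, hi, step, periodic=False)
    nodes = ax.nodes
    xx, yy = np.meshgrid(nodes, nodes, indexing="ij")
    vals = np.empty_like(xx)
    for i in range(xx.shape[0]):
        for j in range(xx.shape[1]):
            vals[i, j] = surf.value(np.array([xx[i, j], yy[i, j]]))
    return GridSurface([ax, ax], vals, order=order)


# ---------------------------------------------------------------------------
# Toy particle systems
# ---------------------------------------------------------------------------

#: Default spring constant (kcal/mol/A^2) and well center of the harmonic toy.
HARMONIC_TOY_K = 2.0
HARMONIC_TOY_CENTER = np.array([[0.5, -0.3, 0.1]])


def harmonic_particle_2cv(k: float = HARMONIC_TOY_K) -> ToySystem:
    """One particle in a separable harmonic well; CVs are its x and y
    coordinates.  Constrained mean force along x is exactly k (c - x0)."""
    specs = (
        CVSpec("coordinate", ((0,),), axis=0),
        CVSpec("coordinate", ((0,),), axis=1),
    )
    return ToySystem(
        masses=np.array([12.0]),
        potential=HarmonicWell(k, HARMONIC_TOY_CENTER),
        cv_specs=specs,
        initial_coords=HARMONIC_TOY_CENTER.copy(),
    )


#: Spring constants of the bath oscillators in the coupled toy.  Spread so
#: the modes dephase quickly and the Berendsen thermostat sees a smooth
#: many-degree-of-freedom kinetic temperature.
COUPLED_BATH_K = (1.6, 2.0, 2.4, 2.8, 3.2)


def coupled_particle_2cv(k: float = HARMONIC_TOY_K, g: float = 0.15) -> ToySystem:
    """Constrained particle anharmonically coupled to a small harmonic bath.

    Atom 0 carries the two constrained CVs (its x and y).  Atoms 1..5 are
    free 3-D oscillators with distinct spring constants k_i; each bath z_i
    couples to the constrained x through g * x * z_i^2, so the Lagrange
    multiplier on x fluctuates thermally.  Canonical closed form:

        <lambda_x> = k c_x + g sum_i kB T / (k_i + 2 g c_x)

    (each bath z_i sees effective stiffness k_i + 2 g c_x at constrained
    x = c_x).  Requires k_i + 2 g c_x > 0.
    """
    natoms = 1 + len(COUPLED_BATH_K)
    specs = (
        CVSpec("coordinate", ((0,),), axis=0),
        CVSpec("coordinate", ((0,),), axis=1),
    )
    k_per_atom = np.array([k, *COUPLED_BATH_K])
    terms = [HarmonicWell(k_per_atom, np.zeros((natoms, 3)))]
    for i in range(1, natoms):
        terms.append(QuadraticCoupling(g, 0, 0, i, 2))
    return ToySystem(masses=np.full(natoms, 12.0),
                     potential=SumPotential(terms),
                     cv_specs=specs,
                     initial_coords=np.zeros((natoms, 3)))


def coupled_lambda_x_closed_form(c_x: float, temperature: float = 298.0,
                                 k: float = HARMONIC_TOY_K, g: float = 0.15) -> float:
    """Canonical mean of the x-constraint multiplier of the coupled toy."""
    from .constants import KB

    bath = sum(KB * temperature / (ki + 2.0 * g * c_x) for ki in COUPLED_BATH_K)
    return k * c_x + g * bath


def two_atom_distance_system(k: float = 3.0, rest: float = 2.0) -> ToySystem:
    """Two atoms tethered harmonically; one distance CV between them."""
    x0 = np.array([[0.0, 0.0, 0.0], [rest, 0.0, 0.0]])
    return ToySystem(
        masses=np.array([12.0, 16.0]),
        potential=HarmonicWell(k, x0),
        cv_specs=(CVSpec("distance", ((0, 1),)),),
        initial_coords=x0.copy(),
    )


# ---------------------------------------------------------------------------
# Steepest-descent-path oracle
# ---------------------------------------------------------------------------

def find_saddle(surface, guess, tol: float = 1e-10) -> np.ndarray:
    """Locate a stationary point of the surface near ``guess`` by Newton root
    finding on the gradient, and verify it is a first-order saddle (exactly
    one negative Hessian eigenvalue, by central finite differences)."""
    guess = np.asarray(guess, dtype=float)

    def grad(chi):
        return surface.gradient(chi)

    sol = root(grad, guess, tol=tol)
    if not sol.success or np.linalg.norm(grad(sol.x)) > 1e-6:
        raise RuntimeError(f"saddle search failed near {guess}: {sol.message}")
    h = 1e-4
    n = guess.size
    hess = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        hess[:, i] = (grad(sol.x + e) - grad(sol.x - e)) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    eig = np.linalg.eigvalsh(hess)
    if np.sum(eig < 0) != 1:
        raise RuntimeError(
            f"stationary point at {sol.x} is not a first-order saddle "
            f"(Hessian eigenvalues {eig})"
        )
    return sol.x


def descend_from_saddle(surface, saddle: np.ndarray, direction: np.ndarray,
                        kick: float = 1e-4, grad_tol: float = 1e-6,
                        t_max: float = 200.0, max_step: float = 0.01) -> np.ndarray:
    """Densely integrate dchi/dt = -dF/dchi downhill from a saddle.

    Starts a small kick along ``direction`` (the unstable eigenvector) and
    integrates with adaptive RK45 until the gradient norm falls below
    ``grad_tol``.  Returns the dense polyline including the saddle point.
    """

    def rhs(_t, chi):
        return -surface.gradient(chi)

    def arrived(_t, chi):
        return float(np.linalg.norm(surface.gradient(chi)) - grad_tol)

    arrived.terminal = True
    arrived.direction = -1
    x0 = saddle + kick * direction / np.linalg.norm(direction)
    sol = solve_ivp(rhs, (0.0, t_max), x0, max_step=max_step,
                    events=arrived, rtol=1e-9, atol=1e-11)
    pts = sol.y.T
    return np.vstack([saddle[None, :], pts])


def steepest_descent_path(surface, saddle: np.ndarray, **kw) -> np.ndarray:
    """Full dense minimum-path oracle through a saddle: downhill integration
    in both unstable directions, concatenated."""
    h = 1e-4
    n = saddle.size
    hess = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        hess[:, i] = (surface.gradient(saddle + e) - surface.gradient(saddle - e)) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    w, v = np.linalg.eigh(hess)
    unstable = v[:, int(np.argmin(w))]
    leg_a = descend_from_saddle(surface, saddle, unstable, **kw)
    leg_b = descend_from_saddle(surface, saddle, -unstable, **kw)
    return np.vstack([leg_a[::-1], leg_b[1:]])


def max_deviation_from_polyline(points: np.ndarray, polyline: np.ndarray) -> float:
    """Max over ``points`` of the distance to the dense ``polyline``
    (point-to-vertex, adequate for densely sampled oracles)."""
    d = np.linalg.norm(points[:, None, :] - polyline[None, :, :], axis=2)
    return float(np.max(np.min(d, axis=1)))
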