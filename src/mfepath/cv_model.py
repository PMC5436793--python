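"""Collective variables and the geometry of collective-variable (CV) space.

A collective variable is a scalar function of Cartesian atomic coordinates.
This module defines the supported CV kinds (interatomic distance, signed
dihedral, smooth hydrogen-bond count, raw coordinate), their values and
analytic gradients, and the geometry of the reduced space the variables
span: periodic wrapping, displacements and norms.

Conventions
-----------
* Dihedrals are IUPAC signed torsions in (-pi, pi]; differences between
  periodic components are always wrapped to the shortest arc.
* The CV-space norm is plain Euclidean on the wrapped displacement, mixing
  radians and Angstrom without rescaling.  An optional per-CV weight vector
  is available for users who want to rescale axes; it defaults to ones.
* Atom indices are 0-based inside the package (file formats use 1-based
  indices; conversion happens at the I/O boundary only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DimensionError, GeometryError

CV_KINDS = ("distance", "dihedral", "hbond_count", "coordinate")

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# CV specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVSpec:
    """Definition of one collective variable over Cartesian coordinates.

    Parameters
    ----------
    kind
        One of ``distance`` (one atom pair), ``dihedral`` (one atom
        quadruple), ``hbond_count`` (k donor-H/acceptor-O pairs entering a
        smooth switching sum), or ``coordinate`` (one atom, one Cartesian
        axis; used by toy particle systems).
    atom_indices
        Tuple of atom-index tuples, 0-based.
    d0
        Reference hydrogen-bond length in Angstrom (``hbond_count`` only).
        The contribution of a pair at separation d is 1/(1+(d/d0)^6), so a
        bond exactly at d0 counts one half.
    axis
        Cartesian axis for ``coordinate`` (0/1/2 or 'x'/'y'/'z').
    """

    kind: str
    atom_indices: tuple[tuple[int, ...], ...]
    d0: float | None = None
    axis: int = 0

    def __post_init__(self):
        if self.kind not in CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        idx = tuple(tuple(int(i) for i in t) for t in self.atom_indices)
        object.__setattr__(self, "atom_indices", idx)
        for t in idx:
            if len(set(t)) != len(t):
                raise ValueError(f"repeated atom index in tuple {t}")
        if self.kind == "distance":
            if len(idx) != 1 or len(idx[0]) != 2:
                raise ValueError("distance CV needs exactly one atom pair")
        elif self.kind == "dihedral":
            if len(idx) != 1 or len(idx[0]) != 4:
                raise ValueError("dihedral CV needs exactly one atom quadruple")
        elif self.kind == "hbond_count":
            if not idx or any(len(t) != 2 for t in idx):
                raise ValueError("hbond_count CV needs k atom pairs")
            if self.d0 is None or self.d0 <= 0:
                raise ValueError("hbond_count CV requires d0 > 0")
        elif self.kind == "coordinate":
            if len(idx) != 1 or len(idx[0]) != 1:
                raise ValueError("coordinate CV names exactly one atom")
            object.__setattr__(self, "axis", _AXES[self.axis])

    @property
    def periodic(self) -> bool:
        """Dihedrals live on a circle of period 2*pi; everything else on a line."""
        return self.kind == "dihedral"

    @property
    def period(self) -> float:
        return TWO_PI if self.periodic else 0.0

    def atoms(self) -> set[int]:
        return {i for t in self.atom_indices for i in t}


def _check_coords(spec: CVSpec, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise DimensionError("coords must have shape (n_atoms, 3)")
    top = max(spec.atoms())
    if top >= coords.shape[0]:
        raise IndexError(
            f"CV names atom {top} but coords hold only {coords.shape[0]} atoms"
        )
    return coords


# ---------------------------------------------------------------------------
# Values
# ---------------------------------------------------------------------------

def cv_value(spec: CVSpec, coords: np.ndarray) -> float:
    """Evaluate one collective variable at Cartesian coordinates ``coords``.

    Dihedrals are returned in (-pi, pi].  Degenerate dihedral geometry
    (three collinear atoms) raises :class:`GeometryError`.
    """
    coords = _check_coords(spec, coords)
    if spec.kind == "distance":
        i, j = spec.atom_indices[0]
        return float(np.linalg.norm(coords[j] - coords[i]))
    if spec.kind == "coordinate":
        (i,) = spec.atom_indices[0]
        return float(coords[i, spec.axis])
    if spec.kind == "hbond_count":
        total = 0.0
        for i, j in spec.atom_indices:
            d = np.linalg.norm(coords[j] - coords[i])
            total += 1.0 / (1.0 + (d / spec.d0) ** 6)
        return float(total)
    # dihedral, praxeolitic formulation
    p0, p1, p2, p3 = (coords[i] for i in spec.atom_indices[0])
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    scale = max(np.linalg.norm(b1), nb2, np.linalg.norm(b3))
    if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-10 * scale * scale:
        raise GeometryError("degenerate dihedral: three collinear atoms")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    phi = np.arctan2(y, x)
    if phi <= -np.pi:  # wrap -pi onto +pi
        phi += TWO_PI
    return float(phi)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

def cv_gradient(spec: CVSpec, coords: np.ndarray) -> np.ndarray:
    """Analytic gradient d(CV)/dx, shape (n_atoms, 3).

    Nonzero only on the atoms named by the spec.  These are the
    d(sigma_alpha)/dx_i entries that assemble the Z matrix of the
    constrained-dynamics correction term.
    """
    coords = _check_coords(spec, coords)
    grad = np.zeros_like(coords)
    if spec.kind == "distance":
        i, j = spec.atom_indices[0]
        r = coords[j] - coords[i]
        d = np.linalg.norm(r)
        if d < 1e-12:
            raise GeometryError("coincident atoms in distance CV")
        u = r / d
        grad[i] = -u
        grad[j] = u
        return grad
    if spec.kind == "coordinate":
        (i,) = spec.atom_indices[0]
        grad[i, spec.axis] = 1.0
        return grad
    if spec.kind == "hbond_count":
        for i, j in spec.atom_indices:
            r = coords[j] - coords[i]
            d = np.linalg.norm(r)
            if d < 1e-12:
                raise GeometryError("coincident atoms in hbond_count CV")
            u = (d / spec.d0) ** 6
            # d/dd [1/(1+u)] = -6 u / (d (1+u)^2)
            dnd = -6.0 * u / (d * (1.0 + u) ** 2)
            g = dnd * (r / d)
            grad[i] -= g
            grad[j] += g
        return grad
    # dihedral
    a0, a1, a2, a3 = spec.atom_indices[0]
    p0, p1, p2, p3 = coords[a0], coords[a1], coords[a2], coords[a3]
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    scale = max(np.linalg.norm(b1), nb2, np.linalg.norm(b3))
    if min(n1sq, n2sq) < (1e-10 * scale * scale) ** 2:
        raise GeometryError("degenerate dihedral: three collinear atoms")
    # signs match the atan2 convention used by cv_value
    g0 = nb2 / n1sq * n1
    g3 = -nb2 / n2sq * n2
    c1 = float(np.dot(b1, b2)) / (nb2 * nb2)
    c3 = float(np.dot(b3, b2)) / (nb2 * nb2)
    g1 = -(1.0 + c1) * g0 + c3 * g3
    g2 = c1 * g0 - (1.0 + c3) * g3
    grad[a0], grad[a1], grad[a2], grad[a3] = g0, g1, g2, g3
    return grad


# ---------------------------------------------------------------------------
# CV-space geometry
# ---------------------------------------------------------------------------

def wrap_values(values: np.ndarray, periodic: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Wrap periodic components into (-period/2, period/2].

    Broadcasts over leading axes: ``values`` may be one point (n,) or a
    stack (..., n).
    """
    out = np.array(values, dtype=float)
    idx = np.nonzero(periodic)[0]
    if idx.size == 0:
        return out
    p = periods[idx]
    v = out[..., idx]
    v = v - p * np.floor(v / p + 0.5)
    v = np.where(v <= -p / 2, v + p, v)  # boundary: prefer +p/2
    out[..., idx] = v
    return out


@dataclass(frozen=True)
class CVSpace:
    """The n-dimensional space spanned by the collective variables.

    Carries per-dimension periodicity flags and periods plus an optional
    per-CV weight vector used by the norm (defaults to ones).
    """

    periodic: tuple[bool, ...]
    periods: tuple[float, ...] | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        per = tuple(bool(p) for p in self.periodic)
        object.__setattr__(self, "periodic", per)
        if self.periods is None:
            object.__setattr__(
                self, "periods", tuple(TWO_PI if p else 0.0 for p in per)
            )
        else:
            object.__setattr__(self, "periods", tuple(float(p) for p in self.periods))
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))

    @classmethod
    def from_specs(cls, specs: Sequence[CVSpec]) -> "CVSpace":
        return cls(tuple(s.periodic for s in specs))

    @classmethod
    def euclidean(cls, n: int) -> "CVSpace":
        return cls((False,) * n)

    @property
    def n(self) -> int:
        return len(self.periodic)

    @property
    def _periodic_mask(self) -> np.ndarray:
        return np.asarray(self.periodic, dtype=bool)

    def wrap(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if values.shape[-1] != self.n:
            raise DimensionError(
                f"expected {self.n} components, got {values.shape[-1]}"
            )
        if not any(self.periodic):
            return np.array(values, dtype=float)
        return wrap_values(values, self._periodic_mask, np.asarray(self.periods))

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Componentwise b - a, periodic components wrapped to the shortest arc."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.shape[-1] != self.n:
            raise DimensionError("displacement endpoints must share the space dimension")
        return self.wrap(b - a)

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Euclidean norm of the wrapped displacement (optionally weighted)."""
        d = self.displacement(a, b)
        if self.weights is not None:
            d = d * np.asarray(self.weights)
        return float(np.linalg.norm(d))


@dataclass(frozen=True)
class CVVector:
    """A point chi in CV space: values plus the space geometry.

    Periodic components are stored wrapped into (-period/2, period/2].
    """

    values: np.ndarray
    space: CVSpace

    def __post_init__(self):
        v = self.space.wrap(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise DimensionError("CVVector holds a single point")

    @property
    def n(self) -> int:
        return self.space.n

    def displacement_to(self, other: "CVVector") -> np.ndarray:
        if other.space.periodic != self.space.periodic:
            raise DimensionError("CVVectors live in different spaces")
        return self.space.displacement(self.values, other.values)

    def distance_to(self, other: "CVVector") -> float:
        return float(np.linalg.norm(self.displacement_to(other)))


def cv_displacement(a: CVVector, b: CVVector) -> np.ndarray:
    """Displacement b - a with periodic wrapping; its Euclidean norm defines
    |chi_a - chi_b| everywhere in the package."""
    return a.displacement_to(b)
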