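"""Free-energy gradient providers that need no molecular simulation.

Two families:

* :class:`AnalyticSurface` — closed-form test surfaces (harmonic bowl,
  quartic double well, a Mueller-Brown-like three-well surface, and sums of
  Gaussian wells/barriers) with exact values and gradients.
* :class:`GridSurface` — a free energy surface tabulated on a regular grid
  (e.g. produced by a flooding / adaptive-bias simulation elsewhere) that is
  interpolated; gradients are the analytic derivative of the interpolant, so
  they are continuous inside each cell.

Anything exposing ``gradient(chi) -> ndarray`` (and optionally ``value``)
satisfies the :class:`GradientField` contract consumed by the path
optimizers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .exceptions import BoundsError, DimensionError, GridFormatError


@runtime_checkable
class GradientField(Protocol):
    """Contract for anything that returns the free-energy gradient dF/dchi."""

    has_value: bool

    def gradient(self, chi: np.ndarray) -> np.ndarray: ...


class CountingField:
    """Wrap a field and count gradient evaluations (feeds the budget ledger)."""

    def __init__(self, field):
        self._field = field
        self.has_value = getattr(field, "has_value", False)
        self.gradient_calls = 0

    def gradient(self, chi):
        self.gradient_calls += 1
        return self._field.gradient(chi)

    def value(self, chi):
        return self._field.value(chi)


# ---------------------------------------------------------------------------
# Analytic surfaces
# ---------------------------------------------------------------------------

class AnalyticSurface:
    """Closed-form free energy surface F(chi) with exact gradient.

    Supported forms
    ---------------
    harmonic
        F = 1/2 k |chi - center|^2.
    double_well
        Quartic double well along the axis through minima ``a`` and ``b``
        with harmonic confinement (stiffness ``kappa``) transverse to it:
        F = h (t^2/L^2 - 1)^2 + 1/2 kappa |r|^2 where t is the signed
        on-axis coordinate, L the half-separation and r the transverse
        part.  Gradient is exactly zero at a and b by construction.
    mueller_brown_like
        The classic sum of four anisotropic Gaussians, multiplied by
        ``scale`` so barriers land in a kcal/mol-like range.
    gaussian_wells
        F = sum_j h_j exp(-|chi - c_j|^2 / (2 w_j^2)) plus an optional
        quartic confinement bowl amp*(|chi-c|/radius)^4.  Negative h_j are
        wells, positive are barriers.
    """

    has_value = True

    def __init__(self, form: str, **params):
        self.form = form
        self.params = params
        if form == "harmonic":
            self._center = np.asarray(params["center"], dtype=float)
            self._k = float(params.get("k", 1.0))
            self.n = self._center.size
        elif form == "double_well":
            a = np.asarray(params["a"], dtype=float)
            b = np.asarray(params["b"], dtype=float)
            self._mid = 0.5 * (a + b)
            sep = b - a
            self._L = 0.5 * float(np.linalg.norm(sep))
            if self._L <= 0:
                raise ValueError("double_well minima must be distinct")
            self._e = sep / (2.0 * self._L)
            self._h = float(params.get("height", 1.0))
            self._kappa = float(params.get("kappa", 1.0))
            self.n = a.size
        elif form == "mueller_brown_like":
            self._scale = float(params.get("scale", 0.02))
            self._A = np.array([-200.0, -100.0, -170.0, 15.0])
            self._a = np.array([-1.0, -1.0, -6.5, 0.7])
            self._b = np.array([0.0, 0.0, 11.0, 0.6])
            self._c = np.array([-10.0, -10.0, -6.5, 0.7])
            self._x0 = np.array([1.0, 0.0, -0.5, -1.0])
            self._y0 = np.array([0.0, 0.5, 1.5, 1.0])
            self.n = 2
        elif form == "gaussian_wells":
            self._centers = np.asarray(params["centers"], dtype=float)
            self._heights = np.asarray(params["heights"], dtype=float)
            self._widths = np.asarray(params["widths"], dtype=float)
            if not (len(self._centers) == len(self._heights) == len(self._widths)):
                raise ValueError("centers/heights/widths must align")
            conf = params.get("confinement")
            self._conf = None
            if conf is not None:
                self._conf = (
                    np.asarray(conf["center"], dtype=float),
                    float(conf["amp"]),
                    float(conf["radius"]),
                )
            self.n = self._centers.shape[1]
        else:
            raise ValueError(f"unknown analytic form {form!r}")

    # -- evaluation ---------------------------------------------------------

    def value(self, chi: np.ndarray) -> float:
        chi = self._as_point(chi)
        if self.form == "harmonic":
            d = chi - self._center
            return 0.5 * self._k * float(np.dot(d, d))
        if self.form == "double_well":
            d = chi - self._mid
            t = float(np.dot(d, self._e))
            r = d - t * self._e
            return (
                self._h * (t * t / (self._L * self._L) - 1.0) ** 2
                + 0.5 * self._kappa * float(np.dot(r, r))
            )
        if self.form == "mueller_brown_like":
            x, y = chi
            dx = x - self._x0
            dy = y - self._y0
            e = np.exp(self._a * dx * dx + self._b * dx * dy + self._c * dy * dy)
            return self._scale * float(np.sum(self._A * e))
        # gaussian_wells
        d = chi[None, :] - self._centers
        r2 = np.sum(d * d, axis=1)
        f = float(np.sum(self._heights * np.exp(-r2 / (2.0 * self._widths**2))))
        if self._conf is not None:
            c, amp, rad = self._conf
            f += amp * (float(np.linalg.norm(chi - c)) / rad) ** 4
        return f

    def gradient(self, chi: np.ndarray) -> np.ndarray:
        chi = self._as_point(chi)
        if self.form == "harmonic":
            return self._k * (chi - self._center)
        if self.form == "double_well":
            d = chi - self._mid
            t = float(np.dot(d, self._e))
            r = d - t * self._e
            dfdt = 4.0 * self._h * t * (t * t / (self._L * self._L) - 1.0) / (self._L * self._L)
            return dfdt * self._e + self._kappa * r
        if self.form == "mueller_brown_like":
            x, y = chi
            dx = x - self._x0
            dy = y - self._y0
            e = self._A * np.exp(self._a * dx * dx + self._b * dx * dy + self._c * dy * dy)
            gx = float(np.sum(e * (2.0 * self._a * dx + self._b * dy)))
            gy = float(np.sum(e * (self._b * dx + 2.0 * self._c * dy)))
            return self._scale * np.array([gx, gy])
        d = chi[None, :] - self._centers
        r2 = np.sum(d * d, axis=1)
        # d/dchi of h exp(-r2/2w^2) = -h exp(.)/w^2 * (chi - c)
        amp = self._heights * np.exp(-r2 / (2.0 * self._widths**2)) / self._widths**2
        g = -np.sum(amp[:, None] * d, axis=0)
        if self._conf is not None:
            c, ampc, rad = self._conf
            dc = chi - c
            r = float(np.linalg.norm(dc))
            if r > 0:
                g = g + 4.0 * ampc * r**2 / rad**4 * dc
        return g

    def _as_point(self, chi) -> np.ndarray:
        chi = np.asarray(getattr(chi, "values", chi), dtype=float)
        if chi.shape != (self.n,):
            raise DimensionError(f"surface is {self.n}-dimensional, got shape {chi.shape}")
        return chi


def analytic_eval(surface: AnalyticSurface, chi) -> tuple[float, np.ndarray]:
    """Closed-form (F, dF/dchi) at chi."""
    return surface.value(chi), surface.gradient(chi)


# ---------------------------------------------------------------------------
# Gridded surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridAxis:
    lo: float
    hi: float
    step: float
    periodic: bool = False

    def __post_init__(self):
        object.__setattr__(self, "lo", float(self.lo))
        object.__setattr__(self, "hi", float(self.hi))
        object.__setattr__(self, "step", float(self.step))
        object.__setattr__(self, "periodic", bool(self.periodic))
        if self.hi <= self.lo or self.step <= 0:
            raise ValueError("axis requires hi > lo and step > 0")
        n = (self.hi - self.lo) / self.step
        if abs(n - round(n)) > 1e-8:
            raise ValueError("axis span must be an integer number of steps")

    @property
    def npoints(self) -> int:
        return int(round((self.hi - self.lo) / self.step)) + 1

    @property
    def nodes(self) -> np.ndarray:
        return self.lo + self.step * np.arange(self.npoints)

    @property
    def period(self) -> float:
        return self.hi - self.lo


class GridSurface:
    """Free energy surface tabulated on a regular grid, interpolated.

    ``order`` is ``"linear"`` (multilinear, any dimension) or ``"cubic"``
    (bicubic spline, two dimensions only).  Periodic axes interpolate across
    the seam; for them the first and last grid columns describe the same
    state and must agree.  Evaluation outside a non-periodic axis raises
    :class:`BoundsError` — there is no extrapolation.
    """

    has_value = True

    def __init__(self, axes: Sequence[GridAxis], values: np.ndarray, order: str = "linear"):
        self.axes = tuple(axes)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != tuple(ax.npoints for ax in self.axes):
            raise ValueError(
                f"grid shape {self.values.shape} inconsistent with axes "
                f"{tuple(ax.npoints for ax in self.axes)}"
            )
        if order not in ("linear", "cubic"):
            raise ValueError("order must be 'linear' or 'cubic'")
        if order == "cubic" and len(self.axes) != 2:
            raise ValueError("cubic interpolation is implemented for 2-D grids only")
        self.order = order
        self.n = len(self.axes)
        self._spline = None
        if order == "cubic":
            self._spline = self._build_spline()

    # -- spline with periodic padding --------------------------------------

    _PAD = 3

    def _build_spline(self):
        ax0, ax1 = self.axes
        x, y = ax0.nodes, ax1.nodes
        v = self.values
        pad = self._PAD

        def extend(nodes, axis_obj, arr, axis):
            if not axis_obj.periodic:
                return nodes, arr
            period = axis_obj.period
            core = np.take(arr, range(arr.shape[axis] - 1), axis=axis)  # drop duplicate seam
            n_core = core.shape[axis]
            left = np.take(core, range(n_core - pad, n_core), axis=axis)
            right = np.take(core, range(0, pad + 1), axis=axis)
            arr2 = np.concatenate([left, core, right], axis=axis)
            nd = nodes[:-1]
            nodes2 = np.concatenate([nd[-pad:] - period, nd, nd[: pad + 1] + period])
            return nodes2, arr2

        x, v = extend(x, ax0, v, 0)
        y, v = extend(y, ax1, v, 1)
        return RectBivariateSpline(x, y, v, kx=3, ky=3)

    # -- coordinate handling ------------------------------------------------

    def _map_in(self, chi) -> np.ndarray:
        chi = np.asarray(getattr(chi, "values", chi), dtype=float)
        if chi.shape != (self.n,):
            raise DimensionError(f"grid is {self.n}-dimensional, got shape {chi.shape}")
        out = np.array(chi)
        for k, ax in enumerate(self.axes):
            if ax.periodic:
                out[k] = ax.lo + (out[k] - ax.lo) % ax.period
            elif out[k] < ax.lo - 1e-12 or out[k] > ax.hi + 1e-12:
                raise BoundsError(
                    f"coordinate {out[k]:.6g} outside non-periodic axis "
                    f"[{ax.lo:.6g}, {ax.hi:.6g}] (no extrapolation)"
                )
            else:
                out[k] = min(max(out[k], ax.lo), ax.hi)
        return out

    # -- evaluation ----------------------------------------------------------

    def value(self, chi) -> float:
        p = self._map_in(chi)
        if self.order == "cubic":
            return float(self._spline(p[0], p[1])[0, 0])
        return self._multilinear(p, derivative=None)

    def gradient(self, chi) -> np.ndarray:
        p = self._map_in(chi)
        if self.order == "cubic":
            return np.array(
                [
                    float(self._spline(p[0], p[1], dx=1)[0, 0]),
                    float(self._spline(p[0], p[1], dy=1)[0, 0]),
                ]
            )
        return np.array([self._multilinear(p, derivative=k) for k in range(self.n)])

    def _multilinear(self, p: np.ndarray, derivative: int | None):
        idx = []
        frac = []
        for k, ax in enumerate(self.axes):
            t = (p[k] - ax.lo) / ax.step
            i = int(np.floor(t))
            i = min(max(i, 0), ax.npoints - 2)
            idx.append(i)
            frac.append(t - i)
        total = 0.0
        for corner in itertools.product((0, 1), repeat=self.n):
            w = 1.0
            for k, c in enumerate(corner):
                if derivative == k:
                    w *= (1.0 if c else -1.0) / self.axes[k].step
                else:
                    w *= frac[k] if c else 1.0 - frac[k]
            total += w * self.values[tuple(idx[k] + corner[k] for k in range(self.n))]
        return float(total)


def grid_gradient(grid: GridSurface, chi) -> np.ndarray:
    """Gradient of the grid interpolant at chi."""
    return grid.gradient(chi)


# ---------------------------------------------------------------------------
# Grid file format
# ---------------------------------------------------------------------------
#
# Delimited text: one header line per axis
#     # axis <i> <min> <max> <step> <periodic 0|1>
# then one "chi_1 ... chi_n F" row per node, row-major in node order.
# Units: kcal/mol and CV-native units.  Extra "# key value" comment lines
# are preserved-agnostic (ignored on load).

def save_grid(path, grid: GridSurface, header_extra: Sequence[str] = ()) -> None:
    lines = []
    for extra in header_extra:
        lines.append(f"# {extra}")
    for i, ax in enumerate(grid.axes, start=1):
        lines.append(
            f"# axis {i} {ax.lo!r} {ax.hi!r} {ax.step!r} {1 if ax.periodic else 0}"
        )
    mesh = np.meshgrid(*[ax.nodes for ax in grid.axes], indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)
    flat = grid.values.ravel()
    for row, f in zip(coords, flat):
        lines.append(" ".join(repr(float(c)) for c in row) + " " + repr(float(f)))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_grid(path, order: str = "linear") -> GridSurface:
    axes: list[GridAxis] = []
    rows: list[tuple[int, list[float]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "axis":
                    try:
                        lo, hi, step = map(float, parts[2:5])
                        per = parts[5] not in ("0", "false", "False")
                        axes.append(GridAxis(lo, hi, step, per))
                    except (ValueError, IndexError) as exc:
                        raise GridFormatError(f"bad axis header: {exc}", lineno)
                continue
            try:
                vals = [float(tok) for tok in line.split()]
            except ValueError:
                raise GridFormatError("non-numeric cell", lineno)
            rows.append((lineno, vals))
    if not axes:
        raise GridFormatError("no axis headers found")
    n = len(axes)
    expected = int(np.prod([ax.npoints for ax in axes]))
    if len(rows) != expected:
        raise GridFormatError(
            f"expected {expected} node rows for the declared axes, found {len(rows)}"
        )
    mesh = np.meshgrid(*[ax.nodes for ax in axes], indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)
    values = np.empty(expected)
    for k, (lineno, vals) in enumerate(rows):
        if len(vals) != n + 1:
            raise GridFormatError(
                f"expected {n + 1} columns, found {len(vals)}", lineno
            )
        if any(np.isnan(vals)):
            raise GridFormatError("NaN cell", lineno)
        node = coords[k]
        if not np.allclose(vals[:n], node, atol=1e-8, rtol=0):
            raise GridFormatError(
                f"row coordinates {vals[:n]} do not match expected node "
                f"{node.tolist()} (rows must be row-major)",
                lineno,
            )
        values[k] = vals[n]
    grid = GridSurface(axes, values.reshape([ax.npoints for ax in axes]), order=order)
    return grid


# ---------------------------------------------------------------------------
# Consistency helper
# ---------------------------------------------------------------------------

def finite_difference_gradient(field, chi: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of field.value — the generic oracle used by
    the gradient-consistency property tests."""
    chi = np.asarray(chi, dtype=float)
    g = np.zeros_like(chi)
    for k in range(chi.size):
        e = np.zeros_like(chi)
        e[k] = h
        g[k] = (field.value(chi + e) - field.value(chi - e)) / (2 * h)
    return g
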