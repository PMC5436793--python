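"""Paths in collective-variable space.

A path is an ordered sequence of m snapshots (points in CV space) whose
first snapshot — the reactant — is always anchored, and whose last snapshot
is anchored once the path is complete (has reached the product).  The
underlying continuous curve is a cubic spline through the snapshots
(not-a-knot ends; piecewise linear for m < 4) parametrized by cumulative
chord length.  Arc length is measured segment-by-segment with composite
Simpson's rule; reparametrization moves snapshots to equal arc-length
fractions on the same curve, keeping the endpoints fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline

from .cv_model import CVSpace, CVVector
from .exceptions import DimensionError, GeometryError, GridFormatError

#: Simpson subdivisions per inter-snapshot segment used for arc length.
SIMPSON_INTERVALS = 16

#: dense samples per segment used to invert s(t) during reparametrization
_DENSE = 64


@dataclass(frozen=True)
class Path:
    """Ordered snapshots chi^(1..m) in CV space.

    ``complete`` marks that the last snapshot is the product and therefore
    anchored; during growth it is False and the growing end may move.
    """

    points: np.ndarray  # (m, n), wrapped
    space: CVSpace
    complete: bool = True

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != self.space.n:
            raise DimensionError("snapshot dimension does not match CV space")
        pts = self.space.wrap(pts)
        object.__setattr__(self, "points", pts)
        if self.complete and len(pts) < 2:
            raise ValueError("a complete path needs at least two snapshots")
        for i in range(len(pts) - 1):
            if np.linalg.norm(self.space.displacement(pts[i], pts[i + 1])) == 0.0:
                raise ValueError(f"consecutive snapshots {i},{i + 1} coincide")

    @property
    def m(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return self.space.n

    @property
    def anchors(self) -> tuple[int, ...]:
        if self.complete and self.m >= 2:
            return (0, self.m - 1)
        return (0,)

    def movable(self) -> np.ndarray:
        """Boolean mask of snapshots the optimizers may move."""
        mask = np.ones(self.m, dtype=bool)
        for a in self.anchors:
            mask[a] = False
        return mask

    def snapshot(self, i: int) -> CVVector:
        return CVVector(self.points[i], self.space)

    def with_points(self, points: np.ndarray) -> "Path":
        return replace(self, points=points)

    def appended(self, point: np.ndarray, complete: bool = False) -> "Path":
        pts = np.vstack([self.points, self.space.wrap(np.asarray(point, dtype=float))])
        return Path(pts, self.space, complete=complete)

    def reversed(self) -> "Path":
        return Path(self.points[::-1].copy(), self.space, complete=self.complete)

    # -- unwrapped view ------------------------------------------------------

    def unwrapped(self) -> np.ndarray:
        """Snapshots as a continuous curve: periodic jumps removed by
        accumulating shortest-arc displacements from the first snapshot."""
        pts = self.points
        out = np.empty_like(pts)
        out[0] = pts[0]
        for i in range(1, len(pts)):
            out[i] = out[i - 1] + self.space.displacement(pts[i - 1], pts[i])
        return out


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def interpolate_linear(reactant, product, m: int, space: CVSpace | None = None) -> Path:
    """Straight-line initial path: m snapshots evenly spaced between reactant
    and product, periodic components along the shortest arc."""
    if m < 2:
        raise ValueError("a path needs m >= 2 snapshots")
    if isinstance(reactant, CVVector):
        space = reactant.space
        reactant = reactant.values
        product = getattr(product, "values", product)
    if space is None:
        raise ValueError("pass CVVectors or an explicit CVSpace")
    reactant = np.asarray(reactant, dtype=float)
    product = np.asarray(product, dtype=float)
    disp = space.displacement(reactant, product)
    frac = np.linspace(0.0, 1.0, m)[:, None]
    pts = reactant[None, :] + frac * disp[None, :]
    return Path(pts, space, complete=True)


# ---------------------------------------------------------------------------
# The interpolating curve
# ---------------------------------------------------------------------------

def _curve(path: Path):
    """Interpolating spline through the (unwrapped) snapshots, parametrized by
    cumulative chord length.  Natural cubic for m >= 4, linear below."""
    pts = path.unwrapped()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0.0:
        raise GeometryError("degenerate path: zero total length")
    if path.m >= 4:
        # not-a-knot ends: natural ends flatten curvature at the anchors and
        # bias Simpson lengths by ~1e-5 relative, breaking refinement
        # stability at the 1e-6 level
        sp = CubicSpline(t, pts, bc_type="not-a-knot")
    else:
        sp = make_interp_spline(t, pts, k=1)
    return sp, t


def _segment_simpson(speed, a: float, b: float, k: int = SIMPSON_INTERVALS) -> float:
    ts = np.linspace(a, b, k + 1)
    v = speed(ts)
    h = (b - a) / k
    return h / 3.0 * (v[0] + v[-1] + 4.0 * np.sum(v[1:-1:2]) + 2.0 * np.sum(v[2:-2:2]))


def arc_length(path: Path) -> float:
    """Total arc length of the interpolating curve, per-segment composite
    Simpson's rule with a fixed subdivision count."""
    if path.m < 2:
        raise ValueError("arc length needs m >= 2")
    sp, t = _curve(path)
    dsp = sp.derivative()

    def speed(ts):
        d = dsp(ts)
        return np.linalg.norm(np.atleast_2d(d), axis=1)

    return float(sum(_segment_simpson(speed, t[i], t[i + 1]) for i in range(len(t) - 1)))


def _cumulative_table(path: Path):
    """Dense (t, s) table along the curve for arc-length inversion."""
    sp, t = _curve(path)
    dsp = sp.derivative()
    ts = []
    for i in range(len(t) - 1):
        seg = np.linspace(t[i], t[i + 1], _DENSE + 1)
        ts.append(seg if i == 0 else seg[1:])
    ts = np.concatenate(ts)
    speed = np.linalg.norm(np.atleast_2d(dsp(ts)), axis=1)
    # cumulative Simpson on consecutive pairs (uniform within each segment)
    s = np.zeros_like(ts)
    mid_t = 0.5 * (ts[:-1] + ts[1:])
    mid_v = np.linalg.norm(np.atleast_2d(dsp(mid_t)), axis=1)
    ds = (ts[1:] - ts[:-1]) / 6.0 * (speed[:-1] + 4.0 * mid_v + speed[1:])
    s[1:] = np.cumsum(ds)
    return sp, ts, s


def reparametrize(path: Path) -> Path:
    """Move snapshots to equal arc-length fractions xi_i = (i-1)/(m-1) on the
    same interpolating curve.  Endpoints are unmoved."""
    if path.m < 3:
        return path
    sp, ts, s = _cumulative_table(path)
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate path: zero total length")
    targets = np.linspace(0.0, total, path.m)
    t_new = np.interp(targets, s, ts)
    pts = np.atleast_2d(sp(t_new))
    pts[0] = path.unwrapped()[0]
    pts[-1] = path.unwrapped()[-1]
    return Path(path.space.wrap(pts), path.space, complete=path.complete)


def segment_lengths(path: Path) -> np.ndarray:
    """Chord lengths between consecutive snapshots (wrapped displacements)."""
    return np.array(
        [
            np.linalg.norm(path.space.displacement(path.points[i], path.points[i + 1]))
            for i in range(path.m - 1)
        ]
    )


def xi_fractions(path: Path) -> np.ndarray:
    """Arc-length fraction of each snapshot along the chord polyline."""
    seg = segment_lengths(path)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s / s[-1]


# ---------------------------------------------------------------------------
# Tangents
# ---------------------------------------------------------------------------

def tangent(path: Path, i: int) -> np.ndarray:
    """Unit tangent s^(i): central difference for interior snapshots,
    one-sided at the ends, periodic wrapping applied."""
    if not 0 <= i < path.m:
        raise IndexError(f"snapshot index {i} out of range")
    pts = path.points
    sp = path.space
    if i == 0:
        d = sp.displacement(pts[0], pts[1])
    elif i == path.m - 1:
        d = sp.displacement(pts[-2], pts[-1])
    else:
        d = sp.displacement(pts[i - 1], pts[i + 1])
    norm = np.linalg.norm(d)
    if norm < 1e-14:
        raise GeometryError(f"zero-norm tangent at snapshot {i}")
    return d / norm


def tangents(path: Path) -> np.ndarray:
    return np.stack([tangent(path, i) for i in range(path.m)])


# ---------------------------------------------------------------------------
# Path file format
# ---------------------------------------------------------------------------
#
#   # n=<dim> periodic=<comma flags> units=<comma list>
#   (optional further "# key value" comment lines)
#   one snapshot per row, whitespace-delimited

def save_path(fname, path: Path, units: list[str] | None = None,
              header_extra: list[str] | None = None) -> None:
    per = ",".join("1" if p else "0" for p in path.space.periodic)
    units = units or ["cv"] * path.n
    lines = [f"# n={path.n} periodic={per} units={','.join(units)}"]
    if not path.complete:
        lines.append("# complete 0")
    for extra in header_extra or ():
        lines.append(f"# {extra}")
    for row in path.points:
        lines.append(" ".join(repr(float(v)) for v in row))
    with open(fname, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_path(fname) -> Path:
    space = None
    complete = True
    rows = []
    with open(fname) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n="):
                    fields = dict(tok.split("=", 1) for tok in body.split())
                    per = tuple(f == "1" for f in fields["periodic"].split(","))
                    if len(per) != int(fields["n"]):
                        raise GridFormatError("periodic flags do not match n", lineno)
                    space = CVSpace(per)
                elif body.startswith("complete"):
                    complete = body.split()[1] != "0"
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError:
                raise GridFormatError("non-numeric snapshot row", lineno)
    if space is None:
        raise GridFormatError("missing '# n=... periodic=...' header")
    pts = np.asarray(rows, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != space.n:
        raise GridFormatError("snapshot rows do not match declared dimension")
    return Path(pts, space, complete=complete)
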