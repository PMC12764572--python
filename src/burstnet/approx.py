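"""Piecewise-linear substitution of nonlinear functions.

Digital neuron datapaths avoid hardware multipliers by replacing the cubic
and quadratic terms of the Hindmarsh-Rose right-hand side (and the decaying
exponential of the plasticity window) with short tables of line segments
``a*x + b``.  This module holds those fixed tables, the random breakpoint
search that produced them, and the normalized error metrics used to judge a
substitution against the exact curve.

Conventions
-----------
Segments are half-open ``[lo, hi)``: a breakpoint value belongs to the
segment on its right.  The outermost segments extend to +/- infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PiecewiseLinear",
    "SearchConfig",
    "PiecewiseFit",
    "PiecewiseFitResults",
    "cube_table",
    "square_table",
    "exp_table",
    "nmae_curve",
    "nrmse_curve",
    "search_best_fit",
]


@dataclass(frozen=True)
class PiecewiseLinear:
    """An ordered piecewise-linear function of one real variable.

    Parameters
    ----------
    breakpoints : ndarray, shape (k-1,)
        Interior segment boundaries, strictly increasing.  With ``k``
        segments there are ``k - 1`` interior breakpoints; the first and
        last segments extend to -inf and +inf respectively.
    slopes, intercepts : ndarray, shape (k,)
        Coefficients of ``a*x + b`` per segment, left to right.
    domain : tuple of float
        Nominal fitting domain (metadata only; evaluation is total).
    """

    breakpoints: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    domain: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        a = np.asarray(self.slopes, dtype=float)
        b = np.asarray(self.intercepts, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("slopes and intercepts must be 1-D and equal length")
        if bp.shape != (a.size - 1,):
            raise ValueError("need exactly one fewer breakpoint than segments")
        if bp.size and np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "slopes", a)
        object.__setattr__(self, "intercepts", b)

    @property
    def n_segments(self) -> int:
        return self.slopes.size

    def segment_index(self, x):
        """Index of the segment containing ``x`` (breakpoints go right)."""
        return np.searchsorted(self.breakpoints, x, side="right")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        i = self.segment_index(x)
        return self.slopes[i] * x + self.intercepts[i]

    @property
    def segments(self) -> list[tuple[float, float, float, float]]:
        """Segments as ``(lo, hi, slope, intercept)`` tuples."""
        edges = np.concatenate(([-np.inf], self.breakpoints, [np.inf]))
        return [
            (edges[i], edges[i + 1], self.slopes[i], self.intercepts[i])
            for i in range(self.n_segments)
        ]

    @classmethod
    def from_segments(cls, segments, domain=(-np.inf, np.inf)) -> "PiecewiseLinear":
        """Build from ``(lo, hi, slope, intercept)`` rows (sorted by lo)."""
        segs = sorted(segments, key=lambda s: s[0])
        bp = [s[1] for s in segs[:-1]]
        return cls(
            breakpoints=np.array(bp, dtype=float),
            slopes=np.array([s[2] for s in segs], dtype=float),
            intercepts=np.array([s[3] for s in segs], dtype=float),
            domain=domain,
        )

    def to_text(self, path) -> None:
        """Write one ``lo hi slope intercept`` line per segment."""
        with open(path, "w") as fh:
            fh.write("# lo hi slope intercept\n")
            for lo, hi, a, b in self.segments:
                fh.write(f"{float(lo)!r} {float(hi)!r} "
                         f"{float(a)!r} {float(b)!r}\n")

    @classmethod
    def from_text(cls, path) -> "PiecewiseLinear":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                lo, hi, a, b = (float(tok) for tok in line.split())
                rows.append((lo, hi, a, b))
        return cls.from_segments(rows)


def eval_piecewise(pw: PiecewiseLinear, x):
    """Evaluate ``pw`` at ``x`` (functional alias for ``pw(x)``)."""
    return pw(x)


# ---------------------------------------------------------------------------
# Fixed tables of the digital datapath.
# ---------------------------------------------------------------------------

_CUBE_BP = [-1.3, -1.03, -0.78, -0.47, 0.0, 0.47, 0.78, 1.03, 1.3]
_CUBE_A = [6.33, 4.08, 2.473, 1.196, 0.22, 0.22, 1.196, 2.473, 4.08, 6.33]
_CUBE_B = [6.03, 3.1, 1.45, 0.458, 0.0, 0.0, -0.458, -1.45, -3.1, -6.03]

_SQUARE_BP = [-1.21, -0.82, -0.41, 0.0, 0.41, 0.82, 1.21]
_SQUARE_A = [-2.859, -2.029, -1.23, -0.41, 0.41, 1.23, 2.029, 2.859]
_SQUARE_B = [-1.997, -0.99, -0.336, 0.0, 0.0, -0.336, -0.99, -1.997]

_EXP_BP = [2.63, 5.23, 8.19, 11.12, 14.15, 17.71, 22.43, 28.95, 34.17]
_EXP_A = [-0.0876, -0.0677, -0.0513, -0.0382, -0.0284,
          -0.0204, -0.0136, -0.0078, -0.0043, -0.0020]
_EXP_B = [0.999, 0.9468, 0.8611, 0.7539, 0.6444,
          0.5321, 0.4104, 0.2810, 0.18, 0.1]


def cube_table() -> PiecewiseLinear:
    """Ten-segment substitution of ``x**3`` used by the linear HR neuron."""
    return PiecewiseLinear(np.array(_CUBE_BP), np.array(_CUBE_A),
                           np.array(_CUBE_B), domain=(-2.0, 2.0))


def square_table() -> PiecewiseLinear:
    """Eight-segment substitution of ``x**2``.

    The last breakpoint is 1.21, the mirror image of the first segment;
    the source table's final condition is inconsistent with the even
    symmetry of the remaining seven segments and is corrected here.
    """
    return PiecewiseLinear(np.array(_SQUARE_BP), np.array(_SQUARE_A),
                           np.array(_SQUARE_B), domain=(-2.0, 2.0))


def exp_table() -> PiecewiseLinear:
    """Ten-segment substitution of ``exp(-dt/10)`` for lags dt >= 0.

    Used by the plasticity window; the nominal fitting domain is
    ``[0, 50]`` ms of burst-lag.
    """
    return PiecewiseLinear(np.array(_EXP_BP), np.array(_EXP_A),
                           np.array(_EXP_B), domain=(0.0, 50.0))


# ---------------------------------------------------------------------------
# Normalized error metrics (curve versus approximation).
# ---------------------------------------------------------------------------

def _check_curves(ref, approx):
    ref = np.asarray(ref, dtype=float)
    approx = np.asarray(approx, dtype=float)
    if ref.shape != approx.shape or ref.ndim != 1 or ref.size < 1:
        raise ValueError("curves must be equal-length 1-D samples")
    mx = np.max(ref)
    if mx == 0:
        raise ValueError("max(ref) must be nonzero for normalization")
    return ref, approx, mx


def nmae_curve(ref, approx) -> float:
    """Normalized mean absolute error: sum|r - a| / (n * max(r))."""
    ref, approx, mx = _check_curves(ref, approx)
    return float(np.sum(np.abs(ref - approx)) / (ref.size * mx))


def nrmse_curve(ref, approx) -> float:
    """Normalized root-mean-square error: rms(r - a) / max(r)."""
    ref, approx, mx = _check_curves(ref, approx)
    return float(np.sqrt(np.mean((ref - approx) ** 2)) / mx)


DEFAULT_GRID_POINTS = 10001


def table_error(table: PiecewiseLinear, target, domain=None,
                n_points: int = DEFAULT_GRID_POINTS):
    """NMAE and NRMSE of ``table`` against callable ``target`` on a grid."""
    lo, hi = domain if domain is not None else table.domain
    x = np.linspace(lo, hi, n_points)
    ref = target(x)
    approx = table(x)
    return nmae_curve(ref, approx), nrmse_curve(ref, approx)


# ---------------------------------------------------------------------------
# Best-approximation search.
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    """Configuration of the random-breakpoint chord search.

    The search picks ``n`` points on the target curve (one per half-domain
    when ``n == 2``, then uniformly), connects consecutive points with
    chords, extends the outer chords to +/- infinity, and scores the result
    by NMAE on a dense grid.  Point counts grow from ``n_points_min`` until
    the tolerance is met or ``n_points_max`` is exceeded.
    """

    target_function: callable
    domain: tuple[float, float]
    n_points_min: int = 2
    n_points_max: int = 11
    error_tolerance: float = 0.02
    grid_resolution: int = DEFAULT_GRID_POINTS
    n_restarts: int = 200

    def __post_init__(self):
        if self.n_points_min < 2:
            raise ValueError("need at least two points")
        if self.n_points_max > 11:
            raise ValueError("point count is capped at eleven")
        if self.error_tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _chord_table(f, xs, domain) -> PiecewiseLinear:
    """Piecewise table from chords through curve points ``xs`` (sorted)."""
    ys = f(xs)
    a = np.diff(ys) / np.diff(xs)
    b = ys[:-1] - a * xs[:-1]
    # interior chords only: outer chords extend beyond their span
    return PiecewiseLinear(breakpoints=xs[1:-1], slopes=a, intercepts=b,
                           domain=domain)


def _sample_points(rng, n, lo, hi):
    """n random points, balanced across the two half-domains."""
    mid = 0.5 * (lo + hi)
    n_left = n // 2
    pts = np.concatenate([
        rng.uniform(lo, mid, size=n_left),
        rng.uniform(mid, hi, size=n - n_left),
    ])
    pts.sort()
    return pts


def search_best_fit(cfg: SearchConfig, seed: int):
    """Run the breakpoint search; returns ``(table, achieved_nmae)``.

    The best-so-far table is returned even when the tolerance is not met
    (``PiecewiseFitResults.converged`` records which case occurred when
    called through :class:`PiecewiseFit`).
    """
    res = PiecewiseFit(cfg).fit(seed)
    return res.table, res.achieved_error


@dataclass
class PiecewiseFitResults:
    """Outcome of a piecewise-linear approximation search."""

    table: PiecewiseLinear
    achieved_error: float
    n_points: int
    converged: bool
    config: SearchConfig = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Piecewise-linear fit",
            f"  segments        : {self.table.n_segments}",
            f"  curve points    : {self.n_points}",
            f"  achieved NMAE   : {self.achieved_error:.6f}",
            f"  tolerance       : {self.config.error_tolerance:.6f}"
            if self.config else "",
            f"  converged       : {self.converged}",
        ]
        return "\n".join(s for s in lines if s)


class PiecewiseFit:
    """Model object for the chord-search; ``fit(seed)`` runs the search."""

    def __init__(self, config: SearchConfig):
        self.config = config

    def fit(self, seed: int = 0) -> PiecewiseFitResults:
        cfg = self.config
        rng = np.random.default_rng(seed)
        lo, hi = cfg.domain
        grid = np.linspace(lo, hi, cfg.grid_resolution)
        ref = cfg.target_function(grid)

        best = None  # (err, table, n)
        for n in range(cfg.n_points_min, cfg.n_points_max + 1):
            for _ in range(cfg.n_restarts):
                pts = _sample_points(rng, n, lo, hi)
                if np.any(np.diff(pts) <= 1e-9 * (hi - lo)):
                    continue
                if n == 2:
                    # a single chord through both points, whole domain
                    table = _chord_table(cfg.target_function, pts, cfg.domain)
                else:
                    table = _chord_table(cfg.target_function, pts, cfg.domain)
                err = nmae_curve(ref, table(grid))
                if best is None or err < best[0]:
                    best = (err, table, n)
            if best is not None and best[0] < cfg.error_tolerance:
                return PiecewiseFitResults(
                    table=best[1], achieved_error=best[0], n_points=best[2],
                    converged=True, config=cfg)
        return PiecewiseFitResults(
            table=best[1], achieved_error=best[0], n_points=best[2],
            converged=False, config=cfg)
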