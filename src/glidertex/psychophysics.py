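"""4AFC texture-segmentation psychophysics: designs, Weibull fits, ellipsoids.

Sensitivity to a glider coordinate is measured with a four-alternative
forced-choice segmentation task: a textured target strip appears at one of
four locations in a noise background (or the roles are swapped), and the
subject reports the location.  Performance along a ray through the origin
of coordinate space follows a Weibull psychometric function

    FC(x) = 1/4 + 3/4 (1 - 2^(-(x/a_r)^b_r)),

where x is the Euclidean distance from the origin, ``a_r`` the threshold
(FC(a_r) = 0.625, halfway between chance and perfect) and ``b_r`` the
shape.  Each coordinate plane is measured along 8 rays (the four signed
axes and the four diagonals); per-ray fits are followed by a joint fit
sharing a single exponent b across the rays of a plane.  Criterion points
``T_r = a_r * u_r`` from all planes determine the 9-D sensitivity
ellipsoid {c : c^T Q c = 1} by linear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .glider_stats import COORD_NAMES_9

__all__ = [
    "COORD_MAXES",
    "RAYS",
    "SessionConfig",
    "WeibullFit",
    "SensitivityEllipsoid",
    "weibull_fc",
    "design_session",
    "fit_weibull",
    "pool_sensitivities",
    "criterion_points",
    "fit_ellipsoid",
]

#: largest coordinate magnitude used in stimulus gamuts, per coordinate
COORD_MAXES = {
    "beta_v": 0.45,
    "beta_h": 0.45,
    "beta_d1": 0.75,
    "beta_d2": 0.75,
    "theta_tl": 1.0,
    "theta_tr": 1.0,
    "theta_br": 1.0,
    "theta_bl": 1.0,
    "alpha": 0.85,
}

#: the 8 rays of a coordinate plane: signed axes then sign-combination diagonals
RAYS = ("+x", "-x", "+y", "-y", "+x+y", "+x-y", "-x+y", "-x-y")

_LOCATIONS = ("top", "bottom", "left", "right")
_TRIAL_TYPES = ("target_structured", "background_structured")

#: coordinate relabeling induced by a 90-degree rotation of the texture
ROT90 = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 6, 6: 7, 7: 4, 8: 8}


@dataclass
class SessionConfig:
    """Composition of one plane's session.

    Defaults reproduce the standard totals: per block,
    4 on-axis rays x 5 magnitudes x 8 repeats + 4 oblique rays x
    2 magnitudes x 16 repeats = 288 trials; 15 blocks give 4320 trials
    per plane and 47,520 over the 11 planes of a full study.  Repeat
    counts must be divisible by 8 so each condition is balanced over the
    4 target locations and 2 trial types.
    """

    on_axis_levels: int = 5
    oblique_levels: int = 2
    on_axis_reps: int = 8
    oblique_reps: int = 16
    blocks: int = 15
    oblique_fracs: tuple[float, ...] = (0.4, 0.8)
    coord_maxes: dict = field(default_factory=lambda: dict(COORD_MAXES))

    @property
    def trials_per_block(self) -> int:
        return (
            4 * self.on_axis_levels * self.on_axis_reps
            + 4 * self.oblique_levels * self.oblique_reps
        )


def parse_plane(plane) -> tuple[str, str]:
    if isinstance(plane, str):
        plane = tuple(plane.split(":"))
    cx, cy = plane
    for c in (cx, cy):
        if c not in COORD_NAMES_9:
            raise ValueError(f"unknown coordinate {c!r}")
    return cx, cy


def ray_direction(plane, ray: str, coord_maxes: dict | None = None) -> np.ndarray:
    """Unit 9-vector along a ray of a coordinate plane.

    On-axis rays point along a single signed coordinate.  Oblique rays mix
    the two coordinates with magnitudes in fixed proportion to their gamut
    maxima, with the requested sign combination.
    """
    cx, cy = parse_plane(plane)
    maxes = coord_maxes or COORD_MAXES
    ix, iy = COORD_NAMES_9.index(cx), COORD_NAMES_9.index(cy)
    v = np.zeros(9)
    if ray in ("+x", "-x"):
        v[ix] = 1.0 if ray == "+x" else -1.0
    elif ray in ("+y", "-y"):
        v[iy] = 1.0 if ray == "+y" else -1.0
    elif ray in ("+x+y", "+x-y", "-x+y", "-x-y"):
        sx = 1.0 if ray[0] == "+" else -1.0
        sy = 1.0 if ray[2] == "+" else -1.0
        v[ix] = sx * maxes[cx]
        v[iy] = sy * maxes[cy]
        v /= np.linalg.norm(v)
    else:
        raise ValueError(f"unknown ray {ray!r}")
    return v


def design_session(
    plane, config: SessionConfig | None = None, seed: int = 0, subject: str = "S1"
) -> pd.DataFrame:
    """Trial table for one plane (responses empty), randomized with seed."""
    config = config or SessionConfig()
    cx, cy = parse_plane(plane)
    if config.on_axis_reps % 8 or config.oblique_reps % 8:
        raise ValueError(
            "repeat counts must be divisible by 8 to balance 4 locations x 2 trial types"
        )
    if len(config.oblique_fracs) != config.oblique_levels:
        raise ValueError("oblique_fracs must list one fraction per oblique level")
    if config.blocks == 0:
        warnings.warn("0 blocks requested: empty trial table")

    maxes = config.coord_maxes
    conditions = []  # (ray, magnitude, reps)
    for axis, coord in (("x", cx), ("y", cy)):
        for sign in "+-":
            for level in range(config.on_axis_levels):
                mag = maxes[coord] * (level + 1) / config.on_axis_levels
                conditions.append((f"{sign}{axis}", mag, config.on_axis_reps))
    oblique_norm = float(np.hypot(maxes[cx], maxes[cy]))
    for sx in "+-":
        for sy in "+-":
            for frac in config.oblique_fracs:
                conditions.append((f"{sx}x{sy}y", frac * oblique_norm, config.oblique_reps))

    rng = np.random.default_rng(seed)
    rows = []
    for block in range(config.blocks):
        block_rows = []
        for ray, mag, reps in conditions:
            per_cell = reps // 8
            for loc in _LOCATIONS:
                for ttype in _TRIAL_TYPES:
                    for _ in range(per_cell):
                        block_rows.append(
                            (subject, f"{cx}:{cy}", ray, mag, ttype, loc, block)
                        )
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)
    df = pd.DataFrame(
        rows,
        columns=[
            "subject", "plane", "ray", "magnitude", "trial_type", "target_loc", "block",
        ],
    )
    df["response_loc"] = pd.NA
    df["correct"] = pd.NA
    return df


def weibull_fc(x, a, b):
    """Eq-style 4AFC Weibull: chance 1/4, criterion 0.625 at x = a."""
    x = np.asarray(x, dtype=float)
    return 0.25 + 0.75 * (1.0 - np.exp2(-((x / a) ** b)))


@dataclass
class WeibullFit:
    plane: str
    thresholds: dict  # ray -> a_r (shared-b fit)
    shared_b: float
    per_ray_a: dict  # stage-1 diagnostics
    per_ray_b: dict
    boundary: dict  # ray -> "all_correct" | "all_incorrect"


def _nll(params_a, b, mags, n_corr, n_tot):
    fc = weibull_fc(mags, params_a, b)
    fc = np.clip(fc, 1e-12, 1 - 1e-12)
    return -np.sum(n_corr * np.log(fc) + (n_tot - n_corr) * np.log(1 - fc))


def _aggregate(trials: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for ray, sub in trials.groupby("ray"):
        g = sub.groupby("magnitude")["correct"]
        mags = np.array([m for m, _ in g])
        n_corr = g.sum().to_numpy(dtype=float)
        n_tot = g.count().to_numpy(dtype=float)
        out[ray] = (mags, n_corr, n_tot)
    return out


def fit_weibull(trials: pd.DataFrame) -> WeibullFit:
    """Two-stage maximum-likelihood Weibull fit for one plane.

    Stage 1 fits (a_r, b_r) independently per ray; stage 2 refits all rays
    jointly with a single shared exponent b (per-ray thresholds free).
    Rays with all-correct or all-incorrect responses have unbounded
    thresholds and are flagged instead of fitted.
    """
    trials = trials.dropna(subset=["correct"])
    if trials.empty:
        raise ValueError("no completed trials")
    trials = trials.assign(correct=trials["correct"].astype(bool))
    plane = str(trials["plane"].iloc[0])
    data = _aggregate(trials)

    boundary, per_a, per_b = {}, {}, {}
    for ray, (mags, n_corr, n_tot) in data.items():
        if n_corr.sum() == n_tot.sum():
            boundary[ray] = "all_correct"
            continue
        if n_corr.sum() == 0:
            boundary[ray] = "all_incorrect"
            continue
        x0 = np.array([np.log(np.median(mags)), np.log(2.5)])
        res = minimize(
            lambda p: _nll(np.exp(p[0]), np.exp(p[1]), mags, n_corr, n_tot),
            x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        per_a[ray] = float(np.exp(res.x[0]))
        per_b[ray] = float(np.exp(res.x[1]))

    rays = list(per_a)
    if not rays:
        raise ValueError("no fittable rays (all at boundary)")
    x0 = np.array([np.log(per_a[r]) for r in rays] + [np.log(np.mean(list(per_b.values())))])

    def joint_nll(p):
        b = np.exp(p[-1])
        return sum(
            _nll(np.exp(p[k]), b, *data[r]) for k, r in enumerate(rays)
        )

    res = minimize(joint_nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 8000})
    thresholds = {r: float(np.exp(res.x[k])) for k, r in enumerate(rays)}
    shared_b = float(np.exp(res.x[-1]))
    return WeibullFit(plane, thresholds, shared_b, per_a, per_b, boundary)


def pool_sensitivities(
    fits: list[WeibullFit],
    pool_rotations: bool = False,
    signed: bool = False,
):
    """Per-coordinate sensitivities s_k pooled across planes.

    For each coordinate, 1/a is averaged over the two signed on-axis rays
    within a plane and then over all planes containing the coordinate.
    With ``pool_rotations`` the rotationally equivalent coordinates
    ({beta_v, beta_h}, {beta_d1, beta_d2}, the four thetas) share one
    pooled value.  With ``signed`` the positive- and negative-ray
    sensitivities are returned separately (for asymmetry comparisons).
    """
    per_sign = {(name, s): [] for name in COORD_NAMES_9 for s in "+-"}
    for fit in fits:
        cx, cy = parse_plane(fit.plane)
        for coord, axis in ((cx, "x"), (cy, "y")):
            for s in "+-":
                ray = f"{s}{axis}"
                if ray in fit.thresholds:
                    per_sign[(coord, s)].append(1.0 / fit.thresholds[ray])

    missing = [
        name for name in COORD_NAMES_9
        if not (per_sign[(name, "+")] or per_sign[(name, "-")])
    ]
    if missing:
        raise ValueError(f"coordinates never measured on-axis: {missing}")

    if signed:
        pos = np.array([np.mean(per_sign[(n, "+")]) for n in COORD_NAMES_9])
        neg = np.array([np.mean(per_sign[(n, "-")]) for n in COORD_NAMES_9])
        return pos, neg

    s = np.empty(9)
    for k, name in enumerate(COORD_NAMES_9):
        per_plane = []
        n_planes = max(len(per_sign[(name, "+")]), len(per_sign[(name, "-")]))
        for i in range(n_planes):
            vals = [
                per_sign[(name, sgn)][i]
                for sgn in "+-"
                if i < len(per_sign[(name, sgn)])
            ]
            per_plane.append(np.mean(vals))
        s[k] = np.mean(per_plane)

    if pool_rotations:
        for group in ((0, 1), (2, 3), (4, 5, 6, 7)):
            s[list(group)] = s[list(group)].mean()
    return s


def criterion_points(fits: list[WeibullFit]) -> np.ndarray:
    """9-D criterion-performance points T_r = a_r * u_r from all fits."""
    pts = []
    for fit in fits:
        for ray, a in fit.thresholds.items():
            pts.append(a * ray_direction(fit.plane, ray))
    return np.array(pts)


@dataclass
class SensitivityEllipsoid:
    Q: np.ndarray  # symmetric 9x9
    rms_residual: float
    measured: np.ndarray  # boolean mask of fitted entries


def _rotation_orbit(i: int, j: int) -> tuple:
    """Canonical representative of an index pair's orbit under 90-degree rotations."""
    orbit = set()
    a, b = i, j
    for _ in range(4):
        a, b = ROT90[a], ROT90[b]
        orbit.add((min(a, b), max(a, b)))
    return min(orbit)


def fit_ellipsoid(points: np.ndarray, pool_rotations: bool = False) -> SensitivityEllipsoid:
    """Least-squares symmetric Q with criterion points on c^T Q c = 1.

    Minimizes sum_r (c(T_r)^T Q c(T_r) - 1)^2 over the Q entries that the
    points actually probe (an entry (i, j) is probed when some point has
    both c_i and c_j nonzero); unprobed entries are zero.  With
    ``pool_rotations``, entries equivalent under 90-degree rotation share
    one parameter.  A rank-deficient design falls back to the
    minimum-norm solution with a warning.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 9:
        raise ValueError("points must be (n, 9)")
    probed = [
        (i, j)
        for i in range(9)
        for j in range(i, 9)
        if np.any((points[:, i] != 0) & (points[:, j] != 0))
    ]
    if pool_rotations:
        groups: dict[tuple, list[tuple[int, int]]] = {}
        for i, j in probed:
            groups.setdefault(_rotation_orbit(i, j), []).append((i, j))
        params = list(groups.values())
    else:
        params = [[(i, j)] for (i, j) in probed]

    design = np.zeros((len(points), len(params)))
    for col, entries in enumerate(params):
        for i, j in entries:
            factor = 1.0 if i == j else 2.0
            design[:, col] += factor * points[:, i] * points[:, j]
    target = np.ones(len(points))
    sol, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < len(params):
        warnings.warn("rank-deficient ellipsoid design; minimum-norm solution used")

    Q = np.zeros((9, 9))
    mask = np.zeros((9, 9), dtype=bool)
    for col, entries in enumerate(params):
        for i, j in entries:
            Q[i, j] = Q[j, i] = sol[col]
            mask[i, j] = mask[j, i] = True
    quad = np.einsum("ri,ij,rj->r", points, Q, points)
    rms = float(np.sqrt(np.mean((quad - 1.0) ** 2)))
    return SensitivityEllipsoid(Q, rms, mask)
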