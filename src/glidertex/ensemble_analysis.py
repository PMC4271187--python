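"""Summaries of the 9-D glider-coordinate distribution.

Provides the quantities used to compare natural-image ensembles with
psychophysics: per-coordinate standard deviations, the full covariance,
per-plane elliptical contours (eccentricity, tilt, and the quarter-sphere
``omega`` vector), positive/negative asymmetry ratios, the single scale
factor aligning standard deviations with sensitivities, and the principal
axes of the covariance grouped into the four symmetry classes of the
glider coordinate system.

Symmetry classes (behavior under 90-degree rotations and mirrors of the
underlying texture):

* SYM (4-D): invariant under 90-degree rotation,
* HVI (2-D): negated by horizontal or vertical mirrors,
* ROT (2-D): a plane in which a 90-degree rotation acts as (v1, v2) ->
  (v2, -v1),
* DII (1-D): negated by a diagonal mirror.

All vectors and matrices use the canonical 9-coordinate ordering
(beta_v, beta_h, beta_d1, beta_d2, theta_tl, theta_tr, theta_br,
theta_bl, alpha).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize_scalar

from .glider_stats import COORD_NAMES_9

__all__ = [
    "EnsembleSummary",
    "EllipseSummary",
    "PrincipalAxes",
    "SYMMETRY_CLASSES",
    "CLASS_ORDER",
    "COORD_SETS",
    "summarize",
    "fit_scale_factor",
    "plane_contour",
    "principal_axes",
    "pairwise_contours",
    "all_planes",
]

logger = logging.getLogger(__name__)

#: the four coordinate sets used for fractional contributions f
COORD_SETS = {
    "beta_cardinal": (0, 1),
    "beta_oblique": (2, 3),
    "theta": (4, 5, 6, 7),
    "alpha": (8,),
}

CLASS_ORDER = ("SYM", "HVI", "ROT", "DII")
CLASS_DIMS = {"SYM": 4, "HVI": 2, "ROT": 2, "DII": 1}


def _unit(entries: dict[int, float]) -> np.ndarray:
    v = np.zeros(9)
    for i, x in entries.items():
        v[i] = x
    return v / np.linalg.norm(v)


#: orthonormal spanning vectors of each symmetry class
SYMMETRY_CLASSES = {
    "SYM": np.stack(
        [
            _unit({0: 1, 1: 1}),
            _unit({2: 1, 3: 1}),
            _unit({4: 1, 5: 1, 6: 1, 7: 1}),
            _unit({8: 1}),
        ]
    ),
    "HVI": np.stack([_unit({2: 1, 3: -1}), _unit({4: 1, 5: -1, 6: 1, 7: -1})]),
    "ROT": np.stack([_unit({4: 1, 6: -1}), _unit({5: 1, 7: -1})]),
    "DII": np.stack([_unit({0: 1, 1: -1})]),
}

_ALL_SPANNING = np.concatenate([SYMMETRY_CLASSES[c] for c in CLASS_ORDER])
assert np.allclose(_ALL_SPANNING @ _ALL_SPANNING.T, np.eye(9)), (
    "symmetry-class spanning vectors must be orthonormal"
)


@dataclass
class EnsembleSummary:
    mean: np.ndarray
    std: np.ndarray
    covariance: np.ndarray
    pos_neg_std_ratio: np.ndarray
    n_patches: int


@dataclass
class EllipseSummary:
    """Shape of a planar contour: eccentricity, tilt, quarter-sphere vector.

    ``omega = (sin a cos d, sin a sin d, cos a)`` with ``sin a`` the
    eccentricity and ``d`` the tilt; circular contours report tilt 0 by
    convention, so omega is continuous at the pole.
    """

    eccentricity: float
    tilt: float
    omega: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.omega is None:
            e = self.eccentricity
            self.omega = np.array(
                [e * np.cos(self.tilt), e * np.sin(self.tilt), np.sqrt(max(1 - e * e, 0.0))]
            )


@dataclass
class PrincipalAxes:
    axes: np.ndarray  # (9, 9), row i is the i-th ordered unit axis
    eigenvalues: np.ndarray  # (9,)
    classes: tuple[str, ...]  # per ordered axis
    f: np.ndarray  # (9, 4) fractional contributions of the coordinate sets
    F: np.ndarray  # (9, 9) squared components


def summarize(vectors: np.ndarray) -> EnsembleSummary:
    """Mean, std, covariance (population convention) and +/- RMS ratios.

    ``pos_neg_std_ratio[k]`` is the RMS of the positive values of
    coordinate k (about zero) divided by the RMS of its negative values;
    NaN when a coordinate has no positive or no negative values.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need an (n, d) array with n >= 2")
    n, d = vectors.shape
    mean = vectors.mean(axis=0)
    cov = np.cov(vectors.T, ddof=0)
    cov = np.atleast_2d(cov)
    std = np.sqrt(np.diag(cov))
    ratio = np.full(d, np.nan)
    for k in range(d):
        pos = vectors[vectors[:, k] > 0, k]
        neg = vectors[vectors[:, k] < 0, k]
        if len(pos) and len(neg):
            ratio[k] = np.sqrt(np.mean(pos**2)) / np.sqrt(np.mean(neg**2))
    return EnsembleSummary(mean, std, cov, ratio, n)


def fit_scale_factor(std: np.ndarray, sensitivity: np.ndarray) -> float:
    """Least-squares scale c minimizing ||c*std - sensitivity||^2.

    Closed form c = (sum sigma_k s_k) / (sum sigma_k^2).
    """
    std = np.asarray(std, dtype=float)
    sens = np.asarray(sensitivity, dtype=float)
    if std.shape != sens.shape:
        raise ValueError("std and sensitivity must have the same shape")
    if (std < 0).any() or (sens < 0).any():
        raise ValueError("std and sensitivity must be nonnegative")
    denom = np.dot(std, std)
    if denom == 0:
        raise ValueError("std vector is identically zero")
    return float(np.dot(std, sens) / denom)


def plane_contour(M: np.ndarray) -> EllipseSummary:
    """Shape of the contour x^T M x = 1 for symmetric positive-definite M.

    Semi-axis lengths are 1/sqrt(eigenvalue); the major axis lies along
    the eigenvector of the *smaller* eigenvalue.  Eccentricity is
    sqrt(1 - (b/a)^2) for semi-axes a >= b, and tilt is the major-axis
    angle in [-pi/2, pi/2).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2) or abs(M[0, 1] - M[1, 0]) > 1e-9 * (1 + np.abs(M).max()):
        raise ValueError("M must be 2x2 symmetric")
    lam, vecs = np.linalg.eigh(M)
    if lam[0] <= 0:
        raise ValueError("M must be positive definite")
    # semi-axes 1/sqrt(lam); major axis <-> smallest eigenvalue
    ratio2 = lam[0] / lam[1]  # (b/a)^2
    ecc = float(np.sqrt(max(1.0 - ratio2, 0.0)))
    if ecc < 1e-12:
        return EllipseSummary(0.0, 0.0)
    major = vecs[:, 0]
    tilt = float(np.arctan2(major[1], major[0]))
    if tilt >= np.pi / 2:
        tilt -= np.pi
    elif tilt < -np.pi / 2:
        tilt += np.pi
    if abs(tilt - np.pi / 2) < 1e-15:
        tilt = -np.pi / 2
    return EllipseSummary(ecc, tilt)


def all_planes() -> list[tuple[int, int]]:
    """The 36 unordered coordinate pairs (i < j) of the 9-D space."""
    return list(itertools.combinations(range(9), 2))


def pairwise_contours(M: np.ndarray) -> dict[tuple[int, int], EllipseSummary]:
    """Planar contours of every 2x2 block of a symmetric 9x9 matrix.

    Works identically for an image-ensemble covariance (precision-matrix
    contours) and for a psychophysical sensitivity matrix Q
    (isodiscrimination contours): both are loci of x^T B x = 1 for the
    2x2 block B.
    """
    M = np.asarray(M, dtype=float)
    out = {}
    for i, j in all_planes():
        block = M[np.ix_([i, j], [i, j])]
        out[(i, j)] = plane_contour(block)
    return out


def _class_projections(axis: np.ndarray) -> np.ndarray:
    return np.array(
        [np.sum((SYMMETRY_CLASSES[c] @ axis) ** 2) for c in CLASS_ORDER]
    )


def _fractional_contributions(axis: np.ndarray) -> np.ndarray:
    return np.array(
        [np.sum(axis[list(idx)] ** 2) for idx in COORD_SETS.values()]
    )


def principal_axes(cov: np.ndarray, degeneracy_rtol: float = 1e-6) -> PrincipalAxes:
    """Eigen-axes of a 9x9 covariance, grouped by symmetry class.

    Each eigenvector is assigned to the symmetry class receiving its
    largest squared projection (ties broken toward the first class in
    SYM > HVI > ROT > DII order, logged).  If the greedy assignment
    overfills a class, a capacity-constrained assignment maximizing the
    total projection is used instead; near-degenerate eigenvector pairs
    that straddle classes are then rotated in their plane to maximize the
    total class overlap (the analogue of forcing symmetry by a 45-degree
    rotation for degenerate components).  Axes are ordered SYM(1-4),
    HVI(5-6), ROT(7-8), DII(9), by eigenvalue (descending) within class.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (9, 9) or not np.allclose(cov, cov.T, atol=1e-9):
        raise ValueError("cov must be a symmetric 9x9 matrix")
    lam, vecs = np.linalg.eigh(cov)
    if lam.min() < -1e-9 * max(lam.max(), 1.0):
        raise ValueError("cov must be positive semidefinite")
    axes = [vecs[:, i] for i in range(9)]
    eigenvalues = lam.copy()

    proj = np.stack([_class_projections(a) for a in axes])  # (9, 4)
    greedy = []
    for row in proj:
        best = np.flatnonzero(row >= row.max() - 1e-12)
        if len(best) > 1:
            logger.info("ambiguous class projection; tie broken toward %s",
                        CLASS_ORDER[best[0]])
        greedy.append(int(best[0]))
    counts = np.bincount(greedy, minlength=4)
    target = np.array([CLASS_DIMS[c] for c in CLASS_ORDER])

    if not np.array_equal(counts, target):
        warnings.warn(
            "greedy symmetry-class assignment violates class dimensions; "
            "using capacity-constrained assignment"
        )
        slots = [c for c, dim in enumerate(target) for _ in range(dim)]
        cost = -proj[:, slots]  # (9 axes, 9 slots)
        rows, cols = linear_sum_assignment(cost)
        assigned = [0] * 9
        for r, ccol in zip(rows, cols):
            assigned[r] = slots[ccol]
        # repair near-degenerate pairs split across classes against their
        # preference: rotate in-plane to maximize total class overlap
        for i, j in itertools.combinations(range(9), 2):
            close = abs(eigenvalues[i] - eigenvalues[j]) <= degeneracy_rtol * max(
                abs(eigenvalues).max(), 1e-30
            )
            if not close or assigned[i] == assigned[j]:
                continue
            Pi = SYMMETRY_CLASSES[CLASS_ORDER[assigned[i]]]
            Pj = SYMMETRY_CLASSES[CLASS_ORDER[assigned[j]]]
            ai, aj = axes[i], axes[j]

            def neg_overlap(t, ai=ai, aj=aj, Pi=Pi, Pj=Pj):
                u = np.cos(t) * ai + np.sin(t) * aj
                w = -np.sin(t) * ai + np.cos(t) * aj
                return -(np.sum((Pi @ u) ** 2) + np.sum((Pj @ w) ** 2))

            res = minimize_scalar(neg_overlap, bounds=(0, np.pi), method="bounded")
            t = float(res.x)
            u = np.cos(t) * ai + np.sin(t) * aj
            w = -np.sin(t) * ai + np.cos(t) * aj
            axes[i], axes[j] = u / np.linalg.norm(u), w / np.linalg.norm(w)
            logger.info("rotated degenerate axis pair (%d, %d) by %.1f deg",
                        i, j, np.degrees(t))
        classes_idx = assigned
    else:
        classes_idx = greedy

    order = []
    for c in range(4):
        members = [i for i in range(9) if classes_idx[i] == c]
        members.sort(key=lambda i: -eigenvalues[i])
        order.extend(members)
    axes_sorted = np.stack([axes[i] for i in order])
    eig_sorted = eigenvalues[order]
    classes = tuple(CLASS_ORDER[classes_idx[i]] for i in order)
    f = np.stack([_fractional_contributions(a) for a in axes_sorted])
    F = axes_sorted**2
    return PrincipalAxes(axes_sorted, eig_sorted, classes, f, F)


def summary_dict(
    summary: EnsembleSummary,
    sensitivity: np.ndarray | None = None,
) -> dict:
    """JSON-serializable report: std, covariance, contours, axes, ratios."""
    contours = pairwise_contours(summary.covariance)
    axes = principal_axes(summary.covariance)
    out = {
        "coordinates": list(COORD_NAMES_9),
        "n_patches": summary.n_patches,
        "mean": summary.mean.tolist(),
        "std": summary.std.tolist(),
        "covariance": summary.covariance.tolist(),
        "pos_neg_std_ratio": summary.pos_neg_std_ratio.tolist(),
        "plane_contours": {
            f"{COORD_NAMES_9[i]}:{COORD_NAMES_9[j]}": {
                "eccentricity": e.eccentricity,
                "tilt": e.tilt,
                "omega": e.omega.tolist(),
            }
            for (i, j), e in contours.items()
        },
        "principal_axes": {
            "axes": axes.axes.tolist(),
            "eigenvalues": axes.eigenvalues.tolist(),
            "classes": list(axes.classes),
            "f": axes.f.tolist(),
            "F": axes.F.tolist(),
        },
    }
    if sensitivity is not None:
        out["scale_factor"] = fit_scale_factor(summary.std, sensitivity)
    return out
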