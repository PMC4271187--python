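"""Local image statistics seen through a 2x2 glider.

A binary image patch (pixels in {-1, +1}) is scanned with a 2x2 window
("glider") whose corners are labelled

    A B     A = top-left,  B = top-right,
    C D     C = bottom-left, D = bottom-right.

The histogram of the 16 possible black/white colorings of the window is a
complete summary of the local fourth-order structure of the patch.  Under
translation invariance the 16 probabilities carry 10 degrees of freedom,
which are conveniently parametrized by expectations of pixel products:

* ``gamma``   -- first order, mean luminance, <(A+B+C+D)/4>
* ``beta_v``  -- vertical pair correlation, <AC+BD>/2
* ``beta_h``  -- horizontal pair correlation, <AB+CD>/2
* ``beta_d1`` -- main-diagonal pair, <AD>
* ``beta_d2`` -- anti-diagonal pair, <BC>
* ``theta_tl`` = <ABC>, ``theta_tr`` = <ABD>,
  ``theta_br`` = <BCD>, ``theta_bl`` = <ACD>  -- the four L-shaped
  third-order correlations (each named after the corner its glyph marks;
  ``theta_tl`` omits D, ``theta_tr`` omits C, ``theta_br`` omits A,
  ``theta_bl`` omits B)
* ``alpha``   -- fourth order, <ABCD>

Each coordinate lies in [-1, 1].  Median-binarized patches have gamma = 0,
leaving nine coordinates.  The canonical ordering used throughout the
package (tables, CSV files, covariance matrices) is

    (gamma, beta_v, beta_h, beta_d1, beta_d2,
     theta_tl, theta_tr, theta_br, theta_bl, alpha)

and the 9-D form simply drops gamma.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "COORD_NAMES",
    "COORD_NAMES_9",
    "COLORINGS",
    "InvalidPatchError",
    "InvalidHistogramError",
    "InfeasibleCoordinatesError",
    "count_colorings",
    "coords_from_histogram",
    "histogram_from_coords",
    "dof_of_constraint_set",
]

COORD_NAMES = (
    "gamma",
    "beta_v",
    "beta_h",
    "beta_d1",
    "beta_d2",
    "theta_tl",
    "theta_tr",
    "theta_br",
    "theta_bl",
    "alpha",
)
COORD_NAMES_9 = COORD_NAMES[1:]

#: the 16 colorings (A, B, C, D) in {-1, +1}; row i encodes i's bits with
#: A as the most significant bit and bit value 1 mapped to +1.
COLORINGS = np.array(
    [[1 if (i >> shift) & 1 else -1 for shift in (3, 2, 1, 0)] for i in range(16)],
    dtype=np.int8,
)


class InvalidPatchError(ValueError):
    """Patch is not a valid binary {-1,+1} array of side >= 2."""


class InvalidHistogramError(ValueError):
    """Histogram is not a probability vector over the 16 colorings."""


class InfeasibleCoordinatesError(ValueError):
    """No window distribution realizes the requested coordinates."""


def _products(colorings: np.ndarray) -> dict[str, np.ndarray]:
    a, b, c, d = (colorings[:, k].astype(float) for k in range(4))
    return {
        "A": a, "B": b, "C": c, "D": d,
        "AB": a * b, "CD": c * d, "AC": a * c, "BD": b * d,
        "AD": a * d, "BC": b * c,
        "ABC": a * b * c, "ABD": a * b * d, "BCD": b * c * d, "ACD": a * c * d,
        "ABCD": a * b * c * d,
    }


_P = _products(COLORINGS)

# forward map: coordinate k = FORWARD[k] . histogram
FORWARD = np.stack(
    [
        (_P["A"] + _P["B"] + _P["C"] + _P["D"]) / 4.0,
        (_P["AC"] + _P["BD"]) / 2.0,
        (_P["AB"] + _P["CD"]) / 2.0,
        _P["AD"],
        _P["BC"],
        _P["ABC"],
        _P["ABD"],
        _P["BCD"],
        _P["ACD"],
        _P["ABCD"],
    ]
)

# inverse map: p = (1 + INVERSE @ v) / 16 with the unaveraged products
INVERSE = np.stack(
    [
        _P["A"] + _P["B"] + _P["C"] + _P["D"],
        _P["AC"] + _P["BD"],
        _P["AB"] + _P["CD"],
        _P["AD"],
        _P["BC"],
        _P["ABC"],
        _P["ABD"],
        _P["BCD"],
        _P["ACD"],
        _P["ABCD"],
    ]
).T


def validate_patch(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise InvalidPatchError(f"patch must be square 2-D, got shape {patch.shape}")
    if patch.shape[0] < 2:
        raise InvalidPatchError("patch side must be >= 2 for one glider placement")
    if not np.isin(patch, (-1, 1)).all():
        raise InvalidPatchError("patch pixels must be exactly -1 or +1")
    return patch.astype(np.int8)


def count_colorings(patch: np.ndarray) -> np.ndarray:
    """Histogram of 2x2 glider colorings over all interior placements.

    Placements never wrap: an R x R patch contributes (R-1)^2 windows.
    Returns a length-16 probability vector indexed as in :data:`COLORINGS`.
    """
    patch = validate_patch(patch)
    bits = (patch > 0).astype(np.intp)
    a = bits[:-1, :-1]
    b = bits[:-1, 1:]
    c = bits[1:, :-1]
    d = bits[1:, 1:]
    idx = (a << 3) | (b << 2) | (c << 1) | d
    counts = np.bincount(idx.ravel(), minlength=16).astype(float)
    return counts / counts.sum()


def validate_histogram(h: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if h.shape != (16,):
        raise InvalidHistogramError(f"histogram must have 16 bins, got {h.shape}")
    if (h < -tol).any():
        raise InvalidHistogramError("histogram has negative probabilities")
    if abs(h.sum() - 1.0) > tol:
        raise InvalidHistogramError(f"histogram sums to {h.sum()!r}, not 1")
    return h


def coords_from_histogram(h: np.ndarray) -> np.ndarray:
    """Map a 16-bin coloring histogram to the 10 glider coordinates."""
    h = validate_histogram(h)
    return FORWARD @ h


def histogram_from_coords(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Invert glider coordinates to the 16-bin window distribution.

    p(A,B,C,D) = (1/16)[1 + gamma(A+B+C+D) + beta_h(AB+CD) + beta_v(AC+BD)
                 + beta_d1*AD + beta_d2*BC + theta_tl*ABC + theta_tr*ABD
                 + theta_br*BCD + theta_bl*ACD + alpha*ABCD]

    Raises :class:`InfeasibleCoordinatesError` when any probability falls
    below ``-tol``; values in [-tol, 0) are treated as rounding noise and
    clamped to zero.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (10,):
        raise ValueError(f"expected 10 coordinates, got shape {v.shape}")
    if (np.abs(v) > 1 + 1e-12).any():
        raise InfeasibleCoordinatesError("coordinates must lie in [-1, 1]")
    p = (1.0 + INVERSE @ v) / 16.0
    if (p < -tol).any():
        worst = p.min()
        raise InfeasibleCoordinatesError(
            f"coordinates give negative window probability (min {worst:.3g})"
        )
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _marginal_matrix(corners: tuple[int, ...]) -> np.ndarray:
    """Rows mapping a 16-vector to the joint marginal over given corners."""
    n = len(corners)
    rows = []
    for values in itertools.product((-1, 1), repeat=n):
        mask = np.ones(16)
        for corner, val in zip(corners, values):
            mask *= COLORINGS[:, corner] == val
        rows.append(mask)
    return np.stack(rows)


def dof_of_constraint_set(
    gamma_zero: bool = False, translation_invariance: bool = True
) -> int:
    """Dimension of the affine hull of admissible 16-bin histograms.

    Constraints: normalization, plus (if ``translation_invariance``) the
    marginal equalities a stationary texture imposes on the window
    distribution -- single-pixel marginals agree across the two columns and
    the two rows, the two horizontal-pair marginals agree, and the two
    vertical-pair marginals agree.  ``gamma_zero`` adds the first-order
    constraint gamma = 0.  The dimension is computed as 16 minus the rank
    of the stacked constraint system.
    """
    rows = [np.ones(16)]  # normalization
    if translation_invariance:
        # one-point marginals: A=B (horizontal shift), A=C (vertical), B=D
        for u, w in [((0,), (1,)), ((0,), (2,)), ((1,), (3,))]:
            rows.extend(_marginal_matrix(u) - _marginal_matrix(w))
        # pair marginals: top horizontal (A,B) = bottom (C,D);
        # left vertical (A,C) = right (B,D)
        rows.extend(_marginal_matrix((0, 1)) - _marginal_matrix((2, 3)))
        rows.extend(_marginal_matrix((0, 2)) - _marginal_matrix((1, 3)))
    if gamma_zero:
        rows.append(FORWARD[0])
    constraint = np.stack(rows)
    return 16 - np.linalg.matrix_rank(constraint, tol=1e-10)
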