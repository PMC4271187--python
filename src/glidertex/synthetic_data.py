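"""Synthetic inputs: textures, noise, coordinate ensembles, a 4AFC observer.

Everything the analysis pipeline consumes can be generated here without
external image databases or human subjects:

* binary texture patches with prescribed glider coordinates, built by a
  Pickard-style sequential rollout from the 2x2 window distribution
  (exact for the single-coordinate and pairwise gamuts used in stimuli),
* white-noise patches (i.i.d. fair-coin pixels),
* 9-D coordinate ensembles drawn from a Gaussian or two-component
  Gaussian mixture, with optional positive skew,
* a simulated 4AFC observer whose performance follows the Weibull law
  for a ground-truth sensitivity ellipsoid Q* and exponent b*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glider_stats import (
    COORD_NAMES,
    coords_from_histogram,
    count_colorings,
    histogram_from_coords,
)
from .psychophysics import ray_direction

__all__ = [
    "ObserverModel",
    "gen_texture",
    "gen_texture_ensemble",
    "gen_white_noise",
    "gen_coordinate_ensemble",
    "simulate_observer",
    "coords_by_name",
]


def coords_by_name(**kwargs: float) -> np.ndarray:
    """Build a 10-D coordinate vector from named components (others zero)."""
    v = np.zeros(10)
    for name, value in kwargs.items():
        v[COORD_NAMES.index(name)] = value
    return v


def maxent_texture_coords(name: str, value: float) -> np.ndarray:
    """Coordinates of the maximum-entropy texture for one prescribed gamut.

    For most single coordinates the maximum-entropy values of the others
    are zero, but the two edge-sharing pair correlations are the
    exception: the maximum-entropy texture with horizontal (vertical)
    correlation b consists of independent rows (columns) of a two-state
    Markov chain, whose window distribution factorizes as
    p = (1 + b*AB)(1 + b*CD)/16 and therefore carries the induced
    fourth-order correlation alpha = b^2.  (With all other coordinates
    literally zero, |b| > 1/2 would require a negative window
    probability.)
    """
    v = coords_by_name(**{name: value})
    if name in ("beta_h", "beta_v"):
        v[COORD_NAMES.index("alpha")] = value**2
    return v


def _rollout_tables(p16: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Conditional tables for the sequential construction.

    Returns (P(pixel=+1), P(+1 | left), P(+1 | above), P(+1 | A,B,C))
    where conditioning pixels are indexed by their +1/-1 state mapped to
    bits (1 for +1).
    """
    p4 = p16.reshape(2, 2, 2, 2)  # indices (A, B, C, D), 1 = white
    pA = p4.sum(axis=(1, 2, 3))  # marginal of one pixel
    pAB = p4.sum(axis=(2, 3))  # horizontal pair
    pAC = p4.sum(axis=(1, 3))  # vertical pair
    single = pA[1]

    def conditional(joint: np.ndarray) -> np.ndarray:
        cond = np.empty(2)
        for a in range(2):
            tot = joint[a].sum()
            if tot <= 0:
                cond[a] = np.nan
            else:
                cond[a] = joint[a, 1] / tot
        return cond

    cond_row = conditional(pAB)  # P(B=+1 | A)
    cond_col = conditional(pAC)  # P(C=+1 | A)
    cond_int = np.empty((2, 2, 2))  # P(D=+1 | A, B, C)
    for a in range(2):
        for b in range(2):
            for c in range(2):
                tot = p4[a, b, c].sum()
                cond_int[a, b, c] = p4[a, b, c, 1] / tot if tot > 0 else np.nan
    return single, cond_row, cond_col, cond_int


def gen_texture(v: np.ndarray, R: int, seed: int) -> np.ndarray:
    """One R x R binary patch with prescribed glider coordinates.

    Sequential rollout: the seed pixel is drawn from the single-pixel
    marginal, the first row from the horizontal-pair conditional, the
    first column from the vertical-pair conditional, and every interior
    pixel D at (r, c) from p(D | A, B, C) given its above-left, above and
    left neighbours -- all conditionals taken from the window distribution
    implied by the coordinates.

    A top-down, left-to-right scan can only *create* correlations whose
    product involves the drawn corner D; the anti-diagonal pair (beta_d2 =
    <BC>) and the D-free triple (theta_tl = <ABC>) would silently come out
    zero.  The generator therefore picks the mirror/rotation of the patch
    that moves such components onto realizable corners (exact for the
    single-coordinate stimulus gamuts), generates in that frame, and
    transforms the patch back.
    """
    v = np.asarray(v, dtype=float)
    name, (perm, undo) = min(
        _PATCH_TRANSFORMS.items(),
        # badness: weight on the two scan-unrealizable components
        key=lambda item: abs(v[item[1][0][4]]) + abs(v[item[1][0][5]]),
    )
    if name != "identity":
        return np.ascontiguousarray(undo(gen_texture(v[perm], R, seed)))
    p16 = histogram_from_coords(v)
    single, cond_row, cond_col, cond_int = _rollout_tables(p16)
    rng = np.random.default_rng(seed)
    u = rng.random((R, R))
    bits = np.empty((R, R), dtype=np.int8)

    def draw(prob: float, unif: float, where: str) -> int:
        if np.isnan(prob):
            raise ValueError(
                f"degenerate conditional (zero-probability context) at {where}"
            )
        return 1 if unif < prob else 0

    bits[0, 0] = draw(single, u[0, 0], "seed pixel")
    for c in range(1, R):
        bits[0, c] = draw(cond_row[bits[0, c - 1]], u[0, c], "first row")
    for r in range(1, R):
        bits[r, 0] = draw(cond_col[bits[r - 1, 0]], u[r, 0], "first column")
        row_above = bits[r - 1]
        row = bits[r]
        urow = u[r]
        for c in range(1, R):
            prob = cond_int[row_above[c - 1], row_above[c], row[c - 1]]
            row[c] = draw(prob, urow[c], f"interior ({r},{c})")
    return (2 * bits.astype(np.int8) - 1).astype(np.int8)


# coordinate permutations induced by patch mirror/rotation symmetries,
# as index maps on the canonical 10-vector; used by gen_texture above
_PATCH_TRANSFORMS = {
    "identity": (list(range(10)), lambda p: p),
    "mirror_lr": ([0, 1, 2, 4, 3, 6, 5, 8, 7, 9], lambda p: p[:, ::-1]),
    "mirror_ud": ([0, 1, 2, 4, 3, 8, 7, 6, 5, 9], lambda p: p[::-1, :]),
    "rotate_180": ([0, 1, 2, 3, 4, 7, 8, 5, 6, 9], lambda p: p[::-1, ::-1]),
}


def gen_texture_ensemble(
    v: np.ndarray,
    R: int,
    n: int,
    seed: int,
    validate: bool = True,
) -> list[np.ndarray]:
    """n independent patches; optionally verify the measured statistics.

    The rollout matches arbitrary coordinate mixtures only approximately;
    when the mean measured coordinates deviate from the prescription by
    more than 5 standard errors a warning is emitted.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n)
    patches = [gen_texture(v, R, int(s)) for s in sub]
    if validate and n >= 10:
        measured = np.stack(
            [coords_from_histogram(count_colorings(p)) for p in patches]
        )
        mean = measured.mean(axis=0)
        se = measured.std(axis=0, ddof=1) / np.sqrt(n) + 1e-12
        dev = np.abs(mean - np.asarray(v, float)) / se
        if dev.max() > 5:
            k = int(np.argmax(dev))
            warnings.warn(
                f"generated ensemble deviates from prescription: {COORD_NAMES[k]} "
                f"off by {dev.max():.1f} standard errors"
            )
    return patches


def gen_white_noise(R: int, n: int, seed: int) -> list[np.ndarray]:
    """n i.i.d. fair-coin +/-1 patches of side R."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        (2 * rng.integers(0, 2, size=(R, R)) - 1).astype(np.int8) for _ in range(n)
    ]


def gen_coordinate_ensemble(spec: dict, n: int, seed: int) -> np.ndarray:
    """Draws from a Gaussian (or 2-component mixture) in coordinate space.

    ``spec`` holds ``means`` (list of d-vectors), ``covariances`` (list of
    d x d PSD matrices), optional ``weights`` (sum to 1) and optional
    ``skew`` -- a {coordinate index: factor} map that scales positive
    deviations from the component mean by the factor, emulating the
    positively skewed tails of natural-image statistics.
    """
    means = [np.asarray(m, dtype=float) for m in spec["means"]]
    covs = [np.asarray(c, dtype=float) for c in spec["covariances"]]
    weights = np.asarray(spec.get("weights", [1.0] * len(means)), dtype=float)
    if len(means) != len(covs) or len(means) != len(weights):
        raise ValueError("means, covariances and weights must have equal length")
    if abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
        raise ValueError("weights must be nonnegative and sum to 1")
    for c in covs:
        if np.linalg.eigvalsh(c).min() < -1e-9:
            raise ValueError("covariances must be PSD")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(means), size=n, p=weights)
    d = means[0].size
    out = np.empty((n, d))
    for k, (m, c) in enumerate(zip(means, covs)):
        idx = labels == k
        if idx.any():
            draws = rng.multivariate_normal(m, c, size=int(idx.sum()),
                                            method="eigh")
            skew = spec.get("skew", {})
            for coord, factor in skew.items():
                dev = draws[:, int(coord)] - m[int(coord)]
                draws[:, int(coord)] = m[int(coord)] + np.where(dev > 0, factor * dev, dev)
            out[idx] = draws
    return out


@dataclass
class ObserverModel:
    """Ground-truth 4AFC observer: sensitivity ellipsoid Q* and exponent b*."""

    Q: np.ndarray  # symmetric PSD 9x9
    b: float

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (9, 9) or not np.allclose(self.Q, self.Q.T):
            raise ValueError("Q must be symmetric 9x9")
        if self.b <= 0:
            raise ValueError("Weibull exponent must be positive")

    def p_correct(self, c: np.ndarray) -> float:
        """Probability of a correct response for coordinate vector c."""
        c = np.asarray(c, dtype=float)
        dist = float(np.sqrt(max(c @ self.Q @ c, 0.0)))
        return 0.25 + 0.75 * (1.0 - 2.0 ** -(dist**self.b)) if dist > 0 else 0.25


def simulate_observer(
    design: pd.DataFrame, model: ObserverModel, seed: int
) -> pd.DataFrame:
    """Fill a trial table's responses by simulating the observer.

    A trial at distance x along ray u has coordinate vector c = x u and is
    answered correctly with probability 1/4 + 3/4 (1 - 2^(-d^b)) where
    d = sqrt(c^T Q* c); incorrect responses pick uniformly among the three
    wrong locations.
    """
    rng = np.random.default_rng(seed)
    out = design.copy()
    locations = ("top", "bottom", "left", "right")
    responses = []
    corrects = []
    for row in out.itertuples():
        c = row.magnitude * ray_direction(row.plane, row.ray)
        correct = rng.random() < model.p_correct(c)
        if correct:
            responses.append(row.target_loc)
        else:
            wrong = [loc for loc in locations if loc != row.target_loc]
            responses.append(wrong[rng.integers(3)])
        corrects.append(correct)
    out["response_loc"] = responses
    out["correct"] = corrects
    return out
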