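"""Overlap statistics and permutation nulls for image/psychophysics matches.

The match between an image ensemble and psychophysics is quantified by
normalized scalar products ("overlaps") of four vector quantities:

* sigma -- the 9 per-coordinate standard deviations vs the 9 sensitivities,
* omega -- the quarter-sphere (eccentricity, tilt) vectors of the 36
  pairwise-plane contours, averaged over planes,
* f     -- fractional contributions of the four coordinate sets to each of
  the 9 symmetry-aligned principal axes, averaged over axes,
* F     -- fractional contributions of the individual 9 coordinates,
  averaged over axes.

Significance is assessed against three permutation nulls:

* **1a** -- the 23 non-identity permutations of the four coordinate-set
  labels {beta_cardinal, beta_oblique, theta, alpha}, applied to the
  psychophysical vectors (a set-label permutation moves whole blocks),
* **1b** -- random permutations of the 9 individual coordinate labels,
  applied to the psychophysical vectors,
* **2**  -- per-coordinate random shuffles of the patch labels of the
  image ensemble (destroys inter-coordinate correlations; marginal
  standard deviations are untouched, so this null is not applicable to
  the sigma overlap).

p-values are the plain exceedance fraction (shuffled >= observed), with
the attainable floor 1/n reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .ensemble_analysis import (
    COORD_SETS,
    EllipseSummary,
    pairwise_contours,
    principal_axes,
    summarize,
)

__all__ = [
    "OverlapReport",
    "NotApplicableError",
    "overlap",
    "set_label_permutations",
    "permute_by_sets",
    "permute_matrix",
    "permute_contours_by_sets",
    "sample_label_permutations",
    "shuffle_patch_labels",
    "permutation_test",
    "omega_overlap",
    "axis_vector_overlap",
    "null_sigma_overlaps",
    "compare_analyses",
]

_SET_SLOTS = [np.array(idx) for idx in COORD_SETS.values()]
_SET_OF = np.empty(9, dtype=int)
for _g, _slots in enumerate(_SET_SLOTS):
    _SET_OF[_slots] = _g


class NotApplicableError(ValueError):
    """Requested null model does not apply to this quantity."""


def overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Scalar product of the two normalized vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("overlap undefined for a zero vector")
    return float(a @ b / (na * nb))


def omega_overlap(contours_a: dict, contours_b: dict) -> float:
    """Plane-wise scalar product of omega vectors, averaged over planes."""
    keys = sorted(contours_a)
    if sorted(contours_b) != keys:
        raise ValueError("contour dictionaries must cover the same planes")
    return float(
        np.mean([contours_a[k].omega @ contours_b[k].omega for k in keys])
    )


def axis_vector_overlap(fa: np.ndarray, fb: np.ndarray) -> float:
    """Mean over axes of the normalized scalar product of f (or F) rows."""
    fa, fb = np.asarray(fa, float), np.asarray(fb, float)
    if fa.shape != fb.shape:
        raise ValueError("fractional-contribution arrays must match in shape")
    return float(np.mean([overlap(x, y) for x, y in zip(fa, fb)]))


def set_label_permutations() -> list[tuple[int, ...]]:
    """The 23 non-identity permutations of the four coordinate-set labels."""
    identity = tuple(range(4))
    return [p for p in itertools.permutations(range(4)) if p != identity]


def permute_by_sets(v: np.ndarray, perm: tuple[int, ...]) -> np.ndarray:
    """Apply a set-label permutation to a 9-coordinate vector.

    The block of set g receives the values of set perm[g]; because the
    sets have unequal sizes (2, 2, 4, 1), the moved block is broadcast as
    its mean (exact for pooled psychophysical data, whose within-set
    values coincide).
    """
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    for g, src in enumerate(perm):
        out[_SET_SLOTS[g]] = v[_SET_SLOTS[src]].mean()
    return out


def sample_label_permutations(
    n_perms: int, seed: int, n_labels: int = 9
) -> list[np.ndarray]:
    """Uniform i.i.d. permutations of the coordinate labels (null 1b)."""
    rng = np.random.default_rng(seed)
    return [rng.permutation(n_labels) for _ in range(n_perms)]


def shuffle_patch_labels(vectors: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently shuffle patch labels within each coordinate (null 2).

    Marginals of every coordinate are preserved exactly; correlations
    between coordinates are destroyed.
    """
    vectors = np.asarray(vectors, dtype=float)
    out = np.empty_like(vectors)
    for k in range(vectors.shape[1]):
        out[:, k] = vectors[rng.permutation(vectors.shape[0]), k]
    return out


@dataclass
class OverlapReport:
    measure: str
    observed: float
    p_value: float
    min_attainable_p: float
    null_mean: float
    null_std: float
    null_min: float
    null_max: float
    n_permutations: int
    seed: int | None = None


def permutation_test(
    observed: float,
    shuffled: np.ndarray,
    measure: str = "",
    seed: int | None = None,
    add_one: bool = False,
) -> OverlapReport:
    """Exceedance-fraction p-value of an observed overlap against a null.

    ``add_one`` switches to the (count+1)/(n+1) convention; the default is
    the plain fraction, with the attainable floor 1/n reported so a zero
    count is interpretable.
    """
    shuffled = np.asarray(shuffled, dtype=float)
    if shuffled.size == 0:
        raise ValueError("need at least one shuffled value")
    count = int(np.sum(shuffled >= observed))
    n = shuffled.size
    p = (count + 1) / (n + 1) if add_one else count / n
    return OverlapReport(
        measure=measure,
        observed=float(observed),
        p_value=float(p),
        min_attainable_p=1.0 / n,
        null_mean=float(shuffled.mean()),
        null_std=float(shuffled.std()),
        null_min=float(shuffled.min()),
        null_max=float(shuffled.max()),
        n_permutations=n,
        seed=seed,
    )


def null_sigma_overlaps(
    image_std: np.ndarray,
    psy_sens: np.ndarray,
    kind: str,
    n_perms: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Shuffled sigma overlaps under null 1a or 1b (kind 2 is inapplicable)."""
    if kind == "2":
        raise NotApplicableError(
            "patch-label shuffling preserves marginal standard deviations; "
            "null model 2 does not apply to the sigma overlap"
        )
    if kind == "1a":
        perms = set_label_permutations()
        return np.array(
            [overlap(image_std, permute_by_sets(psy_sens, p)) for p in perms]
        )
    if kind == "1b":
        perms = sample_label_permutations(n_perms, seed)
        return np.array([overlap(image_std, np.asarray(psy_sens)[p]) for p in perms])
    raise ValueError(f"unknown null kind {kind!r}")


def permute_matrix(M: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Conjugate a symmetric matrix by a coordinate-label permutation."""
    perm = np.asarray(perm)
    return np.asarray(M, dtype=float)[np.ix_(perm, perm)]


def _swap_axes(e: EllipseSummary) -> EllipseSummary:
    """Ellipse after exchanging the plane's x and y axes (reflect about y=x)."""
    if e.eccentricity == 0:
        return EllipseSummary(0.0, 0.0)
    tilt = np.pi / 2 - e.tilt
    if tilt >= np.pi / 2:
        tilt -= np.pi
    return EllipseSummary(e.eccentricity, float(tilt))


def permute_contours_by_sets(
    contours: dict, perm: tuple[int, ...], sens: np.ndarray
) -> dict:
    """Plane contours of a set-label-permuted subject (null 1a).

    The contour of plane {i, j} (i in set g, j in set h) is taken from the
    class of planes spanned by the source sets (perm[g], perm[h]); class
    members are averaged on the quarter sphere (exact for pooled
    psychophysical data, where they coincide), with axes swapped when the
    canonical orientation of source and target planes disagree.  A
    within-set target plane whose source set has a single coordinate (the
    alpha set offers no within-set plane) falls back to the axis-aligned
    contour implied by the permuted on-axis sensitivities.
    """
    sens_p = permute_by_sets(sens, perm)
    # group source ellipses by (set of x coord, set of y coord)
    by_class: dict[tuple[int, int], list[np.ndarray]] = {}
    for (p, q), e in contours.items():
        by_class.setdefault((_SET_OF[p], _SET_OF[q]), []).append(e.omega)
        if _SET_OF[p] != _SET_OF[q]:
            by_class.setdefault((_SET_OF[q], _SET_OF[p]), []).append(_swap_axes(e).omega)

    out = {}
    for (i, j) in contours:
        g, h = _SET_OF[i], _SET_OF[j]
        src = (int(perm[g]), int(perm[h]))
        omegas = by_class.get(src)
        if omegas is None:  # within-set plane mapped to the 1-D alpha set
            si, sj = sens_p[i], sens_p[j]
            if np.isclose(si, sj):
                out[(i, j)] = EllipseSummary(0.0, 0.0)
            else:
                ecc = float(np.sqrt(1 - (min(si, sj) / max(si, sj)) ** 2))
                tilt = 0.0 if si < sj else -np.pi / 2
                out[(i, j)] = EllipseSummary(ecc, tilt)
            continue
        w = np.mean(omegas, axis=0)
        w = w / np.linalg.norm(w)
        ecc = float(np.hypot(w[0], w[1]))
        tilt = float(np.arctan2(w[1], w[0])) if ecc > 1e-12 else 0.0
        out[(i, j)] = EllipseSummary(ecc, tilt, omega=w)
    return out


def compare_analyses(
    image_std: np.ndarray,
    image_cov: np.ndarray,
    psy_sens: np.ndarray,
    psy_Q: np.ndarray,
    kind: str = "1b",
    n_perms: int = 10_000,
    seed: int = 0,
    image_vectors: np.ndarray | None = None,
    add_one: bool = False,
) -> dict[str, OverlapReport]:
    """Observed sigma/omega/f/F overlaps with one permutation null.

    Nulls 1a and 1b shuffle the psychophysical side (set labels resp.
    individual coordinate labels, the latter conjugating Q so plane
    contours and principal axes are recomputed consistently).  Null 2
    shuffles patch labels of the image ensemble per coordinate and
    recomputes the image-side quantities; it requires ``image_vectors``
    and does not apply to sigma.
    """
    image_contours = pairwise_contours(np.asarray(image_cov, float))
    image_axes = principal_axes(np.asarray(image_cov, float))
    psy_contours = pairwise_contours(np.asarray(psy_Q, float))
    psy_axes = principal_axes(np.asarray(psy_Q, float))

    observed = {
        "sigma": overlap(image_std, psy_sens),
        "omega": omega_overlap(image_contours, psy_contours),
        "f": axis_vector_overlap(image_axes.f, psy_axes.f),
        "F": axis_vector_overlap(image_axes.F, psy_axes.F),
    }

    nulls: dict[str, list[float]] = {m: [] for m in observed}
    if kind == "1a":
        for p in set_label_permutations():
            nulls["sigma"].append(overlap(image_std, permute_by_sets(psy_sens, p)))
            shuffled_c = permute_contours_by_sets(psy_contours, p, np.asarray(psy_sens))
            nulls["omega"].append(omega_overlap(image_contours, shuffled_c))
            nulls["f"].append(
                axis_vector_overlap(image_axes.f, psy_axes.f[:, list(p)])
            )
            F_shuffled = np.stack([permute_by_sets(row, p) for row in psy_axes.F])
            nulls["F"].append(axis_vector_overlap(image_axes.F, F_shuffled))
    elif kind == "1b":
        for p in sample_label_permutations(n_perms, seed):
            nulls["sigma"].append(overlap(image_std, np.asarray(psy_sens)[p]))
            Qp = permute_matrix(psy_Q, p)
            nulls["omega"].append(
                omega_overlap(image_contours, pairwise_contours(Qp))
            )
            axes_p = principal_axes(Qp)
            nulls["f"].append(axis_vector_overlap(image_axes.f, axes_p.f))
            nulls["F"].append(axis_vector_overlap(image_axes.F, axes_p.F))
    elif kind == "2":
        if image_vectors is None:
            raise ValueError("null model 2 requires the image coordinate vectors")
        del nulls["sigma"]  # marginal-preserving shuffle cannot move sigma
        del observed["sigma"]
        rng = np.random.default_rng(seed)
        for _ in range(n_perms):
            shuffled = shuffle_patch_labels(image_vectors, rng)
            s = summarize(shuffled)
            ax = principal_axes(s.covariance)
            nulls["omega"].append(
                omega_overlap(pairwise_contours(s.covariance), psy_contours)
            )
            nulls["f"].append(axis_vector_overlap(ax.f, psy_axes.f))
            nulls["F"].append(axis_vector_overlap(ax.F, psy_axes.F))
    else:
        raise ValueError(f"unknown null kind {kind!r}")

    return {
        m: permutation_test(
            observed[m], np.array(nulls[m]), measure=m, seed=seed, add_one=add_one
        )
        for m in observed
    }
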