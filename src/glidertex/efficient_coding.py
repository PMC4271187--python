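"""Two regimes of efficient coding with a linear Gaussian channel model.

**Independent channels.**  A scalar signal of strength ``s`` (standard
deviation, in units of the sampling noise) is corrupted by unit sampling
noise, passed through a gain ``|L|``, and corrupted by unit channel noise;
total output power across channels is constrained through a Lagrange
multiplier ``Lambda`` in (0, 1).  The information-maximizing gain is

    |L|^2 = [-(2 + s^2) + sqrt(s^4 + 4 s^2 / Lambda)] / [2 (1 + s^2)]

clamped at zero; the channel is encoded exactly when s^2 > Lambda/(1-Lambda).
For Lambda -> 1 (transmission-limited) the gain falls off as 1/s
("whitening"); for Lambda -> 0 (sampling-limited) the gain *grows* as
sqrt(s) over Lambda < s < 1 -- the regime in which more variable signals
earn more resources.

**Two-dimensional filter.**  For a 2-D signal with covariance S (trace 1),
isotropic sampling noise Xi and channel noise Sigma, the response is
r = L(s + xi) + eta; the output power d*Sigma + Xi tr(L L^T) + tr(L S L^T)
is constrained to 1 and the mutual information

    I = 1/2 log det(I + S^(1/2) L'^T L' S^(1/2)),   L' = D^(-1/2) V^T L

(with N = Sigma I + Xi L L^T = V D V^T the output-noise covariance) is
maximized numerically.  Below total noise 0.5 the optimal filter is
antialigned with the signal (whitening); above, it is aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ChannelSolution",
    "FilterOptimum",
    "InfeasibleError",
    "analytic_gain",
    "mutual_info",
    "optimize_filter",
    "random_signal_covariance",
    "regime_map",
    "alignment_transition",
    "matrix_shape",
]


class InfeasibleError(ValueError):
    """The power constraint cannot be met (channel noise alone exceeds it)."""


@dataclass
class ChannelSolution:
    Lambda: float
    s: float
    gain: float
    encoded: bool


@dataclass
class FilterOptimum:
    L: np.ndarray
    S: np.ndarray
    Xi: float
    Sigma: float
    info: float
    alignment: str  # "aligned" | "antialigned" | "degenerate"
    filter_tilt: float
    filter_ecc: float
    signal_tilt: float
    signal_ecc: float


def analytic_gain(s: float, Lambda: float) -> ChannelSolution:
    """Optimal gain of one independent channel (closed form)."""
    if not 0 < Lambda < 1:
        raise ValueError("Lambda must lie strictly between 0 and 1")
    if s < 0:
        raise ValueError("signal strength must be nonnegative")
    g2 = (-(2 + s**2) + np.sqrt(s**4 + 4 * s**2 / Lambda)) / (2 * (1 + s**2))
    g2 = max(g2, 0.0)
    return ChannelSolution(Lambda, s, float(np.sqrt(g2)), encoded=g2 > 0)


def mutual_info(L: np.ndarray, S: np.ndarray, Xi: float, Sigma: float) -> float:
    """Mutual information (nats) of r = L(s + xi) + eta, Gaussian throughout."""
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    d = L.shape[0]
    N = Sigma * np.eye(d) + Xi * (L @ L.T)
    eigN, V = np.linalg.eigh(N)
    if eigN.min() <= 1e-300:
        raise ValueError("singular output-noise covariance N")
    Lp = (V / np.sqrt(eigN)).T @ L  # D^(-1/2) V^T L
    eigS, U = np.linalg.eigh(S)
    eigS = np.clip(eigS, 0.0, None)
    Shalf = (U * np.sqrt(eigS)) @ U.T
    M = np.eye(d) + Shalf @ Lp.T @ Lp @ Shalf
    sign, logdet = np.linalg.slogdet(M)
    return float(0.5 * logdet)


def matrix_shape(M: np.ndarray) -> tuple[float, float]:
    """(tilt, eccentricity) of a symmetric PSD 2x2 matrix.

    Eigenvalues g act as semi-axes: ecc = sqrt(1 - (g_min/g_max)^2); tilt
    is the leading eigenvector's angle, wrapped to [-pi/2, pi/2).
    """
    lam, vecs = np.linalg.eigh(np.asarray(M, dtype=float))
    if lam[1] <= 0:
        raise ValueError("matrix must be nonzero PSD")
    ecc = float(np.sqrt(max(1 - (lam[0] / lam[1]) ** 2, 0.0)))
    lead = vecs[:, 1]
    tilt = float(np.arctan2(lead[1], lead[0]))
    if tilt >= np.pi / 2:
        tilt -= np.pi
    elif tilt < -np.pi / 2:
        tilt += np.pi
    return tilt, ecc


def _tilt_distance(t1: float, t2: float) -> float:
    """Angular distance between axial (180-degree symmetric) tilts."""
    d = abs(t1 - t2) % np.pi
    return min(d, np.pi - d)


def optimize_filter(
    S: np.ndarray,
    Xi: float,
    Sigma: float,
    seed: int = 0,
    n_restarts: int = 8,
    tol: float = 1e-9,
) -> FilterOptimum:
    """Information-maximizing 2x2 filter under the unit output-power budget.

    Both the information and the output power depend on L only through
    L^T L, so the left orthogonal factor of L is a pure gauge freedom; it
    is fixed by the polar gauge (L symmetric), which makes the filter
    shape L L^T = L^2 well-defined and reads L as "gains along two
    orthogonal axes".  The power constraint tr(L (Xi I + S) L^T) =
    1 - d*Sigma is enforced by projecting the 3 free symmetric components
    onto the constraint ellipsoid, so each restart is an unconstrained
    smooth ascent (best of ``n_restarts`` seeded starts kept).  At exactly
    Sigma = 0 every full-rank filter is lossless (channel noise is the
    only noise a filter can beat) and the objective is flat; a 1e-4
    tie-breaking channel noise selects the limiting optimum.

    Alignment compares the leading eigenvectors of L L^T and S: within 45
    degrees -> "aligned", otherwise "antialigned"; an isotropic signal is
    flagged "degenerate".
    """
    S = np.asarray(S, dtype=float)
    d = S.shape[0]
    if d != 2:
        raise ValueError("only the 2-D case is implemented")
    if Sigma >= 0.5:
        raise InfeasibleError(
            f"channel noise Sigma={Sigma} >= 0.5: noise alone exhausts the "
            "unit output-power budget (d=2); no solution for L"
        )
    tr = np.trace(S)
    if abs(tr - 1.0) > 1e-9:
        warnings.warn(f"rescaling S by 1/{tr:.6g} to unit trace")
        S = S / tr

    sigma_eff = Sigma if Sigma > 0 else 1e-4
    budget = 1.0 - d * Sigma
    M = Xi * np.eye(d) + S

    def build_L(p: np.ndarray) -> np.ndarray:
        B = np.array([[p[0], p[1]], [p[1], p[2]]])
        power = np.trace(B @ M @ B)
        return np.sqrt(budget / power) * B

    def objective(p: np.ndarray) -> float:
        L = build_L(p)
        return -mutual_info(L, S, Xi, sigma_eff)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        p0 = rng.standard_normal(3)
        res = minimize(objective, p0, method="BFGS",
                       options={"gtol": tol, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    L = build_L(best.x)
    info = -best.fun

    sig_tilt, sig_ecc = matrix_shape(S)
    fil_tilt, fil_ecc = matrix_shape(L @ L.T)
    if sig_ecc < 1e-6:
        alignment = "degenerate"
    else:
        alignment = (
            "aligned" if _tilt_distance(fil_tilt, sig_tilt) < np.pi / 4 else "antialigned"
        )
    return FilterOptimum(L, S, Xi, Sigma, info, alignment,
                         fil_tilt, fil_ecc, sig_tilt, sig_ecc)


def output_power(L: np.ndarray, S: np.ndarray, Xi: float, Sigma: float) -> float:
    """d*Sigma + Xi tr(L L^T) + tr(L S L^T)."""
    L = np.asarray(L, float)
    S = np.asarray(S, float)
    return float(
        L.shape[0] * Sigma + Xi * np.trace(L @ L.T) + np.trace(L @ S @ L.T)
    )


def random_signal_covariance(
    rng: np.random.Generator,
    ecc_range: tuple[float, float] = (0.3, 0.95),
) -> np.ndarray:
    """Unit-trace anisotropic 2x2 covariance with random tilt and eccentricity."""
    ecc = rng.uniform(*ecc_range)
    tilt = rng.uniform(-np.pi / 2, np.pi / 2)
    ratio = np.sqrt(1 - ecc**2)  # g_min / g_max
    g_max = 1.0 / (1.0 + ratio)
    g_min = ratio * g_max
    c, s = np.cos(tilt), np.sin(tilt)
    R = np.array([[c, -s], [s, c]])
    return R @ np.diag([g_max, g_min]) @ R.T


def _aligned_fraction(
    Xi: float, Sigma: float, n_signals: int, seed: int, n_restarts: int
) -> tuple[float, int]:
    rng = np.random.default_rng(seed)
    aligned = 0
    degenerate = 0
    counted = 0
    for k in range(n_signals):
        S = random_signal_covariance(rng)
        opt = optimize_filter(S, Xi, Sigma, seed=seed + 7919 * k + 1,
                              n_restarts=n_restarts)
        if opt.alignment == "degenerate":
            degenerate += 1
            continue
        aligned += opt.alignment == "aligned"
        counted += 1
    return (aligned / counted if counted else float("nan")), degenerate


def regime_map(
    xi_grid,
    sigma_grid,
    n_signals: int = 50,
    seed: int = 0,
    n_restarts: int = 4,
) -> pd.DataFrame:
    """Fraction of random signals whose optimal filter is signal-aligned.

    One row per (Xi, Sigma) grid point; the transition sits at total noise
    Xi + Sigma = 0.5 (antialigned/whitening below, aligned above).
    """
    rows = []
    for Xi in xi_grid:
        for Sigma in sigma_grid:
            frac, degen = _aligned_fraction(Xi, Sigma, n_signals, seed, n_restarts)
            rows.append((Xi, Sigma, Xi + Sigma, frac, degen))
    return pd.DataFrame(
        rows, columns=["xi", "sigma", "total_noise", "frac_aligned", "n_degenerate"]
    )


def alignment_transition(
    n_signals: int = 50,
    seed: int = 0,
    lo: float = 0.3,
    hi: float = 0.7,
    tol: float = 0.02,
    n_restarts: int = 4,
) -> float:
    """Total-noise value where the majority classification flips, by bisection.

    Noise is split evenly between sampling and channel components
    (Xi = Sigma = t/2, keeping Sigma < 0.5 feasible) and the flip point of
    the majority vote over ``n_signals`` random signal covariances is
    bracketed to within ``tol``.
    """

    def majority_aligned(t: float) -> bool:
        frac, _ = _aligned_fraction(t / 2, t / 2, n_signals, seed, n_restarts)
        return frac > 0.5

    if majority_aligned(lo) or not majority_aligned(hi):
        raise RuntimeError("bracketing endpoints do not straddle the transition")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if majority_aligned(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
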