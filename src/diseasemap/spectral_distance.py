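"""Ipsen-Mikhailov (IM) spectral distance between weighted matrices.

The IM distance views a symmetric non-negative matrix W as a weighted graph
and compares the vibrational spectra of the corresponding Laplacians
L = diag(rowsum) - W.  With Laplacian eigenvalues 0 = lambda_1 <= ... <=
lambda_n, the vibrational frequencies are omega_i = sqrt(lambda_i) (the
trivial zero mode is dropped), smoothed into a Lorentzian spectral density

    rho(omega) = K * sum_i gamma / ((omega - omega_i)^2 + gamma^2),

normalized so that the density integrates to one on [0, inf); the distance is

    d(W1, W2) = sqrt( integral_0^inf (rho_1 - rho_2)^2 d omega ).

The half-width gamma sets the resolution of the comparison and is calibrated
per matrix size n so that the distance between the empty and the complete
graph equals exactly 1, the standard IM normalization.  This module is used
to compare *distance matrices* with each other: across the six per-dimension
metrics, across the six data dimensions, and against an ICD-derived matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import integrate, linalg, optimize

from .io_model import DistanceMatrix, FormatError, NumericError

logger = logging.getLogger(__name__)

#: How a DistanceMatrix is interpreted as a weighted adjacency matrix.
#: "distance" passes the matrix verbatim (what feeding a distance matrix to a
#: generic network-distance routine does); "similarity" uses 1 - D off the
#: diagonal instead.
ADJACENCY_INTERPRETATIONS = ("distance", "similarity")

_SYM_TOL = 1e-9
_QUAD_EPSABS = 1e-8
_TRAPEZOID_POINTS = 20001
#: Integration upper bound: max omega + this many gamma widths.
_TAIL_WIDTHS = 10.0


def laplacian_spectrum(w: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of L = diag(rowsum(W)) - W.

    W must be square, symmetric within 1e-9, non-negative, with (near-)zero
    diagonal.  The smallest eigenvalue of a valid Laplacian is 0 up to
    numerical noise.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError(f"expected a square matrix, got shape {w.shape}")
    if w.size and np.abs(w - w.T).max() > _SYM_TOL:
        raise FormatError("matrix is asymmetric beyond 1e-9")
    if w.size and w.min() < -_SYM_TOL:
        raise FormatError("matrix has negative entries")
    if w.size and np.abs(np.diag(w)).max() > _SYM_TOL:
        raise FormatError("matrix diagonal must be zero")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    lap = np.diag(w.sum(axis=1)) - w
    vals = linalg.eigvalsh(lap)
    if vals.size and vals[0] < -1e-8:
        raise NumericError(f"Laplacian produced eigenvalue {vals[0]:.3e} < 0")
    return np.maximum(vals, 0.0)


@dataclass
class SpectralDensity:
    """Lorentzian-smoothed vibrational density of one Laplacian spectrum."""

    omegas: np.ndarray
    gamma: float
    norm_constant: float

    @classmethod
    def from_spectrum(cls, eigenvalues: np.ndarray, gamma: float) -> "SpectralDensity":
        """Drop the trivial zero eigenvalue; keep degenerate extra zeros as
        omega = 0 modes (disconnected graphs)."""
        if gamma <= 0:
            raise FormatError("gamma must be positive")
        omegas = np.sqrt(np.maximum(np.asarray(eigenvalues, dtype=float)[1:], 0.0))
        # closed form: int_0^inf gamma/((w-w_i)^2+gamma^2) dw = pi/2 + atan(w_i/gamma)
        k = 1.0 / float(np.sum(np.pi / 2.0 + np.arctan(omegas / gamma)))
        return cls(omegas=omegas, gamma=gamma, norm_constant=k)

    @classmethod
    def from_matrix(cls, w: np.ndarray, gamma: float) -> "SpectralDensity":
        return cls.from_spectrum(laplacian_spectrum(w), gamma)

    def __call__(self, omega) -> np.ndarray | float:
        """Evaluate the density at scalar or vector omega."""
        g = self.gamma
        if np.ndim(omega) == 0:
            return self.norm_constant * float(
                np.sum(g / ((omega - self.omegas) ** 2 + g * g))
            )
        omega = np.asarray(omega, dtype=float)
        out = np.empty_like(omega)
        # chunked to bound the (n_points, n_modes) broadcast
        for lo in range(0, omega.size, 4096):
            chunk = omega[lo : lo + 4096, None]
            out[lo : lo + 4096] = np.sum(
                g / ((chunk - self.omegas[None, :]) ** 2 + g * g), axis=1
            )
        return self.norm_constant * out


def _im_from_omegas(om1: np.ndarray, om2: np.ndarray, gamma: float) -> float:
    rho1 = SpectralDensity.from_spectrum(np.concatenate([[0.0], om1 ** 2]), gamma)
    rho2 = SpectralDensity.from_spectrum(np.concatenate([[0.0], om2 ** 2]), gamma)
    upper = float(max(om1.max(initial=0.0), om2.max(initial=0.0)) + _TAIL_WIDTHS * gamma)

    def integrand(w: float) -> float:
        return (rho1(w) - rho2(w)) ** 2

    peaks = np.unique(np.round(np.concatenate([om1, om2]), 12))
    peaks = [float(p) for p in peaks if 0.0 < p < upper]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            val, _ = integrate.quad(
                integrand,
                0.0,
                upper,
                epsabs=_QUAD_EPSABS,
                limit=max(200, 2 * len(peaks) + 50),
                points=peaks if 0 < len(peaks) <= 100 else None,
            )
    except integrate.IntegrationWarning:
        grid = np.linspace(0.0, upper, _TRAPEZOID_POINTS)
        val = float(np.trapezoid((rho1(grid) - rho2(grid)) ** 2, grid))
    return float(np.sqrt(max(val, 0.0)))


def im_distance(w1: np.ndarray, w2: np.ndarray, gamma: float) -> float:
    """IM distance between two symmetric non-negative matrices at a given gamma."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise FormatError(f"size mismatch: {w1.shape} vs {w2.shape}")
    om1 = np.sqrt(np.maximum(laplacian_spectrum(w1)[1:], 0.0))
    om2 = np.sqrt(np.maximum(laplacian_spectrum(w2)[1:], 0.0))
    return _im_from_omegas(om1, om2, gamma)


@lru_cache(maxsize=None)
def calibrate_gamma(n: int) -> float:
    """Lorentzian half-width such that d(empty_n, complete_n) = 1.

    The empty graph has all vibrational frequencies at 0 and the complete
    graph (unit weights) has all n-1 of them at sqrt(n); the distance between
    them is strictly decreasing in gamma, so the root is unique and found by
    bracketing + Brent's method.
    """
    if n < 2:
        raise FormatError("calibration needs n >= 2")
    om_empty = np.zeros(n - 1)
    om_complete = np.full(n - 1, np.sqrt(n))

    def objective(g: float) -> float:
        return _im_from_omegas(om_empty, om_complete, g) - 1.0

    lo, hi = 0.01, 1.0
    f_lo = objective(lo)
    while f_lo < 0:
        lo /= 4.0
        if lo < 1e-8:
            raise NumericError(f"gamma bracketing failed at n={n}: no lower bound")
        f_lo = objective(lo)
    f_hi = objective(hi)
    while f_hi > 0:
        hi *= 2.0
        if hi > 1e6:
            raise NumericError(f"gamma bracketing failed at n={n}: no upper bound")
        f_hi = objective(hi)
    gamma = optimize.brentq(objective, lo, hi, xtol=1e-12, rtol=8.9e-16)
    check = objective(gamma)
    if abs(check) > 1e-6:
        raise NumericError(
            f"gamma calibration for n={n} off by {check:.2e} (gamma={gamma:.6g})"
        )
    logger.info("calibrated gamma(n=%d) = %.8g", n, gamma)
    return float(gamma)


@dataclass
class MatrixFamilyDistance:
    """Pairwise IM distances among a labeled family of same-size matrices."""

    labels: list[str]
    values: np.ndarray
    gamma: float
    interpretation: str = "distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise FormatError("family distance shape does not match labels")
        if v.size and (np.abs(v - v.T).max() > 1e-9 or np.abs(np.diag(v)).max() > 1e-9):
            raise FormatError("family distance must be symmetric with zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def to_adjacency(dm: DistanceMatrix, interpretation: str = "distance") -> np.ndarray:
    """Interpret a DistanceMatrix as a weighted adjacency matrix."""
    if interpretation not in ADJACENCY_INTERPRETATIONS:
        raise FormatError(
            f"unknown adjacency interpretation {interpretation!r}; "
            f"expected one of {ADJACENCY_INTERPRETATIONS}"
        )
    if interpretation == "distance":
        w = dm.values.copy()
    else:
        w = 1.0 - dm.values
        np.fill_diagonal(w, 0.0)
    return w


def matrix_family_distance(
    matrices: Sequence[DistanceMatrix],
    labels: Sequence[str],
    interpretation: str = "distance",
    gamma: float | None = None,
) -> MatrixFamilyDistance:
    """Pairwise IM distance among distance matrices over one disease set.

    All matrices must share the identical ordered disease vector; gamma is
    calibrated once for that size (or passed explicitly) and reused for every
    pair, so the family is internally comparable.
    """
    if len(matrices) != len(labels):
        raise FormatError("matrices and labels length mismatch")
    if len(matrices) < 2:
        raise FormatError("need at least two matrices")
    ids = matrices[0].disease_ids
    for m in matrices[1:]:
        if m.disease_ids != ids:
            raise FormatError("inconsistent disease ordering across family matrices")
    if gamma is None:
        gamma = calibrate_gamma(len(ids))
    omegas = [
        np.sqrt(np.maximum(laplacian_spectrum(to_adjacency(m, interpretation))[1:], 0.0))
        for m in matrices
    ]
    k = len(matrices)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = _im_from_omegas(omegas[i], omegas[j], gamma)
    return MatrixFamilyDistance(list(labels), vals, gamma, interpretation)


def write_family_distance(fam: MatrixFamilyDistance, path) -> None:
    import pandas as pd

    df = pd.DataFrame(fam.values, index=fam.labels, columns=fam.labels)
    df.to_csv(path, sep="\t", float_format="%.17g")
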