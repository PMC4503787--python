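"""Spectral screening of weight matrices for slow-assembly potential.

A network supports slow-switching assemblies when (i) a set of leading
eigenvalues of W is separated from the bulk by a gap in the real parts
and (ii) the corresponding Schur vectors are block-localized on groups
of neurons.  This module computes eigen-spectra, detects the gap,
extracts the ordered dominant (real) Schur basis, scores the
block-localization against a partition, and flags the winner-takes-all
regime lambda_max >= 1 in which one assembly sustains itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from ssanet.topology import Partition, WeightMatrix

__all__ = [
    "SpectralSummary", "spectrum", "detect_gap", "dominant_schur_basis",
    "block_localization_score", "winner_takes_all_flag", "spectral_summary",
]


def _values(W) -> np.ndarray:
    return W.values if isinstance(W, WeightMatrix) else np.asarray(W, float)


@dataclass
class SpectralSummary:
    eigenvalues: np.ndarray       # complex, sorted by descending real part
    m: int                        # leading count above the gap
    gap: float                    # Re lambda_(m) - Re lambda_(m+1)
    lambda_max: float             # largest real part
    wta_flag: bool                # lambda_max >= 1
    dominant_basis: np.ndarray | None = None
    localization_leading: float | None = None
    localization_bulk: float | None = None
    balance_pair: complex | None = None


def spectrum(W) -> np.ndarray:
    """All eigenvalues of W, sorted by descending real part.

    Ties in the real part are broken by descending absolute imaginary
    part, keeping complex-conjugate pairs adjacent.
    """
    lam = np.linalg.eigvals(_values(W))
    order = np.lexsort((-np.abs(lam.imag), -lam.real))
    return lam[order]


def detect_gap(eigenvalues: np.ndarray,
               m: int | None = None,
               K: int | None = None) -> tuple[int, float]:
    """Leading count m and gap between real parts m and m+1.

    If ``m`` is given (e.g. c - 1 for a network with c known groups)
    the gap is simply Re lambda_(m) - Re lambda_(m+1) on the sorted
    spectrum.  Otherwise m is chosen as the largest consecutive
    real-part difference within the top ``K`` eigenvalues
    (default K = min(N // 10, 50)); the search is capped to avoid
    picking up spurious gaps deep inside the bulk.
    """
    lam = np.asarray(eigenvalues)
    if lam.size < 2:
        raise ValueError("need at least two eigenvalues")
    order = np.lexsort((-np.abs(lam.imag), -lam.real))
    re = lam[order].real
    if m is not None:
        if not 1 <= m < lam.size:
            raise ValueError("m out of range")
        return m, float(re[m - 1] - re[m])
    if K is None:
        K = min(max(lam.size // 10, 10), 50)
    K = min(K, lam.size - 1)
    diffs = re[:K] - re[1:K + 1]
    m_auto = int(np.argmax(diffs)) + 1
    return m_auto, float(diffs[m_auto - 1])


def dominant_schur_basis(W, m: int) -> np.ndarray:
    """Orthonormal basis of the invariant subspace of the m leading modes.

    Real ordered Schur decomposition with the m eigenvalues of largest
    real part moved to the leading block; returns the first m Schur
    vectors.  If a complex-conjugate pair straddles the cut, the basis
    is extended by one column (the pair cannot be split in a real
    decomposition), so the result may have m + 1 columns.
    """
    A = _values(W)
    N = A.shape[0]
    if not 1 <= m < N:
        raise ValueError("need 1 <= m < N")
    lam_re = np.sort(np.linalg.eigvals(A).real)[::-1]
    # threshold between the m-th and (m+1)-th real parts
    thresh = 0.5 * (lam_re[m - 1] + lam_re[m])
    if np.isclose(lam_re[m - 1], lam_re[m]):
        thresh = lam_re[m - 1] - 1e-12
    T, Z, sdim = sla.schur(A, output="real",
                           sort=lambda re, im: re > thresh)
    k = int(sdim)
    B = Z[:, :k]
    # sign convention: first non-negligible component positive
    for j in range(B.shape[1]):
        nz = np.flatnonzero(np.abs(B[:, j]) > 1e-10)
        if nz.size and B[nz[0], j] < 0:
            B[:, j] = -B[:, j]
    return B


def block_localization_score(basis: np.ndarray,
                             partition: Partition) -> float:
    """Mean energy fraction of basis columns on block-constant patterns.

    For each column u, computes ||Pi u||^2 / ||u||^2 where Pi projects
    onto vectors constant within each partition group and zero on
    unassigned neurons; returns the mean over columns.  Exact group
    indicators score 1; an isotropically random vector scores about
    c / N.
    """
    g = partition.group_of
    if basis.shape[0] != g.shape[0]:
        raise ValueError("basis rows must match partition length")
    c = partition.n_groups
    if c == 0:
        raise ValueError("partition covers no neurons")
    sizes = partition.group_sizes()
    if np.any(sizes == 0):
        raise ValueError("partition contains empty groups")
    mask = g >= 0
    B = np.asarray(basis, dtype=float)
    scores = np.empty(B.shape[1])
    for j in range(B.shape[1]):
        u = B[:, j]
        group_sum = np.bincount(g[mask], weights=u[mask], minlength=c)
        proj_energy = float(np.sum(group_sum**2 / sizes))
        scores[j] = proj_energy / float(u @ u)
    return float(scores.mean())


def winner_takes_all_flag(W) -> tuple[float, bool]:
    """lambda_max (largest real part) and the flag lambda_max >= 1.

    Above 1 the slowest localized mode is linearly unstable: once
    excited it re-excites itself and one assembly dominates the firing
    (suppressing switching) instead of slowly trading activity.
    """
    lam_max = float(np.max(np.linalg.eigvals(_values(W)).real))
    return lam_max, bool(lam_max >= 1.0)


def _balance_pair(lam: np.ndarray) -> complex | None:
    """Isolated complex pair with most-negative real part, if separated.

    The balanced construction produces one damped global-activation
    mode to the left of the bulk.  Detected as a complex conjugate
    pair whose separation from the next eigenvalue exceeds 10x the
    local eigenvalue spacing at the bulk's left edge; informational.
    """
    if lam.size < 8:
        return None
    re = np.sort(lam.real)
    i = int(np.argmin(lam.real))
    if lam[i].imag == 0 or not np.isclose(re[0], re[1]):
        return None
    spacing = np.median(np.diff(re[2:min(40, lam.size)]))
    if spacing > 0 and (re[2] - re[1]) > 10 * spacing:
        return complex(lam[i].real, abs(lam[i].imag))
    return None


def spectral_summary(W, partition: Partition | None = None,
                     m: int | None = None,
                     compute_basis: bool = True) -> SpectralSummary:
    """One-stop spectral screening of a weight matrix.

    Computes the spectrum, detects the gap (auto unless ``m`` given),
    extracts the dominant Schur basis, and -- when a partition is
    supplied -- scores block-localization of the leading basis against
    a size-matched sample of bulk Schur vectors.
    """
    lam = spectrum(W)
    m_det, gap = detect_gap(lam, m=m)
    lam_max = float(lam.real[0])
    summary = SpectralSummary(
        eigenvalues=lam, m=m_det, gap=gap, lambda_max=lam_max,
        wta_flag=lam_max >= 1.0, balance_pair=_balance_pair(lam))
    if compute_basis:
        basis = dominant_schur_basis(W, m_det)
        summary.dominant_basis = basis
        if partition is not None and partition.n_groups > 0:
            summary.localization_leading = block_localization_score(
                basis, partition)
            # bulk reference: Schur vectors just below the gap
            A = _values(W)
            k = basis.shape[1]
            wide = dominant_schur_basis(A, min(3 * k + 1, A.shape[0] - 1))
            bulk = wide[:, k:]
            if bulk.shape[1]:
                summary.localization_bulk = block_localization_score(
                    bulk, partition)
    return summary
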