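"""Stylized linear rate models for clustered balanced networks.

Two coarse-grained models, integrated under

    tau dr/dt = -r + W r + xi = -(I - W) r + xi,

with r measured relative to baseline (components may be negative):

* **3-node model** -- two clustered excitatory groups (self coupling s,
  cross coupling eps < s) plus one uniformly coupled inhibitory node,
  with w = s + eps and inhibition dominance k >= 1:

      W3 = [[s,   eps, -k w],
            [eps, s,   -k w],
            [w/2, w/2, -k w]]

  Eigenvalues are exactly (-w(k-1), 0, s-eps).  The slow mode
  u3 = (-1, 1, 0)/sqrt(2) is an antagonistic pattern on the two
  excitatory groups that leaves the inhibitory node untouched; its
  decay time 1/(1 - (s - eps)) diverges as the clustering strength
  s - eps approaches the stability boundary s - eps = 1.

* **4-node model** -- two excitatory-to-inhibitory feedback pairs
  (e1, e2, i1, i2) with uniform E-E and I-I coupling, w = (s + eps)/2:

      W4 = [[w,   w,   -k eps, -k s],
            [w,   w,   -k s,   -k eps],
            [s,   eps, -k w,   -k w],
            [eps, s,   -k w,   -k w]]

  Its exact eigenvalues are (-(k-1)(s+eps), 0, +sqrt(k)(s-eps),
  -sqrt(k)(s-eps)); the slow mode u3 = (sqrt k, -sqrt k, 1, -1) /
  sqrt(2k+2) correlates each excitatory group with its paired
  inhibitory group and anti-correlates the two pairs.  Stability
  requires sqrt(k) (s - eps) < 1 (equivalently k(s-eps) < 1 at k = 1,
  the regime k ~ 1 the model is intended for).

Both Schur forms are constructed in closed form and verified against
the reconstruction W = U Q U^T; feedforward (off-diagonal) entries of
Q couple the global sum/difference modes (balanced amplification) and,
in the 4-node model, the two localized modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateModelSpec", "SchurForm",
    "build_w3", "build_w4", "eigenvalues_w3", "eigenvalues_w4",
    "analytic_schur3", "analytic_schur4",
    "stability_margin", "integrate_rate_model",
]


@dataclass(frozen=True)
class RateModelSpec:
    """Parameters (s, eps, k) of the stylized rate models.

    Requires s > eps > 0 and k >= 1; the composite coupling w is
    derived per model (s + eps for the 3-node, (s + eps)/2 for the
    4-node).  ``tau`` is the membrane time constant of the rate
    equation and ``noise_sd`` the standard deviation of the white
    noise input per unit sqrt(time).
    """

    s: float
    eps: float
    k: float = 1.0
    tau: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not self.s > self.eps > 0:
            raise ValueError("require s > eps > 0")
        if self.k < 1:
            raise ValueError("require k >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def w3(self) -> float:
        return self.s + self.eps

    @property
    def w4(self) -> float:
        return (self.s + self.eps) / 2.0

    @property
    def gap(self) -> float:
        """Clustering strength s - eps (the eigengap of the 3-node model)."""
        return self.s - self.eps


@dataclass
class SchurForm:
    """Orthonormal basis U, upper-triangular Q = U^T W U, and summaries."""

    U: np.ndarray
    Q: np.ndarray
    eigenvalues: np.ndarray          # diag(Q), slow-to-fast model order
    drift_eigenvalues: np.ndarray    # -1 + eigenvalues
    feedforward: dict

    def reconstruction_error(self, W: np.ndarray) -> float:
        return float(np.abs(W - self.U @ self.Q @ self.U.T).max())


def build_w3(spec: RateModelSpec) -> np.ndarray:
    s, e, k, w = spec.s, spec.eps, spec.k, spec.w3
    return np.array([
        [s, e, -k * w],
        [e, s, -k * w],
        [w / 2, w / 2, -k * w],
    ])


def build_w4(spec: RateModelSpec) -> np.ndarray:
    s, e, k, w = spec.s, spec.eps, spec.k, spec.w4
    return np.array([
        [w, w, -k * e, -k * s],
        [w, w, -k * s, -k * e],
        [s, e, -k * w, -k * w],
        [e, s, -k * w, -k * w],
    ])


def eigenvalues_w3(spec: RateModelSpec) -> tuple[float, float, float]:
    """(lambda1, lambda2, lambda3) = (-w(k-1), 0, s-eps), ascending."""
    return (-spec.w3 * (spec.k - 1.0), 0.0, spec.gap)


def eigenvalues_w4(spec: RateModelSpec) -> tuple[float, float, float, float]:
    """Exact eigenvalues of the 4-node W in model order (modes 1..4)."""
    lam = np.sqrt(spec.k) * spec.gap
    return (-(spec.k - 1.0) * (spec.s + spec.eps), 0.0, lam, -lam)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make the first nonzero component of each column positive."""
    U = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            U[:, j] = -col
    return U


def analytic_schur3(spec: RateModelSpec) -> SchurForm:
    """Closed-form Schur decomposition of the 3-node W.

    U = [u1 | u2 | u3] with u1 the uniform mode, u2 the E-vs-I
    difference mode and u3 the localized switching mode; Q carries the
    eigenvalues (-w+, 0, s-eps) on the diagonal and a single
    feedforward term w_ff = sqrt(2) (k + 1/2) w coupling mode 2 into
    mode 1.  The switching mode is dynamically uncoupled.
    """
    s, e, k, w = spec.s, spec.eps, spec.k, spec.w3
    u1 = np.ones(3) / np.sqrt(3.0)
    u2 = np.array([0.5, 0.5, -1.0]) / np.sqrt(1.5)
    u3 = np.array([-1.0, 1.0, 0.0]) / np.sqrt(2.0)
    U = _fix_signs(np.column_stack([u1, u2, u3]))
    w_plus = w * (k - 1.0)
    w_ff = np.sqrt(2.0) * (k + 0.5) * w
    lams = np.array(eigenvalues_w3(spec))
    Q = np.diag(lams)
    # sign of the feedforward entry follows the sign-fixed basis
    W = build_w3(spec)
    Q[0, 1] = U[:, 0] @ W @ U[:, 1]
    assert np.isclose(abs(Q[0, 1]), w_ff)
    form = SchurForm(U=U, Q=Q, eigenvalues=lams,
                     drift_eigenvalues=-1.0 + lams,
                     feedforward={"w_plus": w_plus, "w_ff": w_ff})
    err = form.reconstruction_error(W)
    if err > 1e-10:
        raise ArithmeticError(f"Schur reconstruction residual {err:.2e}")
    return form


def analytic_schur4(spec: RateModelSpec) -> SchurForm:
    """Closed-form Schur decomposition of the 4-node W.

    Modes: u1, u2 are the global sum and E-vs-I difference modes,
    coupled by the feedforward term w_ff = (k+1)(s+eps) (balanced
    amplification); u3, u4 are the localized pair modes with exact
    eigenvalues +-sqrt(k)(s-eps), coupled by w_ff2 = -(k-1)(s-eps).
    At k = 1 this reduces to u3 = (1, -1, 1, -1)/2,
    u4 = (1, -1, -1, 1)/2 with eigenvalues +-(s-eps).
    """
    s, e, k = spec.s, spec.eps, spec.k
    rk = np.sqrt(k)
    norm = np.sqrt(2.0 * k + 2.0)
    u1 = np.ones(4) / 2.0
    u2 = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
    u3 = np.array([rk, -rk, 1.0, -1.0]) / norm
    u4 = np.array([1.0, -1.0, -rk, rk]) / norm
    U = _fix_signs(np.column_stack([u1, u2, u3, u4]))
    w_plus = (k - 1.0) * (s + e)
    w_ff = (k + 1.0) * (s + e)
    w_ff2 = -(k - 1.0) * spec.gap
    lams = np.array(eigenvalues_w4(spec))
    Q = np.diag(lams)
    W = build_w4(spec)
    Q[0, 1] = U[:, 0] @ W @ U[:, 1]
    Q[2, 3] = U[:, 2] @ W @ U[:, 3]
    assert np.isclose(abs(Q[0, 1]), w_ff)
    assert np.isclose(abs(Q[2, 3]), abs(w_ff2))
    form = SchurForm(U=U, Q=Q, eigenvalues=lams,
                     drift_eigenvalues=-1.0 + lams,
                     feedforward={"w_plus": w_plus, "w_ff": w_ff,
                                  "w_ff2": w_ff2})
    err = form.reconstruction_error(W)
    if err > 1e-10:
        raise ArithmeticError(f"Schur reconstruction residual {err:.2e}")
    return form


def stability_margin(spec: RateModelSpec,
                     model: str = "3node") -> tuple[float, bool]:
    """Largest drift eigenvalue eta_max of -(I - W) and stability flag.

    eta_max = -1 + (s - eps) for the 3-node model and
    -1 + sqrt(k)(s - eps) for the 4-node model (exact; coincides with
    the k ~ 1 approximation -1 + k(s - eps) at k = 1).  The system is
    linearly stable iff eta_max < 0.
    """
    if model == "3node":
        eta = -1.0 + spec.gap
    elif model == "4node":
        eta = -1.0 + np.sqrt(spec.k) * spec.gap
    else:
        raise ValueError("model must be '3node' or '4node'")
    return float(eta), bool(eta < 0)


def integrate_rate_model(W: np.ndarray, tau: float = 1.0,
                         noise_sd: float = 0.1, duration: float = 10.0,
                         dt: float = 1e-3, seed: int = 0,
                         r0: np.ndarray | None = None) -> tuple[np.ndarray,
                                                                np.ndarray]:
    """Euler-Maruyama integration of tau dr/dt = -(I - W) r + xi.

    xi is additive white Gaussian noise, independent per component,
    with increments of standard deviation ``noise_sd * sqrt(dt)``.
    Returns (times, trajectory) with trajectory of shape (T, n).
    Divergence (linear instability) is allowed; the trajectory is
    truncated at the first non-finite state.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("W must be square")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    r = np.zeros(n) if r0 is None else np.asarray(r0, dtype=float).copy()
    A = -(np.eye(n) - W)
    out = np.empty((n_steps + 1, n))
    out[0] = r
    amp = noise_sd * np.sqrt(dt)
    for t in range(1, n_steps + 1):
        drift = A @ r * (dt / tau)
        noise = amp / tau * rng.standard_normal(n) if noise_sd > 0 else 0.0
        r = r + drift + noise
        if not np.all(np.isfinite(r)):
            return dt * np.arange(t), out[:t]
        out[t] = r
    return dt * np.arange(n_steps + 1), out
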