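"""Closed-form forward models for gray-matter neurite exchange imaging (NEXI).

The tissue is modelled as two exchanging water pools: intra-neurite water
diffusing along randomly oriented sticks with parallel diffusivity ``D_i``
(µm²/ms), and extra-neurite water with isotropic Gaussian diffusivity
``D_e``.  The pools exchange with characteristic time ``t_ex`` (ms) in the
barrier-limited (Kärger) regime.  The directional signal is the solution of
a 2×2 linear exchange system; the measured powder-average (spherical-mean)
signal is its integral over the cosine ``u = g·n`` between the gradient and
the stick axis.

Two extensions are provided:

* a stationary "dot" compartment of fraction ``f_dot`` whose signal does not
  decay with diffusion weighting;
* a Rician-mean (RM) transform that maps the noise-free signal onto the
  expected magnitude signal at normalized noise level ``σ``, accounting for
  the Rician noise floor that dominates at high b-value.

All b-values are in ms/µm², times in ms, diffusivities in µm²/ms; signals
are normalized to the b = 0 signal and therefore dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy import special

__all__ = [
    "TissueParameters",
    "NoiseModel",
    "ModelVariant",
    "karger_compartment_signal",
    "nexi_powder_signal",
    "nexi_dot_powder_signal",
    "laguerre_half",
    "rician_mean_transform",
    "model_predict",
    "predict_batch",
    "exchange_validity_times",
    "PARAM_NAMES",
]

PARAM_NAMES = ("t_ex", "D_i", "D_e", "f", "f_dot")

#: Below this signal-to-noise ratio the Rician mean is indistinguishable
#: from the noise floor and is returned directly for numerical stability.
_RM_FLOOR_SNR = 1e-6


@dataclass(frozen=True)
class TissueParameters:
    """Microstructure parameter set ``p = [t_ex, D_i, D_e, f]`` (+ ``f_dot``).

    Parameters
    ----------
    t_ex : float
        Inter-compartment exchange time (ms).  ``1/t_ex`` is the sum of the
        two exit rates.
    D_i : float
        Intra-neurite parallel diffusivity (µm²/ms).
    D_e : float
        Extra-neurite isotropic diffusivity (µm²/ms).
    f : float
        Neurite signal fraction of the exchanging (non-dot) signal, in (0, 1).
    f_dot : float, optional
        Stationary-water fraction in [0, 1); 0 recovers the two-compartment
        model exactly.
    """

    t_ex: float
    D_i: float
    D_e: float
    f: float
    f_dot: float = 0.0

    def __post_init__(self):
        vals = (self.t_ex, self.D_i, self.D_e, self.f, self.f_dot)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("tissue parameters must be finite")
        if self.t_ex <= 0:
            raise ValueError("t_ex must be > 0 (use a small positive bound)")
        if self.D_i < 0 or self.D_e < 0:
            raise ValueError("diffusivities must be >= 0")
        if not 0.0 < self.f < 1.0:
            raise ValueError("f must lie in (0, 1)")
        if not 0.0 <= self.f_dot < 1.0:
            raise ValueError("f_dot must lie in [0, 1)")

    def to_array(self, with_dot: bool = True) -> np.ndarray:
        a = np.array([self.t_ex, self.D_i, self.D_e, self.f, self.f_dot])
        return a if with_dot else a[:4]

    @classmethod
    def from_array(cls, a) -> "TissueParameters":
        a = np.asarray(a, dtype=float)
        f_dot = float(a[4]) if a.size >= 5 else 0.0
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]), f_dot)

    def with_dot(self, f_dot: float) -> "TissueParameters":
        return replace(self, f_dot=f_dot)


@dataclass(frozen=True)
class NoiseModel:
    """Normalized Rician noise level ``σ = σ_signal / S_{b=0}``."""

    sigma: float

    def __post_init__(self):
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and > 0")

    @property
    def snr(self) -> float:
        return 1.0 / self.sigma

    @classmethod
    def from_snr(cls, snr: float) -> "NoiseModel":
        return cls(1.0 / snr)


class ModelVariant(Enum):
    """The four model variants: base model, dot extension, and their
    Rician-mean (RM) corrected versions."""

    NEXI = "nexi"
    NEXI_DOT = "nexi_dot"
    NEXI_RM = "nexi_rm"
    NEXI_DOT_RM = "nexi_dot_rm"

    @property
    def has_dot(self) -> bool:
        return self in (ModelVariant.NEXI_DOT, ModelVariant.NEXI_DOT_RM)

    @property
    def needs_sigma(self) -> bool:
        return self in (ModelVariant.NEXI_RM, ModelVariant.NEXI_DOT_RM)

    @property
    def n_free_params(self) -> int:
        return 5 if self.has_dot else 4

    @classmethod
    def parse(cls, name) -> "ModelVariant":
        if isinstance(name, cls):
            return name
        key = str(name).strip().lower().replace("-", "_").replace(",", "_")
        for v in cls:
            if v.value == key:
                return v
        raise ValueError(f"unknown model variant: {name!r}")


# ---------------------------------------------------------------------------
# Kärger kernel
# ---------------------------------------------------------------------------

def _validate_signal_inputs(b, t_d):
    b = np.asarray(b, dtype=float)
    t_d = np.asarray(t_d, dtype=float)
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(t_d))):
        raise ValueError("b and t_d must be finite")
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if np.any(t_d <= 0):
        raise ValueError("t_d must be > 0")
    return b, t_d


def _karger_closed_form(u2, b, t_d, t_ex, D_i, D_e, f):
    """Spherical-mean integrand: 1ᵀ·exp(−M t_d)·(f, 1−f)ᵀ for the 2×2
    exchange matrix, evaluated analytically.  Broadcasts over all inputs.

    M = [[q²·D_i·u² + k_ie, −k_ei], [−k_ie, q²·D_e + k_ei]] with
    k_ie = (1−f)/t_ex, k_ei = f/t_ex (detailed balance f·k_ie = (1−f)·k_ei).
    Uses exp(−M t) = e^{−T t/2}[cosh(s t)·I − sinh(s t)/s·(M − T/2·I)] with
    T = tr M, s² = (Δdiag/2)² + k_ie·k_ei, rewritten in terms of
    e^{−λ∓ t} to avoid overflow (both eigenvalues are ≥ 0).
    """
    q2 = b / t_d
    k_ie = (1.0 - f) / t_ex
    k_ei = f / t_ex
    a = q2 * D_i * u2 + k_ie
    d = q2 * D_e + k_ei
    half = 0.5 * (a + d)
    s = np.sqrt(0.25 * (a - d) ** 2 + k_ie * k_ei)
    lam_m = half - s
    lam_p = half + s
    e_m = np.exp(-lam_m * t_d)
    e_p = np.exp(-lam_p * t_d)
    # 1ᵀ (M − T/2 I) p0
    c = f * (a - k_ie) + (1.0 - f) * (d - k_ei) - half
    st = s * t_d
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(st > 1e-9, (e_m - e_p) / (2.0 * np.where(s > 0, s, 1.0)),
                         t_d * np.exp(-half * t_d))
    return 0.5 * (e_m + e_p) - c * ratio


def karger_compartment_signal(u, b, t_d, p: TissueParameters):
    """Directional signal of the anisotropic two-pool exchange (Kärger) kernel.

    Parameters
    ----------
    u : float or array
        Cosine of the angle between the gradient and the neurite axis, in [0, 1].
    b, t_d : float
        Diffusion weighting (ms/µm²) and diffusion time (ms); the wave
        vector follows the narrow-pulse convention q² = b / t_d.
    p : TissueParameters

    Returns
    -------
    float or ndarray in (0, 1]; ``f_dot`` is ignored at this layer.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)) or np.any(u < 0) or np.any(u > 1):
        raise ValueError("u must lie in [0, 1]")
    b, t_d = _validate_signal_inputs(b, t_d)
    out = _karger_closed_form(u * u, b, t_d, p.t_ex, p.D_i, p.D_e, p.f)
    return out if out.ndim else float(out)


@lru_cache(maxsize=8)
def _gauss_legendre_01(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    return 0.5 * (x + 1.0), 0.5 * w


def nexi_powder_signal(p: TissueParameters, b, t_d, quad_order: int = 64):
    """Spherical-mean (powder-average) signal S̄ = ∫₀¹ 𝒦(u) du.

    Fixed-order Gauss–Legendre quadrature on u ∈ [0, 1]; S̄(b=0) = 1 exactly
    because the quadrature weights sum to one.
    """
    if quad_order < 8:
        raise ValueError("quad_order must be >= 8")
    b, t_d = _validate_signal_inputs(b, t_d)
    nodes, weights = _gauss_legendre_01(quad_order)
    u2 = nodes * nodes
    vals = _karger_closed_form(
        u2, np.asarray(b)[..., None], np.asarray(t_d)[..., None],
        p.t_ex, p.D_i, p.D_e, p.f,
    )
    out = vals @ weights
    return out if np.ndim(out) else float(out)


def nexi_dot_powder_signal(p: TissueParameters, b, t_d, quad_order: int = 64):
    """Powder-average signal with a stationary dot compartment:
    (1 − f_dot)·S̄ + f_dot, which tends to f_dot as b → ∞."""
    if not 0.0 <= p.f_dot < 1.0:
        raise ValueError("f_dot must lie in [0, 1)")
    s = nexi_powder_signal(p, b, t_d, quad_order)
    return (1.0 - p.f_dot) * s + p.f_dot


# ---------------------------------------------------------------------------
# Rician mean
# ---------------------------------------------------------------------------

def laguerre_half(x):
    """Generalized Laguerre polynomial L_{1/2}(x) = ₁F₁(−1/2, 1, x).

    For x = −t ≤ 0 (the Rician-mean use case) the numerically stable
    Bessel form e^{−t/2}[(1+t)·I₀(t/2) + t·I₁(t/2)] is used with
    exponentially scaled Bessel functions, so arbitrarily large |x| does
    not overflow.  Positive arguments fall back to the hypergeometric
    series.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    t = np.where(x <= 0, -x, 0.0)
    h = 0.5 * t
    neg = (1.0 + t) * special.ive(0, h) + t * special.ive(1, h)
    if np.any(x > 0):
        pos = special.hyp1f1(-0.5, 1.0, np.where(x > 0, x, 0.0))
        out = np.where(x > 0, pos, neg)
    else:
        out = neg
    return out if out.ndim else float(out)


def rician_mean_transform(S, noise):
    """Expected magnitude of a Rician-distributed signal with true value S.

    E[|S + n₁ + i·n₂|] = √(π/2)·σ·L_{1/2}(−S²/(2σ²)) for n₁, n₂ ~ N(0, σ²).
    The output is ≥ max(S, √(π/2)·σ) and reduces to the identity for
    S ≫ σ; as S → 0 it converges to the Rician noise floor √(π/2)·σ.
    """
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)
    if not (math.isfinite(sigma) and sigma > 0):
        raise ValueError("sigma must be > 0")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be >= 0")
    snr = S / sigma
    floor = math.sqrt(math.pi / 2.0) * sigma
    out = np.where(snr < _RM_FLOOR_SNR, floor,
                   floor * laguerre_half(-0.5 * np.square(snr)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Batched / protocol-level prediction
# ---------------------------------------------------------------------------

def _powder_batch_numpy(params, b, t_d, nodes, weights):
    """(N, 5) parameter rows × (M,) shells → (N, M) powder signals.

    Accumulates over quadrature nodes to bound memory; reference path used
    when the compiled kernel is unavailable and as an internal cross-check.
    """
    t_ex = params[:, 0][:, None]
    D_i = params[:, 1][:, None]
    D_e = params[:, 2][:, None]
    f = params[:, 3][:, None]
    f_dot = params[:, 4][:, None]
    out = np.zeros((params.shape[0], b.size))
    for u, w in zip(nodes, weights):
        out += w * _karger_closed_form(u * u, b[None, :], t_d[None, :],
                                       t_ex, D_i, D_e, f)
    return (1.0 - f_dot) * out + f_dot


def _powder_jac_numpy(params, b, t_d, nodes, weights):
    """Reference implementation of the powder signal and its Jacobian with
    respect to (t_ex, D_i, D_e, f), for the exchanging compartments only
    (f_dot and the Rician-mean chain are applied by the caller).

    Returns (S, J) with S (N, M) and J (N, M, 4).  Differentiates the
    closed-form eigen solution: with x = (a−d)/2, s = √(x² + k_ie·k_ei),
    λ∓ = (a+d)/2 ∓ s and R = (E₋−E₊)/(2s),

        S = (E₋+E₊)/2 − C·R,   C = f·q²·D_i·u² + (1−f)·q²·D_e − (a+d)/2.
    """
    n = params.shape[0]
    m = b.size
    S = np.zeros((n, m))
    J = np.zeros((n, m, 4))
    t_ex = params[:, 0][:, None]
    D_i = params[:, 1][:, None]
    D_e = params[:, 2][:, None]
    f = params[:, 3][:, None]
    k_ie = (1.0 - f) / t_ex
    k_ei = f / t_ex
    cross = k_ie * k_ei
    q2 = (b / t_d)[None, :]
    td = t_d[None, :]
    for u, w in zip(nodes, weights):
        u2 = u * u
        a = q2 * D_i * u2 + k_ie
        d = q2 * D_e + k_ei
        T2 = 0.5 * (a + d)
        x = 0.5 * (a - d)
        s = np.sqrt(x * x + cross)
        e_m = np.exp(-(T2 - s) * td)
        e_p = np.exp(-(T2 + s) * td)
        C = f * q2 * D_i * u2 + (1.0 - f) * q2 * D_e - T2
        small = s * td < 1e-9
        s_safe = np.where(s > 0, s, 1.0)
        R = np.where(small, td * np.exp(-T2 * td), (e_m - e_p) / (2 * s_safe))
        S += w * (0.5 * (e_m + e_p) - C * R)
        # per-parameter differentials of (a, d, k_ie, k_ei)
        zeros = np.zeros_like(a)
        diffs = (
            # tex:  da,            dd,            dkie,          dkei
            (-k_ie / t_ex + zeros, -k_ei / t_ex + zeros,
             -k_ie / t_ex + zeros, -k_ei / t_ex + zeros,
             0.5 / (t_ex * t_ex) + zeros),                    # dC
            (q2 * u2 + zeros, zeros, zeros, zeros,
             (f - 0.5) * q2 * u2 + zeros),
            (zeros, q2 + zeros, zeros, zeros,
             (0.5 - f) * q2 + zeros),
            (-1.0 / t_ex + zeros, 1.0 / t_ex + zeros,
             -1.0 / t_ex + zeros, 1.0 / t_ex + zeros,
             q2 * (D_i * u2 - D_e) + zeros),
        )
        for j, (da, dd, dkie, dkei, dC) in enumerate(diffs):
            dT2 = 0.5 * (da + dd)
            dx = 0.5 * (da - dd)
            ds = (x * dx + 0.5 * (dkie * k_ei + k_ie * dkei)) / s_safe
            dEm = -td * e_m * (dT2 - ds)
            dEp = -td * e_p * (dT2 + ds)
            dR = np.where(small, -td * td * np.exp(-T2 * td) * dT2,
                          (dEm - dEp) / (2 * s_safe) - R * ds / s_safe)
            J[:, :, j] += w * (0.5 * (dEm + dEp) - dC * R - C * dR)
    return S, J


try:  # optional compiled kernels; identical math to the numpy versions
    from numba import njit

    @njit(cache=True)
    def _powder_batch_numba(params, b, t_d, nodes, weights):  # pragma: no cover
        n, m, k = params.shape[0], b.size, nodes.size
        out = np.empty((n, m))
        for i in range(n):
            t_ex, D_i, D_e, f, f_dot = (params[i, 0], params[i, 1],
                                        params[i, 2], params[i, 3],
                                        params[i, 4])
            k_ie = (1.0 - f) / t_ex
            k_ei = f / t_ex
            cross = k_ie * k_ei
            for j in range(m):
                q2 = b[j] / t_d[j]
                td = t_d[j]
                d = q2 * D_e + k_ei
                acc = 0.0
                for q in range(k):
                    u2 = nodes[q] * nodes[q]
                    a = q2 * D_i * u2 + k_ie
                    half = 0.5 * (a + d)
                    s = math.sqrt(0.25 * (a - d) ** 2 + cross)
                    e_m = math.exp(-(half - s) * td)
                    e_p = math.exp(-(half + s) * td)
                    c = f * (a - k_ie) + (1.0 - f) * (d - k_ei) - half
                    if s * td > 1e-9:
                        ratio = (e_m - e_p) / (2.0 * s)
                    else:
                        ratio = td * math.exp(-half * td)
                    acc += weights[q] * (0.5 * (e_m + e_p) - c * ratio)
                out[i, j] = (1.0 - f_dot) * acc + f_dot
        return out

    @njit(cache=True)
    def _powder_jac_numba(params, b, t_d, nodes, weights):  # pragma: no cover
        n, m, kq = params.shape[0], b.size, nodes.size
        S = np.zeros((n, m))
        J = np.zeros((n, m, 4))
        for i in range(n):
            t_ex, D_i, D_e, f = (params[i, 0], params[i, 1], params[i, 2],
                                 params[i, 3])
            k_ie = (1.0 - f) / t_ex
            k_ei = f / t_ex
            cross = k_ie * k_ei
            inv_tex = 1.0 / t_ex
            for j in range(m):
                q2 = b[j] / t_d[j]
                td = t_d[j]
                d = q2 * D_e + k_ei
                for q in range(kq):
                    u2 = nodes[q] * nodes[q]
                    w = weights[q]
                    a = q2 * D_i * u2 + k_ie
                    T2 = 0.5 * (a + d)
                    x = 0.5 * (a - d)
                    s = math.sqrt(x * x + cross)
                    e_m = math.exp(-(T2 - s) * td)
                    e_p = math.exp(-(T2 + s) * td)
                    C = f * q2 * D_i * u2 + (1.0 - f) * q2 * D_e - T2
                    small = s * td < 1e-9
                    s_safe = s if s > 0 else 1.0
                    if small:
                        R = td * math.exp(-T2 * td)
                    else:
                        R = (e_m - e_p) / (2.0 * s_safe)
                    S[i, j] += w * (0.5 * (e_m + e_p) - C * R)
                    for pidx in range(4):
                        if pidx == 0:      # t_ex
                            da = -k_ie * inv_tex
                            dd = -k_ei * inv_tex
                            dkie = da
                            dkei = dd
                            dC = 0.5 * inv_tex * inv_tex
                        elif pidx == 1:    # D_i
                            da = q2 * u2
                            dd = 0.0
                            dkie = 0.0
                            dkei = 0.0
                            dC = (f - 0.5) * q2 * u2
                        elif pidx == 2:    # D_e
                            da = 0.0
                            dd = q2
                            dkie = 0.0
                            dkei = 0.0
                            dC = (0.5 - f) * q2
                        else:              # f
                            da = -inv_tex
                            dd = inv_tex
                            dkie = -inv_tex
                            dkei = inv_tex
                            dC = q2 * (D_i * u2 - D_e)
                        dT2 = 0.5 * (da + dd)
                        dx = 0.5 * (da - dd)
                        ds = (x * dx + 0.5 * (dkie * k_ei + k_ie * dkei)
                              ) / s_safe
                        dEm = -td * e_m * (dT2 - ds)
                        dEp = -td * e_p * (dT2 + ds)
                        if small:
                            dR = -td * td * math.exp(-T2 * td) * dT2
                        else:
                            dR = (dEm - dEp) / (2.0 * s_safe) - R * ds / s_safe
                        J[i, j, pidx] += w * (0.5 * (dEm + dEp) - dC * R
                                              - C * dR)
        return S, J

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _powder_batch_numba = None
    _powder_jac_numba = None
    _HAVE_NUMBA = False


def predict_batch(params, b, t_d, sigma=None, quad_order: int = 64):
    """Vectorized forward model over many parameter sets.

    Parameters
    ----------
    params : (N, 5) array
        Rows [t_ex, D_i, D_e, f, f_dot]; f_dot = 0 gives the two-compartment
        model.
    b, t_d : (M,) arrays
        Shell table (paired b-value and diffusion time).
    sigma : float or None
        If given, the Rician-mean transform is applied to every entry.

    Returns
    -------
    (N, M) array of powder-average signals.
    """
    if quad_order < 8:
        raise ValueError("quad_order must be >= 8")
    params = np.ascontiguousarray(np.atleast_2d(params), dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    t_d = np.ascontiguousarray(t_d, dtype=float)
    nodes, weights = _gauss_legendre_01(quad_order)
    if _HAVE_NUMBA:
        out = _powder_batch_numba(params, b, t_d, nodes, weights)
    else:
        out = _powder_batch_numpy(params, b, t_d, nodes, weights)
    if sigma is not None:
        out = rician_mean_transform(out, sigma)
    return out


def _rician_mean_dS(S, sigma):
    """Derivative of the Rician-mean transform with respect to the
    noise-free signal: √(π/2)·S/(2σ)·[I₀+I₁](S²/(4σ²))·e^{−S²/(4σ²)},
    which tends to 1 for S ≫ σ and to 0 as S → 0."""
    S = np.asarray(S, dtype=float)
    h = 0.25 * np.square(S / sigma)
    return (math.sqrt(math.pi / 2.0) * S / (2.0 * sigma)
            * (special.ive(0, h) + special.ive(1, h)))


def predict_batch_with_jacobian(params, b, t_d, sigma=None,
                                quad_order: int = 64):
    """Powder signal and its analytic Jacobian over many parameter sets.

    Returns ``(S, J)`` with S of shape (N, M) and J of shape (N, M, 5),
    columns ordered (t_ex, D_i, D_e, f, f_dot).  The dot-compartment and
    Rician-mean chain rules are included when applicable; for f_dot = 0 the
    f_dot column is still the valid one-sided derivative.
    """
    if quad_order < 8:
        raise ValueError("quad_order must be >= 8")
    params = np.ascontiguousarray(np.atleast_2d(params), dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    t_d = np.ascontiguousarray(t_d, dtype=float)
    nodes, weights = _gauss_legendre_01(quad_order)
    if _HAVE_NUMBA:
        S, J4 = _powder_jac_numba(params, b, t_d, nodes, weights)
    else:
        S, J4 = _powder_jac_numpy(params, b, t_d, nodes, weights)
    f_dot = params[:, 4][:, None]
    out = (1.0 - f_dot) * S + f_dot
    J = np.empty(S.shape + (5,))
    J[:, :, :4] = (1.0 - f_dot[..., None]) * J4
    J[:, :, 4] = 1.0 - S
    if sigma is not None:
        scale = _rician_mean_dS(out, sigma)
        J *= scale[..., None]
        out = rician_mean_transform(out, sigma)
    return out, J


def model_predict(variant, p: TissueParameters, protocol, noise=None,
                  quad_order: int = 64):
    """Predicted powder-average signal vector over a protocol's nonzero
    (b, Δ) shells, ordered by (Δ ascending, b ascending).

    RM variants require ``noise``; non-RM variants ignore it.  Dot variants
    use ``p.f_dot``; two-compartment variants ignore it.
    """
    variant = ModelVariant.parse(variant)
    if variant.needs_sigma and noise is None:
        raise ValueError(f"{variant.value} requires a NoiseModel (sigma)")
    b, t_d = protocol.shell_table()
    row = p.to_array()
    if not variant.has_dot:
        row = row.copy()
        row[4] = 0.0
    sigma = None
    if variant.needs_sigma:
        sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)
    return predict_batch(row[None, :], b, t_d, sigma=sigma,
                         quad_order=quad_order)[0]


# ---------------------------------------------------------------------------
# Validity of the barrier-limited regime
# ---------------------------------------------------------------------------

def exchange_validity_times(d: float, p: TissueParameters,
                            extra_neurite_form: str = "pi_over_f"):
    """Characteristic times to reach the long-time diffusion limit in each
    compartment, for neurites of diameter ``d`` (µm).

    The barrier-limited (Kärger) description is valid when both are much
    shorter than ``t_ex``.  The intra-neurite time is t_c,i = d²/(2·D_i).
    For the extra-neurite time two conventions are exposed:

    * ``"pi_over_f"`` (default): t_c,e = d²/(2·D_e) · π/f — the form that
      reproduces the ≈7.5 ms order of magnitude quoted for cortical tissue
      (d ≈ 1 µm, D_e ≈ 0.7 µm²/ms, f ≈ 0.3);
    * ``"inverse"``: t_c,e = d²/(2·D_e·π·f).

    Returns ``(t_c_intra, t_c_extra)`` in ms.
    """
    if d <= 0:
        raise ValueError("diameter must be > 0")
    if p.D_i <= 0 or p.D_e <= 0:
        raise ValueError("diffusivities must be > 0 for validity times")
    if not p.f > 0:
        raise ValueError("f must be > 0")
    t_ci = d * d / (2.0 * p.D_i)
    base = d * d / (2.0 * p.D_e)
    if extra_neurite_form == "pi_over_f":
        t_ce = base * math.pi / p.f
    elif extra_neurite_form == "inverse":
        t_ce = base / (math.pi * p.f)
    else:
        raise ValueError("extra_neurite_form must be 'pi_over_f' or 'inverse'")
    return t_ci, t_ce
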