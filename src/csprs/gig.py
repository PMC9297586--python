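"""Generalized inverse Gaussian random variates.

The GIG(λ, ρ, χ) distribution has density

    f(x) ∝ x^{λ-1} exp(-(ρ x + χ / x) / 2),   x > 0,

with ρ > 0 and χ ≥ 0 (χ = 0 requires λ > 0, where the density reduces to a
Gamma(λ, rate ρ/2)).  It is the conditional distribution of the local
shrinkage scales in the global-local continuous-shrinkage prior, so the
sampler below sits on the hot path of the Gibbs sweep and is fully
vectorized: all parameters may be arrays, and rejection is carried out
lane-wise with boolean masks until every lane has accepted.

The construction is Devroye's uniformly-fast rejection scheme for the
two-parameter gig(λ, ω) family (ω = sqrt(ρχ)): the log-density on the
log scale, ψ(x) = -α(cosh x - 1) - λ(e^x - x - 1), is enveloped by a flat
center piece and two exponential tails, giving a bounded number of
proposals per draw for every parameter value.
"""

from __future__ import annotations

import numpy as np

from .errors import NumericalError

__all__ = ["sample_gig"]


def _psi(x, alpha, lam):
    return -alpha * (np.cosh(x) - 1.0) - lam * (np.expm1(x) - x)


def _dpsi(x, alpha, lam):
    return -alpha * np.sinh(x) - lam * np.expm1(x)


def _devroye_gig(lam: np.ndarray, omega: np.ndarray, rng) -> np.ndarray:
    """Vectorized draw from the two-parameter gig(λ, ω), λ ≥ 0, ω > 0.

    Density on x > 0: ∝ x^{λ-1} exp(-ω (x + 1/x) / 2).  Returns one draw
    per lane of the broadcast shape of (lam, omega).
    """
    alpha = np.sqrt(omega * omega + lam * lam) - lam  # > 0 whenever ω > 0

    # Envelope geometry: find t > 0 and s > 0 with ψ(t) = ψ(-s) ≈ -1..-2.
    with np.errstate(divide="ignore", over="ignore"):
        x0 = -_psi(1.0, alpha, lam)
        t = np.where(
            (x0 >= 0.5) & (x0 <= 2.0),
            1.0,
            np.where(
                x0 > 2.0,
                np.sqrt(2.0 / (alpha + lam)),
                np.log(4.0 / (alpha + 2.0 * lam)),
            ),
        )

        x1 = -_psi(-1.0, alpha, lam)
        # 1/λ lanes with λ = 0 give inf, which min() then discards.
        inv_lam = np.where(lam > 0, 1.0 / np.where(lam > 0, lam, 1.0), np.inf)
        s_small = np.minimum(
            inv_lam,
            np.log1p(1.0 / alpha + np.sqrt(1.0 / (alpha * alpha) + 2.0 / alpha)),
        )
        s = np.where(
            (x1 >= 0.5) & (x1 <= 2.0),
            1.0,
            np.where(
                x1 > 2.0,
                np.sqrt(4.0 / (alpha * np.cosh(1.0) + lam)),
                s_small,
            ),
        )

    eta = -_psi(t, alpha, lam)
    zeta = -_dpsi(t, alpha, lam)
    theta = -_psi(-s, alpha, lam)
    xi = _dpsi(-s, alpha, lam)

    p = 1.0 / xi
    r = 1.0 / zeta
    td = t - r * eta
    sd = s - p * theta
    q = td + sd
    tot = p + q + r

    out = np.empty(np.broadcast(lam, omega).shape, dtype=float)
    active = np.ones(out.shape, dtype=bool)
    # Devroye's envelope has uniformly bounded rejection probability, so a
    # handful of sweeps clears all lanes; the cap only guards against NaNs.
    for _ in range(200):
        idx = np.flatnonzero(active.ravel())
        if idx.size == 0:
            break
        m = active
        u = rng.random(idx.size)
        v = rng.random(idx.size)
        w = rng.random(idx.size)

        q_m, td_m, sd_m = q[m], td[m], sd[m]
        p_m, r_m, tot_m = p[m], r[m], tot[m]
        t_m, s_m = t[m], s[m]
        eta_m, zeta_m, theta_m, xi_m = eta[m], zeta[m], theta[m], xi[m]
        al_m, lam_m = alpha[m], lam[m]

        logv = np.log(v)
        cand = np.where(
            u < q_m / tot_m,
            -sd_m + q_m * v,
            np.where(u < (q_m + r_m) / tot_m, td_m - r_m * logv, -sd_m + p_m * logv),
        )
        with np.errstate(over="ignore"):
            f1 = np.exp(-eta_m - zeta_m * (cand - t_m))
            f2 = np.exp(-theta_m + xi_m * (cand + s_m))
            g = np.where(
                (cand >= -sd_m) & (cand <= td_m),
                1.0,
                np.where(cand > td_m, f1, f2),
            )
            acc = w * g <= np.exp(_psi(cand, al_m, lam_m))
        if np.any(acc):
            flat = out.ravel()
            flat[idx[acc]] = cand[acc]
            act = active.ravel()
            act[idx[acc]] = False
    else:
        raise NumericalError("GIG rejection sampler failed to accept; check parameters")

    # Back-transform from log scale of the symmetric standardized variable.
    ratio = lam / omega
    return np.exp(out) * (ratio + np.sqrt(1.0 + ratio * ratio))


def sample_gig(lam, rho, chi, rng, size=None):
    """Draw from GIG(λ, ρ, χ) with density ∝ x^{λ-1} exp(-(ρx + χ/x)/2).

    Parameters
    ----------
    lam, rho, chi
        Scalars or broadcastable arrays.  Requires ρ > 0 and χ ≥ 0; lanes
        with χ = 0 require λ > 0 and reduce to Gamma(λ, rate ρ/2).
    rng
        A `numpy.random.Generator`.
    size
        Optional output shape when all parameters are scalar.

    Returns
    -------
    float or ndarray of positive draws, scalar when all inputs are scalar
    and ``size`` is None.
    """
    lam = np.asarray(lam, dtype=float)
    rho = np.asarray(rho, dtype=float)
    chi = np.asarray(chi, dtype=float)
    scalar_in = lam.ndim == 0 and rho.ndim == 0 and chi.ndim == 0 and size is None

    shape = np.broadcast(lam, rho, chi).shape
    if size is not None:
        shape = (size,) if np.isscalar(size) else tuple(size)
    lam = np.broadcast_to(lam, shape).astype(float, copy=True)
    rho = np.broadcast_to(rho, shape)
    chi = np.broadcast_to(chi, shape)

    if np.any(rho <= 0):
        raise NumericalError("GIG parameter rho must be > 0")
    if np.any(chi < 0):
        raise NumericalError("GIG parameter chi must be >= 0")
    gamma_limit = chi == 0
    if np.any(gamma_limit & (lam <= 0)):
        raise NumericalError("GIG with chi = 0 requires lam > 0 (Gamma limit)")

    out = np.empty(shape, dtype=float)

    if np.any(gamma_limit):
        out[gamma_limit] = rng.gamma(lam[gamma_limit], 2.0 / rho[gamma_limit])

    gen = ~gamma_limit
    if np.any(gen):
        lam_g = lam[gen]
        omega = np.sqrt(rho[gen] * chi[gen])
        swap = lam_g < 0
        lam_abs = np.abs(lam_g)
        draw = _devroye_gig(lam_abs, omega, rng)
        draw = np.where(swap, 1.0 / draw, draw)
        out[gen] = draw * np.sqrt(chi[gen] / rho[gen])

    if scalar_in:
        return float(out)
    return out
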