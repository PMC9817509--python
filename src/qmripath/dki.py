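"""Voxel-wise diffusion-kurtosis imaging (DKI) model fitting.

The trace-weighted DKI signal at diffusion weighting ``b`` (s/mm^2) is

    S(b) = S0 * exp(-b*D + b^2 * D^2 * K / 6)

where ``D`` (mm^2/s) is the diffusion coefficient corrected for
non-Gaussian diffusion and ``K`` (unitless) is the diffusional kurtosis.
Fitting is a bound-constrained nonlinear least-squares problem solved on
the linear signal scale with several randomly drawn starting points per
voxel; the lowest-residual solution is kept.  Solutions that fail to
converge are flagged invalid and reported as NaN so that they drop out of
any downstream statistics.

The fitter is vectorised: a whole array of voxels (and all their random
starts) is advanced together through a damped Gauss-Newton
(Levenberg-Marquardt) iteration with box projection, which keeps map-level
fitting fast without changing the per-voxel problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

D_BOUNDS_DEFAULT = (0.3e-3, 3.0e-3)  # mm^2/s
K_BOUNDS_DEFAULT = (0.0, 3.0)


@dataclass(frozen=True)
class FitSettings:
    """Configuration of the constrained multi-start DKI fit.

    Parameters
    ----------
    d_bounds, k_bounds:
        Physiological box constraints on D (mm^2/s) and K.
    n_starts:
        Number of random (D, K) starting points per voxel.
    seed:
        Seed of the RNG stream that draws the starting points.
    tolerance:
        Relative step-size threshold declaring convergence.
    max_iter:
        Iteration cap of the damped Gauss-Newton loop.
    s0_mode:
        ``"fit"`` fits S0 as a third (positive) free parameter;
        ``"fixed"`` pins S0 to the measured b=0 signal.
    """

    d_bounds: tuple[float, float] = D_BOUNDS_DEFAULT
    k_bounds: tuple[float, float] = K_BOUNDS_DEFAULT
    n_starts: int = 10
    seed: int = 0
    tolerance: float = 1e-10
    max_iter: int = 200
    s0_mode: str = "fit"

    def __post_init__(self) -> None:
        if not self.d_bounds[0] < self.d_bounds[1]:
            raise ValueError("d_bounds must be ordered (lo < hi)")
        if not self.k_bounds[0] < self.k_bounds[1]:
            raise ValueError("k_bounds must be ordered (lo < hi)")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.s0_mode not in ("fit", "fixed"):
            raise ValueError("s0_mode must be 'fit' or 'fixed'")


@dataclass
class DKIParams:
    """Per-voxel DKI solution.

    ``d`` and ``k`` are NaN whenever ``valid`` is False; ``reason`` then
    carries a short diagnostic.
    """

    s0: float
    d: float
    k: float
    sse: float
    valid: bool
    reason: str = ""


def dki_signal(s0, d, k, b):
    """Evaluate the DKI signal model S0*exp(-b*D + b^2*D^2*K/6).

    All arguments broadcast; ``b`` in s/mm^2, ``d`` in mm^2/s.
    """
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-b * d + b * b * d * d * k / 6.0)


# ---------------------------------------------------------------------------
# batched constrained Levenberg-Marquardt core
# ---------------------------------------------------------------------------

def _lm_fit_batch(y_n, bm, theta0, lo, hi, tol, max_iter):
    """Damped Gauss-Newton with box projection, vectorised over items.

    Parameters are theta = (a, dm, k) with a = S0/S0_ref and dm = D*1e3,
    which keeps every free parameter of order one.  ``y_n`` is (M, B)
    normalised signal, ``bm`` is b*1e-3 so that bm*dm == b*d.
    Returns (theta, sse, converged).
    """
    m = y_n.shape[0]
    theta = theta0.copy()
    lam = np.full(m, 1e-3)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    bound_eps = 1e-10

    def model_and_jac(th):
        a, dm, k = th[:, 0:1], th[:, 1:2], th[:, 2:3]
        e = np.exp(-bm * dm + bm * bm * dm * dm * k / 6.0)
        f = a * e
        j = np.empty(th.shape[:1] + bm.shape[1:] + (3,))
        j[..., 0] = e
        j[..., 1] = f * (-bm + bm * bm * dm * k / 3.0)
        j[..., 2] = f * (bm * bm * dm * dm / 6.0)
        return f, j

    f, jac = model_and_jac(theta)
    r = f - y_n
    sse = np.einsum("mb,mb->m", r, r)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        j = jac[idx].copy()
        ri = r[idx]
        th = theta[idx]
        g_full = np.einsum("mbi,mb->mi", j, ri)
        # active-set handling: parameters pinned at a bound whose descent
        # direction points outside are frozen out of the LM subproblem
        blocked = ((th <= lo + bound_eps) & (g_full > 0)) | \
                  ((th >= hi - bound_eps) & (g_full < 0))
        j[np.broadcast_to(blocked[:, None, :], j.shape)] = 0.0
        g = np.einsum("mbi,mb->mi", j, ri)

        # projected-gradient stop: at a constrained optimum the free-space
        # gradient vanishes
        flat = np.abs(g).max(axis=1) < 1e-11 * (1.0 + sse[idx])
        converged[idx[flat]] = True
        active[idx[flat]] = False
        if flat.all():
            continue

        a_mat = np.einsum("mbi,mbj->mij", j, j)
        diag = np.einsum("mii->mi", a_mat).copy()
        diag[diag < 1e-12] = 1e-12
        a_damp = a_mat + lam[idx, None, None] * diag[:, None, :] * np.eye(3)
        delta = np.linalg.solve(a_damp, -g[..., None])[..., 0]
        trial = np.clip(theta[idx] + delta, lo, hi)
        f_t, jac_t = model_and_jac(trial)
        r_t = f_t - y_n[idx]
        sse_t = np.einsum("mb,mb->m", r_t, r_t)
        better = (sse_t <= sse[idx]) & ~flat

        acc = idx[better]
        step = np.abs(trial[better] - theta[acc])
        theta[acc] = trial[better]
        sse[acc] = sse_t[better]
        r[acc] = r_t[better]
        jac[acc] = jac_t[better]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-14)
        done = step.max(axis=1) < tol * (1.0 + np.abs(theta[acc]).max(axis=1))
        converged[acc[done]] = True
        active[acc[done]] = False

        rej = idx[~better & ~flat]
        lam[rej] *= 4.0
        stuck = lam[rej] > 1e12
        converged[rej[stuck]] = True  # no descent direction left
        active[rej[stuck]] = False

    return theta, sse, converged


def _fit_dki_batch(signals, b_values, settings):
    """Fit many voxels at once.  ``signals`` is (N, B) on the raw scale.

    Returns arrays (s0, d, k, sse, valid) of length N.  Input screening
    (positivity, finiteness) must have been done by the caller.
    """
    n, nb = signals.shape
    bm = np.asarray(b_values, dtype=float)[None, :] * 1e-3
    s0_ref = signals[:, 0:1]
    y_n = signals / s0_ref

    dlo, dhi = settings.d_bounds[0] * 1e3, settings.d_bounds[1] * 1e3
    klo, khi = settings.k_bounds
    rng = np.random.default_rng(settings.seed)
    ns = settings.n_starts
    d0 = rng.uniform(dlo, dhi, size=(ns, n))
    k0 = rng.uniform(klo, khi, size=(ns, n))

    if settings.s0_mode == "fixed":
        a_lo = a_hi = 1.0
    else:
        a_lo, a_hi = 1e-6, 1e6
    lo = np.array([a_lo, dlo, klo])
    hi = np.array([a_hi, dhi, khi])

    theta0 = np.empty((ns * n, 3))
    theta0[:, 0] = 1.0
    theta0[:, 1] = d0.ravel()
    theta0[:, 2] = k0.ravel()
    y_rep = np.broadcast_to(y_n, (ns, n, nb)).reshape(ns * n, nb)
    bm_rep = np.broadcast_to(bm, (1, nb))

    theta, sse, conv = _lm_fit_batch(
        y_rep, bm_rep, theta0, lo, hi, settings.tolerance, settings.max_iter
    )
    theta = theta.reshape(ns, n, 3)
    sse = sse.reshape(ns, n)
    conv = conv.reshape(ns, n)

    # best converged start per voxel; first-found wins on exact ties
    sse_masked = np.where(conv, sse, np.inf)
    best = np.argmin(sse_masked, axis=0)
    pick = theta[best, np.arange(n)]
    sse_best = sse_masked[best, np.arange(n)]
    valid = np.isfinite(sse_best)

    s0 = pick[:, 0] * s0_ref[:, 0]
    d = pick[:, 1] * 1e-3
    k = pick[:, 2]
    sse_out = np.where(valid, sse_best * s0_ref[:, 0] ** 2, np.nan)
    d[~valid] = np.nan
    k[~valid] = np.nan
    s0[~valid] = np.nan
    return s0, d, k, sse_out, valid


def _screen_voxel(signal, b_values):
    """Return a rejection reason for a single voxel, or an empty string."""
    signal = np.asarray(signal, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if signal.shape != b.shape:
        return "signal/b-value length mismatch"
    if b.size < 4 or b[0] != 0.0:
        return "need >=4 b-values including b=0"
    if not np.all(np.isfinite(signal)):
        return "non-finite signal"
    if signal[0] <= 0:
        return "nonpositive b=0 signal"
    if np.any(signal <= 0):
        return "nonpositive signal value"
    return ""


def fit_dki_voxel(signal, b_values, settings: FitSettings | None = None) -> DKIParams:
    """Constrained multi-start fit of the DKI model to one voxel.

    Returns :class:`DKIParams`; degenerate inputs and non-convergent fits
    give an invalid result (``d``/``k`` NaN) with a diagnostic ``reason``
    instead of raising, mirroring how map-level fitting discards voxels.
    """
    settings = settings or FitSettings()
    reason = _screen_voxel(signal, b_values)
    if reason:
        return DKIParams(np.nan, np.nan, np.nan, np.nan, False, reason)
    sig = np.asarray(signal, dtype=float)[None, :]
    s0, d, k, sse, valid = _fit_dki_batch(sig, b_values, settings)
    if not valid[0]:
        return DKIParams(np.nan, np.nan, np.nan, np.nan, False, "did not converge")
    return DKIParams(float(s0[0]), float(d[0]), float(k[0]), float(sse[0]), True)


def fit_dki_map(dwi, mask, b_values, settings: FitSettings | None = None):
    """Voxel-wise DKI fit over a 4D volume restricted to ``mask``.

    Parameters
    ----------
    dwi:
        4D array (x, y, z, b).
    mask:
        Boolean 3D array; voxels outside it are left NaN.

    Returns
    -------
    dict with ``d``, ``k``, ``s0``, ``sse`` 3D maps (NaN outside the mask
    and on invalid voxels), a boolean ``valid`` map, and counts
    ``n_valid`` / ``n_invalid``.
    """
    settings = settings or FitSettings()
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, b)")
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask shape does not match dwi volume")
    b = np.asarray(b_values, dtype=float)
    if dwi.shape[3] != b.size:
        raise ValueError("number of volumes does not match b_values")

    shape = mask.shape
    out = {key: np.full(shape, np.nan) for key in ("s0", "d", "k", "sse")}
    valid_map = np.zeros(shape, dtype=bool)
    n_masked = int(mask.sum())
    if n_masked == 0:
        warnings.warn("empty mask: no voxels fitted", stacklevel=2)
        return {**out, "valid": valid_map, "n_valid": 0, "n_invalid": 0}

    sig = dwi[mask]
    ok = (
        np.all(np.isfinite(sig), axis=1)
        & (sig[:, 0] > 0)
        & np.all(sig > 0, axis=1)
    )
    res = {key: np.full(n_masked, np.nan) for key in ("s0", "d", "k", "sse")}
    valid = np.zeros(n_masked, dtype=bool)
    if ok.any():
        s0, d, k, sse, v = _fit_dki_batch(sig[ok], b, settings)
        for key, arr in zip(("s0", "d", "k", "sse"), (s0, d, k, sse)):
            res[key][ok] = arr
        valid[ok] = v
    for key in res:
        out[key][mask] = res[key]
    valid_map[mask] = valid
    return {
        **out,
        "valid": valid_map,
        "n_valid": int(valid.sum()),
        "n_invalid": int(n_masked - valid.sum()),
    }
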