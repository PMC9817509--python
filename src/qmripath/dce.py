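"""Two-compartment (standard Tofts) pharmacokinetic DCE-MRI quantification.

Tissue contrast-agent concentration follows the Tofts convolution

    Ct(t) = Ktrans * integral_0^t Cp(tau) * exp(-kep * (t - tau)) dtau

with ``Ktrans`` (min^-1) the plasma-to-EES transfer constant, ``kep``
(min^-1) the back-transfer constant and ``ve = Ktrans / kep`` the
fractional extravascular-extracellular volume.  ``Cp`` is the arterial
input function (AIF); by default the Parker population AIF is used.

The convolution is evaluated with the exponential recursion that is exact
for a piecewise-linear Cp, so the 5 s sampling of the acquisition is
handled without quadrature error beyond the linear-interpolation one.
Fitting exploits the linearity of the model in Ktrans: for every
candidate kep the optimal Ktrans has a closed form, reducing the
constrained least-squares problem to a one-dimensional search over kep
(coarse grid followed by a golden-section refinement in log kep).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

KTRANS_BOUNDS_DEFAULT = (0.0, 10.0)  # min^-1
KEP_BOUNDS_DEFAULT = (0.01, 20.0)  # min^-1

# Parker population AIF constants (mixture of two Gaussians plus a
# sigmoid-modulated exponential washout); whole-blood scale, mM and min.
_PARKER = dict(
    a1=0.809, a2=0.330,
    t1=0.17046, t2=0.365,
    s1=0.0563, s2=0.132,
    alpha=1.050, beta=0.1685,
    s=38.078, tau=0.483,
)


@dataclass(frozen=True)
class AIF:
    """Arterial input function sampled on the acquisition time grid.

    ``time`` in minutes starting at 0 and strictly increasing; ``cp`` the
    plasma concentration in mM, zero before bolus arrival.
    """

    time: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        if t.size == 0:
            raise ValueError("empty AIF time grid")
        if t.size != c.size:
            raise ValueError("time and cp must have the same length")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be nonnegative and strictly increasing")
        if np.any(c < 0):
            raise ValueError("cp must be nonnegative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "cp", c)


def population_aif(time_min, arrival_min: float = 0.0, hematocrit: float = 0.42) -> AIF:
    """Parker population AIF on ``time_min`` with the bolus arriving at
    ``arrival_min``; blood concentration is converted to plasma by
    dividing by (1 - hematocrit).
    """
    t = np.asarray(time_min, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    ts = t - arrival_min
    p = _PARKER
    cb = np.zeros_like(ts)
    pos = ts > 0
    u = ts[pos]
    for a, mu, sig in ((p["a1"], p["t1"], p["s1"]), (p["a2"], p["t2"], p["s2"])):
        cb[pos] += a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((u - mu) ** 2) / (2 * sig**2))
    cb[pos] += p["alpha"] * np.exp(-p["beta"] * u) / (1 + np.exp(-p["s"] * (u - p["tau"])))
    return AIF(time=t, cp=cb / (1.0 - hematocrit))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _tofts_batch(ktrans, kep, time, cp):
    """Tofts curves for arrays of (ktrans, kep); returns (N, T).

    Exponential recursion, exact for piecewise-linear Cp:
    with E = exp(-kep*dt) on each interval,
    Ct[i+1] = Ct[i]*E + Ktrans * int_{t_i}^{t_{i+1}} Cp(tau) e^{-kep (t_{i+1}-tau)} dtau.
    """
    ktrans = np.atleast_1d(np.asarray(ktrans, dtype=float))
    kep = np.atleast_1d(np.asarray(kep, dtype=float))
    if np.any(kep <= 0):
        raise ValueError("kep must be positive")
    if np.any(ktrans < 0):
        raise ValueError("ktrans must be nonnegative")
    t = np.asarray(time, dtype=float)
    cp = np.asarray(cp, dtype=float)
    n, nt = ktrans.size, t.size
    ct = np.zeros((n, nt))
    for i in range(nt - 1):
        dt = t[i + 1] - t[i]
        e = np.exp(-kep * dt)
        m = (cp[i + 1] - cp[i]) / dt
        integ = cp[i + 1] * (1 - e) / kep - m * (1 - (1 + kep * dt) * e) / kep**2
        ct[:, i + 1] = ct[:, i] * e + ktrans * integ
    return ct


def tofts_concentration(ktrans: float, kep: float, aif: AIF, time=None):
    """Tissue concentration curve for one (ktrans, kep) pair.

    ``time`` defaults to the AIF grid and must equal it otherwise.
    """
    if time is not None and not np.array_equal(np.asarray(time, float), aif.time):
        raise ValueError("time grid must match the AIF sampling")
    return _tofts_batch(ktrans, kep, aif.time, aif.cp)[0]


# ---------------------------------------------------------------------------
# signal <-> concentration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConversionSettings:
    """Signal-to-concentration conversion.

    ``mode="linear"``: Ct = (S/S_pre - 1) / calibration, with
    ``calibration`` the relative enhancement per mM.
    ``mode="spgr"``: inversion of the spoiled-gradient-echo signal
    equation using ``t10`` (s), ``r1`` (s^-1 mM^-1), ``tr`` (s) and
    ``flip_deg``; defaults follow a 4.7 ms TR, 30 degree acquisition.
    """

    mode: str = "linear"
    calibration: float = 1.0
    t10: float = 1.0
    r1: float = 3.7
    tr: float = 4.7e-3
    flip_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "spgr"):
            raise ValueError("mode must be 'linear' or 'spgr'")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")


def _spgr_signal(conc, m0_sin, settings):
    e1 = np.exp(-settings.tr * (1.0 / settings.t10 + settings.r1 * conc))
    cosa = np.cos(np.deg2rad(settings.flip_deg))
    return m0_sin * (1 - e1) / (1 - cosa * e1)


def signal_to_concentration(signal, baseline_count: int, settings: ConversionSettings | None = None):
    """Convert a DCE signal series to concentration (mM).

    ``signal`` has time on the last axis; the first ``baseline_count``
    frames are averaged into the pre-contrast level.  Voxels with a
    nonpositive baseline mean come back as all-NaN curves.
    """
    settings = settings or ConversionSettings()
    if baseline_count < 1:
        raise ValueError("baseline_count must be >= 1")
    s = np.asarray(signal, dtype=float)
    base = s[..., :baseline_count].mean(axis=-1, keepdims=True)
    bad = ~(base > 0)

    safe_base = np.where(bad, 1.0, base)
    if settings.mode == "linear":
        conc = (s / safe_base - 1.0) / settings.calibration
    else:
        cosa = np.cos(np.deg2rad(settings.flip_deg))
        e10 = np.exp(-settings.tr / settings.t10)
        m0_sin = safe_base * (1 - cosa * e10) / (1 - e10)
        ratio = np.clip(s / m0_sin, 1e-12, (1 - 1e-12) / (1 - cosa * 1e-12))
        e1 = np.clip((1 - ratio) / (1 - ratio * cosa), 1e-12, 1 - 1e-12)
        r1_t = -np.log(e1) / settings.tr
        conc = (r1_t - 1.0 / settings.t10) / settings.r1
    return np.where(bad, np.nan, conc)


def concentration_to_signal(conc, s_pre, settings: ConversionSettings | None = None):
    """Forward counterpart of :func:`signal_to_concentration`."""
    settings = settings or ConversionSettings()
    c = np.asarray(conc, dtype=float)
    if settings.mode == "linear":
        return s_pre * (1.0 + settings.calibration * c)
    cosa = np.cos(np.deg2rad(settings.flip_deg))
    e10 = np.exp(-settings.tr / settings.t10)
    m0_sin = s_pre * (1 - cosa * e10) / (1 - e10)
    return _spgr_signal(c, m0_sin, settings)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKFitSettings:
    ktrans_bounds: tuple[float, float] = KTRANS_BOUNDS_DEFAULT
    kep_bounds: tuple[float, float] = KEP_BOUNDS_DEFAULT
    grid_size: int = 64
    refine_iters: int = 60
    clip_ve: bool = False  # compatibility option: clip ve to 1 instead of invalidating

    def __post_init__(self) -> None:
        if not 0 <= self.ktrans_bounds[0] < self.ktrans_bounds[1]:
            raise ValueError("ktrans_bounds must be ordered and nonnegative")
        if not 0 < self.kep_bounds[0] < self.kep_bounds[1]:
            raise ValueError("kep_bounds must be ordered and positive")


@dataclass
class PKParams:
    """Per-voxel Tofts solution; ``ve = ktrans / kep`` by construction."""

    ktrans: float
    kep: float
    ve: float
    sse: float
    valid: bool
    reason: str = ""


def _varpro_eval(kep, y, time, cp, kt_lo, kt_hi):
    """Optimal ktrans and SSE at given per-voxel kep values.

    ``y`` is (N, T), ``kep`` is (N,).  Returns (ktrans, sse).
    """
    c = _tofts_batch(np.ones_like(kep), kep, time, cp)
    num = np.einsum("nt,nt->n", y, c)
    den = np.einsum("nt,nt->n", c, c)
    kt = np.clip(num / np.maximum(den, 1e-300), kt_lo, kt_hi)
    resid = y - kt[:, None] * c
    return kt, np.einsum("nt,nt->n", resid, resid)


def _fit_tofts_batch(y, time, cp, settings):
    """VARPRO fit over (ktrans, kep) for (N, T) concentration curves."""
    n = y.shape[0]
    kt_lo, kt_hi = settings.ktrans_bounds
    kep_lo, kep_hi = settings.kep_bounds
    grid = np.geomspace(kep_lo, kep_hi, settings.grid_size)

    # coarse stage: unit curves shared across voxels
    c_grid = _tofts_batch(np.ones_like(grid), grid, time, cp)  # (G, T)
    num = y @ c_grid.T  # (N, G)
    den = np.einsum("gt,gt->g", c_grid, c_grid)
    kt = np.clip(num / den[None, :], kt_lo, kt_hi)
    y2 = np.einsum("nt,nt->n", y, y)
    sse = y2[:, None] - 2 * kt * num + kt**2 * den[None, :]
    best = np.argmin(sse, axis=1)

    # golden-section refinement in log(kep) on the bracketing cells
    lg = np.log(grid)
    lo = lg[np.maximum(best - 1, 0)]
    hi = lg[np.minimum(best + 1, grid.size - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - phi * (hi - lo)
    x2 = lo + phi * (hi - lo)
    _, f1 = _varpro_eval(np.exp(x1), y, time, cp, kt_lo, kt_hi)
    _, f2 = _varpro_eval(np.exp(x2), y, time, cp, kt_lo, kt_hi)
    for _ in range(settings.refine_iters):
        left = f1 < f2  # minimum bracketed in [lo, x2]
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
        x1_new = np.where(left, hi - phi * (hi - lo), x2)
        x2_new = np.where(left, x1, lo + phi * (hi - lo))
        x_eval = np.where(left, x1_new, x2_new)
        _, f_eval = _varpro_eval(np.exp(x_eval), y, time, cp, kt_lo, kt_hi)
        f1, f2 = np.where(left, f_eval, f2), np.where(left, f1, f_eval)
        x1, x2 = x1_new, x2_new

    kep = np.exp((lo + hi) / 2.0)
    ktrans, sse_fin = _varpro_eval(kep, y, time, cp, kt_lo, kt_hi)
    return ktrans, kep, sse_fin


def fit_tofts_voxel(conc, aif: AIF, settings: PKFitSettings | None = None) -> PKParams:
    """Constrained least-squares Tofts fit to one concentration curve."""
    settings = settings or PKFitSettings()
    y = np.asarray(conc, dtype=float)
    if y.shape != aif.time.shape:
        raise ValueError("curve and AIF must share the same time grid")
    if not np.all(np.isfinite(y)):
        return PKParams(np.nan, np.nan, np.nan, np.nan, False, "non-finite curve")
    if np.allclose(y, 0.0):
        return PKParams(0.0, np.nan, np.nan, float(np.sum(y**2)), True, "no enhancement")
    kt, kep, sse = _fit_tofts_batch(y[None, :], aif.time, aif.cp, settings)
    return _finalize_pk(float(kt[0]), float(kep[0]), float(sse[0]), settings)


def _finalize_pk(kt, kep, sse, settings) -> PKParams:
    ve = kt / kep
    if ve > 1.0:
        if settings.clip_ve:
            ve = 1.0
        else:
            return PKParams(np.nan, np.nan, np.nan, sse, False, "ve > 1")
    if ve <= 0.0:
        return PKParams(kt, kep, ve, sse, True, "no enhancement")
    return PKParams(kt, kep, ve, sse, True)


def fit_tofts_map(dce, mask, aif: AIF, settings: PKFitSettings | None = None,
                  conversion: ConversionSettings | None = None,
                  baseline_count: int | None = None):
    """Voxel-wise Tofts fit over a 4D DCE series restricted to ``mask``.

    If ``conversion`` is given, ``dce`` is taken as raw signal and first
    converted with ``baseline_count`` pre-contrast frames; otherwise it is
    taken as concentration directly.

    Returns dict with ``ktrans``, ``kep``, ``ve``, ``sse`` maps, a
    ``valid`` map and counts ``n_valid`` / ``n_invalid``.
    """
    settings = settings or PKFitSettings()
    dce = np.asarray(dce, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dce.ndim != 4:
        raise ValueError("dce must be 4D (x, y, z, t)")
    if mask.shape != dce.shape[:3]:
        raise ValueError("mask shape does not match dce volume")
    if dce.shape[3] != aif.time.size:
        raise ValueError("number of frames does not match the AIF grid")

    shape = mask.shape
    out = {key: np.full(shape, np.nan) for key in ("ktrans", "kep", "ve", "sse")}
    valid_map = np.zeros(shape, dtype=bool)
    n_masked = int(mask.sum())
    if n_masked == 0:
        warnings.warn("empty mask: no voxels fitted", stacklevel=2)
        return {**out, "valid": valid_map, "n_valid": 0, "n_invalid": 0}

    series = dce[mask]
    if conversion is not None:
        if baseline_count is None:
            raise ValueError("baseline_count required when converting signal")
        series = signal_to_concentration(series, baseline_count, conversion)

    finite = np.all(np.isfinite(series), axis=1)
    quiet = finite & np.all(np.abs(series) < 1e-12, axis=1)
    fit_idx = finite & ~quiet

    kt = np.full(n_masked, np.nan)
    kep = np.full(n_masked, np.nan)
    ve = np.full(n_masked, np.nan)
    sse = np.full(n_masked, np.nan)
    valid = np.zeros(n_masked, dtype=bool)

    kt[quiet] = 0.0
    sse[quiet] = 0.0
    valid[quiet] = True

    if fit_idx.any():
        kt_f, kep_f, sse_f = _fit_tofts_batch(series[fit_idx], aif.time, aif.cp, settings)
        ve_f = kt_f / kep_f
        ok = ve_f <= 1.0
        if settings.clip_ve:
            ve_f = np.minimum(ve_f, 1.0)
            ok = np.ones_like(ok)
        kt[fit_idx] = np.where(ok, kt_f, np.nan)
        kep[fit_idx] = np.where(ok, kep_f, np.nan)
        ve[fit_idx] = np.where(ok, ve_f, np.nan)
        sse[fit_idx] = sse_f
        valid[fit_idx] = ok

    for key, arr in zip(("ktrans", "kep", "ve", "sse"), (kt, kep, ve, sse)):
        out[key][mask] = arr
    valid_map[mask] = valid
    return {
        **out,
        "valid": valid_map,
        "n_valid": int(valid.sum()),
        "n_invalid": int(n_masked - valid.sum()),
    }
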