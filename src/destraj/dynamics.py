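"""Transport and reorientation dynamics.

* Mean-square displacement with multiple time origins on unwrapped
  coordinates, the local log–log slope β(τ), and the Einstein
  self-diffusion coefficient D = slope/6 evaluated on the diffusive
  window where |β − 1| ≤ 0.1 (≥ 10 contiguous lag points).
* Normalised velocity autocorrelation function with its first two zero
  crossings (mean collision time and velocity randomization time).
* Vector reorientation dynamics: the lag autocorrelation of unit bond
  vectors, normalised to 1 at zero lag.
* Green–Kubo shear viscosity: η = V/(k_B T) ∫ ⟨P_xy(0)P_xy(t)⟩ dt with
  the ACF averaged over the three independent off-diagonal components;
  the plateau of the running integral is read where the ACF has decayed
  below 2% of its initial value.

Correlation estimators average over **all** time origins.  The direct
O(N·lag) sums and the FFT evaluation are algebraically identical
estimators; ``method='auto'`` switches to FFT for long series, and the
two paths agree to well below 1e-9 on any input.

Internal units: Å, ps.  D is reported in Å²/ns; viscosity in mPa·s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .trajio import (SiteGroup, Trajectory, ValidationError, as_indices,
                     group_com_positions, unwrap_positions)
from .synth import StressSeries

__all__ = [
    "MSDResult", "VACFResult", "VRDResult", "ViscosityResult",
    "msd", "beta_exponent", "self_diffusion", "DiffusionFit",
    "vacf", "vrd", "gk_viscosity", "autocorrelation",
]

_FFT_THRESHOLD = 4096           # series length above which FFT is used


# --------------------------------------------------------------------------
# correlation kernels
# --------------------------------------------------------------------------

def autocorrelation(x: np.ndarray, max_lag: int,
                    method: str = "auto") -> np.ndarray:
    """Multiple-origin autocorrelation of a scalar series:

        C(k) = (1/(n−k)) Σ_t x(t) x(t+k),   k = 0 … max_lag.

    ``method``: 'direct', 'fft' or 'auto'.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValidationError("max_lag must be smaller than the series")
    if method == "auto":
        method = "fft" if n > _FFT_THRESHOLD else "direct"
    if method == "direct":
        return np.array([np.dot(x[:n - k], x[k:]) / (n - k)
                         for k in range(max_lag + 1)])
    if method == "fft":
        size = 1 << int(np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(x, size)
        acf = np.fft.irfft(f * np.conj(f), size)[:max_lag + 1]
        return acf / (n - np.arange(max_lag + 1))
    raise ValueError(f"unknown method {method!r}")


def _vector_acf(v: np.ndarray, max_lag: int, method: str = "auto"):
    """⟨v(t)·v(t+k)⟩ averaged over origins and entities for a
    (n_frames, n_entities, 3) array."""
    n = v.shape[0]
    out = np.zeros(max_lag + 1)
    for e in range(v.shape[1]):
        for c in range(3):
            out += autocorrelation(v[:, e, c], max_lag, method)
    return out / v.shape[1]


def _msd_direct(r: np.ndarray, max_lag: int) -> np.ndarray:
    n = r.shape[0]
    out = np.zeros(max_lag + 1)
    for k in range(1, max_lag + 1):
        d = r[k:] - r[:-k]
        out[k] = np.mean(np.sum(d * d, axis=-1))
    return out


def _msd_fft(r: np.ndarray, max_lag: int) -> np.ndarray:
    """FFT evaluation of the multiple-origin MSD (identical estimator)."""
    n, m, _ = r.shape
    msd = np.zeros(max_lag + 1)
    counts = n - np.arange(max_lag + 1)
    for e in range(m):
        x = r[:, e, :]
        d2 = np.sum(x * x, axis=1)
        s2 = np.zeros(max_lag + 1)
        for c in range(3):
            s2 += autocorrelation(x[:, c], max_lag, "fft") * counts
        # S1 recurrence: S1(k) = S1(k−1) − d2[k−1] − d2[n−k]
        q = 2.0 * d2.sum()
        s1 = np.empty(max_lag + 1)
        s1[0] = q
        for k in range(1, max_lag + 1):
            q -= d2[k - 1] + d2[n - k]
            s1[k] = q
        msd += (s1 - 2.0 * s2) / counts
    return msd / m


# --------------------------------------------------------------------------
# MSD / beta / D
# --------------------------------------------------------------------------

@dataclass
class MSDResult:
    """Multiple-origin MSD with its local power-law exponent."""

    lags: np.ndarray            # ps
    msd: np.ndarray             # Å²
    beta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def msd(traj_or_positions, group=None, max_lag_fraction: float = 0.5,
        dt: float | None = None, method: str = "auto") -> MSDResult:
    """Mean-square displacement averaged over all origins and entities.

    Accepts a Trajectory (coordinates are unwrapped by accumulating
    minimum-image frame-to-frame displacements; a ``by_molecule_com``
    group averages per-molecule centres of mass first) or a pre-unwrapped
    (n_frames, n_entities, 3) array with an explicit ``dt``.
    """
    if isinstance(traj_or_positions, Trajectory):
        traj = traj_or_positions
        if len(traj) < 2:
            raise ValidationError("MSD needs at least two frames")
        dt = traj.dt
        if group is None:
            r = unwrap_positions(traj)
        elif isinstance(group, SiteGroup):
            r = group_com_positions(traj, group)
        else:
            r = unwrap_positions(traj, as_indices(group))
    else:
        r = np.asarray(traj_or_positions, dtype=float)
        if dt is None:
            raise ValidationError("dt is required with a raw position array")
    n = r.shape[0]
    max_lag = max(1, int(max_lag_fraction * (n - 1)))
    if method == "auto":
        method = "fft" if n > _FFT_THRESHOLD else "direct"
    values = _msd_fft(r, max_lag) if method == "fft" else \
        _msd_direct(r, max_lag)
    lags = np.arange(max_lag + 1) * dt
    return MSDResult(lags, values, meta={"dt": dt, "n_entities": r.shape[1],
                                         "method": method})


def beta_exponent(result: MSDResult, smooth_window: int = 5) -> np.ndarray:
    """β(τ) = d log₁₀ MSD / d log₁₀ τ by centred finite differences,
    smoothed with a moving average.  Stored on the result; NaN where the
    MSD is zero."""
    lags = result.lags
    values = result.msd
    good = (lags > 0) & (values > 0)
    beta = np.full(len(lags), np.nan)
    if np.sum(good) >= 3:
        lt = np.log10(lags[good])
        lm = np.log10(values[good])
        b = np.gradient(lm, lt)
        if smooth_window > 1 and len(b) >= smooth_window:
            pad = smooth_window // 2
            bp = np.pad(b, pad, mode="edge")
            kernel = np.ones(smooth_window) / smooth_window
            b = np.convolve(bp, kernel, mode="same")[pad:pad + len(b)]
        beta[good] = b
    result.beta = beta
    return beta


@dataclass
class DiffusionFit:
    """Einstein-relation fit over the diffusive window."""

    d_self: float               # Å²/ns
    window: tuple               # (τ_lo, τ_hi) ps
    slope: float                # Å²/ps
    n_points: int


def self_diffusion(result: MSDResult, beta_tol: float = 0.1,
                   min_points: int = 10) -> DiffusionFit | None:
    """D_self = slope/6 of MSD vs τ on the longest contiguous window with
    |β − 1| ≤ beta_tol spanning at least ``min_points`` lag points.
    Returns None (a non-diffusive signal) when no such window exists."""
    if result.beta is None:
        beta_exponent(result)
    ok = np.abs(result.beta - 1.0) <= beta_tol
    ok &= ~np.isnan(result.beta)
    best = None
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if best is None or best[1] - best[0] < min_points:
        return None
    sl = slice(*best)
    slope = np.polyfit(result.lags[sl], result.msd[sl], 1)[0]
    return DiffusionFit(d_self=float(slope / 6.0 * 1000.0),
                        window=(float(result.lags[sl][0]),
                                float(result.lags[sl][-1])),
                        slope=float(slope), n_points=best[1] - best[0])


# --------------------------------------------------------------------------
# VACF
# --------------------------------------------------------------------------

@dataclass
class VACFResult:
    """Normalised velocity autocorrelation with its zero crossings."""

    lags: np.ndarray            # ps
    cv: np.ndarray              # C_v(0) = 1
    t1: float | None            # first zero crossing: mean collision time
    t2: float | None            # second zero: randomization time
    meta: dict = field(default_factory=dict)


def _zero_crossings(t: np.ndarray, y: np.ndarray, n: int = 2) -> list:
    out = []
    for i in range(len(y) - 1):
        if y[i] == 0.0:
            out.append(float(t[i]))
        elif y[i] * y[i + 1] < 0:
            frac = y[i] / (y[i] - y[i + 1])
            out.append(float(t[i] + frac * (t[i + 1] - t[i])))
        if len(out) == n:
            break
    return out


def vacf(traj_or_velocities, group=None, max_lag_fraction: float = 0.5,
         dt: float | None = None, method: str = "auto") -> VACFResult:
    """Normalised multiple-origin velocity autocorrelation.

    Accepts a Trajectory with velocities (``group`` restricts/aggregates
    entities; a ``by_molecule_com`` group uses mass-weighted molecular
    velocities) or a raw (n_frames, n_entities, 3) velocity array with an
    explicit ``dt``.
    """
    if isinstance(traj_or_velocities, Trajectory):
        traj = traj_or_velocities
        v = traj.velocities_array()
        dt = traj.dt
        if group is not None:
            idx = as_indices(group)
            v = v[:, idx, :]
            if isinstance(group, SiteGroup) and group.mode == "by_molecule_com":
                mids = traj.topology.molecule_ids[idx]
                masses = traj.topology.masses[idx]
                cols = []
                for mid in np.unique(mids):
                    sel = mids == mid
                    w = masses[sel] / masses[sel].sum()
                    cols.append(np.einsum("fkx,k->fx", v[:, sel, :], w))
                v = np.stack(cols, axis=1)
    else:
        v = np.asarray(traj_or_velocities, dtype=float)
        if v.ndim == 2:
            v = v[:, None, :]
        if dt is None:
            raise ValidationError("dt is required with a raw velocity array")
    n = v.shape[0]
    max_lag = max(1, int(max_lag_fraction * (n - 1)))
    acf = _vector_acf(v, max_lag, method)
    if acf[0] == 0:
        raise ValidationError("zero velocity variance")
    cv = acf / acf[0]
    lags = np.arange(max_lag + 1) * dt
    crossings = _zero_crossings(lags, cv)
    t1 = crossings[0] if len(crossings) > 0 else None
    t2 = crossings[1] if len(crossings) > 1 else None
    return VACFResult(lags, cv, t1, t2, meta={"dt": dt,
                                              "n_entities": v.shape[1]})


# --------------------------------------------------------------------------
# VRD
# --------------------------------------------------------------------------

@dataclass
class VRDResult:
    """Bond-vector reorientation autocorrelation, VRD(0) = 1."""

    lags: np.ndarray
    vrd: np.ndarray
    vector_spec: tuple
    n_skipped: int = 0
    meta: dict = field(default_factory=dict)


def vrd(traj_or_vectors, ref_type: str | None = None,
        site_pair: tuple | None = None, max_lag_fraction: float = 0.5,
        dt: float | None = None, normalize_vectors: bool = True,
        method: str = "auto") -> VRDResult:
    """Reorientation correlation of molecular bond vectors.

    From a Trajectory, the vector runs between two site labels inside
    every molecule of ``ref_type``; molecules with a zero-length vector in
    any frame are skipped (counted).  A raw (n_frames, n_vectors, 3) array
    with ``dt`` is also accepted.
    """
    n_skipped = 0
    if isinstance(traj_or_vectors, Trajectory):
        traj = traj_or_vectors
        from .structure import _ref_molecules
        from .trajio import minimum_image
        mols = _ref_molecules(traj.topology, ref_type)
        a_lbl, b_lbl = site_pair
        for s in (a_lbl, b_lbl):
            if any(s not in m for m in mols):
                raise ValidationError(f"site {s!r} missing from a "
                                      f"{ref_type} molecule")
        dt = traj.dt
        vecs = np.stack([
            np.stack([minimum_image(fr.positions[m[b_lbl]]
                                    - fr.positions[m[a_lbl]], fr.box)
                      for m in mols])
            for fr in traj.frames])
    else:
        vecs = np.asarray(traj_or_vectors, dtype=float)
        if vecs.ndim == 2:
            vecs = vecs[:, None, :]
        if dt is None:
            raise ValidationError("dt is required with a raw vector array")
    if normalize_vectors:
        norms = np.linalg.norm(vecs, axis=-1)
        bad = np.any(norms < 1e-12, axis=0)
        n_skipped = int(np.sum(bad))
        if np.all(bad):
            raise ValidationError("all bond vectors have zero length")
        vecs = vecs[:, ~bad, :] / norms[:, ~bad, None]
    n = vecs.shape[0]
    max_lag = max(1, int(max_lag_fraction * (n - 1)))
    acf = _vector_acf(vecs, max_lag, method)
    out = acf / acf[0]
    lags = np.arange(max_lag + 1) * (dt if dt else 1.0)
    return VRDResult(lags, out, (ref_type, site_pair), n_skipped,
                     meta={"dt": dt, "n_vectors": vecs.shape[1]})


# --------------------------------------------------------------------------
# Green–Kubo shear viscosity
# --------------------------------------------------------------------------

#: conversion of a stress unit to Pa
_STRESS_TO_PA = {"pa": 1.0, "bar": 1e5, "atm": 101325.0, "mpa": 1e6}


@dataclass
class ViscosityResult:
    """Stress ACF, running Green–Kubo integral and its plateau (mPa·s)."""

    lags: np.ndarray            # ps
    acf: np.ndarray             # (stress unit)², component-averaged
    eta_t: np.ndarray           # running integral, mPa·s
    eta: float | None           # plateau (None when the ACF never decays)
    window: tuple | None        # plateau estimation window (ps)
    volume: float               # Å³
    temperature: float          # K
    meta: dict = field(default_factory=dict)


def gk_viscosity(stress, volume: float, temperature: float,
                 dt: float | None = None, stress_unit: str = "atm",
                 max_lag: int | None = None,
                 integration_cut: float | None = None,
                 decay_fraction: float = 0.02,
                 method: str = "auto") -> ViscosityResult:
    """Shear viscosity from the off-diagonal stress autocorrelation.

    ``stress`` is a StressSeries or an (n, 3) array of (P_xy, P_xz, P_yz)
    samples with spacing ``dt`` ps.  The ACF of each component is averaged
    (they are equivalent off-diagonal elements), the running integral is
    accumulated by the trapezoid rule and converted to mPa·s, and the
    plateau is the mean of η(t) between the time the ACF first falls below
    ``decay_fraction``·ACF(0) and twice that time.  ``integration_cut``
    (ps) overrides the automatic decay detection.
    """
    if isinstance(stress, StressSeries):
        data = stress.data
        dt = stress.dt
    else:
        data = np.asarray(stress, dtype=float)
        if dt is None:
            raise ValidationError("dt is required with a raw stress array")
    if volume <= 0 or temperature <= 0:
        raise ValidationError("volume and temperature must be positive")
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValidationError("stress series must have shape (n, 3)")
    try:
        to_pa = _STRESS_TO_PA[stress_unit.lower()]
    except KeyError:
        raise ValueError(f"unknown stress unit {stress_unit!r}")
    n = data.shape[0]
    if max_lag is None:
        max_lag = min(n - 1, max(100, n // 10))
    acf = np.mean([autocorrelation(data[:, c], max_lag, method)
                   for c in range(3)], axis=0)
    lags = np.arange(max_lag + 1) * dt
    # η(t) = V/(kB T) ∫ ACF dt'   [Å³ → m³, ps → s, stress² → Pa²] → mPa·s
    factor = (volume * 1e-30) / (constants.k * temperature) \
        * to_pa ** 2 * 1e-12 * 1e3
    integral = np.concatenate([[0.0], np.cumsum(
        0.5 * (acf[1:] + acf[:-1]) * dt)])
    eta_t = factor * integral

    if acf[0] == 0:
        return ViscosityResult(lags, acf, eta_t, 0.0, (0.0, float(lags[-1])),
                               volume, temperature,
                               meta={"stress_unit": stress_unit})
    if integration_cut is not None:
        i_cut = int(np.searchsorted(lags, integration_cut))
    else:
        below = np.nonzero(np.abs(acf) < decay_fraction * acf[0])[0]
        if len(below) == 0:
            warnings.warn("stress ACF has not decayed below the plateau "
                          "threshold by the last lag; no plateau estimated")
            return ViscosityResult(lags, acf, eta_t, None, None, volume,
                                   temperature,
                                   meta={"stress_unit": stress_unit})
        i_cut = int(below[0])
    i_hi = min(max(2 * i_cut, i_cut + 1), len(eta_t))
    eta = float(np.mean(eta_t[i_cut:i_hi]))
    return ViscosityResult(lags, acf, eta_t, eta,
                           (float(lags[i_cut]), float(lags[i_hi - 1])),
                           volume, temperature,
                           meta={"stress_unit": stress_unit,
                                 "decay_fraction": decay_fraction})
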