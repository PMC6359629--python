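"""Dynamical metrics: lateral diffusion and tail rotational relaxation.

* Lateral mean-square displacement of head-group centers projected onto
  the membrane plane, with the two-dimensional Einstein relation
  MSD(t) → 4·D_xy·t fitted over a chosen window.
* Rotational autocorrelation of tail carbon-triplet normal vectors:
  for carbon window k the unit normal u is the normalized cross product
  of the two bond vectors around carbon k+1, and
  C(t) = ⟨u(ξ)·u(ξ+t)⟩ is averaged over time origins, lipids and both
  tails (an incoherent, per-molecule quantity — the P1 orientational
  correlator).
* The integral correlation time ∫C(t)dt and bounded least-squares fits
  of the sum of two stretched exponentials (KWW), the fast component
  with τ₁ ∈ [1, 100] ps and the slow with τ₂ ∈ [0.1, 10] ns, amplitudes
  constrained to B + A₁ + A₂ = C(0).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from ._pbc import minimum_image
from .types import (
    AutocorrFunction,
    DiffusionResult,
    MsdCurve,
    StretchedExpParams,
    Trajectory,
    TopologyRoles,
)

__all__ = [
    "unwrap_coordinates",
    "lateral_msd",
    "lateral_diffusion",
    "triplet_normal_acf",
    "acf_integral_time",
    "fit_double_stretched",
    "kww_integral_time",
]

_HEAD_ROLES = ("choline", "phosphate", "acceptor-oxygen")


def unwrap_coordinates(coords: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping along the trajectory.

    Frame-to-frame displacements are minimum-imaged and re-accumulated,
    which is exact as long as no particle moves more than half a box
    length between consecutive frames.
    """
    disp = minimum_image(np.diff(coords, axis=0), boxes[1:, None, :])
    out = np.empty_like(coords)
    out[0] = coords[0]
    np.cumsum(disp, axis=0, out=out[1:])
    out[1:] += coords[0]
    return out


def _msd_fft_1particle(x: np.ndarray) -> np.ndarray:
    """MSD over all time origins for one particle track (F, d), via FFT."""
    f, d = x.shape
    nfft = 1 << (2 * f - 1).bit_length()
    sq = np.einsum("ij,ij->i", x, x)
    s2 = np.zeros(f)
    for k in range(d):
        fx = np.fft.rfft(x[:, k], nfft)
        ac = np.fft.irfft(fx * np.conj(fx), nfft)[:f]
        s2 += ac
    # s1[m] = Σ_t (|x(t)|² + |x(t+m)|²) over the F−m valid origins
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    total = csum[-1]
    m = np.arange(f)
    s1 = 2.0 * total - csum[m] - (total - csum[f - m])
    n = f - m
    return s1 / n - 2.0 * s2 / n


def _head_com_tracks(traj: Trajectory, roles: TopologyRoles, group: str) -> np.ndarray:
    """Unwrapped (F, n_molecules, 2) xy tracks of head-group centers."""
    unwrapped = unwrap_coordinates(traj.coords, traj.boxes)
    if group == "head":
        tracks = []
        for lid in roles.lipid_ids:
            mol = roles.molecule_indices(lid)
            sel = [i for i in mol if roles.role[i] in _HEAD_ROLES]
            tracks.append(unwrapped[:, sel, :2].mean(axis=1))
        return np.stack(tracks, axis=1)
    raise ValueError(f"unknown group {group!r}")


def lateral_msd(
    traj: Trajectory,
    roles: Optional[TopologyRoles] = None,
    group: str = "head",
    max_lag: Optional[float] = None,
) -> MsdCurve:
    """Lateral (xy) MSD averaged over all time origins and molecules.

    Coordinates are unwrapped across periodic boundaries before
    differencing.  With ``roles`` provided, the tracked points are the
    head-group centers of each lipid; without roles, every particle is
    tracked as its own walker (useful for planted random walks).
    """
    disp = minimum_image(np.diff(traj.coords, axis=0), traj.boxes[1:, None, :])
    if np.any(np.abs(disp) > traj.boxes[1:, None, :] / 2 - 1e-9):
        raise ValueError("frame gaps too large to unwrap")
    if roles is not None:
        tracks = _head_com_tracks(traj, roles, group)
    else:
        tracks = unwrap_coordinates(traj.coords, traj.boxes)[:, :, :2]
    f = traj.n_frames
    msd = np.zeros(f)
    for p in range(tracks.shape[1]):
        msd += _msd_fft_1particle(tracks[:, p, :])
    msd /= tracks.shape[1]
    msd[0] = 0.0
    lags = traj.times - traj.times[0]
    n_origins = f - np.arange(f)
    if max_lag is not None:
        keep = lags <= max_lag
        lags, msd, n_origins = lags[keep], msd[keep], n_origins[keep]
    return MsdCurve(lag=lags, msd=msd, n_origins=n_origins)


def lateral_diffusion(
    msd: MsdCurve,
    window: Optional[Tuple[float, float]] = None,
    preferred_window: Tuple[float, float] = (20e3, 160e3),
) -> DiffusionResult:
    """Einstein D_xy = slope/4 from a linear fit of the MSD window.

    The default window is 20–160 ns when the curve reaches that far
    (the most linear portion for long membrane runs), otherwise the
    [10%, 80%] span of available lags.
    """
    t_max = float(msd.lag[-1])
    if window is None:
        if t_max >= preferred_window[1]:
            window = preferred_window
        else:
            window = (0.10 * t_max, 0.80 * t_max)
    sel = (msd.lag >= window[0]) & (msd.lag <= window[1])
    if sel.sum() < 3:
        raise ValueError("fewer than 3 MSD points in fit window")
    t, y = msd.lag[sel], msd.msd[sel]
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionResult(d_xy=float(slope) / 4.0, fit_window=tuple(window), fit_r2=r2)


def _acf_direct(u: np.ndarray, n_lags: int) -> np.ndarray:
    """⟨u(ξ)·u(ξ+t)⟩ by direct origin sums; u has shape (F, T, 3)."""
    f = u.shape[0]
    out = np.empty(n_lags)
    for k in range(n_lags):
        out[k] = np.mean(np.einsum("fti,fti->ft", u[: f - k], u[k:]))
    return out


def _acf_fft(u: np.ndarray, n_lags: int) -> np.ndarray:
    """Same estimator via FFT autocorrelation per component and tail."""
    f, t, _ = u.shape
    nfft = 1 << (2 * f - 1).bit_length()
    acc = np.zeros(f)
    for c in range(3):
        fx = np.fft.rfft(u[:, :, c], nfft, axis=0)
        ac = np.fft.irfft(fx * np.conj(fx), nfft, axis=0)[:f]
        acc += ac.sum(axis=1)
    return acc[:n_lags] / (t * (f - np.arange(n_lags)))


def triplet_normal_acf(
    traj: Trajectory,
    roles: TopologyRoles,
    carbon_window: int,
    span: Optional[float] = None,
    chain: str = "both",
    estimator: str = "auto",
) -> AutocorrFunction:
    """P1 rotational ACF of the tail carbon-triplet normal vectors.

    Carbon window k uses carbons (k, k+1, k+2) counted from the
    carbonyl-proximal carbon; the unit normal is the cross product of the
    two bonds around the middle carbon.  Windows 4–7 (mid-tail methylene
    region) give the most stable statistics.  Frames where the two bonds
    are collinear are skipped.
    """
    if not (1 <= carbon_window <= 12):
        raise ValueError("carbon_window must lie in 1..12")
    chains = ("SN1", "SN2") if chain == "both" else (chain,)
    normals = []
    for c in chains:
        carbons = roles.tail_carbons(c)  # (n_lipids, 14)
        trip = carbons[:, carbon_window - 1 : carbon_window + 2]
        if trip.shape[1] < 3:
            raise ValueError("carbon window lacks two bonded neighbours")
        p = traj.coords[:, trip, :]  # (F, n_lipids, 3, 3)
        b1 = minimum_image(p[:, :, 0] - p[:, :, 1], traj.boxes[:, None, :])
        b2 = minimum_image(p[:, :, 2] - p[:, :, 1], traj.boxes[:, None, :])
        u = np.cross(b1, b2)
        norm = np.linalg.norm(u, axis=-1, keepdims=True)
        if np.any(norm < 1e-10):
            bad = norm[..., 0] < 1e-10
            u = u.copy()
            u[bad] = np.nan  # collinear bonds: frame skipped below
        normals.append(u / np.where(norm < 1e-10, 1.0, norm))
    u = np.concatenate(normals, axis=1)  # (F, T, 3)
    if np.isnan(u).any():
        keep = ~np.isnan(u).any(axis=(0, 2))
        u = u[:, keep]

    f = traj.n_frames
    dt = traj.dt if f > 1 else 1.0
    n_lags = f if span is None else min(f, int(np.floor(span / dt)) + 1)
    if estimator == "auto":
        estimator = "direct" if f <= 4096 else "fft"
    if estimator == "direct":
        c = _acf_direct(u, n_lags)
    elif estimator == "fft":
        c = _acf_fft(u, n_lags)
    else:
        raise ValueError("estimator must be 'auto', 'direct' or 'fft'")
    lags = dt * np.arange(n_lags)
    return AutocorrFunction(lag=lags, c=c, carbon_window=carbon_window)


def acf_integral_time(acf: AutocorrFunction, span: Optional[float] = None) -> float:
    """Integral correlation time: trapezoidal ∫C(t)dt over the span (ps)."""
    if span is None:
        lag, c = acf.lag, acf.c
    else:
        if span > acf.lag[-1] + 1e-9:
            raise ValueError("integration span exceeds the available data")
        keep = acf.lag <= span
        lag, c = acf.lag[keep], acf.c[keep]
    return float(np.trapezoid(c, lag))


def kww_integral_time(tau: float, beta: float) -> float:
    """Analytic ∫₀^∞ exp[−(t/τ)^β] dt = (τ/β)·Γ(1/β)."""
    from scipy.special import gamma

    return float(tau / beta * gamma(1.0 / beta))


def _kww_model(t, a1, a2, logt1, b1, logt2, b2, c0):
    b = c0 - a1 - a2
    return (b + a1 * np.exp(-np.power(t / np.exp(logt1), b1))
            + a2 * np.exp(-np.power(t / np.exp(logt2), b2)))


def fit_double_stretched(
    acf: AutocorrFunction,
    tau1_bounds: Tuple[float, float] = (1.0, 100.0),
    tau2_bounds: Tuple[float, float] = (100.0, 10000.0),
    constrain_total: bool = True,
    n_starts: int = 9,
    seed: int = 0,
) -> StretchedExpParams:
    """Bounded least-squares fit of C(t) ≈ B + A₁e^{−(t/τ₁)^β₁} + A₂e^{−(t/τ₂)^β₂}.

    τ₁ is bounded to the fast (ps) decade and τ₂ to the slow (ns) decade;
    both stretching exponents lie in (0, 1].  With ``constrain_total``
    the baseline is tied so B + A₁ + A₂ = C(0).  Residuals carry a
    log-time point weighting so the picosecond and nanosecond decades
    contribute comparably.  Fits restart from a log-spaced τ grid and the
    best residual wins; R² is reported unweighted.
    """
    t, y = acf.lag, acf.c
    if t.size < 50:
        raise ValueError("need ≥ 50 ACF points spanning the ps and ns decades")
    c0 = float(y[0])
    tpos = np.where(t > 0, t, t[1] if t.size > 1 else 1.0)
    # log-time weights: each point weighted by its share of the log-t axis
    logt = np.log(tpos)
    dl = np.gradient(logt)
    w = np.sqrt(np.clip(dl, 0.0, None))
    w[0] = w[1] if w.size > 1 else 1.0

    lo = np.array([0.0, 0.0, np.log(tau1_bounds[0]), 0.05, np.log(tau2_bounds[0]), 0.05])
    hi = np.array([1.5, 1.5, np.log(tau1_bounds[1]), 1.0, np.log(tau2_bounds[1]), 1.0])

    def residual(x):
        a1, a2, lt1, b1, lt2, b2 = x
        pred = _kww_model(t, a1, a2, lt1, b1, lt2, b2, c0)
        res = (pred - y) * w
        if constrain_total:
            b = c0 - a1 - a2
            res = np.append(res, 100.0 * min(b, 0.0))
        return res

    rng = np.random.default_rng(seed)
    n_t1 = max(int(np.sqrt(n_starts)), 1)
    n_t2 = max(n_starts // n_t1, 1)
    t1_starts = np.exp(np.linspace(*np.log(tau1_bounds), n_t1 + 2))[1:-1]
    t2_starts = np.exp(np.linspace(*np.log(tau2_bounds), n_t2 + 2))[1:-1]
    best = None
    for t1s in t1_starts:
        for t2s in t2_starts:
            x0 = np.array([
                min(0.6 * c0, 1.4), min(0.35 * c0, 1.4),
                np.log(t1s), 0.7 + 0.05 * rng.standard_normal(),
                np.log(t2s), 0.8 + 0.05 * rng.standard_normal(),
            ])
            x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
            try:
                sol = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                                    xtol=1e-12, ftol=1e-12, max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("double stretched-exponential fit failed to converge")

    a1, a2, lt1, b1, lt2, b2 = best.x
    b = c0 - a1 - a2 if constrain_total else c0 - a1 - a2
    pred = _kww_model(t, a1, a2, lt1, b1, lt2, b2, c0)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    converged = bool(best.status > 0)
    return StretchedExpParams(
        b=float(b), a1=float(a1), tau1=float(np.exp(lt1)), beta1=float(b1),
        a2=float(a2), tau2=float(np.exp(lt2)), beta2=float(b2),
        r2=r2, converged=converged,
    )
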