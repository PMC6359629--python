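"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: model
bilayer density profiles and multi-order Bragg reflectivity curves,
2-D in-plane maps with a prescribed Herman's orientation factor, and toy
bilayer trajectories that plant gauche fractions, lateral diffusion,
hydrogen-bond geometries, glucose placements and tail rotational
relaxation with a double stretched-exponential (KWW) ground truth.

The generators match *statistics*, not physics: there is no force field,
no energetics and no thermodynamic realism.  Their purpose is that every
downstream estimator, applied to its matched generator, recovers the
planted parameter within a stated tolerance.

Design notes on the trajectory generator
----------------------------------------
* Tail dihedrals are planted by exact count (``round(target·n_dihedrals)``
  gauche placements, shuffled across tails) and held fixed over time, so
  each tail is a rigid body.  This keeps the time-averaged gauche fraction
  at the target to within one part in 2·n_dihedrals *and* leaves the
  triplet-normal orientation free to evolve only through the planted
  rotation process.
* Each tail performs stationary isotropic rotational diffusion whose P1
  autocorrelation is exp(−λt).  Rates are drawn per tail so the ensemble
  average equals the target B + A₁e^{−(t/τ₁)^β₁} + A₂e^{−(t/τ₂)^β₂}:
  a fraction B of tails is frozen and components A₁/A₂ draw λ = X/τ with
  X one-sided β-stable (Kanter's sampler), for which
  E[exp(−tX/τ)] = exp(−(t/τ)^β) exactly.
* Head groups ride a planted 2-D Brownian walk (variance 2·D·dt per axis
  per step); planted water molecules and attached glucose ride their
  lipid, so hydrogen-bond geometries and glucose distances hold in every
  frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from ._pbc import minimum_image
from .types import (
    AutocorrFunction,
    ElectronDensityProfile,
    InPlaneMap,
    ReflectivityCurve,
    StretchedExpParams,
    Trajectory,
    TopologyRoles,
)

__all__ = [
    "ModelBilayerSpec",
    "SyntheticTrajectorySpec",
    "default_rot_params",
    "model_edp",
    "model_form_factors",
    "synth_reflectivity",
    "synth_inplane_map",
    "synth_trajectory",
    "synth_random_walk",
    "synth_acf_curve",
]

_BOND = 1.53  # C–C bond length, Å
_ANGLE = np.radians(111.0)  # C–C–C bond angle


@dataclass
class ModelBilayerSpec:
    """Parameters of a DMPC-like model electron-density profile.

    The profile over one lamellar repeat is a sum of Gaussians: a symmetric
    head-group pair at ±``head_position``, a central core trough
    (``core_amplitude`` < 0 for the terminal-methyl dip), and a narrow
    low-density inter-bilayer feature at the cell edge z = ±d/2
    (``edge_amplitude`` < 0), which carries the high-order structure of a
    dehydrated multilamellar stack.  Defaults emulate dehydrated DMPC with
    a 57.4 Å repeat and head maxima at ±17 Å.
    """

    lamellar_period: float = 57.4  # Å
    head_position: float = 17.0  # Å
    head_width: float = 5.0  # Å
    core_width: float = 6.0  # Å
    head_amplitude: float = 1.0
    core_amplitude: float = -0.3
    edge_width: float = 2.0  # Å
    edge_amplitude: float = -1.0
    n_orders: int = 11

    def __post_init__(self):
        if not (self.lamellar_period > 2.0 * self.head_position > 0):
            raise ValueError("require lamellar_period > 2·head_position > 0")
        if self.n_orders < 1:
            raise ValueError("n_orders must be ≥ 1")
        for w in (self.head_width, self.core_width, self.edge_width):
            if w <= 0:
                raise ValueError("widths must be positive")


def model_edp(spec: ModelBilayerSpec, grid_step: float = 0.05) -> ElectronDensityProfile:
    """Evaluate the model profile on a symmetric grid over one repeat.

    The grid spans [−d/2, d/2]; the profile is evaluated on the
    non-negative half and mirrored, so ρ(z) = ρ(−z) holds exactly on the
    grid.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    d = spec.lamellar_period
    m = int(round((d / 2.0) / grid_step))
    z = grid_step * np.arange(0, m + 1)

    def gauss(center, width):
        # periodized over neighbouring repeats so the profile is one cell
        # of a continuous multilamellar stack (no kink at z = ±d/2)
        out = np.zeros_like(z)
        for k in (-1, 0, 1):
            out += np.exp(-0.5 * ((z - center - k * d) / width) ** 2)
        return out

    rho = spec.head_amplitude * (gauss(spec.head_position, spec.head_width)
                                 + gauss(-spec.head_position, spec.head_width))
    rho += spec.core_amplitude * gauss(0.0, spec.core_width)
    # a single periodized edge Gaussian: its −d/2 image makes it symmetric
    rho += spec.edge_amplitude * gauss(d / 2.0, spec.edge_width)
    z_full = np.concatenate([-z[:0:-1], z])
    rho_full = np.concatenate([rho[:0:-1], rho])
    return ElectronDensityProfile(z=z_full, rho=rho_full, component_label="whole-membrane")


def model_form_factors(spec: ModelBilayerSpec, n_orders: Optional[int] = None,
                       grid_step: float = 0.01) -> np.ndarray:
    """Signed form factors F_n = ∫ρ(z)cos(2πnz/d)dz by direct integration."""
    n = n_orders or spec.n_orders
    edp = model_edp(spec, grid_step=grid_step)
    d = spec.lamellar_period
    orders = np.arange(1, n + 1)
    return np.trapezoid(edp.rho[None, :] * np.cos(2 * np.pi * orders[:, None] * edp.z / d),
                        edp.z, axis=1)


def synth_reflectivity(
    edp: ElectronDensityProfile,
    spec: ModelBilayerSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    q_step: float = 5e-4,
    peak_sigma: float = 0.004,
) -> ReflectivityCurve:
    """Reflectivity curve with Gaussian Bragg peaks at q_n = 2πn/d.

    The integrated area of peak n is I_n = |F_n|/q_n with F_n obtained by
    cosine integration of ``edp``, i.e. the same product convention
    |F_n| = I_n·q_n that :func:`memglass.xray_lamellar.compute_form_factors`
    applies by default, so the generator and the analysis round-trip.
    With ``noise_sd = 0`` the curve is deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if spec.n_orders > 12:
        raise ValueError("n_orders must be ≤ 12")
    d = spec.lamellar_period
    orders = np.arange(1, spec.n_orders + 1)
    q_n = 2 * np.pi * orders / d
    f_signed = np.trapezoid(
        edp.rho[None, :] * np.cos(2 * np.pi * orders[:, None] * edp.z / d), edp.z, axis=1
    )
    intensities = np.abs(f_signed) / q_n

    q = np.arange(q_step, q_n[-1] + 0.7 * q_n[0], q_step)
    y = np.zeros_like(q)
    norm = 1.0 / (peak_sigma * np.sqrt(2 * np.pi))
    for qi, ii in zip(q_n, intensities):
        y += ii * norm * np.exp(-0.5 * ((q - qi) / peak_sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, y.size), 0.0, None)
    return ReflectivityCurve(q_z=q, intensity=y)


def synth_inplane_map(
    orientation_h: float,
    q_t: float,
    seed: int = 0,
    q_step: float = 0.005,
    ring_sigma: float = 0.06,
    noise_sd: float = 0.0,
) -> InPlaneMap:
    """2-D in-plane map whose azimuthal distribution has a planted H.

    The intensity is a Gaussian ring at |q| = ``q_t`` whose azimuthal mass
    is a mixture of a uniform component and a sharply aligned component at
    φ ≈ 0, mixed so Herman's factor equals ``orientation_h``:
    w = (H − 0.25)/0.75 of the mass is aligned.  Mass is painted per
    0.5° azimuthal bin normalized by the cell count in that bin, so the
    analyzed H is insensitive to grid pixelation.
    """
    if not (0.25 <= orientation_h <= 1.0):
        raise ValueError("orientation_h must lie in [0.25, 1]")
    if not (0.1 <= q_t <= 3.0):
        raise ValueError("q_t outside instrument range [0.1, 3.0] Å⁻¹")
    w = (orientation_h - 0.25) / 0.75
    q_max = q_t + 0.45
    grid = np.arange(0.0, q_max + q_step, q_step)
    qp, qz = np.meshgrid(grid, grid)
    qabs = np.hypot(qp, qz)
    phi = np.degrees(np.arctan2(qz, qp))

    ring = (np.abs(qabs - q_t) <= 3.0 * ring_sigma)
    radial = np.exp(-0.5 * ((qabs - q_t) / ring_sigma) ** 2)

    bw = 0.5
    edges = np.arange(0.0, 90.0 + bw, bw)
    nbins = edges.size - 1
    binidx = np.clip(np.digitize(phi, edges) - 1, 0, nbins - 1)
    counts = np.bincount(binidx[ring], minlength=nbins).astype(float)
    weights = np.full(nbins, (1.0 - w) / nbins)
    weights[0] += w
    per_cell = np.zeros(nbins)
    ok = counts > 0
    per_cell[ok] = weights[ok] / counts[ok]

    intensity = np.zeros_like(qabs)
    intensity[ring] = per_cell[binidx[ring]] * radial[ring]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(
            intensity + rng.normal(0.0, noise_sd * intensity.max(), intensity.shape), 0.0, None
        )
    return InPlaneMap(q_parallel=grid, q_z=grid, intensity=intensity)


def default_rot_params() -> StretchedExpParams:
    """Default planted tail-relaxation ground truth (ps units)."""
    return StretchedExpParams(b=0.1, a1=0.5, tau1=10.0, beta1=0.6,
                              a2=0.4, tau2=2000.0, beta2=0.9)


@dataclass
class SyntheticTrajectorySpec:
    """Composition and planted ground truth of a toy bilayer trajectory.

    Defaults mirror a 128-lipid patch at low hydration (7 waters per
    lipid) with a few glucose molecules, a gauche fraction in the fluid
    plateau range, a lateral diffusion constant typical for DMPC
    (10⁻³ Å²/ps ≈ 10⁻⁷ cm²/s) and two KWW relaxation components on the
    picosecond and nanosecond scales.
    """

    n_lipids: int = 128
    n_glucose: int = 4
    waters_per_lipid: int = 7
    gauche_target: float = 0.245
    lateral_d: float = 1e-3  # Å²/ps
    rot_params: StretchedExpParams = field(default_factory=default_rot_params)
    hbond_pairs_per_lipid: int = 3
    frame_interval: float = 4.0  # ps
    n_frames: int = 500
    seed: int = 0
    glucose_distance: float = 4.0  # Å from the designated lipid's phosphate
    box_z: float = 57.4  # Å
    lipid_spacing: float = 7.8  # Å lateral grid pitch

    def __post_init__(self):
        for name in ("n_lipids", "n_glucose", "waters_per_lipid",
                     "hbond_pairs_per_lipid", "n_frames"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not (0.0 <= self.gauche_target <= 1.0):
            raise ValueError("gauche_target must lie in [0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.lateral_d < 0:
            raise ValueError("lateral_d must be ≥ 0")
        if self.hbond_pairs_per_lipid > self.waters_per_lipid:
            raise ValueError("box too small: more planted H-bond waters than waters per lipid")
        if self.n_glucose > 2 * max(self.n_lipids, 1):
            raise ValueError("box too small to hold requested glucose count")
        total = self.rot_params.total_amplitude
        if abs(total - 1.0) > 1e-6:
            raise ValueError("rot_params amplitudes must satisfy B + A1 + A2 = 1")


# --- internal helpers ----------------------------------------------------

def _kanter_stable(beta: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """One-sided β-stable samples X with E[exp(−sX)] = exp(−s^β)."""
    if beta >= 1.0:
        return np.ones(size)
    th = rng.uniform(1e-9, np.pi - 1e-9, size)
    w = rng.exponential(1.0, size)
    a = (np.sin(beta * th) ** beta * np.sin((1 - beta) * th) ** (1 - beta)
         / np.sin(th)) ** (1.0 / (1.0 - beta))
    return (a / w) ** ((1.0 - beta) / beta)


def _step_sigma_for_decay(f: np.ndarray) -> np.ndarray:
    """Per-step rotation scale s with E[P1 decay per step] = f.

    For a rotation by the random vector ω ~ N(0, s²I₃) the expected P1
    decay of a fixed unit vector is g(s) = (1 + 2(1−s²)e^{−s²/2})/3,
    monotone on [0, √3].  Inverted by table interpolation.
    """
    s_tab = np.linspace(0.0, np.sqrt(3.0), 2001)
    g_tab = (1.0 + 2.0 * (1.0 - s_tab**2) * np.exp(-0.5 * s_tab**2)) / 3.0
    # g decreases with s: interpolate on reversed tables
    return np.interp(np.clip(f, g_tab[-1], 1.0), g_tab[::-1], s_tab[::-1])


_G_MIN = float((1.0 + 2.0 * (1.0 - 3.0) * np.exp(-1.5)) / 3.0)  # g(√3) ≈ 0.0358


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = (q1[..., i] for i in range(4))
    w2, x2, y2, z2 = (q2[..., i] for i in range(4))
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v, axis=-1, keepdims=True)
    half = 0.5 * angle
    small = angle < 1e-12
    axis = np.where(small, 0.0, v / np.where(small, 1.0, angle))
    return np.concatenate([np.cos(half), np.sin(half) * axis], axis=-1)


def _quat_to_mat(q: np.ndarray) -> np.ndarray:
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def _random_quats(rng: np.random.Generator, shape) -> np.ndarray:
    q = rng.normal(size=tuple(shape) + (4,))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def _build_chains(dihedrals: np.ndarray) -> np.ndarray:
    """Carbon chains (T, 14, 3) from planted dihedrals (T, 11) by NeRF."""
    t = dihedrals.shape[0]
    pos = np.zeros((t, 14, 3))
    pos[:, 1] = (0.0, 0.0, _BOND)
    gamma = np.pi - _ANGLE
    pos[:, 2] = pos[:, 1] + _BOND * np.array([np.sin(gamma), 0.0, np.cos(gamma)])
    sin_t, cos_t = np.sin(_ANGLE), np.cos(_ANGLE)
    for k in range(3, 14):
        a, b, c = pos[:, k - 3], pos[:, k - 2], pos[:, k - 1]
        phi = dihedrals[:, k - 3]
        bc = c - b
        bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
        n = np.cross(b - a, bc)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        m = np.cross(n, bc)
        d_loc = np.stack([
            -_BOND * cos_t * np.ones(t),
            _BOND * sin_t * np.cos(phi),
            _BOND * sin_t * np.sin(phi),
        ], axis=-1)
        pos[:, k] = c + (d_loc[:, 0:1] * bc + d_loc[:, 1:2] * m + d_loc[:, 2:3] * n)
    return pos


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of vector v about unit axis."""
    a = np.radians(angle_deg)
    return (v * np.cos(a) + np.cross(axis, v) * np.sin(a)
            + axis * np.dot(axis, v) * (1 - np.cos(a)))


# lipid internal layout: index offsets within the 34-particle molecule
_LIPID_ROLES = (
    ["choline", "phosphate", "acceptor-oxygen", "acceptor-oxygen",
     "glycerol-carbon", "glycerol-carbon"]
    + [f"SN1-carbon-{k}" for k in range(1, 14)] + ["terminal-methyl"]
    + [f"SN2-carbon-{k}" for k in range(1, 14)] + ["terminal-methyl"]
)
_LIPID_WEIGHTS = np.array([50.0, 47.0, 8.0, 8.0, 8.0, 8.0]
                          + [8.0] * 13 + [9.0] + [8.0] * 13 + [9.0])


def synth_trajectory(spec: SyntheticTrajectorySpec) -> Tuple[Trajectory, TopologyRoles]:
    """Generate a toy bilayer trajectory with planted ground truth.

    See the module docstring for the construction.  Identical specs
    (including the seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_lipids
    F = spec.n_frames
    dt = spec.frame_interval
    T = 2 * L  # tails

    n_upper = (L + 1) // 2
    n_side = max(1, int(np.ceil(np.sqrt(max(n_upper, L - n_upper, 1)))))
    box_xy = n_side * spec.lipid_spacing
    box = np.array([box_xy, box_xy, spec.box_z])

    # --- lipid anchors: grid start + planted Brownian walk in xy ---------
    leaflet = np.where(np.arange(L) < n_upper, 1.0, -1.0)
    cell = np.arange(L) % n_upper if n_upper else np.arange(L)
    gx = (np.arange(L) - (leaflet < 0) * n_upper) % n_side
    gy = ((np.arange(L) - (leaflet < 0) * n_upper) // n_side) % n_side
    x0 = (gx + 0.5) * spec.lipid_spacing - box_xy / 2.0
    y0 = (gy + 0.5) * spec.lipid_spacing - box_xy / 2.0
    start = np.stack([x0, y0], axis=-1)  # (L, 2)
    if spec.lateral_d > 0 and F > 1:
        steps = rng.normal(0.0, np.sqrt(2.0 * spec.lateral_d * dt), (F - 1, L, 2))
        walk = np.concatenate([np.zeros((1, L, 2)), np.cumsum(steps, axis=0)])
    else:
        walk = np.zeros((F, L, 2))
    anchor = start[None] + walk  # (F, L, 2), unwrapped

    # --- head-group offsets (static in the lipid frame) ------------------
    s = leaflet[:, None]
    head_offsets = np.zeros((L, 6, 3))
    head_offsets[:, 0, 2] = 19.5 * leaflet   # choline
    head_offsets[:, 1, 2] = 17.0 * leaflet   # phosphate
    head_offsets[:, 2] = np.stack([np.full(L, 1.2), np.zeros(L), 16.0 * leaflet], -1)
    head_offsets[:, 3] = np.stack([np.full(L, -1.2), np.zeros(L), 16.0 * leaflet], -1)
    head_offsets[:, 4] = np.stack([np.zeros(L), np.full(L, 0.6), 14.0 * leaflet], -1)
    head_offsets[:, 5] = np.stack([np.zeros(L), np.full(L, -0.6), 14.0 * leaflet], -1)

    # --- planted tail dihedrals (static: rigid tails) ---------------------
    n_dih = T * 11
    n_gauche = int(round(spec.gauche_target * n_dih))
    is_gauche = np.zeros(n_dih, dtype=bool)
    is_gauche[:n_gauche] = True
    rng.shuffle(is_gauche)
    signs = rng.choice((-1.0, 1.0), n_dih)
    dihedrals = np.where(is_gauche, signs * np.radians(65.0), np.pi).reshape(T, 11)
    chains = _build_chains(dihedrals)  # (T, 14, 3), local, first atom at origin

    # --- tail rotational diffusion with planted ensemble KWW ACF ----------
    rp = spec.rot_params
    n_frozen = int(round(rp.b * T))
    n_c1 = int(round(rp.a1 * T))
    n_c2 = max(T - n_frozen - n_c1, 0)
    rates = np.concatenate([
        np.zeros(n_frozen),
        _kanter_stable(rp.beta1, n_c1, rng) / rp.tau1,
        _kanter_stable(rp.beta2, n_c2, rng) / rp.tau2,
    ])[:T]
    rng.shuffle(rates)
    decay = np.exp(-rates * dt)
    resample = decay < _G_MIN + 1e-9
    sigma = _step_sigma_for_decay(decay)

    quats = np.empty((F, T, 4))
    quats[0] = _random_quats(rng, (T,))
    if F > 1:
        rotvecs = rng.normal(size=(F - 1, T, 3)) * sigma[None, :, None]
        step_quats = _quat_from_rotvec(rotvecs)
        fresh = _random_quats(rng, (F - 1, int(resample.sum()))) if resample.any() else None
        for f in range(1, F):
            quats[f] = _quat_mul(step_quats[f - 1], quats[f - 1])
            if fresh is not None:
                quats[f, resample] = fresh[f - 1]
    rot = _quat_to_mat(quats)  # (F, T, 3, 3)

    tail_base = np.zeros((T, 3))
    tail_base[0::2, 0] = -1.5  # SN1
    tail_base[1::2, 0] = 1.5   # SN2
    tail_base[:, 2] = 12.5 * np.repeat(leaflet, 2)

    # --- assemble per-frame coordinates ----------------------------------
    anchor3 = np.concatenate([anchor, np.zeros((F, L, 1))], axis=-1)  # (F, L, 3)
    heads = anchor3[:, :, None, :] + head_offsets[None]  # (F, L, 6, 3)
    rotated = np.einsum("ftij,taj->ftai", rot, chains)  # (F, T, 14, 3)
    tails = rotated + (np.repeat(anchor3, 2, axis=1) + tail_base[None])[:, :, None, :]
    lipid_atoms = np.concatenate(
        [heads, tails.reshape(F, L, 28, 3)], axis=2
    ).reshape(F, L * 34, 3)

    blocks = [lipid_atoms]
    mol_id = list(np.repeat(np.arange(L), 34))
    mol_type = ["lipid"] * (L * 34)
    roles = list(_LIPID_ROLES) * L
    weights = list(np.tile(_LIPID_WEIGHTS, L))
    next_mol = L

    # --- planted H-bond waters (ride their lipid) -------------------------
    npl = spec.hbond_pairs_per_lipid
    if npl > 0 and L > 0:
        w_off = np.zeros((L, npl, 3, 3))
        for j in range(npl):
            az = 2.0 * np.pi * j / max(npl, 1)
            for i in range(L):
                acc = head_offsets[i, 2 + (j % 2)]
                e = np.array([0.45 * np.cos(az), 0.45 * np.sin(az), leaflet[i]])
                e /= np.linalg.norm(e)
                o_pos = acc + 3.2 * e
                axis = np.cross(e, np.array([1.0, 0.3, 0.2]))
                axis /= np.linalg.norm(axis)
                h1 = o_pos + 1.0 * _rotate_about(-e, axis, 10.0)
                h2 = o_pos + 1.0 * _rotate_about(-e, axis, 120.0)
                w_off[i, j] = np.stack([o_pos, h1, h2])
        waters = anchor3[:, :, None, None, :] + w_off[None]  # (F, L, npl, 3, 3)
        blocks.append(waters.reshape(F, L * npl * 3, 3))
        for i in range(L):
            for j in range(npl):
                mol_id += [next_mol] * 3
                next_mol += 1
                mol_type += ["water"] * 3
                roles += ["water-oxygen", "water-hydrogen", "water-hydrogen"]
                weights += [8.0, 1.0, 1.0]

    # --- bulk waters (static slab) ----------------------------------------
    n_bulk = max(spec.waters_per_lipid * L - npl * L, 0)
    if n_bulk > 0:
        zsign = rng.choice((-1.0, 1.0), n_bulk)
        o_xy = rng.uniform(-box_xy / 2, box_xy / 2, (n_bulk, 2))
        o_z = zsign * rng.uniform(24.0, spec.box_z / 2 - 0.3, n_bulk)
        o_pos = np.column_stack([o_xy, o_z])
        d1 = rng.normal(size=(n_bulk, 3))
        d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
        d2 = rng.normal(size=(n_bulk, 3))
        d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
        bulk = np.stack([o_pos, o_pos + d1, o_pos + d2], axis=1)  # (n_bulk, 3, 3)
        blocks.append(np.broadcast_to(bulk.reshape(1, -1, 3), (F, n_bulk * 3, 3)).copy())
        for _ in range(n_bulk):
            mol_id += [next_mol] * 3
            next_mol += 1
            mol_type += ["water"] * 3
            roles += ["water-oxygen", "water-hydrogen", "water-hydrogen"]
            weights += [8.0, 1.0, 1.0]

    # --- glucose: attached at the prescribed distance, rest in the slab ---
    if spec.n_glucose > 0:
        n_att = min(spec.n_glucose, L)
        glu = np.zeros((F, spec.n_glucose, 3))
        for g in range(n_att):
            e = np.array([0.62, 0.0, 0.78 * leaflet[g]])
            e /= np.linalg.norm(e)
            off = head_offsets[g, 1] + spec.glucose_distance * e
            glu[:, g] = anchor3[:, g] + off[None]
        for g in range(n_att, spec.n_glucose):
            zs = 1.0 if g % 2 == 0 else -1.0
            glu[:, g] = np.array([
                rng.uniform(-box_xy / 2, box_xy / 2),
                rng.uniform(-box_xy / 2, box_xy / 2),
                zs * rng.uniform(22.0, spec.box_z / 2 - 1.0),
            ])[None]
        blocks.append(glu)
        for _ in range(spec.n_glucose):
            mol_id.append(next_mol)
            next_mol += 1
            mol_type.append("glucose")
            roles.append("glucose-atom")
            weights.append(96.0)

    coords = np.concatenate(blocks, axis=1)
    coords = minimum_image(coords, box)  # wrap into [-box/2, box/2)

    times = dt * np.arange(F)
    boxes = np.broadcast_to(box, (F, 3)).copy()
    traj = Trajectory(times=times, boxes=boxes, coords=coords)
    topo = TopologyRoles(
        molecule_id=np.array(mol_id),
        molecule_type=np.array(mol_type, dtype=object),
        role=np.array(roles, dtype=object),
        electron_weight=np.array(weights),
    )
    return traj, topo


def synth_random_walk(
    d_xy: float,
    n_steps: int,
    dt: float,
    seed: int = 0,
    n_walkers: int = 1,
) -> Trajectory:
    """Planar Brownian walkers with planted diffusion constant ``d_xy``.

    Increments are Gaussian with variance 2·D·dt per axis; the box is huge
    so no wrapping occurs and the Einstein relation MSD = 4·D·t holds.
    """
    if d_xy < 0:
        raise ValueError("diffusion constant must be ≥ 0")
    if n_steps < 1 or n_walkers < 1:
        raise ValueError("invalid counts")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * d_xy * dt), (n_steps, n_walkers, 2))
    xy = np.concatenate([np.zeros((1, n_walkers, 2)), np.cumsum(steps, axis=0)])
    coords = np.concatenate([xy, np.zeros((n_steps + 1, n_walkers, 1))], axis=-1)
    times = dt * np.arange(n_steps + 1)
    boxes = np.full((n_steps + 1, 3), 1e6)
    return Trajectory(times=times, boxes=boxes, coords=coords)


def synth_acf_curve(
    params: StretchedExpParams,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AutocorrFunction:
    """Closed-form double-KWW curve on ``t_grid`` with additive noise."""
    t = np.asarray(t_grid, dtype=float)
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0 so that C(0) = 1")
    if abs(params.total_amplitude - 1.0) > 1e-6:
        raise ValueError("amplitudes must satisfy B + A1 + A2 = 1 at t = 0")
    c = params.evaluate(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c + rng.normal(0.0, noise_sd, c.shape)
    return AutocorrFunction(lag=t, c=c)
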