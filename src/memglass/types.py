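"""Shared data containers for the memglass pipeline.

Internal units are Å for lengths, ps for times and Å⁻¹ for wavevectors
throughout the package; unit conversion happens only at the I/O boundary
(:mod:`memglass.io`).

All containers are plain dataclasses around NumPy arrays with validation in
``__post_init__``; they carry no behaviour beyond small convenience
accessors, so every analysis step is an explicit function call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ReflectivityCurve",
    "BraggPeakSet",
    "FormFactorSet",
    "PhaseArray",
    "ElectronDensityProfile",
    "MembraneGeometry",
    "InPlaneMap",
    "AzimuthalProfile",
    "OrientationResult",
    "Trajectory",
    "TopologyRoles",
    "MetricPoint",
    "DistanceResolvedSeries",
    "RdfCurve",
    "FluctuationResult",
    "MsdCurve",
    "DiffusionResult",
    "AutocorrFunction",
    "StretchedExpParams",
]

# Electron counts used for united-atom density profiles.  Methylene united
# atoms carry 8 electrons and the terminal methyl 9; the head-group values
# lump each moiety (choline ~C5H13N, phosphate ~PO4) into one bead.
ELECTRON_WEIGHTS = {
    "choline": 50.0,
    "phosphate": 47.0,
    "acceptor-oxygen": 8.0,
    "glycerol-carbon": 8.0,
    "methylene": 8.0,
    "terminal-methyl": 9.0,
    "glucose-atom": 96.0,
    "water-oxygen": 8.0,
    "water-hydrogen": 1.0,
}


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class ReflectivityCurve:
    """One-dimensional out-of-plane reflectivity: intensity versus q_z."""

    q_z: np.ndarray  # Å⁻¹, strictly increasing
    intensity: np.ndarray  # counts, >= 0

    def __post_init__(self):
        self.q_z = _as_f64(self.q_z)
        self.intensity = _as_f64(self.intensity)
        if self.q_z.shape != self.intensity.shape or self.q_z.ndim != 1:
            raise ValueError("q_z and intensity must be 1-D arrays of equal length")
        if self.q_z.size == 0:
            raise ValueError("empty reflectivity curve")
        if np.any(np.diff(self.q_z) <= 0):
            raise ValueError("q_z must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class BraggPeakSet:
    """Integrated lamellar Bragg peaks with consecutive order assignment.

    Missing intermediate orders are recorded with ``intensity == 0`` at the
    position predicted by the fundamental spacing, so ``order`` always runs
    1..N without gaps.
    """

    order: np.ndarray  # int, 1..N consecutive
    position: np.ndarray  # q_n, Å⁻¹
    intensity: np.ndarray  # integrated, background-subtracted area
    width: np.ndarray  # Gaussian sigma, Å⁻¹

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=int)
        self.position = _as_f64(self.position)
        self.intensity = _as_f64(self.intensity)
        self.width = _as_f64(self.width)
        n = self.order.size
        if not np.array_equal(self.order, np.arange(1, n + 1)):
            raise ValueError("orders must be unique and consecutive from 1")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must increase with order")
        if np.any(self.intensity < 0):
            raise ValueError("integrated intensities must be non-negative")

    @property
    def n_orders(self) -> int:
        return int(self.order.size)


@dataclass
class FormFactorSet:
    """Form-factor magnitudes |F(q_n)| per order, plus the repeat distance.

    ``convention`` records how magnitudes were formed from integrated
    intensities: ``"product"`` for |F| = I_n·q_n (as used in the Fourier
    synthesis here) or ``"sqrt"`` for the Lorentz-style |F| = sqrt(I_n·q_n).
    """

    order: np.ndarray
    magnitude: np.ndarray
    d_z: float  # Å
    convention: str = "product"

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=int)
        self.magnitude = _as_f64(self.magnitude)
        if self.order.shape != self.magnitude.shape:
            raise ValueError("one magnitude per order required")
        if np.any(self.magnitude < 0):
            raise ValueError("|F| must be non-negative")
        if self.d_z <= 0:
            raise ValueError("d_z must be positive")
        if self.convention not in ("product", "sqrt"):
            raise ValueError("convention must be 'product' or 'sqrt'")

    @property
    def q(self) -> np.ndarray:
        """Peak positions 2πn/d_z implied by the order assignment."""
        return 2.0 * np.pi * self.order / self.d_z


@dataclass
class PhaseArray:
    """Sign assignment ν_n ∈ {−1, +1}, one per Bragg order."""

    signs: np.ndarray

    def __post_init__(self):
        self.signs = np.asarray(self.signs, dtype=int)
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("phases must be ±1")

    def __len__(self) -> int:
        return int(self.signs.size)


@dataclass
class ElectronDensityProfile:
    """Relative electron density on a uniform z grid across one repeat."""

    z: np.ndarray  # Å
    rho: np.ndarray  # relative (arbitrary) units
    component_label: str = "whole-membrane"

    def __post_init__(self):
        self.z = _as_f64(self.z)
        self.rho = _as_f64(self.rho)
        if self.z.shape != self.rho.shape or self.z.ndim != 1:
            raise ValueError("z and rho must be matching 1-D arrays")
        dz = np.diff(self.z)
        if self.z.size > 1 and not np.allclose(dz, dz[0], rtol=1e-8, atol=1e-10):
            raise ValueError("z grid must be uniform")

    @property
    def grid_step(self) -> float:
        return float(self.z[1] - self.z[0]) if self.z.size > 1 else 0.0


@dataclass
class MembraneGeometry:
    """Lamellar geometry: d_z = d_HH + d_w by construction."""

    d_z: float  # lamellar spacing, Å
    d_hh: float  # head-to-head membrane width, Å
    d_w: float  # hydration water layer, Å
    a_l: Optional[float] = None  # area per lipid chain, Å²

    def __post_init__(self):
        if not (self.d_z > self.d_hh > 0):
            raise ValueError("require d_z > d_HH > 0")
        if abs(self.d_w - (self.d_z - self.d_hh)) > 1e-9:
            raise ValueError("d_w must equal d_z - d_HH")


@dataclass
class InPlaneMap:
    """Gridded 2-D in-plane scattering intensity I(q_z, q_parallel)."""

    q_parallel: np.ndarray  # Å⁻¹, monotone
    q_z: np.ndarray  # Å⁻¹, monotone
    intensity: np.ndarray  # shape (len(q_z), len(q_parallel)), >= 0

    def __post_init__(self):
        self.q_parallel = _as_f64(self.q_parallel)
        self.q_z = _as_f64(self.q_z)
        self.intensity = _as_f64(self.intensity)
        if self.intensity.shape != (self.q_z.size, self.q_parallel.size):
            raise ValueError("intensity must have shape (len(q_z), len(q_parallel))")
        for g in (self.q_parallel, self.q_z):
            if np.any(np.diff(g) <= 0):
                raise ValueError("q grids must be strictly monotone increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class AzimuthalProfile:
    """Intensity binned over azimuthal angle φ (degrees, φ=0 along q_∥)."""

    phi: np.ndarray  # degrees, in [0, 90]
    intensity: np.ndarray

    def __post_init__(self):
        self.phi = _as_f64(self.phi)
        self.intensity = _as_f64(self.intensity)
        if self.phi.shape != self.intensity.shape:
            raise ValueError("phi and intensity must match")
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("phi must be strictly increasing")
        if np.any((self.phi < 0) | (self.phi > 90)):
            raise ValueError("phi must lie in [0, 90] degrees")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class OrientationResult:
    """Herman's orientation function H = (3⟨cos²φ⟩ − 1)/2."""

    h: float
    cos2_mean: float

    def __post_init__(self):
        if not (0.0 <= self.cos2_mean <= 1.0):
            raise ValueError("⟨cos²φ⟩ must lie in [0, 1]")
        if abs(self.h - (1.5 * self.cos2_mean - 0.5)) > 1e-12:
            raise ValueError("H must equal 1.5⟨cos²φ⟩ − 0.5")


@dataclass
class Trajectory:
    """Time-ordered particle coordinates with orthorhombic periodic boxes."""

    times: np.ndarray  # ps, strictly increasing, shape (F,)
    boxes: np.ndarray  # Å, shape (F, 3), > 0
    coords: np.ndarray  # Å, shape (F, N, 3)

    def __post_init__(self):
        self.times = _as_f64(self.times)
        self.boxes = _as_f64(self.boxes)
        self.coords = _as_f64(self.coords)
        f = self.times.size
        if self.boxes.shape != (f, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if self.coords.ndim != 3 or self.coords.shape[0] != f or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if f > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.boxes <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def n_particles(self) -> int:
        return int(self.coords.shape[1])

    @property
    def dt(self) -> float:
        """Frame interval in ps (assumes a uniform cadence)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


@dataclass
class TopologyRoles:
    """Role map assigning every particle to a molecule and a chemical role.

    Within a lipid molecule the particle layout is contiguous and ordered
    (head beads, then SN1 carbons 1..13 + terminal methyl, then SN2); the
    tail accessors below rely on that ordering, which both the synthetic
    generator and the role-map loader guarantee.
    """

    molecule_id: np.ndarray  # int per particle
    molecule_type: np.ndarray  # 'lipid' | 'glucose' | 'water'
    role: np.ndarray  # role label per particle
    electron_weight: np.ndarray  # electrons per united atom

    def __post_init__(self):
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.molecule_type = np.asarray(self.molecule_type, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        self.electron_weight = _as_f64(self.electron_weight)
        n = self.molecule_id.size
        for arr in (self.molecule_type, self.role, self.electron_weight):
            if arr.shape != (n,):
                raise ValueError("all role-map fields must have equal length")

    @property
    def n_particles(self) -> int:
        return int(self.molecule_id.size)

    def indices(self, role: Optional[str] = None, molecule_type: Optional[str] = None) -> np.ndarray:
        mask = np.ones(self.n_particles, dtype=bool)
        if role is not None:
            mask &= self.role == role
        if molecule_type is not None:
            mask &= self.molecule_type == molecule_type
        return np.flatnonzero(mask)

    @property
    def lipid_ids(self) -> np.ndarray:
        return np.unique(self.molecule_id[self.molecule_type == "lipid"])

    def molecule_indices(self, mol_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_id == mol_id)

    def tail_carbons(self, chain: str) -> np.ndarray:
        """Particle indices of the 14 carbons of ``chain`` per lipid.

        Returns an ``(n_lipids, 14)`` index array ordered carbonyl-proximal
        to terminal methyl; rows follow ``lipid_ids`` order.
        """
        if chain not in ("SN1", "SN2"):
            raise ValueError("chain must be 'SN1' or 'SN2'")
        rows = []
        for lid in self.lipid_ids:
            idx = self.molecule_indices(lid)
            roles = self.role[idx]
            carbons = [idx[i] for i, r in enumerate(roles) if str(r).startswith(chain + "-carbon-")]
            carbons.sort(key=lambda p: int(str(self.role[p]).rsplit("-", 1)[1]))
            if len(carbons) == 0:
                raise ValueError(f"lipid {lid} has no {chain} carbons")
            # the terminal methyl immediately follows the last indexed carbon
            term = carbons[-1] + 1
            if term >= self.n_particles or self.role[term] != "terminal-methyl":
                raise ValueError(f"lipid {lid}: no terminal methyl after {chain} chain")
            rows.append(carbons + [term])
        out = np.asarray(rows, dtype=int)
        return out

    def validate(self) -> None:
        """Check the structural invariants of the role map."""
        for lid in self.lipid_ids:
            idx = self.molecule_indices(lid)
            roles = self.role[idx]
            if np.sum(roles == "phosphate") != 1:
                raise ValueError(f"lipid {lid} must have exactly one phosphate")
            for chain in ("SN1", "SN2"):
                if not any(str(r).startswith(chain + "-carbon-") for r in roles):
                    raise ValueError(f"lipid {lid} missing {chain} chain")
        methylene = [
            i for i, r in enumerate(self.role) if str(r).startswith(("SN1-carbon-", "SN2-carbon-"))
        ]
        if methylene and not np.allclose(self.electron_weight[methylene], 8.0):
            raise ValueError("methylene united atoms must carry 8 electrons")
        term = self.indices(role="terminal-methyl")
        if term.size and not np.allclose(self.electron_weight[term], 9.0):
            raise ValueError("terminal methyls must carry 9 electrons")


@dataclass
class MetricPoint:
    """A single distance-resolved metric value with its uncertainty."""

    value: float
    stderr: float
    n_frames: int
    n_contributing: float  # mean number of lipids contributing per frame
    defined: bool = True


@dataclass
class DistanceResolvedSeries:
    """A metric evaluated at increasing cutoff radii from glucose."""

    radii: np.ndarray  # Å
    value: np.ndarray
    stderr: np.ndarray
    n_contributing: np.ndarray

    def __post_init__(self):
        self.radii = _as_f64(self.radii)
        self.value = _as_f64(self.value)
        self.stderr = _as_f64(self.stderr)
        self.n_contributing = _as_f64(self.n_contributing)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be increasing")
        if np.any(np.diff(self.n_contributing) < -1e-9):
            raise ValueError("n_contributing must be non-decreasing with radius")


@dataclass
class RdfCurve:
    """Radial distribution function g_AB(r) on uniform shells."""

    r: np.ndarray  # bin centers, Å
    g: np.ndarray
    bin_width: float
    pair_labels: tuple = ("A", "B")

    def __post_init__(self):
        self.r = _as_f64(self.r)
        self.g = _as_f64(self.g)
        if self.r.shape != self.g.shape:
            raise ValueError("r and g must match")
        if np.any(self.g < -1e-12):
            raise ValueError("g(r) must be non-negative")


@dataclass
class FluctuationResult:
    """Phosphate-to-carbon distance fluctuation, normalized and raw."""

    normalized: float  # mean over lipids of std/mean of the distance
    raw: float  # mean over lipids of the distance std, Å
    mean_distance: float  # mean over lipids of the mean distance, Å


@dataclass
class MsdCurve:
    """Lateral mean-square displacement versus lag time."""

    lag: np.ndarray  # ps
    msd: np.ndarray  # Å²
    n_origins: np.ndarray

    def __post_init__(self):
        self.lag = _as_f64(self.lag)
        self.msd = _as_f64(self.msd)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be increasing")
        if abs(self.msd[0]) > 1e-9 or abs(self.lag[0]) > 1e-12:
            raise ValueError("MSD must start at lag 0 with msd 0")


@dataclass
class DiffusionResult:
    """Einstein lateral diffusion constant from an MSD window fit."""

    d_xy: float  # Å²/ps
    fit_window: tuple  # (t_min, t_max), ps
    fit_r2: float


@dataclass
class AutocorrFunction:
    """Orientational autocorrelation C(t) of tail-triplet normal vectors."""

    lag: np.ndarray  # ps
    c: np.ndarray  # dimensionless, C(0) = 1
    carbon_window: Optional[int] = None

    def __post_init__(self):
        self.lag = _as_f64(self.lag)
        self.c = _as_f64(self.c)
        if self.lag.shape != self.c.shape:
            raise ValueError("lag and c must match")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be increasing")


@dataclass
class StretchedExpParams:
    """Parameters of C(t) = B + A₁e^{−(t/τ₁)^β₁} + A₂e^{−(t/τ₂)^β₂}."""

    b: float
    a1: float
    tau1: float  # ps
    beta1: float
    a2: float
    tau2: float  # ps
    beta2: float
    r2: Optional[float] = None
    converged: bool = True

    def __post_init__(self):
        for beta in (self.beta1, self.beta2):
            if not (0.0 < beta <= 1.0):
                raise ValueError("stretching exponents must lie in (0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("relaxation times must be positive")

    @property
    def total_amplitude(self) -> float:
        return self.b + self.a1 + self.a2

    def evaluate(self, t) -> np.ndarray:
        """Closed-form C(t) with decaying exponents."""
        t = _as_f64(t)
        return (
            self.b
            + self.a1 * np.exp(-np.power(t / self.tau1, self.beta1))
            + self.a2 * np.exp(-np.power(t / self.tau2, self.beta2))
        )
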