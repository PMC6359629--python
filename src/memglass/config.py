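"""Pipeline configuration: every cutoff and convention in one place.

Defaults are the values the analysis was designed around: geometric
hydrogen-bond cutoffs of 3.5 Å and 30°, RDF shells of 0.02 Å with score
positions 4.5/5.5 Å, a 120° gauche window, five-block error estimation,
a 50 ns analysis span, KWW relaxation-time bounds of 1–100 ps and
0.1–10 ns, the product form-factor convention and the √3 hexagonal
area-per-chain formula.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Tuple

import yaml


@dataclass
class PipelineConfig:
    # hydrogen bonding
    hbond_dist: float = 3.5  # Å donor–acceptor cutoff
    hbond_angle: float = 30.0  # degrees H–donor–acceptor cutoff
    hbond_stride: int = 50  # frames between H-bond samples
    # radial distribution function
    rdf_bin: float = 0.02  # Å shell thickness
    rdf_hydrated_pos: float = 5.5  # Å (hydrated first-peak position)
    rdf_dehydrated_pos: float = 4.5  # Å (dehydrated first-peak position)
    # dihedrals
    gauche_window: float = 120.0  # degrees: gauche iff |φ| < window
    dihedral_stride: int = 25  # frames between dihedral samples
    # error estimation & analysis span
    n_blocks: int = 5
    analysis_span_ns: float = 50.0
    # diffusion
    msd_fit_window_ns: Tuple[float, float] = (20.0, 160.0)
    # KWW fitting bounds (ps)
    tau1_bounds: Tuple[float, float] = (1.0, 100.0)
    tau2_bounds: Tuple[float, float] = (100.0, 10000.0)
    # X-ray conventions
    ff_convention: str = "product"  # 'product' (|F| = I·q) or 'sqrt'
    al_formula: str = "sqrt3"  # area-per-chain denominator: √3 or 3
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("msd_fit_window_ns", "tau1_bounds", "tau2_bounds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("msd_fit_window_ns", "tau1_bounds", "tau2_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
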