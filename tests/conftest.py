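"""Shared fixtures: session-scoped synthetic datasets reused across tests."""

import numpy as np
import pytest

import memglass as mg


@pytest.fixture(scope="session")
def model_spec():
    return mg.ModelBilayerSpec()


@pytest.fixture(scope="session")
def xray_chain(model_spec):
    """Full noiseless X-ray analysis chain on the default model bilayer."""
    edp = mg.model_edp(model_spec)
    curve = mg.synth_reflectivity(edp, model_spec)
    peaks = mg.find_peaks(curve, max_order=model_spec.n_orders)
    d_z = mg.lamellar_spacing(peaks)
    ffs = mg.compute_form_factors(peaks)
    phases = mg.determine_phases(ffs)
    recon = mg.reconstruct_edp(ffs, phases)
    return dict(edp=edp, curve=curve, peaks=peaks, d_z=d_z, ffs=ffs,
                phases=phases, recon=recon)


@pytest.fixture(scope="session")
def small_traj():
    """Small planted bilayer: 32 lipids, glucose, waters, gauche 0.30."""
    spec = mg.SyntheticTrajectorySpec(
        n_lipids=32, n_glucose=2, waters_per_lipid=4, hbond_pairs_per_lipid=2,
        gauche_target=0.30, n_frames=100, frame_interval=4.0, seed=1,
    )
    traj, roles = mg.synth_trajectory(spec)
    return spec, traj, roles


@pytest.fixture(scope="session")
def dyn_traj():
    """Dynamics-focused trajectory: 64 lipids, 2000 frames at 5 ps."""
    spec = mg.SyntheticTrajectorySpec(
        n_lipids=64, n_glucose=0, waters_per_lipid=0, hbond_pairs_per_lipid=0,
        n_frames=2000, frame_interval=5.0, seed=11,
    )
    traj, roles = mg.synth_trajectory(spec)
    return spec, traj, roles


def make_tail_only_system(dihedrals_deg):
    """Single-frame system of SN1-only 'lipids', one planted dihedral each.

    Each lipid carries a 14-carbon chain whose 11 dihedrals all equal the
    lipid's entry of ``dihedrals_deg``; useful for classification tests.
    """
    from memglass.synthetic import _build_chains

    phi = np.radians(np.asarray(dihedrals_deg, dtype=float))
    t = phi.size
    chains = _build_chains(np.repeat(phi[:, None], 11, axis=1))
    coords = chains + np.arange(t)[:, None, None] * np.array([50.0, 0, 0])
    coords = coords.reshape(1, t * 14, 3)
    roles = mg.TopologyRoles(
        molecule_id=np.repeat(np.arange(t), 14),
        molecule_type=np.array(["lipid"] * (t * 14), dtype=object),
        role=np.array(([f"SN1-carbon-{k}" for k in range(1, 14)] + ["terminal-methyl"]) * t,
                      dtype=object),
        electron_weight=np.array(([8.0] * 13 + [9.0]) * t),
    )
    traj = mg.Trajectory(times=np.array([0.0]), boxes=np.array([[1e5, 1e5, 1e5]]),
                         coords=coords)
    return traj, roles
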