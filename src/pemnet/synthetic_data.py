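"""Synthetic trajectory ensembles with planted metastable structure.

The generator emulates the statistical structure the analysis assumes —
not the physics of any real molecule.  Latent conformational states
evolve as a lag-1 Markov chain; each state emits a small set of dihedral
angles from von Mises distributions around state-specific centers (the
exact circular analogue of Gaussian emissions); molecular properties are
smooth periodic functions of the dihedrals (truncated Fourier surfaces)
plus additive Gaussian noise.  Per-atom charges are independent Fourier
surfaces whose coefficients are constrained so the net charge is exactly
the configured total at every geometry, which makes charge
renormalisation exactly testable.

Ground-truth state labels, the planted transition matrix and a noiseless
property oracle are carried alongside the data, so clustering recovery,
transition-matrix estimation and prediction skill can all be scored
against a known truth.

Geometries: when Cartesian frames are needed (for the XYZ round trip)
the sampled angles are realised as the backbone torsions of a toy chain
molecule of p + 3 atoms, placed by natural extension reference frame
(NeRF) internal-to-Cartesian construction with fixed 1.5 A bonds and
109.47 degree angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .descriptors import DihedralSpec, Frame, Trajectory, wrap_angle
from .tsf_network import stationary_distribution

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "simulate_trajectories",
    "property_oracle",
    "property_gradient",
    "charge_oracle",
    "make_benchmark",
    "angles_to_chain_coords",
    "chain_dihedral_specs",
    "PRESETS",
]

_BOND_LENGTH = 1.5        # A, toy chain
_BOND_ANGLE = 109.47      # degrees


@dataclass
class SyntheticSpec:
    """Full generative description of a synthetic ensemble."""

    k_states: int
    transition_matrix: np.ndarray       # (k, k) row-stochastic
    state_centers: np.ndarray           # (k, p) degrees
    state_kappa: np.ndarray             # (k,) von Mises concentration
    property_coeffs: tuple[float, np.ndarray, np.ndarray]
    # (a0, b[(p,)], c[(p,)]): T*(X) = a0 + sum_m b_m cos th_m + c_m sin th_m
    noise_sigma: float = 0.0            # property units
    charge_coeffs: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    # (a0[(A,)], b[(A,p)], c[(A,p)]) with sum_a b = sum_a c = 0 per column
    net_charge: float = 0.0
    timestep: float = 0.5               # fs

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.state_centers = np.asarray(self.state_centers, float)
        self.state_kappa = np.broadcast_to(
            np.asarray(self.state_kappa, float), (self.k_states,)
        ).copy()
        t = self.transition_matrix
        if t.shape != (self.k_states, self.k_states):
            raise ValueError("transition matrix shape mismatch")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix must be row-stochastic")
        if np.any(self.state_kappa <= 0):
            raise ValueError("kappa must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def p(self) -> int:
        return self.state_centers.shape[1]


@dataclass
class SyntheticDataset:
    """Generated ensemble: descriptors, latent labels, properties, charges."""

    spec: SyntheticSpec
    descriptors: list[np.ndarray]       # per traj (n_frames, p) degrees
    states: list[np.ndarray]            # per traj (n_frames,) ground truth
    properties: list[np.ndarray]        # per traj (n_frames,) scalar
    charges: list[np.ndarray] | None    # per traj (n_frames, A)
    seed: int

    @property
    def n_traj(self) -> int:
        return len(self.descriptors)

    def all_descriptors(self) -> np.ndarray:
        return np.concatenate(self.descriptors)

    def all_states(self) -> np.ndarray:
        return np.concatenate(self.states)

    def all_properties(self) -> np.ndarray:
        return np.concatenate(self.properties)

    def all_charges(self) -> np.ndarray:
        if self.charges is None:
            raise ValueError("dataset carries no charges")
        return np.concatenate(self.charges)

    def to_trajectory(self, i: int) -> Trajectory:
        """Realise trajectory ``i`` as Cartesian frames of the toy chain."""
        ang = self.descriptors[i]
        frames = []
        for t, row in enumerate(ang):
            coords = angles_to_chain_coords(row)
            frames.append(Frame(
                atom_symbols=["C"] * coords.shape[0],
                coords=coords,
                time=t * self.spec.timestep,
                properties={"excitation_energy": float(self.properties[i][t])},
                charges=None if self.charges is None
                else self.charges[i][t].copy(),
            ))
        return Trajectory(f"synth_{i:03d}", frames, timestep=self.spec.timestep)


# ---------------------------------------------------------------------------
# Property surfaces
# ---------------------------------------------------------------------------

def property_oracle(spec: SyntheticSpec, x) -> float | np.ndarray:
    """Noiseless planted property T*(X) at descriptor vector(s) x (degrees).

    T*(X) = a0 + sum_m (b_m cos th_m + c_m sin th_m): smooth and
    360-degree periodic in every dihedral by construction.
    """
    a0, b, c = spec.property_coeffs
    th = np.radians(np.asarray(x, dtype=float))
    val = a0 + np.cos(th) @ np.asarray(b, float) + np.sin(th) @ np.asarray(c, float)
    return float(val) if np.ndim(x) == 1 else val


def property_gradient(spec: SyntheticSpec, x) -> np.ndarray:
    """Gradient of T* with respect to the descriptors, per degree."""
    a0, b, c = spec.property_coeffs
    th = np.radians(np.asarray(x, dtype=float))
    return (np.radians(1.0)
            * (-np.asarray(b, float) * np.sin(th)
               + np.asarray(c, float) * np.cos(th)))


def charge_oracle(spec: SyntheticSpec, x) -> np.ndarray:
    """Noiseless per-atom charges at x; sums exactly to spec.net_charge."""
    if spec.charge_coeffs is None:
        raise ValueError("spec has no charge coefficients")
    a0, b, c = spec.charge_coeffs
    th = np.radians(np.asarray(x, dtype=float))
    return a0 + b @ np.cos(th) + c @ np.sin(th)


def _make_charge_coeffs(
    rng: np.random.Generator, n_atoms: int, p: int,
    net_charge: float, scale: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random per-atom Fourier coefficients with exact net-charge constraint.

    Column sums of the harmonic coefficients are removed, so the
    geometry-dependent part cancels over atoms and the total charge is
    ``net_charge`` at every geometry.
    """
    a0 = rng.normal(0.0, scale, size=n_atoms)
    a0 += (net_charge - a0.sum()) / n_atoms
    b = rng.normal(0.0, scale, size=(n_atoms, p))
    c = rng.normal(0.0, scale, size=(n_atoms, p))
    b -= b.mean(axis=0, keepdims=True)
    c -= c.mean(axis=0, keepdims=True)
    return a0, b, c


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_trajectories(
    spec: SyntheticSpec, n_traj: int, n_frames: int, seed: int = 0
) -> SyntheticDataset:
    """Simulate an ensemble of uncoupled state-chain trajectories.

    Initial states are drawn from the chain's stationary distribution;
    states then evolve by the transition matrix, each frame emitting
    angles von Mises-distributed around the current state's centers and a
    property value T*(X) + N(0, noise_sigma).  Fully reproducible per
    seed.
    """
    if n_traj < 1 or n_frames < 1:
        raise ValueError("n_traj and n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(spec.transition_matrix)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    k, p = spec.k_states, spec.p
    descriptors, states, props, charges = [], [], [], []
    for _ in range(n_traj):
        s = np.empty(n_frames, dtype=int)
        s[0] = rng.choice(k, p=pi)
        u = rng.random(n_frames - 1)
        for t in range(1, n_frames):
            s[t] = np.searchsorted(cum[s[t - 1]], u[t - 1], side="right")
        centers = spec.state_centers[s]                       # (n_frames, p)
        kappa = spec.state_kappa[s][:, None]
        ang = np.degrees(
            rng.vonmises(np.radians(centers), kappa)
        )
        ang = wrap_angle(ang)
        val = property_oracle(spec, ang)
        if spec.noise_sigma > 0:
            val = val + rng.normal(0.0, spec.noise_sigma, size=n_frames)
        descriptors.append(ang)
        states.append(s)
        props.append(np.asarray(val, float))
        if spec.charge_coeffs is not None:
            qa0, qb, qc = spec.charge_coeffs
            th = np.radians(ang)
            charges.append(qa0 + np.cos(th) @ qb.T + np.sin(th) @ qc.T)
    return SyntheticDataset(
        spec=spec, descriptors=descriptors, states=states,
        properties=props, charges=charges if spec.charge_coeffs is not None else None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Internal -> Cartesian (toy chain)
# ---------------------------------------------------------------------------

def chain_dihedral_specs(p: int) -> list[DihedralSpec]:
    """Backbone torsion specs of the toy (p + 3)-atom chain."""
    return [
        DihedralSpec(f"phi_{m + 1}", (m, m + 1, m + 2, m + 3))
        for m in range(p)
    ]


def angles_to_chain_coords(
    torsions_deg,
    bond_length: float = _BOND_LENGTH,
    bond_angle_deg: float = _BOND_ANGLE,
) -> np.ndarray:
    """Coordinates of a chain whose backbone torsions equal ``torsions_deg``.

    NeRF placement: atoms 0..2 fixed (origin, x-axis, xy-plane); atom
    m + 3 is placed with the given bond length, bond angle and torsion
    m.  The torsion convention matches :func:`pemnet.descriptors.dihedral_angle`,
    so computing descriptors on the result recovers the inputs.
    """
    tors = np.atleast_1d(np.asarray(torsions_deg, dtype=float))
    p = len(tors)
    theta = np.radians(bond_angle_deg)
    coords = np.empty((p + 3, 3))
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (bond_length, 0.0, 0.0)
    coords[2] = coords[1] + bond_length * np.array(
        (np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0)
    )
    for m in range(p):
        a, b, c = coords[m], coords[m + 1], coords[m + 2]
        phi = np.radians(tors[m])
        d2 = bond_length * np.array((
            -np.cos(theta),
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
        ))
        bc = c - b
        bc /= np.linalg.norm(bc)
        n = np.cross(b - a, bc)
        n /= np.linalg.norm(n)
        m_frame = np.column_stack((bc, np.cross(n, bc), n))
        coords[m + 3] = c + m_frame @ d2
    return coords


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

def _ring_chain(k: int, stay: float = 0.88) -> np.ndarray:
    """Row-stochastic matrix: stay prob + hops to ring neighbours."""
    hop = (1.0 - stay) / 2.0
    t = np.eye(k) * stay
    for i in range(k):
        t[i, (i + 1) % k] += hop
        t[i, (i - 1) % k] += hop
    return t


def _two_state_easy(seed: int) -> SyntheticSpec:
    rng = np.random.default_rng(seed + 101)
    return SyntheticSpec(
        k_states=2,
        transition_matrix=np.array([[0.95, 0.05], [0.05, 0.95]]),
        state_centers=np.array([[-60.0, 60.0], [60.0, -60.0]]),
        state_kappa=np.array([50.0, 50.0]),
        property_coeffs=(2.4, np.array([0.5, -0.3]), np.array([0.2, 0.4])),
        noise_sigma=0.02,
        charge_coeffs=_make_charge_coeffs(rng, n_atoms=5, p=2, net_charge=0.0),
        net_charge=0.0,
    )


_MIRROR_BASE = np.array([
    [30.0, 60.0, 90.0],
    [90.0, 120.0, 30.0],
    [150.0, 30.0, 60.0],
    [60.0, 150.0, 120.0],
    [120.0, 90.0, 150.0],
    [30.0, 120.0, 150.0],
])


def _twelve_state_mirror(seed: int) -> SyntheticSpec:
    # 6 base states and their elementwise negations: i / i' mirror pairs
    centers = np.concatenate([_MIRROR_BASE, -_MIRROR_BASE])
    rng = np.random.default_rng(seed + 202)
    return SyntheticSpec(
        k_states=12,
        transition_matrix=_ring_chain(12, stay=0.88),
        state_centers=centers,
        state_kappa=np.full(12, 50.0),
        property_coeffs=(
            2.34,
            np.array([0.4, -0.25, 0.3]),
            np.array([0.15, 0.35, -0.2]),
        ),
        noise_sigma=0.02,
        charge_coeffs=_make_charge_coeffs(rng, n_atoms=6, p=3, net_charge=0.0),
        net_charge=0.0,
    )


def _noisy_overlap(seed: int) -> SyntheticSpec:
    rng = np.random.default_rng(seed + 303)
    return SyntheticSpec(
        k_states=3,
        transition_matrix=_ring_chain(3, stay=0.8),
        state_centers=np.array([[-40.0, 0.0], [0.0, 45.0], [40.0, -45.0]]),
        state_kappa=np.full(3, 8.0),
        property_coeffs=(2.0, np.array([0.6, 0.2]), np.array([-0.3, 0.5])),
        noise_sigma=0.2,
        charge_coeffs=_make_charge_coeffs(rng, n_atoms=5, p=2, net_charge=0.0),
        net_charge=0.0,
    )


PRESETS: dict[str, Callable[[int], SyntheticSpec]] = {
    "two_state_easy": _two_state_easy,
    "twelve_state_mirror": _twelve_state_mirror,
    "noisy_overlap": _noisy_overlap,
}


def make_benchmark(
    preset_name: str,
    n_traj: int = 20,
    n_frames: int = 400,
    seed: int = 0,
) -> tuple[SyntheticDataset, dict]:
    """Generate a preset benchmark with machine-readable expectations.

    Returns (dataset, expectations).  Expectations carry the planted
    cluster count, labels, transition matrix, mirror-pair count (where
    applicable) and a handle to the noiseless property oracle.
    """
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    spec = PRESETS[preset_name](seed)
    ds = simulate_trajectories(spec, n_traj=n_traj, n_frames=n_frames, seed=seed)
    expect = {
        "preset": preset_name,
        "k": spec.k_states,
        "labels": ds.all_states(),
        "transition_matrix": spec.transition_matrix.copy(),
        "stationary": stationary_distribution(spec.transition_matrix),
        "oracle": lambda x: property_oracle(spec, x),
        "noise_sigma": spec.noise_sigma,
        "ari_target": 1.0 if preset_name == "two_state_easy" else 0.95,
    }
    if preset_name == "twelve_state_mirror":
        expect["n_merged"] = 6
    return ds, expect
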