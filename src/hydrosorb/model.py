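"""Coarse-grained physical model: box, species, topology, configuration, energies.

The model is a single-site bead representation of an amorphous hydrated
matrix.  Matrix beads come in hydrophilic and hydrophobic flavours that differ
only in their water ``affinity`` multiplier; water is a single Lennard-Jones
site.  Chain bonds (backbone analog) and non-local crosslinks (disulfide
analog) are harmonic springs.  Everything runs in reduced LJ units
(sigma = epsilon = k_B = 1); particle masses carry gram-per-mole scale values
solely for the hydration-level (g water / g dry matrix) bookkeeping.

One molecule at a time may be partially coupled with parameter ``lam`` in
[0, 1]: its pair sum is multiplied by ``lam`` and evaluated through a
separation-shifted soft-core radial form that is finite at zero separation for
``lam < 1`` and reduces exactly to the plain potential at ``lam == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

__all__ = [
    "Box", "Species", "HarmonicBonds", "Tethers", "Topology", "Configuration",
    "EnergyReport", "minimum_image", "pair_energy", "lambda_scaled_energy",
    "delta_energy_remove", "hydration_level",
    "WATER_SPECIES", "HYDROPHILIC_SPECIES", "HYDROPHOBIC_SPECIES",
    "DEFAULT_CUTOFF",
]

#: default interaction cutoff in units of sigma (truncated, no tail correction)
DEFAULT_CUTOFF = 3.0


@dataclass
class Box:
    """Orthorhombic simulation box with per-axis periodicity flags."""

    lengths: np.ndarray
    periodic: np.ndarray = None

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=np.float64).reshape(3)
        if np.any(self.lengths <= 0):
            raise ValueError("box lengths must be positive")
        if self.periodic is None:
            self.periodic = np.ones(3, dtype=bool)
        else:
            self.periodic = np.asarray(self.periodic, dtype=bool).reshape(3)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def fully_periodic(self) -> bool:
        return bool(np.all(self.periodic))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into [0, L) along periodic axes."""
        pos = np.array(positions, dtype=np.float64, copy=True)
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                pos[..., ax] -= L * np.floor(pos[..., ax] / L)
        return pos

    def minimum_image(self, displacement: np.ndarray) -> np.ndarray:
        return minimum_image(displacement, self)


def minimum_image(displacement: np.ndarray, box: Box) -> np.ndarray:
    """Nearest periodic image of a displacement vector.

    Along each periodic axis the returned component lies in [-L/2, L/2);
    non-periodic components pass through unchanged.
    """
    d = np.array(displacement, dtype=np.float64, copy=True)
    for ax in range(3):
        if box.periodic[ax]:
            L = box.lengths[ax]
            d[..., ax] -= L * np.floor(d[..., ax] / L + 0.5)
    return d


@dataclass
class Species:
    """Interaction parameters for one particle class.

    ``affinity`` multiplies the water-bead well depth (hydrophilic > 1,
    hydrophobic < 1, water itself 1).  ``sasa_radius`` is the hard radius used
    by the surface-area analysis; it defaults to sigma/2.
    """

    name: str
    mass: float
    epsilon: float = 1.0
    sigma: float = 1.0
    affinity: float = 1.0
    sasa_radius: float = None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0 or self.affinity < 0:
            raise ValueError("epsilon and affinity must be non-negative")
        if self.sasa_radius is None:
            self.sasa_radius = 0.5 * self.sigma


WATER_SPECIES = Species("W", mass=18.0, epsilon=1.0, sigma=1.0, affinity=1.0)
HYDROPHILIC_SPECIES = Species("P", mass=110.0, epsilon=1.0, sigma=1.0, affinity=2.0)
HYDROPHOBIC_SPECIES = Species("H", mass=110.0, epsilon=1.0, sigma=1.0, affinity=0.5)


class HarmonicBonds:
    """A set of harmonic springs between particle pairs."""

    def __init__(self, pairs=None, k=None, r0=None):
        if pairs is None:
            pairs = np.zeros((0, 2), dtype=np.int64)
        self.pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        n = len(self.pairs)
        self.k = np.broadcast_to(np.asarray(
            k if k is not None else np.zeros(0), dtype=np.float64), (n,)).copy()
        self.r0 = np.broadcast_to(np.asarray(
            r0 if r0 is not None else np.zeros(0), dtype=np.float64), (n,)).copy()
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-bonds are not allowed")

    def __len__(self):
        return len(self.pairs)


class Tethers:
    """Optional per-bead harmonic anchors (spring to a fixed point)."""

    def __init__(self, indices=None, k=None, anchors=None):
        if indices is None:
            indices = np.zeros(0, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int64).reshape(-1)
        n = len(self.indices)
        self.k = np.broadcast_to(np.asarray(
            k if k is not None else np.zeros(0), dtype=np.float64), (n,)).copy()
        self.anchors = np.asarray(
            anchors if anchors is not None else np.zeros((0, 3)),
            dtype=np.float64).reshape(-1, 3)

    def __len__(self):
        return len(self.indices)


@dataclass
class Topology:
    """Bonded structure of the matrix: chain bonds, crosslinks, tethers."""

    chain_bonds: HarmonicBonds = field(default_factory=HarmonicBonds)
    crosslinks: HarmonicBonds = field(default_factory=HarmonicBonds)
    tethers: Tethers = field(default_factory=Tethers)

    def validate_crosslink_locality(self, chain_index: np.ndarray,
                                    chain_position: np.ndarray) -> None:
        """Check that crosslinks connect only sequentially distant beads.

        A crosslink qualifies as non-local when its beads sit on different
        chains or more than two positions apart along the same chain.
        """
        for i, j in self.crosslinks.pairs:
            if chain_index[i] == chain_index[j] and \
                    abs(int(chain_position[i]) - int(chain_position[j])) <= 2:
                raise ValueError(
                    f"crosslink ({i},{j}) is local along its chain")

    def all_bond_indices(self) -> np.ndarray:
        if len(self.chain_bonds) == 0 and len(self.crosslinks) == 0:
            return np.zeros((0, 2), dtype=np.int64)
        return np.vstack([self.chain_bonds.pairs, self.crosslinks.pairs])


@dataclass
class EnergyReport:
    """Additive decomposition of the configurational energy."""

    total: float
    pair: float
    bonded: float
    coupling_part: float


class Configuration:
    """Particle positions, species, topology and coupling state.

    Invariants: positions wrapped into [0, L); at most one particle carries a
    coupling parameter lam < 1; water particles have no bonds, crosslinks or
    tethers.  The sorption engine additionally keeps matrix beads at the low
    indices with all waters after them, so bond indices stay valid across
    water insertion/removal.
    """

    def __init__(self, positions, species_ids, is_water, topology, box,
                 species, coupling=None, residue_ids=None, wrap=True):
        self.box = box
        pos = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        self.positions = box.wrap(pos) if wrap else pos.copy()
        self.species_ids = np.asarray(species_ids, dtype=np.int64).reshape(-1)
        self.is_water = np.asarray(is_water, dtype=bool).reshape(-1)
        self.topology = topology
        self.species = list(species)
        self.coupling = coupling
        self.residue_ids = (None if residue_ids is None
                            else np.asarray(residue_ids, dtype=np.int64))
        n = len(self.positions)
        if len(self.species_ids) != n or len(self.is_water) != n:
            raise ValueError("per-particle arrays must have equal length")
        if coupling is not None:
            idx, lam = coupling
            if not (0.0 <= lam <= 1.0):
                raise ValueError("coupling lam must lie in [0, 1]")
            if not self.is_water[idx]:
                raise ValueError("coupling particle must be a water")
        self._adjacency = None

    # -- basic properties -------------------------------------------------

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_waters(self) -> int:
        return int(np.count_nonzero(self.is_water))

    def water_indices(self, fully_coupled_only: bool = False) -> np.ndarray:
        idx = np.flatnonzero(self.is_water)
        if fully_coupled_only and self.coupling is not None:
            idx = idx[idx != self.coupling[0]]
        return idx

    def copy(self) -> "Configuration":
        return Configuration(self.positions, self.species_ids, self.is_water,
                             self.topology, self.box, self.species,
                             coupling=self.coupling,
                             residue_ids=self.residue_ids, wrap=False)

    # -- per-particle parameter tables ------------------------------------

    def species_arrays(self):
        eps = np.array([s.epsilon for s in self.species])[self.species_ids]
        sig = np.array([s.sigma for s in self.species])[self.species_ids]
        aff = np.array([s.affinity for s in self.species])[self.species_ids]
        return eps, sig, aff

    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.species])[self.species_ids]

    def sasa_radii(self) -> np.ndarray:
        return np.array([s.sasa_radius for s in self.species])[self.species_ids]

    def coupling_state(self):
        if self.coupling is None:
            return -1, 1.0
        return int(self.coupling[0]), float(self.coupling[1])

    def bond_adjacency(self):
        """CSR adjacency (offsets, neighbors, k, r0) over bonds + crosslinks.

        Cached; invalidate with ``_invalidate_topology_cache`` after editing
        the topology or particle count.
        """
        if self._adjacency is not None and self._adjacency[0] == self.n_particles:
            return self._adjacency[1]
        n = self.n_particles
        pairs = self.topology.all_bond_indices()
        ks = np.concatenate([self.topology.chain_bonds.k, self.topology.crosslinks.k])
        r0s = np.concatenate([self.topology.chain_bonds.r0, self.topology.crosslinks.r0])
        counts = np.zeros(n + 1, dtype=np.int64)
        for i, j in pairs:
            counts[i + 1] += 1
            counts[j + 1] += 1
        off = np.cumsum(counts)
        nbr = np.zeros(off[-1], dtype=np.int64)
        kk = np.zeros(off[-1], dtype=np.float64)
        rr0 = np.zeros(off[-1], dtype=np.float64)
        cursor = off[:-1].copy()
        for b, (i, j) in enumerate(pairs):
            nbr[cursor[i]] = j
            kk[cursor[i]] = ks[b]
            rr0[cursor[i]] = r0s[b]
            cursor[i] += 1
            nbr[cursor[j]] = i
            kk[cursor[j]] = ks[b]
            rr0[cursor[j]] = r0s[b]
            cursor[j] += 1
        teth_k = np.zeros(n, dtype=np.float64)
        teth_anchor = np.zeros((n, 3), dtype=np.float64)
        t = self.topology.tethers
        teth_k[t.indices] = t.k
        teth_anchor[t.indices] = t.anchors
        adj = (off, nbr, kk, rr0, teth_k, teth_anchor)
        self._adjacency = (n, adj)
        return adj

    def _invalidate_topology_cache(self):
        self._adjacency = None

    # -- mutation (returns new objects sharing topology/species) -----------

    def with_water_added(self, position, species_id, lam=1.0,
                         residue_id=-1) -> "Configuration":
        if self.coupling is not None and lam < 1.0:
            raise ValueError("only one partially coupled particle is allowed")
        pos = np.vstack([self.positions, self.box.wrap(np.asarray(position))])
        sid = np.append(self.species_ids, species_id)
        isw = np.append(self.is_water, True)
        rid = (None if self.residue_ids is None
               else np.append(self.residue_ids, residue_id))
        coupling = (len(pos) - 1, lam) if lam < 1.0 else self.coupling
        return Configuration(pos, sid, isw, self.topology, self.box,
                             self.species, coupling=coupling,
                             residue_ids=rid, wrap=False)

    def with_water_removed(self, index) -> "Configuration":
        if not self.is_water[index]:
            raise ValueError(f"particle {index} is not a water")
        if np.any(self.topology.all_bond_indices() >= index):
            # bonds must reference beads below the removed water's index
            raise ValueError("cannot remove a water below bonded bead indices")
        keep = np.ones(self.n_particles, dtype=bool)
        keep[index] = False
        coupling = self.coupling
        if coupling is not None:
            cidx, lam = coupling
            if cidx == index:
                coupling = None
            elif cidx > index:
                coupling = (cidx - 1, lam)
        rid = None if self.residue_ids is None else self.residue_ids[keep]
        return Configuration(self.positions[keep], self.species_ids[keep],
                             self.is_water[keep], self.topology, self.box,
                             self.species, coupling=coupling,
                             residue_ids=rid, wrap=False)

    def validate(self) -> None:
        """Raise if a core invariant is violated."""
        for ax in range(3):
            if self.box.periodic[ax]:
                col = self.positions[:, ax]
                if np.any(col < 0) or np.any(col >= self.box.lengths[ax]):
                    raise ValueError("positions not wrapped into [0, L)")
        bonded = self.topology.all_bond_indices()
        if bonded.size and np.any(self.is_water[bonded.ravel()]):
            raise ValueError("water particles may not carry bonds")
        t = self.topology.tethers
        if len(t) and np.any(self.is_water[t.indices]):
            raise ValueError("water particles may not carry tethers")
        if self.coupling is not None:
            idx, lam = self.coupling
            if not (0 <= idx < self.n_particles) or not (0.0 <= lam <= 1.0):
                raise ValueError("invalid coupling state")


# -- energy operations ----------------------------------------------------

def _check_cutoff(config: Configuration, cutoff: float) -> None:
    per = config.box.periodic
    if np.any(per):
        if cutoff > 0.5 * config.box.lengths[per].min() + 1e-12:
            raise ValueError(
                f"cutoff {cutoff} exceeds half the smallest periodic box extent")


def pair_energy(config: Configuration, cutoff: float = DEFAULT_CUTOFF) -> EnergyReport:
    """Total configurational energy with additive decomposition.

    Lennard-Jones pair sum under the minimum-image convention, truncated (not
    shifted) at ``cutoff``, with water-bead epsilon scaled by the bead
    affinity; plus harmonic bond/crosslink/tether terms; plus the lam-scaled
    soft-core contribution of the coupling particle if present.
    """
    _check_cutoff(config, cutoff)
    if not config.box.fully_periodic:
        raise ValueError("energy kernels require a fully periodic box")
    eps, sig, aff = config.species_arrays()
    lam_idx, lam = config.coupling_state()
    e_pair, e_coup = K.pair_and_coupling_energy(
        config.positions, eps, sig, aff,
        config.is_water.astype(np.uint8), config.box.lengths, cutoff,
        lam_idx, lam)
    pairs = config.topology.all_bond_indices()
    ks = np.concatenate([config.topology.chain_bonds.k, config.topology.crosslinks.k])
    r0s = np.concatenate([config.topology.chain_bonds.r0, config.topology.crosslinks.r0])
    _, _, _, _, teth_k, teth_anchor = config.bond_adjacency()
    e_bond = K.bonded_energy(config.positions, config.box.lengths,
                             pairs, ks, r0s, teth_k, teth_anchor)
    return EnergyReport(total=e_pair + e_bond + e_coup, pair=e_pair,
                        bonded=e_bond, coupling_part=e_coup)


def lambda_scaled_energy(config: Configuration, lam: float,
                         cutoff: float = DEFAULT_CUTOFF) -> float:
    """Total energy with the coupling particle evaluated at coupling ``lam``.

    Returns U_rest + lam * U_inserted(lam); at lam = 0 this is exactly the
    energy of the system without the inserted molecule, at lam = 1 exactly the
    plain pair sum with the molecule fully present.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    if config.coupling is None:
        raise ValueError("configuration has no coupling particle")
    idx = config.coupling[0]
    probe = config.copy()
    probe.coupling = (idx, lam)
    return pair_energy(probe, cutoff).total


def delta_energy_remove(config: Configuration, water_index: int,
                        cutoff: float = DEFAULT_CUTOFF) -> float:
    """Energy change caused by removing one fully coupled water molecule.

    Computed incrementally from the molecule's own interactions:
    dU = U(without) - U(with) = -(interaction energy of the molecule).
    """
    _check_cutoff(config, cutoff)
    if not config.is_water[water_index]:
        raise ValueError(f"particle {water_index} is not a water")
    lam_idx, lam = config.coupling_state()
    if lam_idx == water_index:
        raise ValueError("cannot remove the partially coupled molecule")
    eps, sig, aff = config.species_arrays()
    u = K.particle_interaction_energies(
        config.positions, eps, sig, aff, config.is_water.astype(np.uint8),
        config.box.lengths, cutoff, lam_idx, lam,
        np.array([water_index], dtype=np.int64))[0]
    return -u


def hydration_level(config: Configuration) -> float:
    """Hydration level h in g water per g dry matrix.

    A partially coupled molecule counts with weight lam.
    """
    masses = config.masses()
    dry = masses[~config.is_water].sum()
    if dry <= 0:
        raise ValueError("configuration has no matrix beads")
    water = masses[config.is_water].sum()
    if config.coupling is not None:
        idx, lam = config.coupling
        water -= (1.0 - lam) * masses[idx]
    return float(water / dry)
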