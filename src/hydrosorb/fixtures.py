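"""Synthetic system generators: bead matrices, percolation fixtures, work samples.

The matrix builder is the package's stand-in for an amorphous protein powder:
multi-chain bead matrices with a tunable fraction of non-local harmonic
crosslinks (the disulfide-bridge analog), toggleable chain bonds (the
backbone-connectivity analog), and hydrophilic/hydrophobic bead flavours.
Every generator is bit-deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import Frame, WATER_RESIDUE
from .model import (Box, Configuration, HarmonicBonds, Topology,
                    HYDROPHILIC_SPECIES, HYDROPHOBIC_SPECIES, WATER_SPECIES)

__all__ = ["MatrixSpec", "generate_matrix", "generate_percolation_fixture",
           "generate_crooks_samples", "chain_groups"]

#: species table order used by generated configurations
SPECIES_TABLE = [WATER_SPECIES, HYDROPHILIC_SPECIES, HYDROPHOBIC_SPECIES]
WATER_ID, PHILIC_ID, PHOBIC_ID = 0, 1, 2


@dataclass
class MatrixSpec:
    """Parameters of one coarse-grained matrix.

    ``crosslink_fraction`` is the fraction of beads that carry a non-local
    crosslink (so ``0.2`` on 100 beads gives 10 crosslinks involving 20
    beads); ``bonded=False`` drops the chain bonds, turning the chains into a
    free-bead mixture.  ``box_density`` is the bead number density; it is kept
    low enough to leave head space for the water taken up during adsorption.
    """

    n_chains: int = 8
    chain_length: int = 25
    bonded: bool = True
    crosslink_fraction: float = 0.2
    hydrophilic_fraction: float = 0.4
    box_density: float = 0.15
    bond_k: float = 100.0
    bond_r0: float = 1.0
    crosslink_k: float = 100.0
    anneal_sweeps: int = 300
    temperature: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.crosslink_fraction <= 1.0:
            raise ValueError("crosslink_fraction must lie in [0, 1]")
        if self.chain_length < 1 or self.n_chains < 1:
            raise ValueError("need at least one chain with one bead")
        if self.box_density <= 0:
            raise ValueError("box_density must be positive")

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_length


def _place_chains(spec: MatrixSpec, box: Box, rng: np.random.Generator,
                  min_sep: float = 0.85, max_retries: int = 200) -> np.ndarray:
    """Grow non-overlapping random-walk chains with step length bond_r0."""
    L = box.lengths

    def clash(p, others):
        if len(others) == 0:
            return False
        d = np.asarray(others) - p
        d -= L * np.floor(d / L + 0.5)
        return bool(np.any(np.einsum("ij,ij->i", d, d) < min_sep * min_sep))

    placed: list[np.ndarray] = []
    for _ in range(spec.n_chains):
        for _attempt in range(max_retries):
            chain = [rng.random(3) * L]
            ok = not clash(chain[0], placed)
            while ok and len(chain) < spec.chain_length:
                for _try in range(50):
                    step = rng.normal(size=3)
                    step *= spec.bond_r0 / np.linalg.norm(step)
                    trial = box.wrap(chain[-1] + step).reshape(3)
                    # the bonded predecessor sits at bond_r0 > min_sep, so it
                    # passes the clash check naturally
                    if not clash(trial, placed + chain):
                        chain.append(trial)
                        break
                else:
                    ok = False
            if ok and len(chain) == spec.chain_length:
                placed.extend(chain)
                break
        else:
            raise RuntimeError(
                f"could not place chains at density {spec.box_density:.3f}")
    return np.vstack(placed)


def generate_matrix(spec: MatrixSpec) -> Configuration:
    """Build, crosslink, and anneal a coarse-grained bead matrix.

    Chains are grown as non-overlapping random walks; species are assigned by
    the hydrophilic fraction (exact count, shuffled); chain bonds are added
    iff ``bonded``; the structure is relaxed by a short seeded Metropolis
    anneal; finally crosslink partner pairs are sampled uniformly without
    replacement among non-local, spatially proximate pairs of the annealed
    structure until the bead fraction target is met, with their rest lengths
    frozen at the observed separations.  Crosslink sampling uses a dedicated
    random stream, so two specs differing only in ``crosslink_fraction`` give
    bit-identical bead geometry: the with/without-crosslink comparison probes
    the constraint itself, not a different powder realization.

    Residue labels are per bead (one bead = one amino-acid analog).
    """
    from .sorption import relax  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_beads
    L = (n / spec.box_density) ** (1.0 / 3.0)
    box = Box([L, L, L])
    pos = _place_chains(spec, box, rng)

    species_ids = np.full(n, PHOBIC_ID, dtype=np.int64)
    n_philic = int(round(spec.hydrophilic_fraction * n))
    philic = rng.permutation(n)[:n_philic]
    species_ids[philic] = PHILIC_ID

    chain_index = np.repeat(np.arange(spec.n_chains), spec.chain_length)
    chain_position = np.tile(np.arange(spec.chain_length), spec.n_chains)

    if spec.bonded and spec.chain_length > 1:
        pairs = [(c * spec.chain_length + k, c * spec.chain_length + k + 1)
                 for c in range(spec.n_chains)
                 for k in range(spec.chain_length - 1)]
        chain_bonds = HarmonicBonds(np.array(pairs), k=spec.bond_k,
                                    r0=spec.bond_r0)
    else:
        chain_bonds = HarmonicBonds()

    config = Configuration(pos, species_ids, np.zeros(n, dtype=bool),
                           Topology(chain_bonds=chain_bonds), box,
                           SPECIES_TABLE, residue_ids=np.arange(n))
    if spec.anneal_sweeps:
        config = relax(config, spec.anneal_sweeps, spec.temperature, rng,
                       in_place=True)

    xl_rng = np.random.default_rng([spec.seed, 0x5eed])
    crosslinks = _sample_crosslinks(spec, config.positions, box, chain_index,
                                    chain_position, xl_rng)
    topology = Topology(chain_bonds=chain_bonds, crosslinks=crosslinks)
    topology.validate_crosslink_locality(chain_index, chain_position)
    config.topology = topology
    config._invalidate_topology_cache()
    config.chain_index = chain_index
    config.chain_position = chain_position
    config.validate()
    return config


def _sample_crosslinks(spec: MatrixSpec, pos, box, chain_index,
                       chain_position, rng, max_pair_distance: float = 2.5
                       ) -> HarmonicBonds:
    n_cross = int(round(spec.crosslink_fraction * spec.n_beads / 2.0))
    if n_cross == 0:
        return HarmonicBonds()
    d = pos[None, :, :] - pos[:, None, :]
    d = box.minimum_image(d)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    i, j = np.triu_indices(spec.n_beads, k=1)
    nonlocal_ok = (chain_index[i] != chain_index[j]) | \
        (np.abs(chain_position[i] - chain_position[j]) > 2)
    eligible = nonlocal_ok & (r[i, j] < max_pair_distance)
    cand = np.flatnonzero(eligible)
    order = rng.permutation(cand)
    used = np.zeros(spec.n_beads, dtype=bool)
    chosen = []
    for p in order:
        a, b = int(i[p]), int(j[p])
        if used[a] or used[b]:
            continue
        chosen.append((a, b))
        used[a] = used[b] = True
        if len(chosen) == n_cross:
            break
    if len(chosen) < n_cross:
        raise RuntimeError(
            f"only {len(chosen)} of {n_cross} crosslinks could be placed; "
            "matrix too sparse for the requested crosslink fraction")
    pairs = np.array(chosen)
    r0 = r[pairs[:, 0], pairs[:, 1]]
    return HarmonicBonds(pairs, k=spec.crosslink_k, r0=r0)


def chain_groups(spec: MatrixSpec):
    """Per-chain bead index arrays for a matrix built from ``spec``.

    Bead indices are laid out chain by chain, so the grouping is a pure
    function of the MatrixSpec (independent of the seed).
    """
    return [np.arange(c * spec.chain_length, (c + 1) * spec.chain_length)
            for c in range(spec.n_chains)]


def generate_percolation_fixture(box: Box, spacing: float, spanning: bool,
                                 seed: int = 0, cutoff: float = None) -> Frame:
    """Deterministic water arrangement that does (or does not) percolate in x.

    A row of waters at the given spacing runs the full x extent of the box;
    for ``spanning=False`` one row member is removed, breaking the wrap-around
    connection.  A handful of seeded off-row waters is added as clutter, far
    enough from the row not to bridge the gap.
    """
    n_row = int(round(box.lengths[0] / spacing))
    if spanning and abs(n_row * spacing - box.lengths[0]) > 1e-9:
        raise ValueError("spacing must divide the box length for a spanning row")
    if cutoff is not None and spacing >= cutoff:
        raise ValueError("spacing must be below the clustering cutoff")
    rng = np.random.default_rng(seed)
    y0, z0 = 0.5 * box.lengths[1], 0.5 * box.lengths[2]
    row = np.column_stack([
        spacing * np.arange(n_row),
        np.full(n_row, y0),
        np.full(n_row, z0),
    ])
    if not spanning:
        row = row[1:]
    clutter = rng.random((4, 3)) * box.lengths
    # keep clutter away from the row plane so it cannot re-bridge the gap
    clutter[:, 1] = 0.1 * box.lengths[1]
    pos = np.vstack([row, clutter])
    n = len(pos)
    return Frame(positions=box.wrap(pos), is_water=np.ones(n, dtype=bool),
                 residue_ids=np.full(n, WATER_RESIDUE), box=box)


def generate_crooks_samples(delta_f: float, sigma: float, n: int,
                            beta: float = 1.0, seed: int = 0):
    """Gaussian work samples satisfying the Crooks relation with known truth.

    Forward works are Normal(delta_f + beta sigma^2 / 2, sigma^2) and reverse
    works Normal(-delta_f + beta sigma^2 / 2, sigma^2), which satisfies
    P_F(W) = P_R(-W) exp(beta (W - delta_f)) exactly; BAR applied to these
    samples should recover ``delta_f``.
    """
    from .chempot import WorkSamples

    if n < 2:
        raise ValueError("need at least two samples per direction")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    shift = 0.5 * beta * sigma * sigma
    fwd = rng.normal(delta_f + shift, sigma, size=n)
    rev = rng.normal(-delta_f + shift, sigma, size=n)
    return WorkSamples(forward=fwd, reverse=rev, beta=beta)
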