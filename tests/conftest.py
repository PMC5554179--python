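"""Shared fixtures: small configurations built programmatically."""

import numpy as np
import pytest

from hydrosorb.model import (Box, Configuration, HarmonicBonds, Species,
                             Topology, WATER_SPECIES, HYDROPHILIC_SPECIES,
                             HYDROPHOBIC_SPECIES)

SPECIES = [WATER_SPECIES, HYDROPHILIC_SPECIES, HYDROPHOBIC_SPECIES]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_config(positions, species_ids=None, is_water=None, box_length=10.0,
                topology=None, coupling=None, residue_ids=None, wrap=True):
    """Small-configuration builder used across the suite."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    if species_ids is None:
        species_ids = np.zeros(n, dtype=int)
    if is_water is None:
        is_water = np.ones(n, dtype=bool)
    return Configuration(positions, species_ids, is_water,
                         topology or Topology(), Box([box_length] * 3),
                         SPECIES, coupling=coupling, residue_ids=residue_ids,
                         wrap=wrap)


def random_config(rng, n=20, box_length=8.0, n_water=None, bonds=False):
    """Random mixed bead/water configuration with optional harmonic bonds.

    Matrix beads occupy the low indices (the layout the engine maintains).
    """
    n_water = n // 2 if n_water is None else n_water
    n_beads = n - n_water
    # rejection-sample positions with a minimum separation so pair energies
    # stay O(1) and absolute tolerances are meaningful
    positions = []
    while len(positions) < n:
        trial = rng.random(3) * box_length
        if positions:
            d = np.asarray(positions) - trial
            d -= box_length * np.floor(d / box_length + 0.5)
            if np.min(np.einsum("ij,ij->i", d, d)) < 0.85 ** 2:
                continue
        positions.append(trial)
    positions = np.asarray(positions)
    species_ids = np.concatenate([
        rng.integers(1, 3, size=n_beads), np.zeros(n_water, dtype=int)])
    is_water = np.concatenate([
        np.zeros(n_beads, dtype=bool), np.ones(n_water, dtype=bool)])
    topology = Topology()
    if bonds and n_beads >= 4:
        pairs = np.column_stack([np.arange(n_beads - 1),
                                 np.arange(1, n_beads)])
        topology = Topology(chain_bonds=HarmonicBonds(pairs, k=50.0, r0=1.0))
    residue_ids = np.concatenate([np.arange(n_beads),
                                  np.full(n_water, -1)])
    return Configuration(positions, species_ids, is_water, topology,
                         Box([box_length] * 3), SPECIES,
                         residue_ids=residue_ids)


@pytest.fixture
def small_mixed_config(rng):
    return random_config(rng, n=20)


def brute_force_energy(config, cutoff=3.0):
    """O(N^2) reference energy: plain double loop in Python/NumPy.

    Independent of the compiled kernels; coupling-aware via the soft-core
    closed form.
    """
    from hydrosorb._kernels import SOFTCORE_ALPHA

    eps, sig, aff = config.species_arrays()
    isw = config.is_water
    lam_idx, lam = config.coupling_state()
    L = config.box.lengths
    pos = config.positions
    n = len(pos)
    e_pair = e_coup = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= L * np.floor(d / L + 0.5)
            r2 = float(d @ d)
            if r2 >= cutoff * cutoff:
                continue
            e = np.sqrt(eps[i] * eps[j])
            if isw[i] != isw[j]:
                e *= aff[i] * aff[j]
            s2 = (0.5 * (sig[i] + sig[j])) ** 2
            if i == lam_idx or j == lam_idx:
                r2e = r2 + SOFTCORE_ALPHA * (1 - lam) * s2
                sr6 = (s2 / r2e) ** 3
                e_coup += lam * 4 * e * (sr6 * sr6 - sr6)
            else:
                sr6 = (s2 / r2) ** 3
                e_pair += 4 * e * (sr6 * sr6 - sr6)
    e_bond = 0.0
    topo = config.topology
    for bonds in (topo.chain_bonds, topo.crosslinks):
        for (i, j), k, r0 in zip(bonds.pairs, bonds.k, bonds.r0):
            d = pos[i] - pos[j]
            d -= L * np.floor(d / L + 0.5)
            e_bond += 0.5 * k * (np.sqrt(d @ d) - r0) ** 2
    for i, k, anchor in zip(topo.tethers.indices, topo.tethers.k,
                            topo.tethers.anchors):
        d = pos[i] - anchor
        d -= L * np.floor(d / L + 0.5)
        e_bond += 0.5 * k * (d @ d)
    return e_pair, e_bond, e_coup
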