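"""Reference desk-scale sorption studies.

Two paired computer experiments probe how structural constraints shape the
sorption isotherm of the coarse-grained powder:

* **Crosslink study** — one 200-bead chain matrix run through a full
  adsorption/desorption loop twice, with and without non-local crosslinks on
  20% of the beads (the disulfide-bridge analog).  Both runs share
  bit-identical bead geometry; only the constraint differs.  The readout is
  the hysteresis area between the branches.
* **Connectivity study** — a bonded chain matrix versus the free-bead mixture
  of identical composition (the backbone-connectivity analog), each run on
  its adsorption branch up to its approximate saturation limit (0.4 g/g
  bonded, 0.9 g/g free, mirroring the ratio seen for globular proteins
  versus free amino-acid mixtures).  The readout is the hydration level
  reached at 90% relative humidity, where a branch that never reaches the
  target reports its largest sampled h as a lower bound.

Both studies use the desk-scale protocol at T* = 0.9 with mu_sat calibrated
on the pure toy-water liquid at coexistence.
"""

from __future__ import annotations

import numpy as np

from . import sorption
from .fixtures import MatrixSpec, generate_matrix

__all__ = ["crosslink_study_pair", "connectivity_study_pair",
           "study_protocol", "STUDY_TEMPERATURE"]

#: reduced temperature of the reference studies
STUDY_TEMPERATURE = 0.9


def study_protocol(seed: int, h_max: float, mu_sat: float,
                   h_min: float = 0.04) -> sorption.SorptionProtocol:
    """Desk-scale protocol shared by the reference studies."""
    return sorption.SorptionProtocol.desk_scale(
        h_min=h_min, h_max=h_max, seed=seed, mu_sat=mu_sat,
        temperature=STUDY_TEMPERATURE)


def crosslink_study_pair(seed: int, mu_sat: float, h_max: float = 0.28):
    """(hysteresis area without crosslinks, with crosslinks) for one seed."""
    areas = {}
    for fraction in (0.0, 0.2):
        matrix = generate_matrix(MatrixSpec(
            seed=seed, crosslink_fraction=fraction,
            temperature=STUDY_TEMPERATURE))
        iso, _ = sorption.run_isotherm(matrix,
                                       study_protocol(seed, h_max, mu_sat))
        res = sorption.hysteresis_area(iso.branch("adsorption"),
                                       iso.branch("desorption"))
        areas[fraction] = res
    return areas[0.0], areas[0.2]


def connectivity_study_pair(seed: int, mu_sat: float,
                            collect_frames: bool = False):
    """(uptake at RH 90% bonded, free, free-run adsorption frames) for one seed.

    The frame dict (saved h -> frame list, free-bead run) is empty unless
    ``collect_frames`` is set.
    """
    results = {}
    frames_free = {}
    for name, bonded, n_chains, chain_length, h_max in (
            ("bonded", True, 4, 16, 0.40),
            ("free", False, 64, 1, 0.90)):
        spec = MatrixSpec(seed=seed, crosslink_fraction=0.0, bonded=bonded,
                          n_chains=n_chains, chain_length=chain_length,
                          box_density=0.10, temperature=STUDY_TEMPERATURE)
        matrix = generate_matrix(spec)
        proto = study_protocol(seed, h_max, mu_sat)
        rng = np.random.default_rng(proto.seed)
        config = sorption.solvate_to(matrix, proto.h_min, rng, proto,
                                     relax_sweeps=proto.production_sweeps)
        recs, frames, _ = sorption.run_branch(
            config, proto, "adsorb", rng,
            collect_frames=collect_frames and name == "free")
        results[name] = sorption.uptake_at_rh(recs, 90.0)
        if name == "free":
            frames_free = frames
    return results["bonded"], results["free"], frames_free
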