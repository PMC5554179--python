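"""Adsorption/desorption protocol engine and hysteresis quantification.

The engine alternates single-molecule sorption events with Metropolis
relaxation of the whole system at fixed N, V, T:

* adsorption inserts one water at a non-overlapping random position as an
  ideal-gas ghost and ramps its coupling linearly to full interaction, with
  relaxation sweeps between increments ("continuous" insertion);
* desorption deletes one water chosen with probability proportional to the
  Boltzmann factor exp(-beta dU) of its removal energy, then relaxes.

Whenever the hydration level h crosses a point of the save grid (default
every 0.02 g/g) the engine runs a longer production relaxation, discards an
equilibration fraction, stores frames, and estimates the water chemical
potential (BAR) and relative humidity on them.  The collected
(branch, h, mu_w, RH) records form the sorption isotherm; hysteresis is
quantified as the integral of RH_ads(h) - RH_des(h) over the common h range
plus the maximum RH gap and its location.

Relaxation is Metropolis Monte Carlo rather than barostatted MD: the box
volume is fixed per run, which preserves the sorption physics at this scale
while giving a provable stationary distribution.  Water moves mix local
displacements with box-uniform repositioning (a symmetric proposal) so that
the fast water degrees of freedom equilibrate quickly and history dependence
is carried by the slow matrix rearrangements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from . import _kernels as K
from . import chempot
from .model import (Configuration, DEFAULT_CUTOFF, WATER_SPECIES,
                    hydration_level)

__all__ = [
    "SorptionProtocol", "IsothermRecord", "Isotherm", "HysteresisResult",
    "select_removal_candidate", "remove_water_step", "insert_water_continuous",
    "relax", "run_branch", "run_isotherm", "hysteresis_area", "uptake_at_rh",
    "solvate_to",
]

log = logging.getLogger(__name__)


@dataclass
class SorptionProtocol:
    """Schedule and engine knobs for one sorption run.

    Sweep counts play the role of the relaxation times of a molecular
    dynamics protocol; the defaults (200 relaxation sweeps per sorption
    event, 5000 production sweeps per saved h point) are the full-length
    settings, and scaled-down values are appropriate for quick studies.
    """

    h_min: float = 0.04
    h_max: float = 0.40
    h_save_interval: float = 0.02
    relax_sweeps_per_step: int = 200
    ramp_steps: int = 10
    production_sweeps: int = 5000
    equilibration_fraction: float = 1.0 / 7.0
    temperature: float = 0.9
    seed: int = 0
    # engine knobs
    cutoff: float = DEFAULT_CUTOFF
    max_displacement: float = 0.3
    water_teleport_prob: float = 0.5
    frame_interval: int = 10
    n_insertions_per_point: int = 20000
    insertion_min_separation: float = 0.8
    insertion_max_attempts: int = 10_000
    mu_sat: float = math.nan

    def __post_init__(self):
        if not self.h_min < self.h_max:
            raise ValueError("h_min must be below h_max")
        if self.h_save_interval <= 0:
            raise ValueError("h_save_interval must be positive")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must lie in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "SorptionProtocol":
        """Reduced-length protocol used for desk-scale toy studies.

        Ten relaxation sweeps per sorption event (three coupling increments)
        and 200 production sweeps per saved point with frames every 20
        sweeps.  These lengths are calibrated so that the water subsystem
        equilibrates within a grid point (a fully tethered rigid matrix then
        shows near-zero hysteresis) while matrix rearrangements stay slow on
        the branch timescale.
        """
        base = dict(relax_sweeps_per_step=10, ramp_steps=3,
                    production_sweeps=200, frame_interval=20,
                    n_insertions_per_point=18000)
        base.update(overrides)
        return cls(**base)


@dataclass
class IsothermRecord:
    branch: str
    h: float
    n_waters: int
    mu_w: float
    mu_stderr: float
    rh: float

    def __post_init__(self):
        if self.branch not in ("adsorption", "desorption"):
            raise ValueError("branch must be adsorption or desorption")
        if self.n_waters < 0:
            raise ValueError("n_waters must be non-negative")


@dataclass
class Isotherm:
    """Ordered records of one or both branches plus run metadata."""

    records: List[IsothermRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def branch(self, name: str) -> List[IsothermRecord]:
        return [r for r in self.records if r.branch == name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.branch, r.h, r.n_waters, r.mu_w, r.mu_stderr, r.rh)
             for r in self.records],
            columns=["branch", "h", "n_waters", "mu_w", "mu_stderr", "rh"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def validate_monotone(self) -> None:
        for name, sign in (("adsorption", 1.0), ("desorption", -1.0)):
            hs = np.array([r.h for r in self.branch(name)])
            if len(hs) > 1 and np.any(sign * np.diff(hs) <= 0):
                raise ValueError(f"{name} branch h values are not monotone")


# -- elementary engine operations -----------------------------------------

def relax(config: Configuration, n_sweeps: int, temperature: float,
          rng: np.random.Generator, cutoff: float = DEFAULT_CUTOFF,
          max_displacement: float = 0.3, water_teleport_prob: float = 0.2,
          in_place: bool = False) -> Configuration:
    """Metropolis single-particle displacement sweeps at fixed N, V, T.

    Returns the relaxed configuration (a copy unless ``in_place``); with
    ``n_sweeps == 0`` the configuration is returned unchanged.
    """
    if n_sweeps < 0:
        raise ValueError("n_sweeps must be non-negative")
    out = config if in_place else config.copy()
    if n_sweeps == 0 or out.n_particles == 0:
        return out
    if not out.box.fully_periodic:
        raise ValueError("the engine requires a fully periodic box")
    if cutoff > 0.5 * out.box.lengths.min() + 1e-12:
        raise ValueError("cutoff exceeds half the smallest box extent")
    eps, sig, aff = out.species_arrays()
    lam_idx, lam = out.coupling_state()
    adj = out.bond_adjacency()
    rand = rng.random((n_sweeps, out.n_particles, 5))
    K.mc_sweeps(out.positions, eps, sig, aff, out.is_water.astype(np.uint8),
                out.box.lengths, cutoff, lam_idx, lam, *adj,
                1.0 / temperature, max_displacement, water_teleport_prob, rand)
    return out


def _relax_with(config, protocol: SorptionProtocol, n_sweeps: int, rng):
    return relax(config, n_sweeps, protocol.temperature, rng,
                 cutoff=protocol.cutoff,
                 max_displacement=protocol.max_displacement,
                 water_teleport_prob=protocol.water_teleport_prob,
                 in_place=True)


def select_removal_candidate(config: Configuration, temperature: float,
                             rng: np.random.Generator,
                             cutoff: float = DEFAULT_CUTOFF) -> int:
    """Boltzmann-weighted choice of the water molecule to remove.

    Water i is drawn with probability proportional to exp(-beta dU_i), where
    dU_i is the energy change its removal would cause; weights are normalized
    with a max shift, and the draw uses a single uniform against the
    cumulative weights in stable (ascending index) order.
    """
    idx = config.water_indices(fully_coupled_only=True)
    if len(idx) == 0:
        raise ValueError("no fully coupled waters to remove")
    eps, sig, aff = config.species_arrays()
    lam_idx, lam = config.coupling_state()
    u = K.particle_interaction_energies(
        config.positions, eps, sig, aff, config.is_water.astype(np.uint8),
        config.box.lengths, cutoff, lam_idx, lam, idx)
    beta = 1.0 / temperature
    logw = -beta * (-u)  # dU_i = -u_i
    logw -= logw.max()
    w = np.exp(logw)
    cdf = np.cumsum(w)
    pick = np.searchsorted(cdf, rng.random() * cdf[-1], side="right")
    return int(idx[min(pick, len(idx) - 1)])


def remove_water_step(config: Configuration, protocol: SorptionProtocol,
                      rng: np.random.Generator) -> Configuration:
    """One desorption cycle: Boltzmann-weighted removal, then relaxation."""
    victim = select_removal_candidate(config, protocol.temperature, rng,
                                      protocol.cutoff)
    log.debug("removing water %d", victim)
    config = config.with_water_removed(victim)
    return _relax_with(config, protocol, protocol.relax_sweeps_per_step, rng)


def _find_insertion_position(config: Configuration, protocol: SorptionProtocol,
                             rng: np.random.Generator) -> np.ndarray:
    sig = config.species_arrays()[1]
    min_sep = protocol.insertion_min_separation
    L = config.box.lengths
    for _ in range(protocol.insertion_max_attempts):
        trial = rng.random(3) * L
        if config.n_particles == 0:
            return trial
        d = config.positions - trial
        d -= L * np.floor(d / L + 0.5)
        r2 = np.einsum("ij,ij->i", d, d)
        thresh = (min_sep * 0.5 * (sig + WATER_SPECIES.sigma)) ** 2
        if np.all(r2 >= thresh):
            return trial
    density = config.n_particles / config.box.volume
    raise RuntimeError(
        f"no non-overlapping insertion position found in "
        f"{protocol.insertion_max_attempts} attempts "
        f"(number density {density:.3f})")


def insert_water_continuous(config: Configuration, protocol: SorptionProtocol,
                            rng: np.random.Generator,
                            water_species_id: Optional[int] = None
                            ) -> Configuration:
    """One adsorption cycle: ghost insertion plus a linear coupling ramp.

    The new water is placed at a non-overlapping random position with zero
    coupling, then lam is ramped linearly over ``ramp_steps`` increments with
    ``relax_sweeps_per_step / ramp_steps`` relaxation sweeps after each one;
    the returned configuration is fully coupled.  ``ramp_steps == 1``
    degenerates to discrete insertion followed by relaxation.
    """
    if water_species_id is None:
        water_species_id = next(
            i for i, s in enumerate(config.species) if s.name == WATER_SPECIES.name)
    pos = _find_insertion_position(config, protocol, rng)
    log.debug("inserting water at %s", np.array_str(pos, precision=3))
    config = config.with_water_added(pos, water_species_id, lam=0.0)
    widx = config.n_particles - 1
    ramp = max(1, protocol.ramp_steps)
    sweeps_per_inc = max(1, protocol.relax_sweeps_per_step // ramp)
    for k in range(1, ramp + 1):
        lam = k / ramp
        config.coupling = (widx, lam) if lam < 1.0 else None
        config = _relax_with(config, protocol, sweeps_per_inc, rng)
    return config


# -- branch driver ---------------------------------------------------------

def _production(config, protocol: SorptionProtocol, rng):
    """Production relaxation at a grid point: equilibrate, then store frames."""
    eq = int(round(protocol.production_sweeps * protocol.equilibration_fraction))
    config = _relax_with(config, protocol, eq, rng)
    n_frames = max(1, (protocol.production_sweeps - eq) // protocol.frame_interval)
    frames = []
    for _ in range(n_frames):
        config = _relax_with(config, protocol, protocol.frame_interval, rng)
        frames.append(config.copy())
    return config, frames


def run_branch(config: Configuration, protocol: SorptionProtocol,
               direction: str, rng: np.random.Generator,
               collect_frames: bool = True):
    """Run one sorption branch over the h grid.

    Repeats insertion (``direction="adsorb"``) or removal (``"desorb"``)
    events; at every crossing of an ``h_save_interval`` grid point the system
    gets a production relaxation, frames are stored, and the chemical
    potential / RH are estimated on them.

    Returns ``(records, frames_by_h, final_config)`` where ``frames_by_h``
    maps each saved grid h to its frame list (empty dict when
    ``collect_frames`` is false, but frames are always used internally for
    the mu estimate).
    """
    if direction not in ("adsorb", "desorb"):
        raise ValueError("direction must be 'adsorb' or 'desorb'")
    branch = "adsorption" if direction == "adsorb" else "desorption"
    n_grid = int(round((protocol.h_max - protocol.h_min) / protocol.h_save_interval))
    grid = protocol.h_min + protocol.h_save_interval * np.arange(n_grid + 1)
    targets = grid if direction == "adsorb" else grid[::-1]

    records: List[IsothermRecord] = []
    frames_by_h = {}
    tol = 1e-9
    for target in targets:
        while True:
            h = hydration_level(config)
            if direction == "adsorb":
                if h >= target - tol:
                    break
            else:
                # remove only while the post-removal h stays on/above the
                # target, so a full adsorb/desorb loop conserves the water
                # count exactly
                masses = config.masses()
                dry = masses[~config.is_water].sum()
                quantum = (masses[config.is_water][0] / dry
                           if config.n_waters else 0.0)
                if config.n_waters == 0 or h - quantum < target - tol:
                    break
            try:
                if direction == "adsorb":
                    config = insert_water_continuous(config, protocol, rng)
                else:
                    config = remove_water_step(config, protocol, rng)
            except RuntimeError as err:
                raise RuntimeError(
                    f"{branch} stalled at h = {h:.4f} g/g "
                    f"(target {target:.3f}): {err}") from err
        config, frames = _production(config, protocol, rng)
        res = chempot.estimate_mu(frames, protocol.n_insertions_per_point,
                                  protocol.temperature, rng,
                                  mu_sat=protocol.mu_sat,
                                  cutoff=protocol.cutoff)
        h_now = hydration_level(config)
        records.append(IsothermRecord(branch=branch, h=float(h_now),
                                      n_waters=config.n_waters,
                                      mu_w=res.mu_total,
                                      mu_stderr=res.stderr, rh=res.rh))
        log.info("%s h=%.3f N_w=%d mu=%.3f RH=%.1f", branch, h_now,
                 config.n_waters, res.mu_total, res.rh)
        if collect_frames:
            frames_by_h[float(target)] = frames
    return records, frames_by_h, config


def solvate_to(config: Configuration, h_target: float,
               rng: np.random.Generator, protocol: SorptionProtocol,
               relax_sweeps: int = 0) -> Configuration:
    """Insert waters at random non-overlapping positions up to ``h_target``.

    Used to prepare a starting state; insertions here are discrete (the
    branch protocol handles continuous coupling during the runs).
    """
    wid = next(i for i, s in enumerate(config.species)
               if s.name == WATER_SPECIES.name)
    while hydration_level(config) < h_target - 1e-9:
        pos = _find_insertion_position(config, protocol, rng)
        config = config.with_water_added(pos, wid, lam=1.0)
    if relax_sweeps:
        config = _relax_with(config, protocol, relax_sweeps, rng)
    return config


def run_isotherm(config: Configuration, protocol: SorptionProtocol,
                 collect_frames: bool = False):
    """Full sorption loop: solvate to h_min, adsorb to h_max, desorb back.

    Returns ``(isotherm, frames_by_branch_h)``; the isotherm carries both
    branches in run order and a metadata fingerprint (protocol + seed).
    """
    rng = np.random.default_rng(protocol.seed)
    config = solvate_to(config, protocol.h_min, rng, protocol,
                        relax_sweeps=protocol.production_sweeps)
    ads, ads_frames, config = run_branch(config, protocol, "adsorb", rng,
                                         collect_frames)
    des, des_frames, config = run_branch(config, protocol, "desorb", rng,
                                         collect_frames)
    meta = {"protocol": {k: (v if np.isfinite(v) else None)
                         if isinstance(v, float) else v
                         for k, v in asdict(protocol).items()},
            "n_beads": int(np.count_nonzero(~config.is_water))}
    iso = Isotherm(records=ads + des, metadata=meta)
    frames = {"adsorption": ads_frames, "desorption": des_frames}
    return iso, frames


# -- hysteresis metrics ----------------------------------------------------

@dataclass
class HysteresisResult:
    """Area between branches plus the maximum RH gap and its location."""

    area: float
    max_gap: float
    h_at_max_gap: float


def _branch_arrays(records: Iterable[IsothermRecord]):
    rs = sorted(records, key=lambda r: r.h)
    return (np.array([r.h for r in rs]), np.array([r.rh for r in rs]))


def hysteresis_area(adsorption: Iterable[IsothermRecord],
                    desorption: Iterable[IsothermRecord]) -> HysteresisResult:
    """Quantify hysteresis between two isotherm branches.

    Both branches are interpolated onto the union of their h values within
    the overlapping range; the area is the trapezoidal integral of
    RH_ads(h) - RH_des(h), reported together with the maximum RH difference
    and the h at which it occurs.
    """
    h_a, rh_a = _branch_arrays(adsorption)
    h_d, rh_d = _branch_arrays(desorption)
    if len(h_a) == 0 or len(h_d) == 0:
        raise ValueError("both branches must contain records")
    lo = max(h_a.min(), h_d.min())
    hi = min(h_a.max(), h_d.max())
    if hi <= lo:
        raise ValueError("branches do not overlap in h")
    grid = np.union1d(h_a, h_d)
    grid = grid[(grid >= lo - 1e-12) & (grid <= hi + 1e-12)]
    diff = np.interp(grid, h_a, rh_a) - np.interp(grid, h_d, rh_d)
    area = float(np.trapezoid(diff, grid))
    k = int(np.argmax(np.abs(diff)))
    return HysteresisResult(area=area, max_gap=float(diff[k]),
                            h_at_max_gap=float(grid[k]))


def uptake_at_rh(branch: Iterable[IsothermRecord], rh_target: float) -> float:
    """Hydration level at which a branch reaches the given relative humidity.

    The RH curve is made nondecreasing in h (running maximum) before inverse
    interpolation; if the branch never reaches ``rh_target`` the largest
    sampled h is returned as a lower bound.
    """
    h, rh = _branch_arrays(branch)
    if len(h) == 0:
        raise ValueError("empty branch")
    rh_mono = np.maximum.accumulate(rh)
    if rh_target > rh_mono[-1]:
        return float(h[-1])
    return float(np.interp(rh_target, rh_mono, h))
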