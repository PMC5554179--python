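"""Water chemical potential from test insertions/deletions, and relative humidity.

Two estimators are provided for the excess chemical potential of water in a
saved trajectory: Bennett's acceptance ratio (BAR), combining forward test
insertions with reverse deletions of the real waters, and plain Widom test
insertion as a cross-check / fallback.  Both treat the test moves as ghosts:
the stored frames are never modified.

Work/sign conventions
---------------------
* forward sample  W_F = dU of inserting a ghost water into an N-water frame
  (the N -> N+1 direction);
* reverse sample  W_R = dU of deleting a real water (the N -> N-1 direction),
  i.e. minus that water's interaction energy.

With the Fermi function f(x) = 1/(1 + e^x), Bennett's self-consistent
equation reads

    sum_F f(beta (W_F - C)) = sum_R f(beta (W_R + C))

and the excess chemical potential is mu_ex = C + kT ln(n_F / n_R).  This
follows from the Crooks relation P_F(W) = P_R(-W) e^{beta (W - dF)}.

Total chemical potential and relative humidity
----------------------------------------------
mu_w = mu_ex + kT ln(rho_w Lambda^3) with rho_w the water number density and
Lambda a reference thermal wavelength.  The saturation value is obtained from
the ideal-gas law, mu_sat = kT ln(rho_sat Lambda^3) with
rho_sat = p_sat / (kT), using the *same* Lambda, so that

    RH = 100 exp((mu_w - mu_sat) / kT)

is independent of the Lambda reference.  For reduced-unit toy water, whose
vapor pressure is not known a priori, :func:`calibrate_mu_sat` computes mu_sat
directly on the liquid side of coexistence (at coexistence the liquid and
vapor chemical potentials are equal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from . import _kernels as K
from .model import Configuration, DEFAULT_CUTOFF, WATER_SPECIES

__all__ = [
    "WorkSamples", "ChemPotResult",
    "sample_insertion_energies", "sample_deletion_energies",
    "bar_estimate", "widom_estimate", "mu_total", "mu_saturation",
    "relative_humidity", "estimate_mu", "calibrate_mu_sat", "block_stderr",
]

log = logging.getLogger(__name__)


@dataclass
class WorkSamples:
    """Forward (insertion) and reverse (deletion) energy samples.

    ``forward[i]`` is the energy change of a test insertion; ``reverse[j]`` is
    the energy change of deleting a real water (see module docstring for the
    sign convention).
    """

    forward: np.ndarray
    reverse: np.ndarray
    beta: float

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=np.float64).reshape(-1)
        self.reverse = np.asarray(self.reverse, dtype=np.float64).reshape(-1)
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def n_forward(self) -> int:
        return len(self.forward)

    @property
    def n_reverse(self) -> int:
        return len(self.reverse)


@dataclass
class ChemPotResult:
    mu_excess: float
    mu_total: float = math.nan
    stderr: float = 0.0
    rh: float = math.nan


# -- ghost sampling -------------------------------------------------------

def _frame_kernel_args(frame: Configuration, cutoff: float):
    if frame.coupling is not None:
        raise ValueError("frames fed to the estimator must be fully coupled")
    eps, sig, aff = frame.species_arrays()
    return (frame.positions, eps, sig, aff, frame.is_water.astype(np.uint8),
            frame.box.lengths, cutoff)


def sample_insertion_energies(frames: Sequence[Configuration], n_insertions: int,
                              rng: np.random.Generator,
                              cutoff: float = DEFAULT_CUTOFF,
                              water: "Species" = None) -> np.ndarray:
    """Energy changes of uniform random ghost-water insertions.

    ``n_insertions`` is the total count, split evenly over the frames (the
    remainder goes to the first frames).  Frames are never modified.
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    water = water if water is not None else WATER_SPECIES
    per = np.full(len(frames), n_insertions // len(frames), dtype=int)
    per[: n_insertions % len(frames)] += 1
    out = []
    for frame, m in zip(frames, per):
        if m == 0:
            continue
        trials = rng.random((m, 3)) * frame.box.lengths
        out.append(K.ghost_insertion_energies(
            *_frame_kernel_args(frame, cutoff), water.epsilon, water.sigma,
            trials))
    return np.concatenate(out) if out else np.zeros(0)


def sample_deletion_energies(frames: Sequence[Configuration],
                             cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Energy changes of ghost-deleting every real water in every frame.

    Returns one reverse sample per water per frame (dU = -u_i with u_i the
    water's interaction energy).  An empty result flags the Widom-only
    fallback in :func:`estimate_mu`.
    """
    out = []
    for frame in frames:
        idx = frame.water_indices()
        if len(idx) == 0:
            continue
        u = K.particle_interaction_energies(
            *_frame_kernel_args(frame, cutoff), -1, 1.0, idx)
        out.append(-u)
    return np.concatenate(out) if out else np.zeros(0)


# -- estimators -----------------------------------------------------------

def _fermi_sum(x: np.ndarray) -> float:
    # sum of 1/(1+e^x), stable for large |x|
    return float(np.sum(np.exp(-np.logaddexp(0.0, x))))


def bar_estimate(samples: WorkSamples) -> ChemPotResult:
    """Excess chemical potential via Bennett's acceptance ratio.

    Solves the self-consistent Bennett equation by bracketed root finding to
    an absolute imbalance below 1e-10.  Falls back to the Widom average (with
    a logged warning) when the reverse set is empty.  Degenerate forward sets
    (all insertions rejected, +inf) return a +inf sentinel.
    """
    beta = samples.beta
    fwd = samples.forward
    rev = samples.reverse
    if samples.n_forward == 0:
        raise ValueError("forward sample set is empty")
    if not np.any(np.isfinite(fwd)):
        log.warning("all forward samples are infinite (hard overlap)")
        return ChemPotResult(mu_excess=math.inf)
    if samples.n_reverse == 0:
        log.warning("no reverse (deletion) samples; falling back to Widom")
        return ChemPotResult(mu_excess=widom_estimate(fwd, beta))

    def imbalance(c):
        return (_fermi_sum(beta * (fwd - c)) - _fermi_sum(beta * (rev + c)))

    # imbalance is strictly increasing in c (from -n_R to +n_F); expand a
    # bracket around a Widom-based initial guess until the sign changes
    c0 = widom_estimate(fwd, beta)
    if not np.isfinite(c0):
        c0 = float(np.median(fwd[np.isfinite(fwd)]))
    width = max(1.0, abs(c0))
    lo, hi = c0 - width, c0 + width
    for _ in range(200):
        if imbalance(lo) < 0 and imbalance(hi) > 0:
            break
        width *= 2.0
        lo, hi = c0 - width, c0 + width
    else:
        raise RuntimeError(
            "BAR bracket search failed; forward/reverse overlap statistics: "
            f"fwd median {np.median(fwd):.3g}, rev median {np.median(rev):.3g}")
    c = brentq(imbalance, lo, hi, xtol=1e-12)
    # polish: brentq's tolerance is on c, but the contract is on the imbalance
    if abs(imbalance(c)) > 1e-10:
        c = brentq(imbalance, c - 1e-6, c + 1e-6, xtol=1e-15)
    mu_ex = c + math.log(samples.n_forward / samples.n_reverse) / beta
    return ChemPotResult(mu_excess=float(mu_ex))


def widom_estimate(forward: np.ndarray, beta: float) -> float:
    """Widom test-particle estimate mu_ex = -kT ln <exp(-beta dU)>."""
    forward = np.asarray(forward, dtype=np.float64).reshape(-1)
    if len(forward) == 0:
        raise ValueError("forward sample set is empty")
    if not np.any(np.isfinite(-forward)):
        return math.inf
    # logsumexp handles the max-shift; -inf entries (rejected insertions)
    # contribute zero weight
    return float(-(logsumexp(-beta * forward) - math.log(len(forward))) / beta)


# -- ideal-gas reference, RH ----------------------------------------------

def mu_total(mu_excess: float, density: float, temperature: float,
             thermal_wavelength: float = 1.0, k_B: float = 1.0) -> float:
    """Total chemical potential mu = mu_ex + kT ln(rho Lambda^3)."""
    if density <= 0 or temperature <= 0:
        raise ValueError("density and temperature must be positive")
    return mu_excess + k_B * temperature * math.log(
        density * thermal_wavelength ** 3)


def mu_saturation(temperature: float, p_sat: float,
                  thermal_wavelength: float = 1.0, k_B: float = 1.0) -> float:
    """Saturation chemical potential from the ideal-gas law.

    mu_sat = kT ln(rho_sat Lambda^3) with rho_sat = p_sat / (kT).  The vapor
    is treated as ideal (mu_ex,vapor = 0).  The Lambda reference must match
    the one used in :func:`mu_total`; relative humidity is then independent
    of it.
    """
    if temperature <= 0 or p_sat <= 0:
        raise ValueError("temperature and p_sat must be positive")
    rho_sat = p_sat / (k_B * temperature)
    return k_B * temperature * math.log(rho_sat * thermal_wavelength ** 3)


def relative_humidity(mu_w: float, mu_sat: float, temperature: float,
                      k_B: float = 1.0) -> float:
    """RH in percent: 100 exp((mu_w - mu_sat) / kT).

    Values above 100 are returned as computed and flagged supersaturated in
    the log.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rh = 100.0 * math.exp((mu_w - mu_sat) / (k_B * temperature))
    if rh > 100.0:
        log.info("supersaturated state: RH = %.2f%%", rh)
    return rh


# -- block errors and the full per-h estimate ------------------------------

def block_stderr(values: np.ndarray, n_blocks: int = 5):
    """(mean of block means, stderr from the scatter of block means)."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    n_blocks = min(n_blocks, len(values))
    if n_blocks < 1:
        raise ValueError("need at least one value")
    m = len(values) // n_blocks
    blocks = values[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=0) / math.sqrt(n_blocks))


def estimate_mu(frames: Sequence[Configuration], n_insertions: int,
                temperature: float, rng: np.random.Generator,
                mu_sat: float = math.nan, cutoff: float = DEFAULT_CUTOFF,
                n_blocks: int = 5) -> ChemPotResult:
    """Full per-h-point estimate: BAR mu_ex, total mu, block stderr, RH.

    The headline value uses all frames pooled; the standard error comes from
    re-estimating mu on ``n_blocks`` contiguous frame blocks (trajectory block
    averaging).
    """
    beta = 1.0 / temperature
    fwd = sample_insertion_energies(frames, n_insertions, rng, cutoff)
    rev = sample_deletion_energies(frames, cutoff)
    res = bar_estimate(WorkSamples(fwd, rev, beta))
    n_w = np.mean([f.n_waters for f in frames])
    vol = frames[0].box.volume
    if n_w > 0 and np.isfinite(res.mu_excess):
        res.mu_total = mu_total(res.mu_excess, n_w / vol, temperature)
    # block analysis over frames
    nb = min(n_blocks, len(frames))
    if nb >= 2 and np.isfinite(res.mu_total):
        m = len(frames) // nb
        vals = []
        for b in range(nb):
            blk = frames[b * m:(b + 1) * m]
            bf = sample_insertion_energies(blk, max(1, n_insertions // nb), rng,
                                           cutoff)
            br = sample_deletion_energies(blk, cutoff)
            r = bar_estimate(WorkSamples(bf, br, beta))
            nw_b = np.mean([f.n_waters for f in blk])
            vals.append(mu_total(r.mu_excess, nw_b / vol, temperature)
                        if nw_b > 0 and np.isfinite(r.mu_excess) else np.nan)
        vals = np.asarray(vals)
        if np.all(np.isfinite(vals)):
            res.stderr = float(vals.std(ddof=0) / math.sqrt(nb))
    if np.isfinite(mu_sat) and np.isfinite(res.mu_total):
        res.rh = relative_humidity(res.mu_total, mu_sat, temperature)
    return res


#: liquid coexistence density of the toy (cutoff-truncated LJ) water at the
#: default study temperature T* = 0.9, used to calibrate mu_sat
DEFAULT_LIQUID_DENSITY = 0.75


def calibrate_mu_sat(temperature: float = 0.9,
                     liquid_density: float = DEFAULT_LIQUID_DENSITY,
                     n_particles: int = 216, seed: int = 0,
                     equil_sweeps: int = 600, production_sweeps: int = 300,
                     frame_interval: int = 15, n_insertions: int = 30000,
                     cutoff: float = DEFAULT_CUTOFF) -> float:
    """Saturation chemical potential of the toy water from the liquid side.

    Builds a pure-water box at the user-supplied liquid coexistence density,
    equilibrates it with Metropolis sweeps, and evaluates
    mu_sat = mu_ex(BAR) + kT ln(rho_liq) on the sampled frames.  At
    coexistence this equals the chemical potential of the saturated vapor.
    """
    from .model import Box, Topology
    from .sorption import relax

    rng = np.random.default_rng(seed)
    vol = n_particles / liquid_density
    L = vol ** (1.0 / 3.0)
    if L < 2 * cutoff:
        raise ValueError("calibration box too small for the cutoff")
    # start from a simple cubic lattice
    m = int(math.ceil(n_particles ** (1.0 / 3.0)))
    grid = np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"),
                    axis=-1).reshape(-1, 3)[:n_particles]
    pos = (grid + 0.5) * (L / m)
    box = Box([L, L, L])
    config = Configuration(pos, np.zeros(n_particles, dtype=int),
                           np.ones(n_particles, dtype=bool), Topology(), box,
                           [WATER_SPECIES])
    config = relax(config, equil_sweeps, temperature, rng, cutoff=cutoff)
    frames = []
    for _ in range(production_sweeps // frame_interval):
        config = relax(config, frame_interval, temperature, rng, cutoff=cutoff)
        frames.append(config.copy())
    res = estimate_mu(frames, n_insertions, temperature, rng, cutoff=cutoff)
    return res.mu_total
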