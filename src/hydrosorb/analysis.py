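"""Structural observables for hydrated-matrix trajectories.

Implements the hydration-structure analysis suite: Shrake-Rupley
solvent-accessible surface area, per-chain radius of gyration, averaged
inter-residue shortest-distance maps and their differences, water clustering
with periodic spanning-network detection, largest-cluster curves, first-shell
neighbor-count distributions, radial distribution functions with
first-minimum cutoff extraction, residue-level adsorption/desorption
hydration differences, and block-averaged error estimation.

All operators work on :class:`Frame` objects (or anything frame-like, e.g. a
:class:`~hydrosorb.model.Configuration`) under the minimum-image convention,
and accept either reduced-unit toy frames or Angstrom-unit frames read from
trajectory files: cutoffs are lengths in whatever unit the frame uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Box, Configuration, minimum_image

__all__ = [
    "Frame", "DistanceMap", "ClusterResult", "ShellHistogram", "as_frame",
    "sasa", "radius_of_gyration", "residue_distance_map",
    "distance_map_difference", "water_clusters", "largest_cluster_curve",
    "shell_count_distribution", "rdf", "first_minimum",
    "local_hydration_difference", "block_average", "golden_spiral_points",
    "hydration_level_of_frame",
]

#: reserved residue label carried by water particles
WATER_RESIDUE = -1


@dataclass
class Frame:
    """One trajectory snapshot with per-particle grouping labels."""

    positions: np.ndarray
    is_water: np.ndarray
    residue_ids: np.ndarray
    box: Box
    species_ids: np.ndarray = None
    masses: np.ndarray = None
    radii: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        n = len(self.positions)
        self.is_water = np.asarray(self.is_water, dtype=bool).reshape(-1)
        if self.residue_ids is None:
            self.residue_ids = np.where(self.is_water, WATER_RESIDUE, 0)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64).reshape(-1)
        if self.species_ids is None:
            self.species_ids = np.zeros(n, dtype=np.int64)
        if self.masses is None:
            self.masses = np.ones(n, dtype=np.float64)
        if self.radii is None:
            self.radii = np.full(n, 0.5, dtype=np.float64)

    @property
    def n_particles(self) -> int:
        return len(self.positions)


def as_frame(obj) -> Frame:
    """Coerce a Configuration (or Frame) into a Frame."""
    if isinstance(obj, Frame):
        return obj
    if isinstance(obj, Configuration):
        rid = obj.residue_ids
        if rid is None:
            rid = np.where(obj.is_water, WATER_RESIDUE, 0)
        return Frame(positions=obj.positions, is_water=obj.is_water,
                     residue_ids=rid, box=obj.box, species_ids=obj.species_ids,
                     masses=obj.masses(), radii=obj.sasa_radii())
    raise TypeError(f"cannot interpret {type(obj)!r} as a Frame")


def hydration_level_of_frame(frame) -> float:
    f = as_frame(frame)
    dry = f.masses[~f.is_water].sum()
    return float(f.masses[f.is_water].sum() / dry) if dry > 0 else math.nan


# -- geometry helpers ------------------------------------------------------

def _pair_displacements(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """(len(a), len(b), 3) minimum-image displacement tensor b - a."""
    d = b[None, :, :] - a[:, None, :]
    return minimum_image(d, box)


def _select(frame: Frame, which) -> np.ndarray:
    """Resolve a particle selection to an index array."""
    if isinstance(which, str):
        if which == "water":
            return np.flatnonzero(frame.is_water)
        if which == "matrix":
            return np.flatnonzero(~frame.is_water)
        if which == "all":
            return np.arange(frame.n_particles)
        raise ValueError(f"unknown selection {which!r}")
    return np.asarray(which, dtype=np.int64).reshape(-1)


def golden_spiral_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points on a golden-angle spiral lattice."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


# -- SASA ------------------------------------------------------------------

def sasa(frame, probe_radius: float = 0.5, n_sphere_points: int = 960,
         subset=None):
    """Shrake-Rupley solvent-accessible surface area with periodic neighbors.

    Each particle's accessible area is the fraction of quasi-uniform test
    points on its expanded sphere (radius + probe) that are not buried inside
    any neighbor's expanded sphere, scaled by 4 pi (r + probe)^2.  By default
    the surface of the matrix (non-water particles) is computed, with waters
    treated as solvent; pass ``subset`` to override.  Interior cavity surface
    is included.  Returns (per-particle areas over the subset, total).
    """
    f = as_frame(frame)
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be at least 32")
    idx = _select(f, "matrix" if subset is None else subset)
    pos = f.positions[idx]
    rad = f.radii[idx] + probe_radius
    sphere = golden_spiral_points(n_sphere_points)
    areas = np.zeros(len(idx))
    if len(idx) == 0:
        return areas, 0.0
    # neighbor pairs among the subset within R_i + R_j
    reach = 2.0 * rad.max()
    pairs = _neighbor_pairs(pos, f.box, reach)
    nbrs: List[List[int]] = [[] for _ in idx]
    for i, j in pairs:
        nbrs[i].append(j)
        nbrs[j].append(i)
    for i in range(len(idx)):
        pts = pos[i] + rad[i] * sphere
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in nbrs[i]:
            # nearest image of neighbor j relative to particle i
            pj = pos[i] + minimum_image(pos[j] - pos[i], f.box)
            d2 = np.einsum("pk,pk->p", pts - pj, pts - pj)
            tol = 1e-9 * rad[j] ** 2
            buried = d2 < rad[j] ** 2 - tol
            if j < i:
                # points exactly on a neighbor sphere belong to the
                # lower-index particle, so coincident spheres share a surface
                buried |= np.abs(d2 - rad[j] ** 2) <= tol
            exposed &= ~buried
        areas[i] = 4.0 * math.pi * rad[i] ** 2 * exposed.mean()
    return areas, float(areas.sum())


def _neighbor_pairs(pos: np.ndarray, box: Box, cutoff: float) -> np.ndarray:
    """Index pairs (i < j) with minimum-image distance below ``cutoff``."""
    n = len(pos)
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64)
    if box.fully_periodic and cutoff < 0.5 * box.lengths.min():
        wrapped = box.wrap(pos)
        # cKDTree requires strictly inside [0, L)
        wrapped = np.minimum(wrapped, np.nextafter(box.lengths, 0.0))
        tree = cKDTree(wrapped, boxsize=box.lengths)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs.astype(np.int64)
    d = _pair_displacements(pos, pos, box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    mask = np.triu(r2 < cutoff * cutoff, k=1)
    return np.column_stack(np.nonzero(mask)).astype(np.int64)


# -- radius of gyration ----------------------------------------------------

def _unwrap_group(pos: np.ndarray, box: Box, group: np.ndarray,
                  bonds: np.ndarray = None) -> np.ndarray:
    """Unwrap a group across periodic images.

    With ``bonds`` (pairs of particle indices) the group is unwrapped by a
    minimum-image walk over its bonded path and must be connected; without
    bonds every member is taken at its nearest image to the first member,
    which is valid for groups smaller than half the box.
    """
    g = np.asarray(group, dtype=np.int64)
    if bonds is None or len(bonds) == 0:
        ref = pos[g[0]]
        return ref + minimum_image(pos[g] - ref, box)
    local = {p: k for k, p in enumerate(g)}
    adj: List[List[int]] = [[] for _ in g]
    for i, j in bonds:
        if i in local and j in local:
            adj[local[i]].append(local[j])
            adj[local[j]].append(local[i])
    out = np.full((len(g), 3), np.nan)
    out[0] = pos[g[0]]
    stack = [0]
    seen = {0}
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if b not in seen:
                out[b] = out[a] + minimum_image(pos[g[b]] - pos[g[a]], box)
                seen.add(b)
                stack.append(b)
    if len(seen) != len(g):
        raise ValueError("group is split across the box without a bonded path")
    return out


def radius_of_gyration(frame, groups: Sequence[np.ndarray],
                       bonds: np.ndarray = None) -> float:
    """Mean mass-weighted radius of gyration over particle groups.

    Each group (e.g. one chain of the matrix) is unwrapped across the
    periodic boundary before computing Rg; the returned value is the
    unweighted mean of the per-group Rg values.
    """
    f = as_frame(frame)
    vals = []
    for group in groups:
        g = np.asarray(group, dtype=np.int64)
        if len(g) < 2:
            raise ValueError("each group needs at least two particles")
        pos = _unwrap_group(f.positions, f.box, g, bonds)
        m = f.masses[g]
        com = (m[:, None] * pos).sum(axis=0) / m.sum()
        rg2 = (m * np.einsum("ik,ik->i", pos - com, pos - com)).sum() / m.sum()
        vals.append(math.sqrt(rg2))
    return float(np.mean(vals))


# -- inter-residue distance maps -------------------------------------------

@dataclass
class DistanceMap:
    """Mean shortest inter-residue distances (symmetric, zero diagonal)."""

    values: np.ndarray
    n_frames: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def _residue_groups(frame: Frame) -> List[np.ndarray]:
    ids = np.unique(frame.residue_ids[~frame.is_water])
    return [np.flatnonzero((frame.residue_ids == r) & ~frame.is_water)
            for r in ids]


def residue_distance_map(frames: Iterable, grouping=None) -> DistanceMap:
    """Average over frames of the per-frame shortest inter-residue distances.

    The distance between two residues in one frame is the minimum over all
    atom pairs of the minimum-image distance; the map is the arithmetic mean
    of this over frames.  ``grouping`` may be a flat list of residue index
    arrays, a nested list (one residue list per protein copy, averaged over
    copies), or None to group by the frames' residue labels.
    """
    frames = [as_frame(fr) for fr in frames]
    if not frames:
        raise ValueError("no frames")
    nested = (grouping is not None and len(grouping) > 0
              and len(grouping[0]) > 0
              and isinstance(grouping[0][0], (list, tuple, np.ndarray)))
    copies = grouping if nested else [grouping]
    acc = None
    for fr in frames:
        per_copy = []
        for copy_groups in copies:
            groups = (_residue_groups(fr) if copy_groups is None
                      else [np.asarray(g, dtype=np.int64) for g in copy_groups])
            nr = len(groups)
            mat = np.zeros((nr, nr))
            for a in range(nr):
                for b in range(a + 1, nr):
                    d = _pair_displacements(fr.positions[groups[a]],
                                            fr.positions[groups[b]], fr.box)
                    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
                    mat[a, b] = mat[b, a] = r.min()
            per_copy.append(mat)
        frame_mat = np.mean(per_copy, axis=0)
        acc = frame_mat if acc is None else acc + frame_mat
    return DistanceMap(values=acc / len(frames), n_frames=len(frames))


def distance_map_difference(map_high, map_low) -> np.ndarray:
    """Elementwise difference of two distance maps (high minus low)."""
    a = map_high.values if isinstance(map_high, DistanceMap) else np.asarray(map_high)
    b = map_low.values if isinstance(map_low, DistanceMap) else np.asarray(map_low)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


# -- water clustering and percolation --------------------------------------

@dataclass
class ClusterResult:
    """Connected components of the water-water contact graph.

    ``labels`` assigns a cluster id to every water (in water-index order);
    ``spanning`` flags, per axis, whether any cluster connects to its own
    periodic image (i.e. percolates across the box).
    """

    labels: np.ndarray
    sizes: np.ndarray
    largest_fraction: float
    spanning: np.ndarray
    component_spanning: np.ndarray = field(default=None, repr=False)


def water_clusters(frame, cutoff: float = 3.5) -> ClusterResult:
    """Cluster waters whose pair distance is below ``cutoff``.

    Two waters are connected when their (minimum-image) distance is less than
    the cutoff.  Components are found by breadth-first search that tracks the
    periodic image vector of every member; a component spans an axis when a
    member is reachable through two paths whose image vectors differ there.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    f = as_frame(frame)
    widx = np.flatnonzero(f.is_water)
    nw = len(widx)
    if nw == 0:
        return ClusterResult(labels=np.zeros(0, dtype=int),
                             sizes=np.zeros(0, dtype=int),
                             largest_fraction=math.nan,
                             spanning=np.zeros(3, dtype=bool),
                             component_spanning=np.zeros((0, 3), dtype=bool))
    pos = f.positions[widx]
    raw = pos[None, :, :] - pos[:, None, :]  # j - i
    shift = np.zeros_like(raw)
    for ax in range(3):
        if f.box.periodic[ax]:
            L = f.box.lengths[ax]
            shift[..., ax] = np.floor(raw[..., ax] / L + 0.5)
            raw[..., ax] -= L * shift[..., ax]
    r2 = np.einsum("ijk,ijk->ij", raw, raw)
    adj = r2 < cutoff * cutoff
    np.fill_diagonal(adj, False)

    labels = np.full(nw, -1, dtype=int)
    comp_span: List[np.ndarray] = []
    n_comp = 0
    img = np.zeros((nw, 3), dtype=np.int64)
    for root in range(nw):
        if labels[root] >= 0:
            continue
        labels[root] = n_comp
        img[root] = 0
        span = np.zeros(3, dtype=bool)
        stack = [root]
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adj[i]):
                # image vector consistent with stepping i -> j
                sj = img[i] - shift[i, j].astype(np.int64)
                if labels[j] < 0:
                    labels[j] = n_comp
                    img[j] = sj
                    stack.append(j)
                elif np.any(img[j] != sj):
                    span |= img[j] != sj
        comp_span.append(span)
        n_comp += 1
    sizes = np.bincount(labels, minlength=n_comp)
    comp_span = np.array(comp_span, dtype=bool).reshape(n_comp, 3)
    return ClusterResult(labels=labels, sizes=sizes,
                         largest_fraction=float(sizes.max() / nw),
                         spanning=comp_span.any(axis=0),
                         component_spanning=comp_span)


def largest_cluster_curve(trajectories: Dict[float, Sequence], cutoff: float = 3.5,
                          n_blocks: int = 5) -> pd.DataFrame:
    """Block-averaged largest-cluster fraction as a function of h.

    ``trajectories`` maps hydration level to its frame list; returns a
    DataFrame with columns h, largest_fraction, stderr, sorted by h.
    """
    rows = []
    for h in sorted(trajectories):
        fr = [water_clusters(f, cutoff).largest_fraction
              for f in trajectories[h]]
        mean, err = block_average(np.asarray(fr), min(n_blocks, len(fr)))
        rows.append((h, mean, err))
    return pd.DataFrame(rows, columns=["h", "largest_fraction", "stderr"])


# -- shell histograms and RDFs ---------------------------------------------

@dataclass
class ShellHistogram:
    """Distribution of integer neighbor counts within a cutoff."""

    probabilities: np.ndarray
    center_label: str
    partner_label: str
    cutoff: float

    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.probabilities)),
                            self.probabilities))


def shell_count_distribution(frames: Iterable, centers, partners,
                             cutoff: float) -> ShellHistogram:
    """Histogram of partner counts within ``cutoff`` of each center particle.

    Counts are pooled over centers and frames and normalized; a center that is
    also a partner never counts itself.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = [as_frame(fr) for fr in frames]
    counts: List[int] = []
    for fr in frames:
        ci = _select(fr, centers)
        pi = _select(fr, partners)
        if len(ci) == 0:
            raise ValueError("center set is empty")
        if len(pi) == 0:
            counts.extend([0] * len(ci))
            continue
        d = _pair_displacements(fr.positions[ci], fr.positions[pi], fr.box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        within = r2 < cutoff * cutoff
        # remove self-pairs where the same particle is center and partner
        self_mask = ci[:, None] == pi[None, :]
        within &= ~self_mask
        counts.extend(within.sum(axis=1).tolist())
    hist = np.bincount(np.asarray(counts, dtype=int))
    prob = hist / hist.sum()
    return ShellHistogram(probabilities=prob,
                          center_label=str(centers), partner_label=str(partners),
                          cutoff=cutoff)


def rdf(frames: Iterable, set_a, set_b, r_max: float, n_bins: int = 100):
    """Radial distribution function g(r) between two particle sets.

    Pair-distance histogram normalized by the ideal-gas expectation
    (shell volume times partner density), averaged over frames.  Returns
    (bin centers, g).
    """
    frames = [as_frame(fr) for fr in frames]
    if not frames:
        raise ValueError("no frames")
    if r_max > 0.5 * min(f.box.lengths.min() for f in frames) + 1e-12:
        raise ValueError("r_max exceeds half the smallest box extent")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    norm = 0.0
    for fr in frames:
        ai = _select(fr, set_a)
        bi = _select(fr, set_b)
        d = _pair_displacements(fr.positions[ai], fr.positions[bi], fr.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        same = ai[:, None] == bi[None, :]
        r = r[~same]
        hist += np.histogram(r, bins=edges)[0]
        vol = fr.box.volume
        n_pairs_ideal = len(ai) * len(bi) - same.sum()
        norm += n_pairs_ideal / vol
    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (shell * norm)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


def first_minimum(r: np.ndarray, g: np.ndarray) -> float:
    """First local minimum of g(r) after its first maximum.

    The bin-center location is refined by a parabola through the minimum and
    its two neighbors.  Raises if no interior maximum is found.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    i_max = None
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 0:
            i_max = i
            break
    if i_max is None:
        raise ValueError("no maximum found in g(r)")
    i_min = None
    for i in range(i_max + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] < g[i + 1]:
            i_min = i
            break
    if i_min is None:
        raise ValueError("no minimum found after the first maximum of g(r)")
    y0, y1, y2 = g[i_min - 1], g[i_min], g[i_min + 1]
    denom = y0 - 2.0 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    dr = r[1] - r[0]
    return float(r[i_min] + offset * dr)


# -- branch-difference hydration and block averaging -----------------------

def local_hydration_difference(ads_frames: Sequence, des_frames: Sequence,
                               grouping=None, cutoff: float = 4.3,
                               h_tolerance: float = 0.05, n_blocks: int = 5):
    """Per-residue water-count difference between the two sorption branches.

    For every residue, the mean number of waters within ``cutoff`` of any of
    its atoms is computed on the adsorption frames and on the desorption
    frames (which must sit at the same hydration level within
    ``h_tolerance``); returns (adsorption minus desorption, combined block
    standard error), both per residue.  Swapping the inputs negates the
    difference exactly.
    """
    ads = [as_frame(f) for f in ads_frames]
    des = [as_frame(f) for f in des_frames]
    h_a = np.mean([hydration_level_of_frame(f) for f in ads])
    h_d = np.mean([hydration_level_of_frame(f) for f in des])
    if abs(h_a - h_d) > h_tolerance:
        raise ValueError(
            f"branches are at different hydration levels ({h_a:.3f} vs {h_d:.3f})")
    groups = ([np.asarray(g, dtype=np.int64) for g in grouping]
              if grouping is not None else _residue_groups(ads[0]))

    def per_frame_counts(frames):
        out = np.zeros((len(frames), len(groups)))
        for k, fr in enumerate(frames):
            wi = np.flatnonzero(fr.is_water)
            for gi, g in enumerate(groups):
                if len(wi) == 0:
                    continue
                d = _pair_displacements(fr.positions[g], fr.positions[wi], fr.box)
                r2 = np.einsum("ijk,ijk->ij", d, d)
                out[k, gi] = np.count_nonzero((r2 < cutoff * cutoff).any(axis=0))
        return out

    ca = per_frame_counts(ads)
    cd = per_frame_counts(des)
    diff = ca.mean(axis=0) - cd.mean(axis=0)
    err = np.zeros(len(groups))
    for gi in range(len(groups)):
        _, ea = block_average(ca[:, gi], min(n_blocks, len(ads)))
        _, ed = block_average(cd[:, gi], min(n_blocks, len(des)))
        err[gi] = math.hypot(ea, ed)
    return diff, err


def block_average(series: np.ndarray, n_blocks: int = 5):
    """Mean and standard error from contiguous-block analysis.

    The series is split into ``n_blocks`` equal blocks (trailing remainder
    elements dropped); the standard error is the standard deviation of the
    block means divided by sqrt(n_blocks).
    """
    series = np.asarray(series, dtype=np.float64).reshape(-1)
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    if len(series) < n_blocks:
        raise ValueError("series shorter than the number of blocks")
    m = len(series) // n_blocks
    blocks = series[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=0) / math.sqrt(n_blocks))
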