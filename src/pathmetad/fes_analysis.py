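"""Basin analysis of free-energy surfaces and GROMOS trajectory clustering.

Minima on the gridded FES are detected in the 8-neighbourhood, grown into
basins by discrete steepest descent, and filtered by topological persistence:
a minimum whose lowest escape saddle lies less than ``min_depth`` above it is
merged into the deeper basin it drains to.  ``min_depth`` defaults to 1.5
kcal/mol, the isoline spacing at which such surfaces are typically read.
Basins are labelled A, B, C, ... by increasing free energy.

Frames harvested from the biased trajectory are assigned to basins through
their (s, z) values and clustered per basin with the GROMOS algorithm
(greedy neighbour-count clustering at a fixed RMSD cutoff); the centroid of
the most populated cluster is the representative structure of the minimum.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .toy_systems import ParameterError
from .wtmetad import ColvarSeries, FreeEnergySurface
from . import pathcv


@dataclass
class Basin:
    label: str
    location: tuple              # (s, z) of the grid minimum
    depth: float                 # F at the minimum, relative to the global min
    region: np.ndarray           # boolean mask over the FES grid
    member_frames: list = field(default_factory=list)


@dataclass
class Cluster:
    members: list                # frame indices, centre included
    center: int                  # index of the max-neighbour frame

    @property
    def population(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# minima and basins
# ---------------------------------------------------------------------------

def _neighbors(i, j, ns, nz):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < ns and 0 <= b < nz:
                yield a, b


def find_minima(fes: FreeEnergySurface, min_depth: float = 1.5) -> list:
    """Locate significant FES basins.

    All 8-neighbourhood local minima are found, every grid cell is assigned
    to its attracting minimum by steepest descent, and minima with
    persistence (lowest connecting saddle minus the minimum) below
    ``min_depth`` are merged into the neighbouring deeper basin.  The global
    minimum always survives.  Returns basins ordered and labelled by
    increasing free energy.
    """
    f = fes.F
    ns, nz = f.shape
    flat = f.ravel()
    order = np.argsort(flat, kind="stable")

    # steepest-descent attractor for every cell
    attract = np.full(ns * nz, -1, dtype=int)

    def descend(idx: int) -> int:
        trail = []
        while attract[idx] == -1:
            trail.append(idx)
            i, j = divmod(idx, nz)
            best, bestv = idx, flat[idx]
            for a, b in _neighbors(i, j, ns, nz):
                k = a * nz + b
                if flat[k] < bestv or (flat[k] == bestv and k < best):
                    best, bestv = k, flat[k]
            if best == idx:          # local minimum
                attract[idx] = idx
                break
            idx = best
        root = attract[idx] if attract[idx] != -1 else idx
        for t in trail:
            attract[t] = root
        return root

    for idx in range(ns * nz):
        descend(idx)
    minima = np.unique(attract[attract == np.arange(ns * nz)])

    # persistence by flooding: process cells by increasing F; union-find
    parent = {int(m): int(m) for m in minima}
    merged_into = {}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    comp = np.full(ns * nz, -1, dtype=int)
    for idx in order:
        i, j = divmod(int(idx), nz)
        roots = set()
        for a, b in _neighbors(i, j, ns, nz):
            k = a * nz + b
            if comp[k] != -1:
                roots.add(find(comp[k]))
        if not roots:
            comp[idx] = attract[idx]
            continue
        roots = sorted(roots, key=lambda m: (flat[m], m))
        deepest = roots[0]
        for r in roots[1:]:
            persistence = flat[idx] - flat[r]
            if persistence < min_depth:
                parent[r] = deepest
                merged_into[r] = deepest
        comp[idx] = deepest

    survivors = sorted({find(int(m)) for m in minima}, key=lambda m: (flat[m], m))

    if fes.bias is not None:
        visited = (fes.bias > 1e-12).ravel()
    else:
        visited = np.ones(ns * nz, dtype=bool)

    labels = list(string.ascii_uppercase)
    basins = []
    final = np.array([find(int(a)) for a in attract])
    for rank, m in enumerate(survivors):
        mask = (final == m) & visited
        i, j = divmod(m, nz)
        basins.append(Basin(
            label=labels[rank % 26] * (rank // 26 + 1),
            location=(float(fes.s_grid[i]), float(fes.z_grid[j])),
            depth=float(flat[m] - flat[survivors[0]]),
            region=mask.reshape(ns, nz),
        ))
    return basins


def assign_frames(
    colvar: ColvarSeries,
    basins: Sequence[Basin],
    fes: FreeEnergySurface,
    stride: float = 10.0,
) -> list:
    """Assign strided trajectory snapshots to basins by their (s, z).

    Snapshots are taken every ``stride`` ps; each one falling in a basin's
    region (nearest grid cell) is appended to that basin's member list as its
    index into the colvar series.  Basin regions are disjoint, so no frame is
    assigned twice; frames outside all regions stay unassigned.
    """
    if stride <= 0:
        raise ParameterError(f"stride must be positive, got {stride}")
    for b in basins:
        b.member_frames = []
    t = colvar.times
    next_t = t[0]
    sg, zg = fes.s_grid, fes.z_grid
    for idx in range(len(t)):
        if t[idx] + 1e-9 < next_t:
            continue
        next_t = t[idx] + stride
        i = int(np.argmin(np.abs(sg - colvar.s[idx])))
        j = int(np.argmin(np.abs(zg - colvar.z[idx])))
        for b in basins:
            if b.region[i, j]:
                b.member_frames.append(idx)
                break
    return list(basins)


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd(
    frames: Sequence[np.ndarray],
    distance_selection=None,
    align_selection=None,
) -> np.ndarray:
    """Pairwise RMSD matrix (A) over frames.

    With ``align_selection`` given, each pair is optimally superposed first
    (:func:`pathmetad.pathcv.frame_distance`); otherwise the plain RMSD over
    ``distance_selection`` (default: all atoms) is used, appropriate when
    frames share a fixed reference frame such as a frozen host.
    """
    n = len(frames)
    sel = (np.arange(len(frames[0])) if distance_selection is None
           else np.asarray(distance_selection, dtype=int))
    if align_selection is None:
        # fixed-reference frames: vectorised plain RMSD
        x = np.stack([np.asarray(f, dtype=float)[sel] for f in frames])
        x = x.reshape(n, -1)
        g = x @ x.T
        sq = np.diag(g)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * g, 0.0) / len(sel)
        return np.sqrt(d2)
    m = np.zeros((n, n))
    for i in range(n):
        fi = np.asarray(frames[i], dtype=float)
        for j in range(i + 1, n):
            d = math.sqrt(pathcv.frame_distance(
                fi, np.asarray(frames[j], dtype=float), align_selection, sel))
            m[i, j] = m[j, i] = d
    return m


def gromos_cluster(
    frames: Sequence[np.ndarray],
    cutoff: float = 2.0,
    distance_matrix: Optional[np.ndarray] = None,
    distance_selection=None,
    align_selection=None,
) -> list:
    """GROMOS clustering at a fixed RMSD cutoff.

    Repeatedly: count, for every unassigned frame, its neighbours within
    ``cutoff``; the frame with the most neighbours (ties: lowest index)
    becomes a cluster centre and is removed together with its neighbours.
    Clusters are returned by decreasing population (ties keep extraction
    order).  Every member is within ``cutoff`` of its centre, clusters are
    disjoint, and their union is the input set.
    """
    n = len(frames)
    if n < 1:
        raise ParameterError("at least one frame is required")
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    d = (pairwise_rmsd(frames, distance_selection, align_selection)
         if distance_matrix is None else np.asarray(distance_matrix, dtype=float))
    within = d <= cutoff
    alive = np.ones(n, dtype=bool)
    clusters = []
    while alive.any():
        counts = (within & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))      # argmax takes the lowest index on ties
        members = np.where(within[center] & alive)[0]
        clusters.append(Cluster(members=members.tolist(), center=center))
        alive[members] = False
    clusters.sort(key=lambda c: -c.population)
    return clusters


def representative_structure(
    basin: Basin,
    clusters: Sequence[Cluster],
    frames: Optional[Sequence[np.ndarray]] = None,
):
    """Centroid of the most populated cluster of a basin's members.

    ``clusters`` must come from clustering the basin's member frames; ties in
    population resolve to the cluster whose centre has the lower frame index.
    Returns the centre's index into the clustered frame list (and the frame
    itself when ``frames`` is given).
    """
    if not basin.member_frames and not clusters:
        raise ParameterError(f"basin {basin.label} has no member frames")
    if not clusters:
        raise ParameterError("no clusters given")
    best = min(clusters, key=lambda c: (-c.population, c.center))
    if frames is not None:
        return best.center, np.asarray(frames[best.center], dtype=float)
    return best.center
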