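"""Reference paths and path collective variables (PCVs).

A reference path is an ordered set of frames tracing the unbinding event,
built from the lowest-work steered trajectory (inner, cavity-to-mouth
segment, frames picked equally spaced in RMSD) plus a linearly interpolated
outer segment to a bulk end frame.  Progress along the path and distance
from it are the PCVs of Branduardi-type form

    s(R) = sum_i i exp(-lambda d_i) / sum_i exp(-lambda d_i)
    z(R) = -(1/lambda) ln sum_i exp(-lambda d_i)

where d_i is the mean-square deviation (A^2) between the configuration R and
path frame i after optimal rigid superposition on an alignment selection.
lambda carries inverse squared-distance units (A^-2 internally, nm^-2 at the
I/O boundary; 1 nm^2 = 100 A^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .toy_systems import ParameterError, Trajectory


class AlignmentError(ValueError):
    """Alignment selection is degenerate (coincident or collinear points)."""


# ---------------------------------------------------------------------------
# frame metric
# ---------------------------------------------------------------------------

def superpose(ref: np.ndarray, target: np.ndarray, align_selection) -> np.ndarray:
    """Rigidly superpose ``ref`` onto ``target`` (both (n, 3)).

    Rotation and translation minimise the squared deviation over
    ``align_selection``; the transform is then applied to all atoms of
    ``ref``.  Raises :class:`AlignmentError` when the selection does not
    determine the rotation (fewer than 3 non-collinear points).
    """
    sel = np.asarray(align_selection, dtype=int)
    p = np.asarray(target, dtype=float)[sel]
    q = np.asarray(ref, dtype=float)[sel]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if len(sel) < 3 or np.linalg.matrix_rank(q0, tol=1e-8) < 2:
        raise AlignmentError(
            "alignment selection is degenerate: need >= 3 non-collinear points"
        )
    h = q0.T @ p0
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt             # maps centred ref -> centred target
    return (np.asarray(ref, dtype=float) - qc) @ rot + pc


def frame_distance(
    config: np.ndarray,
    ref: np.ndarray,
    align_selection,
    distance_selection,
) -> float:
    """Mean-square deviation (A^2) between two frames after optimal rigid
    superposition of ``ref`` onto ``config`` using ``align_selection``."""
    align_selection = np.asarray(align_selection, dtype=int)
    distance_selection = np.asarray(distance_selection, dtype=int)
    if align_selection.size == 0 or distance_selection.size == 0:
        raise ParameterError("selections must be non-empty")
    fitted = superpose(ref, config, align_selection)
    diff = np.asarray(config, dtype=float)[distance_selection] - fitted[distance_selection]
    return float(np.mean(np.sum(diff * diff, axis=1)))


# ---------------------------------------------------------------------------
# reference path
# ---------------------------------------------------------------------------

@dataclass
class ReferencePath:
    """Ordered frames defining the s/z coordinate system."""

    frames: list                     # list of (n_atoms, 3) arrays
    align_selection: np.ndarray
    distance_selection: np.ndarray
    lambda_: float                   # A^-2
    spacing_target: float            # A, RMSD between adjacent inner frames
    n_smd_frames: Optional[int] = None

    def __post_init__(self):
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        self.align_selection = np.asarray(self.align_selection, dtype=int)
        self.distance_selection = np.asarray(self.distance_selection, dtype=int)
        if len(self.frames) < 3:
            raise ParameterError("a reference path needs at least 3 frames")
        if self.lambda_ <= 0:
            raise ParameterError(f"lambda must be positive, got {self.lambda_}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def adjacent_distances(self) -> np.ndarray:
        """RMSD (A) between consecutive frames."""
        return np.array([
            math.sqrt(frame_distance(
                self.frames[i + 1], self.frames[i],
                self.align_selection, self.distance_selection,
            ))
            for i in range(self.n_frames - 1)
        ])


def _frames_of(seed) -> list:
    if isinstance(seed, Trajectory):
        return [seed.frame_coords(i) for i in range(len(seed))]
    return [np.asarray(f, dtype=float) for f in seed]


def build_reference_path(
    seed_traj,
    spacing: float,
    n_smd_frames: int,
    end_frame: np.ndarray,
    n_interp: int,
    align_selection,
    distance_selection,
    guest_indices=None,
    lambda_: Optional[float] = None,
) -> ReferencePath:
    """Build the hybrid reference path.

    The inner segment takes ``n_smd_frames`` frames from ``seed_traj`` by a
    greedy forward scan: starting from the first frame, a frame is emitted
    whenever its RMSD from the last emitted frame reaches ``spacing``.  The
    outer segment appends ``n_interp`` frames interpolating the guest
    coordinates linearly from the last selected frame to ``end_frame``
    (guest fully in bulk); host coordinates are held fixed at the last inner
    frame.  If ``lambda_`` is omitted it is set by :func:`choose_lambda`.
    """
    if spacing <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing}")
    if n_smd_frames < 2 or n_interp < 1:
        raise ParameterError("need at least 2 inner and 1 interpolated frames")
    frames_in = _frames_of(seed_traj)
    align_selection = np.asarray(align_selection, dtype=int)
    distance_selection = np.asarray(distance_selection, dtype=int)
    if guest_indices is None:
        guest_indices = distance_selection
    guest_indices = np.asarray(guest_indices, dtype=int)

    selected = [frames_in[0]]
    last = frames_in[0]
    for f in frames_in[1:]:
        if len(selected) == n_smd_frames:
            break
        d = math.sqrt(frame_distance(f, last, align_selection, distance_selection))
        if d >= spacing:
            selected.append(f)
            last = f
    if len(selected) < n_smd_frames:
        raise ParameterError(
            f"seed trajectory too short for {n_smd_frames} frames at spacing "
            f"{spacing} A; only {len(selected)} achievable"
        )

    end_frame = np.asarray(end_frame, dtype=float)
    base = selected[-1].copy()
    interp = []
    for k in range(1, n_interp + 1):
        f = base.copy()
        frac = k / n_interp
        f[guest_indices] = (1 - frac) * base[guest_indices] + frac * end_frame[guest_indices]
        interp.append(f)

    frames = selected + interp
    path = ReferencePath(
        frames=frames,
        align_selection=align_selection,
        distance_selection=distance_selection,
        lambda_=1.0,  # placeholder until chosen below
        spacing_target=spacing,
        n_smd_frames=n_smd_frames,
    )
    path.lambda_ = lambda_ if lambda_ is not None else choose_lambda(path)
    return path


def rmsd_matrix(path: ReferencePath, tolerance: float = 1e-6):
    """Pairwise frame RMSD matrix (A) and the gull-wing diagnostic.

    A well-spaced path produces a symmetric matrix whose rows are unimodal
    with the minimum on the diagonal and entries growing monotonically with
    |i - j|; the diagnostic fails when any row violates monotonicity by more
    than ``tolerance``.
    """
    n = path.n_frames
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = math.sqrt(frame_distance(
                path.frames[j], path.frames[i],
                path.align_selection, path.distance_selection,
            ))
            m[i, j] = m[j, i] = d
    ok = True
    for i in range(n):
        right = m[i, i:]
        left = m[i, :i + 1][::-1]
        for arm in (right, left):
            if np.any(np.diff(arm) < -tolerance):
                ok = False
    return m, ok


def choose_lambda(path: ReferencePath, multiplier: float = 1.0) -> float:
    """Default PCV sharpness: lambda = ln 2 / <d_adj> so that the weight of a
    neighbouring frame is one half, times an optional multiplier."""
    if path.n_frames < 2:
        raise ParameterError("need at least 2 frames to choose lambda")
    d2 = path.adjacent_distances() ** 2
    mean = float(d2.mean())
    if mean <= 0:
        raise ParameterError("adjacent frames coincide; cannot choose lambda")
    return multiplier * math.log(2.0) / mean


# ---------------------------------------------------------------------------
# PCV evaluation
# ---------------------------------------------------------------------------

@dataclass
class PCVValue:
    s: float            # path progress, in [1, N]
    z: float            # A^2
    grad_s: Optional[np.ndarray] = None   # (n_mobile, 3), d s / d x
    grad_z: Optional[np.ndarray] = None


def _pcv_from_distances(d: np.ndarray, lambda_: float):
    """(s, z, softmax weights) from per-frame squared distances, overflow-safe."""
    a = -lambda_ * d
    m = float(a.max())
    w = np.exp(a - m)
    tot = float(w.sum())
    p = w / tot
    idx = np.arange(1, len(d) + 1, dtype=float)
    s = float(idx @ p)
    z = -(m + math.log(tot)) / lambda_
    return s, z, p


def pcv_evaluate(
    config: np.ndarray,
    path: ReferencePath,
    gradient_indices=None,
) -> PCVValue:
    """Evaluate s(R) and z(R), optionally with gradients.

    ``gradient_indices`` selects the mobile atoms with respect to which the
    gradients are returned; these must not be part of the alignment
    selection (the superposition then does not depend on them and the
    gradients are exact).
    """
    config = np.asarray(config, dtype=float)
    n = path.n_frames
    dsel = path.distance_selection
    mvec = len(dsel)
    d = np.empty(n)
    fitted = []
    for i, ref in enumerate(path.frames):
        fr = superpose(ref, config, path.align_selection)
        diff = config[dsel] - fr[dsel]
        d[i] = float(np.mean(np.sum(diff * diff, axis=1)))
        fitted.append(fr)
    if not np.all(np.isfinite(d)):
        raise ParameterError("non-finite frame distance in PCV evaluation")
    s, z, p = _pcv_from_distances(d, path.lambda_)

    if gradient_indices is None:
        return PCVValue(s=s, z=z)

    gidx = np.asarray(gradient_indices, dtype=int)
    if np.intersect1d(gidx, path.align_selection).size:
        raise ParameterError(
            "gradient atoms must be outside the alignment selection"
        )
    # position of each gradient atom inside the distance selection
    pos = np.array([np.where(dsel == g)[0][0] for g in gidx])
    idx = np.arange(1, n + 1, dtype=float)
    grad_s = np.zeros((len(gidx), 3))
    grad_z = np.zeros((len(gidx), 3))
    lam = path.lambda_
    for i in range(n):
        dd = (2.0 / mvec) * (config[dsel][pos] - fitted[i][dsel][pos])  # d d_i / d x
        grad_s += (-lam) * p[i] * (idx[i] - s) * dd
        grad_z += p[i] * dd
    return PCVValue(s=s, z=z, grad_s=grad_s, grad_z=grad_z)


class PathCVMapping:
    """Maps mobile coordinates of a simulated system to (s, z) with gradients.

    Used as the CV interface for metadynamics on bead systems.  When the host
    is frozen and identical in every reference frame, the superposition is
    the identity and evaluation reduces to distances between the guest bead
    and the per-frame reference guest positions, which is what the biased
    inner loop uses; otherwise the full superposition route is taken.
    """

    n_cv = 2

    def __init__(self, path: ReferencePath, system):
        self.path = path
        self.system = system
        self.guest_atoms = np.asarray(system.guest_indices, dtype=int)
        self._template = system.frame_coords(system.default_start())
        self._fast = self._check_fast()
        if self._fast:
            dsel = path.distance_selection
            self._refs = np.stack([f[dsel] for f in path.frames])  # (N, M, 3)
            self._mvec = len(dsel)

    def _check_fast(self) -> bool:
        if getattr(self.system, "tether_k", None) is not None:
            return False
        asel = self.path.align_selection
        dsel = self.path.distance_selection
        if np.intersect1d(dsel, asel).size:
            return False
        if not np.all(np.isin(dsel, self.guest_atoms)):
            return False
        ref0 = self.path.frames[0]
        return all(
            np.allclose(f[asel], ref0[asel], atol=1e-9) for f in self.path.frames
        ) and np.allclose(self._template[asel], ref0[asel], atol=1e-9)

    def evaluate(self, x: np.ndarray):
        """Return ``(s, z, ds_dx, dz_dx)`` for mobile coordinates ``x``."""
        if self._fast:
            guest = x[:2]
            rel = self._refs[:, :, :2] - guest          # (N, M, 2)
            d = np.einsum("nmk,nmk->n", rel, rel) / self._mvec
            s, z, p = _pcv_from_distances(d, self.path.lambda_)
            idx = np.arange(1, len(d) + 1, dtype=float)
            dd = (-2.0 / self._mvec) * rel.sum(axis=1)  # (N, 2): d d_i / d guest
            lam = self.path.lambda_
            ds = (-lam) * ((p * (idx - s)) @ dd)
            dz = p @ dd
            ds_dx = np.zeros_like(x)
            dz_dx = np.zeros_like(x)
            ds_dx[:2] = ds
            dz_dx[:2] = dz
            return s, z, ds_dx, dz_dx
        config = self.system.frame_coords(x)
        val = pcv_evaluate(config, self.path, gradient_indices=self.guest_atoms)
        ds_dx = np.zeros_like(x)
        dz_dx = np.zeros_like(x)
        # mobile layout: guest xy first, then (optionally) host xy
        ds_dx[:2] = val.grad_s[0, :2]
        dz_dx[:2] = val.grad_z[0, :2]
        return val.s, val.z, ds_dx, dz_dx


class IdentityCVMapping:
    """s = the single coordinate, z = 0: for 1D model potentials where the
    path coordinate is the coordinate itself."""

    n_cv = 2

    def __init__(self, index: int = 0):
        self.index = index

    def evaluate(self, x: np.ndarray):
        ds = np.zeros_like(x)
        ds[self.index] = 1.0
        return float(x[self.index]), 0.0, ds, np.zeros_like(x)
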