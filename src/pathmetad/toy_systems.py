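"""Model systems and the overdamped Langevin engine.

Everything downstream (steered pulls, path building, metadynamics) runs on
the systems defined here: analytic low-dimensional potentials with exact
gradients, and a two-dimensional bead host--guest system whose guest sits in
a buried cavity connected to bulk by two gated channels with independently
tunable barriers.  The host--guest system is the desk-scale analogue of a
ligand buried in a protein cavity with two unbinding routes of different
difficulty.

Units: kcal/mol, Angstrom, ps, Kelvin (see :mod:`pathmetad.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .units import KB, kbt


class ParameterError(ValueError):
    """Invalid model or integrator parameter."""


class IntegrationError(RuntimeError):
    """Trajectory left the domain or produced non-finite coordinates."""


class ConstructionError(RuntimeError):
    """A requested model system cannot be realised."""


# ---------------------------------------------------------------------------
# potential surfaces
# ---------------------------------------------------------------------------

@dataclass
class PotentialSurface:
    """An analytic potential with exact gradient.

    Parameters
    ----------
    dimensionality:
        Number of configuration coordinates.
    energy:
        Maps a configuration (ndarray of shape ``(dimensionality,)``, or a
        scalar for 1D) to energy in kcal/mol.
    gradient:
        Maps a configuration to the energy gradient, kcal/mol/A.
    domain_bounds:
        Array ``(dimensionality, 2)`` of [lo, hi] per coordinate; dynamics
        aborts if a trajectory leaves this box.
    """

    dimensionality: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain_bounds: np.ndarray
    metadata: dict = field(default_factory=dict)

    def default_start(self) -> np.ndarray:
        start = self.metadata.get("default_start")
        if start is None:
            start = self.domain_bounds.mean(axis=1)
        return np.atleast_1d(np.asarray(start, dtype=float)).copy()


def make_double_well(
    barrier: float, separation: float, asymmetry: float = 0.0
) -> PotentialSurface:
    """Quartic 1D double well with prescribed barrier and well asymmetry.

    The potential is ``U(x) = c (x^4/4 - b x^3/3 - a^2 x^2/2 + a^2 b x)``
    whose stationary points are exactly ``-a`` (deep minimum A), ``+a``
    (shallow minimum B, with ``U(+a) - U(-a) = asymmetry``) and ``b`` (the
    barrier top, with ``U(b) - U(-a) = barrier``).  ``a = separation / 2``.
    The tilt location ``b`` and overall scale ``c`` are solved from the two
    requested energies, so both are met to machine precision.
    """
    if barrier <= 0:
        raise ParameterError(f"barrier must be positive, got {barrier}")
    if separation <= 0:
        raise ParameterError(f"separation must be positive, got {separation}")
    if asymmetry < 0:
        raise ParameterError(f"asymmetry must be non-negative, got {asymmetry}")
    if asymmetry >= barrier:
        raise ParameterError(
            "asymmetry must be smaller than the barrier or the shallow well vanishes"
        )

    a = separation / 2.0

    def _u_unit(x: float, b: float) -> float:
        # c = 1 reference shape
        return x**4 / 4.0 - b * x**3 / 3.0 - a**2 * x**2 / 2.0 + a**2 * b * x

    if asymmetry == 0.0:
        b = 0.0
    else:
        target = asymmetry / barrier

        def _ratio(b: float) -> float:
            return (_u_unit(a, b) - _u_unit(-a, b)) / (_u_unit(b, b) - _u_unit(-a, b))

        b = brentq(lambda bb: _ratio(bb) - target, 0.0, a * (1 - 1e-12), xtol=1e-14)

    c = barrier / (_u_unit(b, b) - _u_unit(-a, b))
    u_min = c * _u_unit(-a, b)

    def energy(x):
        x = float(np.asarray(x).reshape(()))
        return c * (x**4 / 4.0 - b * x**3 / 3.0 - a**2 * x**2 / 2.0 + a**2 * b * x) - u_min

    def gradient(x):
        x = float(np.asarray(x).reshape(()))
        return np.array([c * (x - a) * (x + a) * (x - b)])

    # domain: where the walls rise ~15 kcal/mol above the barrier top
    lim = barrier + 15.0
    hi = brentq(lambda x: (c * _u_unit(x, b) - u_min) - lim, a, 50 * a)
    lo = brentq(lambda x: (c * _u_unit(x, b) - u_min) - lim, -50 * a, -a)

    surf = PotentialSurface(
        dimensionality=1,
        energy=energy,
        gradient=gradient,
        domain_bounds=np.array([[lo, hi]]),
        metadata={
            "kind": "double_well",
            "minima": (-a, a),
            "barrier_top": b,
            "barrier": barrier,
            "asymmetry": asymmetry,
            "default_start": -a,
        },
    )
    return surf


def double_well_free_energy_difference(surf: PotentialSurface, temperature: float) -> float:
    """Exact well-to-well free-energy difference F(B) - F(A) by quadrature.

    Basins are split at the barrier top; each basin partition function is the
    Boltzmann integral of the potential over its basin.  Used as the
    independent oracle against which biased-sampling estimates are compared.
    """
    if surf.metadata.get("kind") != "double_well":
        raise ParameterError("quadrature oracle only defined for double-well surfaces")
    kT = kbt(temperature)
    b = surf.metadata["barrier_top"]
    lo, hi = surf.domain_bounds[0]
    za, _ = quad(lambda x: math.exp(-surf.energy(x) / kT), lo, b, limit=200)
    zb, _ = quad(lambda x: math.exp(-surf.energy(x) / kT), b, hi, limit=200)
    return -kT * math.log(zb / za)


# ---------------------------------------------------------------------------
# bead host--guest system
# ---------------------------------------------------------------------------

@dataclass
class ChannelDefinition:
    name: str
    direction: np.ndarray        # unit vector from cavity centre through the gate
    designed_barrier: float      # kcal/mol
    gate_height: float           # calibrated Gaussian repulsion amplitude
    gate_index: int              # index of the gate bead in host_coords


@dataclass
class BeadSystem:
    """2D bead model: a ring of repulsive host beads encloses an attractive
    cavity; two gaps in the ring are blocked by "gate" beads whose repulsion
    heights are calibrated so each channel presents its designed barrier.

    The guest is a single mobile bead.  Host beads are frozen by default;
    with ``tether_k`` set they become mobile on harmonic tethers to their
    reference positions (a stand-in for gate/mouth flexibility).
    """

    host_coords: np.ndarray                 # (n_host, 2) reference positions
    guest_indices: tuple                    # indices of guest bead(s) in a Frame
    channel_definitions: dict               # name -> ChannelDefinition
    bead_heights: np.ndarray                # per-host-bead Gaussian amplitude
    bead_widths: np.ndarray                 # per-host-bead Gaussian width, A
    cavity_depth: float                     # kcal/mol, designed bound-minimum depth
    cavity_amp: float                       # kcal/mol, Gaussian amplitude realising it
    cavity_width: float                     # A
    ring_radius: float
    box_half: float
    tether_k: Optional[float] = None        # kcal/mol/A^2, None = frozen host

    # -- PotentialSurface-style interface on the mobile coordinates --------
    @property
    def dimensionality(self) -> int:
        if self.tether_k is None:
            return 2
        return 2 + 2 * len(self.host_coords)

    @property
    def domain_bounds(self) -> np.ndarray:
        b = self.box_half
        return np.tile([-b, b], (self.dimensionality, 1)).astype(float)

    def default_start(self) -> np.ndarray:
        guest = np.zeros(2)
        if self.tether_k is None:
            return guest
        return np.concatenate([guest, self.host_coords.ravel()])

    def _split(self, x: np.ndarray):
        x = np.asarray(x, dtype=float).ravel()
        guest = x[:2]
        host = self.host_coords if self.tether_k is None else x[2:].reshape(-1, 2)
        return guest, host

    def energy(self, x) -> float:
        guest, host = self._split(x)
        d2 = np.sum((host - guest) ** 2, axis=1)
        e = float(np.sum(self.bead_heights * np.exp(-d2 / (2 * self.bead_widths**2))))
        e -= self.cavity_amp * math.exp(
            -float(guest @ guest) / (2 * self.cavity_width**2)
        )
        if self.tether_k is not None:
            disp = host - self.host_coords
            e += 0.5 * self.tether_k * float(np.sum(disp**2))
        return e

    def gradient(self, x) -> np.ndarray:
        guest, host = self._split(x)
        rel = guest - host                                     # (n, 2)
        d2 = np.sum(rel**2, axis=1)
        w = self.bead_heights * np.exp(-d2 / (2 * self.bead_widths**2))
        pair_grad = (w / self.bead_widths**2)[:, None] * rel   # d/d host_i
        g_guest = -pair_grad.sum(axis=0)
        g_guest += (self.cavity_amp / self.cavity_width**2) * guest * math.exp(
            -float(guest @ guest) / (2 * self.cavity_width**2)
        )
        if self.tether_k is None:
            return g_guest
        g_host = pair_grad + self.tether_k * (host - self.host_coords)
        return np.concatenate([g_guest, g_host.ravel()])

    # -- frame materialisation ---------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.host_coords) + 1

    def bead_roles(self) -> list:
        roles = []
        gate_idx = {c.gate_index for c in self.channel_definitions.values()}
        for i in range(len(self.host_coords)):
            roles.append("gate" if i in gate_idx else "host")
        roles.append("guest")
        return roles

    def frame_coords(self, x) -> np.ndarray:
        """Full (n_beads, 3) coordinates (z = 0) for a mobile-coordinate vector."""
        guest, host = self._split(x)
        coords = np.zeros((self.n_beads, 3))
        coords[:-1, :2] = host
        coords[-1, :2] = guest
        return coords

    def channel_anchor(self, name: str) -> np.ndarray:
        """Anchor point for the pulling variable of a channel: a point behind
        the cavity on the side opposite the channel mouth, so that increasing
        guest--anchor distance drives the guest out through that channel."""
        ch = self.channel_definitions[name]
        return -(self.ring_radius + 2.0) * ch.direction


def make_host_guest(
    barrier_path1: float,
    barrier_path2: float,
    cavity_depth: float = 8.0,
    ring_radius: float = 6.0,
    n_ring: int = 16,
    gap_half_angle: float = 0.6,
    bead_width: float = 1.2,
    gate_width: float = 2.4,
    wall_height: float = 30.0,
    cavity_width: float = 2.0,
    tether_k: Optional[float] = None,
) -> BeadSystem:
    """Build the two-channel host--guest bead system.

    A ring of strongly repulsive beads (amplitude ``wall_height``) encloses a
    Gaussian cavity of depth ``cavity_depth``; gaps centred on the +x and -x
    directions are each blocked by a single wide "gate" bead.  Gate
    amplitudes are calibrated numerically -- bisection on the wedge saddle,
    i.e. the min over gap angles of the max over radius of the guest energy
    -- so each channel's lowest saddle sits at the requested energy relative
    to bulk (guest far from the host, energy zero); the cavity amplitude is
    corrected self-consistently so the bound minimum sits at
    ``-cavity_depth``.  The total unbinding barrier through a channel is
    therefore ``barrier_pathN + cavity_depth``.
    """
    for name, b in (("barrier_path1", barrier_path1), ("barrier_path2", barrier_path2)):
        if b <= 0:
            raise ParameterError(f"{name} must be positive, got {b}")
    if cavity_depth <= 0:
        raise ParameterError(f"cavity_depth must be positive, got {cavity_depth}")
    max_barrier = 0.55 * wall_height
    if barrier_path1 > max_barrier or barrier_path2 > max_barrier:
        raise ConstructionError(
            f"requested barriers exceed what the ring wall (height {wall_height}) "
            f"can enclose; maximum supported is {max_barrier:.1f} kcal/mol"
        )

    # ring beads, leaving gaps of +-gap_half_angle around 0 and pi
    angles = np.linspace(0, 2 * math.pi, n_ring, endpoint=False)
    keep = []
    for th in angles:
        d0 = abs(math.remainder(th, 2 * math.pi))
        dpi = abs(math.remainder(th - math.pi, 2 * math.pi))
        if d0 > gap_half_angle and dpi > gap_half_angle:
            keep.append(th)
    ring = ring_radius * np.stack([np.cos(keep), np.sin(keep)], axis=1)

    gate1 = ring_radius * np.array([1.0, 0.0])
    gate2 = ring_radius * np.array([-1.0, 0.0])
    host = np.vstack([ring, gate1, gate2])
    heights = np.concatenate([np.full(len(ring), wall_height), [0.0, 0.0]])
    widths = np.concatenate([np.full(len(ring), bead_width), [gate_width, gate_width]])
    i_gate1, i_gate2 = len(ring), len(ring) + 1

    cav_amp = cavity_depth

    def _energy_grid(points: np.ndarray) -> np.ndarray:
        # vectorised guest energy at (P, 2) points with current heights
        d2 = np.sum((points[:, None, :] - host[None, :, :]) ** 2, axis=2)
        e = np.sum(heights * np.exp(-d2 / (2 * widths**2)), axis=1)
        e -= cav_amp * np.exp(-np.sum(points**2, axis=1) / (2 * cavity_width**2))
        return e

    thetas = np.linspace(-gap_half_angle - 0.15, gap_half_angle + 0.15, 41)
    radii = np.linspace(0.8, ring_radius + 4.0, 240)
    tt, rr = np.meshgrid(thetas, radii, indexing="ij")

    def _wedge_saddle(gate_idx: int, sign: float, eps: float) -> float:
        # lowest crossing of the gap: min over angle of max over radius
        heights[gate_idx] = eps
        ang = tt if sign > 0 else tt + math.pi
        pts = np.stack([rr * np.cos(ang), rr * np.sin(ang)], axis=-1)
        e = _energy_grid(pts.reshape(-1, 2)).reshape(tt.shape)
        heights[gate_idx] = 0.0
        return float(e.max(axis=1).min())

    def _calibrate(gate_idx: int, sign: float, target: float) -> float:
        f = lambda eps: _wedge_saddle(gate_idx, sign, eps) - target
        lo, hi = 1e-6, 2.0 * wall_height
        if f(hi) < 0:
            raise ConstructionError(
                f"cannot realise a {target} kcal/mol channel saddle with "
                f"gate amplitude <= {hi}"
            )
        if f(lo) > 0:
            # residual ring/cavity contributions along the open gap already
            # exceed the target; such a low gate cannot enclose the cavity
            raise ConstructionError(
                f"requested channel saddle {target} kcal/mol is below the open-gap "
                f"baseline {f(lo) + target:.2f}; barrier too small to enclose the cavity"
            )
        return brentq(f, lo, hi, xtol=1e-8)

    # gates and cavity amplitude interact weakly; a few sweeps converge
    eps1 = eps2 = 0.0
    for _ in range(3):
        heights[i_gate1] = heights[i_gate2] = 0.0
        eps1 = _calibrate(i_gate1, +1.0, barrier_path1)
        heights[i_gate1] = eps1
        eps2 = _calibrate(i_gate2, -1.0, barrier_path2)
        heights[i_gate2] = eps2
        # set the cavity amplitude so the bound minimum sits at -cavity_depth
        other = float(np.sum(heights * np.exp(
            -np.sum(host**2, axis=1) / (2 * widths**2))))
        cav_amp = cavity_depth + other
    heights[i_gate1] = eps1
    heights[i_gate2] = eps2

    channels = {
        "channel1": ChannelDefinition(
            "channel1", np.array([1.0, 0.0]), barrier_path1, eps1, i_gate1
        ),
        "channel2": ChannelDefinition(
            "channel2", np.array([-1.0, 0.0]), barrier_path2, eps2, i_gate2
        ),
    }

    return BeadSystem(
        host_coords=host,
        guest_indices=(len(host),),
        channel_definitions=channels,
        bead_heights=heights,
        bead_widths=widths,
        cavity_depth=cavity_depth,
        cavity_amp=cav_amp,
        cavity_width=cavity_width,
        ring_radius=ring_radius,
        box_half=ring_radius + 12.0,
        tether_k=tether_k,
    )


# ---------------------------------------------------------------------------
# Langevin engine
# ---------------------------------------------------------------------------

@dataclass
class LangevinParams:
    """Overdamped (Brownian) dynamics parameters.

    ``friction`` is the drag coefficient gamma in kcal/mol*ps/A^2; the
    diffusion constant is D = k_B*T/gamma and the Euler--Maruyama update is
    ``dx = -grad(U)/gamma dt + sqrt(2 k_B T dt / gamma) xi``.
    """

    dt: float = 0.005
    friction: float = 1.0
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.temperature < 0:
            raise ParameterError(f"temperature must be non-negative, got {self.temperature}")
        if self.friction <= 0:
            raise ParameterError(f"friction must be positive, got {self.friction}")


@dataclass
class Trajectory:
    """Recorded dynamics: mobile-coordinate snapshots on a strictly
    increasing time grid, plus the seed that produced them."""

    times: np.ndarray                 # ps, (n,)
    positions: np.ndarray             # (n, dim)
    seed: int
    system: object = None
    cv_series: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.times) != len(self.positions):
            raise ValueError("frame count must equal time count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def frame_coords(self, i: int) -> np.ndarray:
        """Full (n_atoms, 3) coordinates of snapshot ``i`` (bead systems)."""
        if self.system is None or not hasattr(self.system, "frame_coords"):
            raise ValueError("trajectory has no bead system attached")
        return self.system.frame_coords(self.positions[i])


def run_langevin(
    system,
    params: LangevinParams,
    n_steps: int,
    bias: Optional[Callable] = None,
    start: Optional[np.ndarray] = None,
    sample_stride: int = 1,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate overdamped Langevin dynamics.

    ``bias``, if given, is called as ``bias(x, step) -> (V, gradV)`` and its
    gradient is added to the systematic force.  The trajectory is
    deterministic given ``params.seed``: the same seed yields bit-identical
    output.  Snapshots are recorded every ``sample_stride`` steps (step 0
    included).
    """
    if n_steps < 1:
        raise ParameterError(f"n_steps must be >= 1, got {n_steps}")
    x = np.array(
        system.default_start() if start is None else np.atleast_1d(start),
        dtype=float,
    )
    dim = x.size
    bounds = np.asarray(system.domain_bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    dt, gamma = params.dt, params.friction
    kT = KB * params.temperature
    mob = dt / gamma
    sig = math.sqrt(2.0 * kT * dt / gamma)
    rng = np.random.default_rng(params.seed)

    n_rec = n_steps // sample_stride + 1
    rec_t = np.empty(n_rec)
    rec_x = np.empty((n_rec, dim))
    rec_t[0], rec_x[0] = t0, x
    j = 1

    grad = system.gradient
    chunk = 8192
    step = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = rng.standard_normal((m, dim)) if sig > 0 else None
        for i in range(m):
            g = grad(x)
            if bias is not None:
                g = g + bias(x, step + i)[1]
            if sig > 0:
                x = x - mob * g + sig * noise[i]
            else:
                x = x - mob * g
            s = step + i + 1
            if s % sample_stride == 0:
                if not np.all(np.isfinite(x)) or np.any(x < lo) or np.any(x > hi):
                    raise IntegrationError(
                        f"coordinates diverged or left the domain at step {s}"
                    )
                rec_t[j] = t0 + s * dt
                rec_x[j] = x
                j += 1
        step += m

    return Trajectory(rec_t[:j], rec_x[:j], params.seed, system=system)


def harvest_start_states(
    traj: Trajectory, n: int, stride_time: float, tail_fraction: float = 0.5
) -> list:
    """Pick ``n`` equally spaced snapshots from the tail of a trajectory.

    Snapshots are anchored at the final frame and spaced ``stride_time``
    apart going backwards, so ``n = 1`` returns the last frame; all selected
    frames must lie within the final ``tail_fraction`` of the run.
    Returns a list of mobile-coordinate arrays.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if stride_time <= 0:
        raise ParameterError(f"stride_time must be positive, got {stride_time}")
    t = traj.times
    span = t[-1] - t[0]
    tail_start = t[-1] - tail_fraction * span
    needed = (n - 1) * stride_time
    if t[-1] - needed < tail_start - 1e-9:
        max_n = int((tail_fraction * span) / stride_time) + 1
        raise ParameterError(
            f"cannot harvest {n} states at stride {stride_time} ps from the "
            f"final {tail_fraction:.0%} of a {span:g} ps trajectory; "
            f"at most {max_n} fit"
        )
    targets = t[-1] - needed + stride_time * np.arange(n)
    idx = np.searchsorted(t, targets - 1e-9)
    idx = np.clip(idx, 0, len(t) - 1)
    return [traj.positions[i].copy() for i in idx]
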