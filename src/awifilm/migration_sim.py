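"""Stochastic migration of particles between the two AWIs of a thin film.

Particles in a freshly blotted film diffuse along the film normal and,
within a fraction of a second, stick to one of the two free surfaces
because adsorption lowers the system energy.  This module models that
migration as overdamped (position) Langevin dynamics of independent
particles on the one-dimensional film-normal coordinate ``z``:

.. math::

    z \\leftarrow z + \\frac{D}{k_B T} F(z)\\, dt + \\sqrt{2 D\\, dt}\\, \\xi,

with reflecting boundaries at the two interfaces ``z = +-h/2``, the
Stokes-Einstein diffusion coefficient ``D = kT / 6 pi eta r``, and
``F = -dU/dz`` the force of a short-range adsorption well hugging each
interface.  The per-particle well depth follows the surface-energy
bookkeeping: ``dE = 2 * a2 * gamma_lg_effective(c)``, the energy gained
when a particle of contact area ``a2`` exposes itself at one interface
under the effective liquid-gas surface energy at surfactant
concentration ``c``.  Surfactants therefore act purely by shallowing the
well — at the CMC of a surfactant that drives ``gamma_lg`` to zero the
dynamics reduce to free diffusion and the stationary distribution is
uniform.

The well is an essentially square slab of width ``w`` next to each
interface, with a short cosine ramp (half-width ``w/10``) so forces stay
bounded; the stationary occupancy of ``|z| >= h/2 - w`` then matches the
two-slab Boltzmann partition implemented in
:func:`equilibrium_adsorbed_fraction`, which serves as the closed-form
oracle for the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import constants

from .surface_energy import SurfactantSpec, WATER_GAMMA_LG, gamma_lg_effective

__all__ = [
    "FilmSystem",
    "SimConfig",
    "ZTrajectory",
    "stokes_einstein_diffusion",
    "equilibrium_adsorbed_fraction",
    "simulate_film",
    "adsorbed_fraction",
]

#: Fraction of the well width occupied by the cosine ramp half-width.
_RAMP_FRAC = 0.1


def stokes_einstein_diffusion(radius: float, T: float = 298.15, viscosity: float = 0.89) -> float:
    """Stokes-Einstein diffusion coefficient, nm^2/ns.

    ``D = kB T / (6 pi eta r)`` for a sphere of hydrodynamic *radius*
    (nm) in a solvent of *viscosity* (mPa s) at temperature *T* (K).
    A 1-nm sphere in water at 298 K diffuses at about 0.245 nm^2/ns;
    the small hydrodynamic radius of surfactant monomers is why they
    out-race protein particles to the surface.
    """
    if radius <= 0 or T <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must all be positive")
    d_si = constants.Boltzmann * T / (6.0 * math.pi * viscosity * 1e-3 * radius * 1e-9)
    return d_si * 1e9  # m^2/s -> nm^2/ns


@dataclass(frozen=True)
class FilmSystem:
    """Geometry, particle and surfactant parameters of the thin film.

    ``thickness_h``: film thickness in nm (distance between the AWIs);
    ``well_width_w``: width of the adsorption zone at each interface, nm;
    ``particle_radius``: hydrodynamic radius, nm; ``particle_contact_area_a2``:
    per-particle interface contact area in nm^2 (the single-particle
    analogue of the collective area A2); ``gamma_lg``: surfactant-free
    liquid-gas surface energy, mJ/m^2.  With a ``surfactant`` and a
    ``surfactant_conc`` (mmol/L) the well depth uses the effective
    surface energy from the isotherm instead.
    """

    thickness_h: float
    well_width_w: float
    particle_radius: float = 2.0
    particle_contact_area_a2: float = 0.0
    temperature: float = 298.15
    viscosity: float = 0.89
    gamma_lg: float = WATER_GAMMA_LG
    surfactant: Optional[SurfactantSpec] = None
    surfactant_conc: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < 2 * self.well_width_w < self.thickness_h:
            raise ValueError("geometry requires 0 < 2*well_width_w < thickness_h")
        if self.particle_radius <= 0:
            raise ValueError("particle radius must be positive")
        if self.particle_contact_area_a2 < 0:
            raise ValueError("contact area must be non-negative")

    @classmethod
    def with_well_depth(cls, depth_kT: float, thickness_h: float, well_width_w: float,
                        **kwargs) -> "FilmSystem":
        """Build a system whose contact area gives the stated well depth.

        Solves ``2 a2 gamma_lg = depth_kT * kB T`` for the per-particle
        contact area under the system's (surfactant-free) surface
        energy; convenient for parameter scans in kB T units.
        """
        T = kwargs.get("temperature", 298.15)
        gamma = kwargs.get("gamma_lg", WATER_GAMMA_LG)
        if depth_kT < 0:
            raise ValueError("well depth must be non-negative")
        a2 = depth_kT * constants.Boltzmann * T / (2.0 * gamma * 1e-21)
        return cls(thickness_h=thickness_h, well_width_w=well_width_w,
                   particle_contact_area_a2=a2, **kwargs)

    @property
    def effective_gamma_lg(self) -> float:
        """Liquid-gas surface energy after surfactant depression, mJ/m^2."""
        if self.surfactant is None:
            return self.gamma_lg
        return gamma_lg_effective(self.surfactant, self.surfactant_conc)

    @property
    def well_depth_kT(self) -> float:
        """Adsorption well depth ``2 a2 gamma_lg_eff`` in units of kB T.

        mJ/m^2 * nm^2 = 1e-21 J, divided by kB T.
        """
        e_joule = 2.0 * self.particle_contact_area_a2 * self.effective_gamma_lg * 1e-21
        return e_joule / (constants.Boltzmann * self.temperature)

    @property
    def diffusion_coefficient(self) -> float:
        """Particle diffusion coefficient, nm^2/ns."""
        return stokes_einstein_diffusion(self.particle_radius, self.temperature, self.viscosity)


@dataclass(frozen=True)
class SimConfig:
    """Run-control parameters; the seed is mandatory and fully determines
    the trajectory stream."""

    n_particles: int
    n_steps: int
    seed: int
    dt: Optional[float] = None  # ns; auto-chosen from stability bounds if None
    record_every: int = 100
    start: str = "uniform"  # or "one_side": all particles near z=-h/2

    def __post_init__(self) -> None:
        if self.n_particles <= 0 or self.n_steps <= 0 or self.record_every <= 0:
            raise ValueError("n_particles, n_steps and record_every must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.start not in ("uniform", "one_side"):
            raise ValueError("start must be 'uniform' or 'one_side'")


@dataclass(frozen=True)
class ZTrajectory:
    """Recorded film-normal positions: ``z[t, i]`` in nm for recorded
    frame ``t`` and particle ``i``; ``times`` in ns."""

    times: np.ndarray
    z: np.ndarray
    thickness_h: float
    well_width_w: float

    def __post_init__(self) -> None:
        if self.z.ndim != 2 or self.z.shape[0] != self.times.shape[0]:
            raise ValueError("z must be (n_frames, n_particles) aligned with times")
        if np.any(np.abs(self.z) > self.thickness_h / 2 + 1e-9):
            raise ValueError("trajectory leaves the film")


def equilibrium_adsorbed_fraction(delta_E: float, well_width_w: float, thickness_h: float) -> float:
    """Boltzmann equilibrium fraction of particles in the adsorption zones.

    Two square wells of width *w* and depth *delta_E* (in kB T) at the
    edges of a film of thickness *h* partition as

    ``f = 2w e^dE / (2w e^dE + (h - 2w))``.

    This is the closed-form oracle the Langevin simulator is checked
    against; at ``delta_E = 0`` it reduces to the uniform value ``2w/h``
    and it tends to 1 as the well deepens.
    """
    if not 0 < 2 * well_width_w < thickness_h:
        raise ValueError("geometry requires 0 < 2*well_width_w < thickness_h")
    if not math.isfinite(delta_E):
        raise ValueError("delta_E must be finite")
    zone = 2.0 * well_width_w * math.exp(delta_E)
    return zone / (zone + (thickness_h - 2.0 * well_width_w))


def _well_force(z: np.ndarray, h: float, w: float, depth_kT: float) -> np.ndarray:
    """Force (kB T / nm) of the smoothed edge wells at positions *z*.

    Potential ``U(z) = -depth * s(d)`` with ``d = h/2 - |z|`` the
    distance to the nearest interface and ``s`` a cosine smoothstep from
    1 (inside the well) to 0 (bulk) over ``d in [w - r, w + r]``,
    ``r = w/10``.  Positive force pushes toward larger z.
    """
    r = _RAMP_FRAC * w
    d = h / 2.0 - np.abs(z)
    force = np.zeros_like(z)
    in_ramp = (d > w - r) & (d < w + r)
    if np.any(in_ramp):
        u = (d[in_ramp] - (w - r)) / (2.0 * r)  # in (0, 1)
        # dU/dd = depth * s'(d), s(d) = (1 + cos(pi*u)) / 2
        dUdd = depth_kT * math.pi / (4.0 * r) * np.sin(math.pi * u)
        # F = -dU/dz = -dU/dd * dd/dz, dd/dz = -sign(z)
        force[in_ramp] = dUdd * np.sign(z[in_ramp])
    return force


def _default_dt(system: FilmSystem) -> float:
    """Largest dt honouring the noise and drift stability bounds."""
    D = system.diffusion_coefficient
    w = system.well_width_w
    r = _RAMP_FRAC * w
    dt_noise = (w / 5.0) ** 2 / (2.0 * D)
    depth = system.well_depth_kT
    if depth > 0:
        f_max = depth * math.pi / (4.0 * r)
        dt_drift = (r / 2.0) / (D * f_max)
        return min(dt_noise, dt_drift)
    return dt_noise


def simulate_film(system: FilmSystem, config: SimConfig) -> ZTrajectory:
    """Run the overdamped Langevin migration simulation.

    Returns the recorded trajectory; identical ``(system, config)``
    inputs give bitwise-identical output.  Raises a configuration error
    when the requested ``dt`` would step drift farther than half the
    well width in one move.
    """
    h, w = system.thickness_h, system.well_width_w
    D = system.diffusion_coefficient
    depth = system.well_depth_kT
    dt = config.dt if config.dt is not None else _default_dt(system)
    r = _RAMP_FRAC * w
    if depth > 0:
        max_drift = D * depth * math.pi / (4.0 * r) * dt
        if max_drift > w / 2.0:
            raise ValueError(
                f"dt={dt} ns too large: drift per step {max_drift:.3g} nm exceeds w/2={w / 2:.3g} nm"
            )
    rng = np.random.default_rng(config.seed)
    if config.start == "uniform":
        z = rng.uniform(-h / 2.0, h / 2.0, size=config.n_particles)
    else:
        # sample applied to the bottom face: start within one well width of it
        z = -h / 2.0 + rng.uniform(0.0, w, size=config.n_particles)

    sigma = math.sqrt(2.0 * D * dt)
    frames = [z.copy()]
    times = [0.0]
    # Leimkuhler-Matthews averaged-noise update: sharing each Gaussian
    # increment between consecutive steps gives far smaller sampling
    # bias than plain Euler-Maruyama at the same time step.
    xi_prev = rng.standard_normal(config.n_particles)
    for step in range(1, config.n_steps + 1):
        force = _well_force(z, h, w, depth)
        xi = rng.standard_normal(config.n_particles)
        z = z + D * force * dt + sigma * 0.5 * (xi_prev + xi)
        xi_prev = xi
        # reflecting boundaries at the interfaces
        z = np.abs(z + h / 2.0) % (2.0 * h)
        z = np.where(z > h, 2.0 * h - z, z) - h / 2.0
        if step % config.record_every == 0:
            frames.append(z.copy())
            times.append(step * dt)
    return ZTrajectory(
        times=np.asarray(times), z=np.vstack(frames), thickness_h=h, well_width_w=w
    )


def adsorbed_fraction(traj: ZTrajectory, well_width_w: float | None = None,
                      thickness_h: float | None = None) -> np.ndarray:
    """Fraction of particles inside either adsorption zone per frame.

    A particle counts as adsorbed when ``|z| >= h/2 - w``.  Geometry
    defaults to the trajectory's own.
    """
    h = traj.thickness_h if thickness_h is None else thickness_h
    w = traj.well_width_w if well_width_w is None else well_width_w
    if traj.z.size == 0:
        raise ValueError("empty trajectory")
    return np.mean(np.abs(traj.z) >= h / 2.0 - w, axis=1)
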