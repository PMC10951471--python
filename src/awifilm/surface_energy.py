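"""Three-state surface-energy model of a particle in a grid-hole film.

The thin aqueous film spanning a cryoEM grid hole has two free surfaces
(air-water interfaces, AWI).  A particle suspended in it can sit in one of
three states: fully in the bulk, exposed at one interface (*single
adsorption*), or spanning the film and exposed at both (*double
adsorption*).  The total potential energy of each state is a sum of
``area x surface energy`` terms over every interface along the film
normal:

.. math::

    \\Omega_\\text{bulk}   &= 2 A_1 \\gamma_{lg} + 2 A_2 \\gamma_{ls} \\\\
    \\Omega_\\text{single} &= 2 A_1 \\gamma_{lg} + A_2 \\gamma_{ls}
                              + A_2 \\gamma_{sg} - A_2 \\gamma_{lg} \\\\
    \\Omega_\\text{double} &= 2 A_1 \\gamma_{lg} + 2 A_2 \\gamma_{sg}
                              - 2 A_2 \\gamma_{lg}

where :math:`A_1` is the liquid surface area of the hole, :math:`A_2`
the combined top-or-bottom surface area of the particles, and
:math:`\\gamma_{lg}, \\gamma_{ls}, \\gamma_{sg}` the liquid-gas,
liquid-solid and solid-gas surface energies.  Young's equation,
:math:`\\gamma_{sg} = \\gamma_{ls} + \\gamma_{lg}\\cos\\theta`, couples
the three through the equilibrium contact angle; at the
:math:`\\theta = 180^\\circ` limit relevant to a particle poking through
the surface, every transition gain collapses to a multiple of
:math:`A_2 \\gamma_{lg}`, which is why lowering the liquid-gas surface
energy with a surfactant removes the drive toward the interface.

Units
-----
Surface energies are mJ/m^2 throughout (water is 72 mJ/m^2 at room
temperature) and areas are um^2, so every energy returned here is in
femtojoules: 1 mJ/m^2 * 1 um^2 = 1e-15 J = 1 fJ.

Transition gains are always computed by direct subtraction of the state
energies, so ``gain(a->b) = omega(a) - omega(b)`` holds exactly by
construction; a positive gain means the transition lowers the system
energy.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "WATER_GAMMA_LG",
    "AdsorptionState",
    "InterfaceGeometry",
    "SurfaceEnergies",
    "SurfactantSpec",
    "SURFACTANTS",
    "young_gamma_sg",
    "gamma_lg_effective",
    "omega",
    "transition_gain",
    "all_transition_gains",
]

#: Liquid-gas surface energy of pure water at room temperature, mJ/m^2
#: (equivalently mN/m); among the highest of common liquids.
WATER_GAMMA_LG = 72.0


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def young_gamma_sg(gamma_ls: float, gamma_lg: float, theta_deg: float) -> float:
    """Solid-gas surface energy from Young's equation.

    ``gamma_sg = gamma_ls + gamma_lg * cos(theta)`` with *theta* the
    equilibrium contact angle the liquid forms on the solid, in degrees.
    At ``theta = 180`` (complete dewetting, the relevant limit for a
    particle exposed at the film surface) this reduces to
    ``gamma_ls - gamma_lg``.

    Parameters are in mJ/m^2 and degrees; the result is in mJ/m^2.
    """
    _require_finite(gamma_ls=gamma_ls, gamma_lg=gamma_lg, theta_deg=theta_deg)
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError(f"contact angle must be in [0, 180] degrees, got {theta_deg}")
    return gamma_ls + gamma_lg * math.cos(math.radians(theta_deg))


@dataclass(frozen=True)
class SurfaceEnergies:
    """The three interfacial energies of the film-particle system, mJ/m^2.

    ``gamma_lg``: liquid-gas, ``gamma_ls``: liquid-solid, ``gamma_sg``:
    solid-gas; ``theta_deg`` records the contact angle used when the
    solid-gas value was derived through Young's equation.
    """

    gamma_lg: float
    gamma_ls: float
    gamma_sg: float
    theta_deg: float | None = None

    def __post_init__(self) -> None:
        _require_finite(
            gamma_lg=self.gamma_lg, gamma_ls=self.gamma_ls, gamma_sg=self.gamma_sg
        )
        if self.gamma_lg < 0:
            raise ValueError("liquid-gas surface energy must be non-negative")

    @classmethod
    def from_young(
        cls, gamma_lg: float, gamma_ls: float, theta_deg: float = 180.0
    ) -> "SurfaceEnergies":
        """Build the triple with gamma_sg supplied by Young's equation."""
        return cls(
            gamma_lg=gamma_lg,
            gamma_ls=gamma_ls,
            gamma_sg=young_gamma_sg(gamma_ls, gamma_lg, theta_deg),
            theta_deg=theta_deg,
        )


@dataclass(frozen=True)
class InterfaceGeometry:
    """Areas entering the energy bookkeeping, um^2.

    ``a1`` is the liquid surface area of the grid hole (one face);
    ``a2`` is the combined top-or-bottom surface area of all particles,
    necessarily no larger than the hole itself.
    """

    a1: float
    a2: float

    def __post_init__(self) -> None:
        _require_finite(a1=self.a1, a2=self.a2)
        if self.a1 <= 0:
            raise ValueError("hole surface area a1 must be positive")
        if not 0 <= self.a2 <= self.a1:
            raise ValueError("particle area a2 must satisfy 0 <= a2 <= a1")


class AdsorptionState(str, enum.Enum):
    """Occupancy state of the particles with respect to the two AWIs."""

    BULK = "bulk"
    SINGLE = "single_adsorption"
    DOUBLE = "double_adsorption"


def omega(state: AdsorptionState, geom: InterfaceGeometry, e: SurfaceEnergies) -> float:
    """Total potential energy of the film-particle system in *state*, fJ.

    Implements the three printed state energies verbatim (areas in um^2,
    energies in mJ/m^2, result in fJ).
    """
    state = AdsorptionState(state)
    a1, a2 = geom.a1, geom.a2
    if state is AdsorptionState.BULK:
        return 2 * a1 * e.gamma_lg + 2 * a2 * e.gamma_ls
    if state is AdsorptionState.SINGLE:
        return 2 * a1 * e.gamma_lg + a2 * e.gamma_ls + a2 * e.gamma_sg - a2 * e.gamma_lg
    if state is AdsorptionState.DOUBLE:
        return 2 * a1 * e.gamma_lg + 2 * a2 * e.gamma_sg - 2 * a2 * e.gamma_lg
    raise ValueError(f"unknown adsorption state {state!r}")  # pragma: no cover


_ALLOWED_TRANSITIONS = {
    (AdsorptionState.BULK, AdsorptionState.SINGLE),
    (AdsorptionState.SINGLE, AdsorptionState.DOUBLE),
    (AdsorptionState.BULK, AdsorptionState.DOUBLE),
}


def transition_gain(
    from_state: AdsorptionState,
    to_state: AdsorptionState,
    geom: InterfaceGeometry,
    e: SurfaceEnergies,
) -> float:
    """Energy released by the transition ``from_state -> to_state``, fJ.

    Computed as ``omega(from) - omega(to)`` by direct subtraction of the
    state energies; positive means the move is energetically favorable.
    Under the ``theta = 180`` Young substitution the bulk->single and
    single->double gains both equal ``2 * a2 * gamma_lg`` and
    bulk->double equals ``4 * a2 * gamma_lg``.
    """
    pair = (AdsorptionState(from_state), AdsorptionState(to_state))
    if pair not in _ALLOWED_TRANSITIONS:
        raise ValueError(
            f"unsupported transition {pair[0].value} -> {pair[1].value}; "
            "allowed: bulk->single, single->double, bulk->double"
        )
    return omega(pair[0], geom, e) - omega(pair[1], geom, e)


def all_transition_gains(
    geom: InterfaceGeometry, e: SurfaceEnergies
) -> dict[str, float]:
    """All three admissible transition gains keyed ``from->to``, fJ."""
    return {
        f"{a.value}->{b.value}": transition_gain(a, b, geom, e)
        for a, b in sorted(_ALLOWED_TRANSITIONS, key=lambda p: (p[0].value, p[1].value))
    }


@dataclass(frozen=True)
class SurfactantSpec:
    """A surfactant and the parameters of its surface-energy isotherm.

    ``cmc`` is the critical micelle concentration in mmol/L;
    ``gamma_water`` the liquid-gas surface energy at zero surfactant and
    ``gamma_min`` the plateau value reached at and above the CMC (both
    mJ/m^2).  ``isotherm_scale`` sets the knee of the Szyszkowski-type
    decrease as a fraction of the CMC.
    """

    name: str
    cmc: float
    gamma_water: float = WATER_GAMMA_LG
    gamma_min: float = 20.0
    isotherm_scale: float = 0.1

    def __post_init__(self) -> None:
        _require_finite(
            cmc=self.cmc,
            gamma_water=self.gamma_water,
            gamma_min=self.gamma_min,
            isotherm_scale=self.isotherm_scale,
        )
        if self.cmc <= 0:
            raise ValueError("CMC must be positive")
        if self.gamma_min > self.gamma_water:
            raise ValueError("gamma_min cannot exceed gamma_water")
        if self.isotherm_scale <= 0:
            raise ValueError("isotherm_scale must be positive")


def gamma_lg_effective(spec: SurfactantSpec, c: float) -> float:
    """Liquid-gas surface energy at surfactant concentration *c* (mmol/L).

    A Szyszkowski/Langmuir-type monotone decrease,

    ``gamma(c) = gamma_water - (gamma_water - gamma_min)
                 * log(1 + c/k) / log(1 + cmc/k)``,   ``k = scale * cmc``,

    clamped to ``gamma_min`` for ``c >= cmc``.  The form is continuous,
    non-increasing, equals ``gamma_water`` at zero surfactant and reaches
    its minimum exactly at the critical micelle concentration, above
    which added surfactant only forms micelles and the surface energy
    stays flat.
    """
    if not math.isfinite(c) or c < 0:
        raise ValueError(f"concentration must be a finite non-negative value, got {c!r}")
    if c >= spec.cmc:
        return spec.gamma_min
    k = spec.isotherm_scale * spec.cmc
    drop = (spec.gamma_water - spec.gamma_min) * math.log1p(c / k) / math.log1p(spec.cmc / k)
    return spec.gamma_water - drop


#: Surfactants characterised for cryoEM grid preparation, keyed by name.
#: CMCs: fluorinated fos-choline 8 (FFC8) 3.0 mmol/L, dodecyl maltoside
#: (DDM) 0.17 mmol/L, NP-40 0.3 mmol/L.  The plateau surface energies are
#: representative literature-scale values (~20-30 mN/m for micellar
#: solutions), not measured constants.
SURFACTANTS: dict[str, SurfactantSpec] = {
    "FFC8": SurfactantSpec(name="FFC8", cmc=3.0, gamma_min=20.0),
    "DDM": SurfactantSpec(name="DDM", cmc=0.17, gamma_min=30.0),
    "NP40": SurfactantSpec(name="NP40", cmc=0.3, gamma_min=30.0),
}
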