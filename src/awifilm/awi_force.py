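"""Hydropathy interface forces and electrostatic screening at the AWI.

Two short-range physics pieces govern what a protein feels near the free
surface of the film.  First, a coarse-grained, residue-level force: each
residue *i*, with Kyte-Doolittle hydropathy index :math:`q_i`, is pulled
toward (hydrophobic, :math:`q_i > 0`) or away from (hydrophilic,
:math:`q_i < 0`) the interface plane by a Gaussian-localised force

.. math::

    F_i = q_i A \\frac{\\exp(-z_i^2 / 2W^2)}{\\sqrt{2\\pi}\\, W},

where *A* is the amplitude of the interaction (model units), *W* the
interface width in nm and :math:`z_i` the residue's distance from the
interface plane at ``z = 0``.  The kernel is a normalised Gaussian, so
the force integrated over all depths is exactly ``q * A``.  Opposing
pulls on hydrophilic and hydrophobic residues of one chain are what
deform proteins trapped at the surface.

Second, the Debye-Hückel screening length of the buffer,

.. math::

    \\lambda_D = \\sqrt{\\frac{\\varepsilon \\varepsilon_0 k_B T}
                             {\\sum_j n_j q_j^2}},

with :math:`n_j` the number density and :math:`q_j` the charge of ionic
species *j*.  In phosphate-buffered saline at room temperature this is
about 0.7 nm — smaller than any folded domain — which is why the
electrostatic contribution to interface trapping is negligible and the
migration simulator carries no electrostatic term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import constants

__all__ = [
    "KYTE_DOOLITTLE",
    "HydropathyTable",
    "InterfaceField",
    "ResidueBead",
    "BufferSolution",
    "PBS_1X",
    "hydropathy_index",
    "interface_force",
    "chain_force_profile",
    "beads_from_sequence",
    "debye_length",
]

#: Kyte-Doolittle hydropathy scale for the 20 standard residues.
#: Spans -4.5 (arginine, most polar) to +4.5 (isoleucine, most
#: hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HydropathyTable = dict[str, float]


def hydropathy_index(code: str) -> float:
    """Kyte-Doolittle hydropathy of a one-letter residue code.

    Case-insensitive; raises ``KeyError`` naming the symbol for anything
    outside the 20 standard residues.
    """
    try:
        return KYTE_DOOLITTLE[code.upper()]
    except (KeyError, AttributeError):
        raise KeyError(f"unknown residue code {code!r}; expected a standard one-letter symbol") from None


@dataclass(frozen=True)
class InterfaceField:
    """Gaussian interface potential: amplitude ``A`` (model units) and
    width ``W`` in nm; the interface plane sits at ``z = 0``."""

    amplitude_A: float = 1.0
    width_W: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.amplitude_A):
            raise ValueError("amplitude must be finite")
        if not (math.isfinite(self.width_W) and self.width_W > 0):
            raise ValueError(f"interface width must be positive, got {self.width_W}")


@dataclass(frozen=True)
class ResidueBead:
    """One residue as a bead: code, depth ``z`` in nm, hydropathy ``q``."""

    code: str
    z: float
    q: float

    @classmethod
    def at(cls, code: str, z: float) -> "ResidueBead":
        return cls(code=code.upper(), z=z, q=hydropathy_index(code))


def interface_force(q, z, field: InterfaceField):
    """Force on a bead of hydropathy *q* at depth *z* nm from the interface.

    ``q * A * exp(-z^2 / 2W^2) / (sqrt(2*pi) * W)``, in the model units
    of *A* per nm.  Positive values pull toward the interface plane;
    hydrophilic residues (``q < 0``) are pushed toward the bulk.  Accepts
    scalars or arrays in *q* and *z*.
    """
    w = field.width_W
    kernel = np.exp(-np.square(z) / (2.0 * w * w)) / (math.sqrt(2.0 * math.pi) * w)
    return q * field.amplitude_A * kernel


def chain_force_profile(
    beads: Sequence[ResidueBead], field: InterfaceField
) -> tuple[np.ndarray, float]:
    """Per-residue interface forces for a chain and their sum.

    Returns ``(forces, net)`` where ``forces[i]`` is the force on bead
    *i* and ``net`` their sum — zero when hydrophobic and hydrophilic
    pulls cancel.  Raises on an empty chain or a bead whose ``q``
    disagrees with the hydropathy table.
    """
    if len(beads) == 0:
        raise ValueError("chain_force_profile requires a non-empty bead list")
    for b in beads:
        if b.q != hydropathy_index(b.code):
            raise ValueError(
                f"bead {b.code!r} carries q={b.q}, table value is {hydropathy_index(b.code)}"
            )
    q = np.array([b.q for b in beads])
    z = np.array([b.z for b in beads])
    forces = interface_force(q, z, field)
    return forces, float(forces.sum())


def beads_from_sequence(sequence: str, z: Sequence[float] | np.ndarray) -> list[ResidueBead]:
    """Beads for a residue sequence laid out at caller-supplied depths."""
    z = np.asarray(z, dtype=float)
    if z.shape != (len(sequence),):
        raise ValueError(f"z layout length {z.shape} does not match sequence length {len(sequence)}")
    return [ResidueBead.at(code, float(zi)) for code, zi in zip(sequence, z)]


@dataclass(frozen=True)
class BufferSolution:
    """Ionic composition of a buffer for screening-length calculations.

    ``species`` is a list of ``(charge, concentration)`` pairs with the
    charge in elementary units and the concentration in mmol/L;
    ``temperature`` in K and ``epsilon_r`` the relative permittivity of
    the solvent (78.4 for water near room temperature).
    """

    species: tuple[tuple[float, float], ...]
    temperature: float = 298.15
    epsilon_r: float = 78.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple((float(q), float(c)) for q, c in self.species))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for q, c in self.species:
            if c < 0:
                raise ValueError(f"concentration must be non-negative, got {c} for charge {q}")

    @property
    def ionic_strength_molar(self) -> float:
        """Ionic strength ``1/2 sum c_j z_j^2`` in mol/L."""
        return 0.5 * sum(c * q * q for q, c in self.species) / 1000.0


#: Standard 1x phosphate-buffered saline: 137 mM NaCl, 2.7 mM KCl,
#: 10 mM Na2HPO4, 1.8 mM KH2PO4, with phosphates at nominal charges.
PBS_1X = BufferSolution(
    species=(
        (+1, 137.0 + 2 * 10.0),   # Na+ from NaCl and Na2HPO4
        (-1, 137.0 + 2.7),        # Cl- from NaCl and KCl
        (+1, 2.7 + 1.8),          # K+ from KCl and KH2PO4
        (-2, 10.0),               # HPO4(2-)
        (-1, 1.8),                # H2PO4(-)
    )
)


def debye_length(buffer: BufferSolution) -> float:
    """Debye-Hückel screening length of *buffer*, in nm.

    ``sqrt(eps_r * eps0 * kB * T / sum_j n_j (q_j e)^2)`` with number
    densities from the mmol/L concentrations.  Diverges (raises) for a
    buffer with no charged species.
    """
    # mmol/L == mol/m^3, so number density n_j = c_j * N_A per m^3.
    denom = sum(
        c * constants.Avogadro * (q * constants.elementary_charge) ** 2
        for q, c in buffer.species
    )
    if denom <= 0:
        raise ValueError("screening length undefined: buffer has zero ionic strength")
    lam_m = math.sqrt(
        buffer.epsilon_r * constants.epsilon_0 * constants.Boltzmann * buffer.temperature / denom
    )
    return lam_m * 1e9
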