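"""Synthetic film scenes and residue chains with known ground truth.

No particle coordinates from real tomograms ship with the package, so
every analysis stage is exercised against generated data whose
generating parameters are known exactly.  A *film scene* places ``n``
particles between two interface planes a film thickness apart: a chosen
fraction adsorbed at the top plane, another at the bottom (each with
half-normal jitter drawn into the film interior, so adsorbed particles
never start beyond an interface), and the remainder uniform in the
bulk.  Both planes, and the points with them, can be rigidly tilted to
mimic a tomogram whose ice is not parallel to the field of view.

The named presets mirror a surfactant titration: without surfactant
most particles sit at the interfaces — more on the side opposite sample
application — and the adsorbed fraction falls with surfactant
concentration until, at the critical micelle concentration, particles
are uniform through the depth.  The preset fractions are documented
synthetic defaults chosen to reproduce that qualitative series, not
measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .tomo_distribution import ParticleModel, Plane

__all__ = [
    "FilmSceneParams",
    "FilmScene",
    "PRESETS",
    "generate_film_scene",
    "preset_scene",
    "generate_chain",
]

#: Å per voxel used for generated models; 1 voxel == 1 nm.
_SCENE_PIXEL_SIZE = 10.0


@dataclass(frozen=True)
class FilmSceneParams:
    """Parameters of a synthetic film scene.

    ``thickness_h`` and ``lateral_extent`` in nm; ``f_top`` and
    ``f_bottom`` the fractions adsorbed at each interface
    (``f_top + f_bottom <= 1``); ``jitter_sigma`` the scale (nm) of the
    half-normal scatter of adsorbed particles into the film;
    ``plane_tilt_deg`` a rigid tilt of the whole scene about the y axis.
    """

    n_particles: int = 1000
    thickness_h: float = 150.0
    lateral_extent: float = 800.0
    f_top: float = 0.0
    f_bottom: float = 0.0
    jitter_sigma: float = 2.0
    plane_tilt_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.thickness_h <= 0 or self.lateral_extent <= 0:
            raise ValueError("thickness and lateral extent must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if not (0 <= self.f_top <= 1 and 0 <= self.f_bottom <= 1):
            raise ValueError("adsorbed fractions must lie in [0, 1]")
        if self.f_top + self.f_bottom > 1:
            raise ValueError("f_top + f_bottom must not exceed 1")


@dataclass(frozen=True)
class FilmScene:
    """A generated scene: the particle model, per-particle ground-truth
    labels (``top`` / ``bottom`` / ``bulk``) and the true planes."""

    model: ParticleModel
    labels: tuple[str, ...]
    top: Plane
    bottom: Plane
    params: FilmSceneParams


def _tilt_matrix(tilt_deg: float) -> np.ndarray:
    t = math.radians(tilt_deg)
    return np.array(
        [[math.cos(t), 0.0, math.sin(t)], [0.0, 1.0, 0.0], [-math.sin(t), 0.0, math.cos(t)]]
    )


def generate_film_scene(params: FilmSceneParams) -> FilmScene:
    """Generate a particle scene with known adsorbed fractions.

    Exactly ``round(n f_top)`` particles go at the top interface and
    ``round(n f_bottom)`` at the bottom, each displaced into the film by
    half-normal jitter of scale ``jitter_sigma``; the rest are uniform
    in the bulk.  The returned planes are the exact generating planes
    (tilted together with the points when ``plane_tilt_deg`` is set),
    and the labels record each particle's generating component.
    Generation is fully determined by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_particles
    h = params.thickness_h
    n_top = round(n * params.f_top)
    n_bot = round(n * params.f_bottom)
    n_bulk = n - n_top - n_bot

    z_top = h / 2.0 - np.abs(rng.normal(0.0, params.jitter_sigma, n_top)) if n_top else np.empty(0)
    z_bot = -h / 2.0 + np.abs(rng.normal(0.0, params.jitter_sigma, n_bot)) if n_bot else np.empty(0)
    z_bulk = rng.uniform(-h / 2.0, h / 2.0, n_bulk) if n_bulk else np.empty(0)
    # jitter may overshoot the mid-plane for thick jitter; keep inside film
    z = np.clip(np.concatenate([z_top, z_bot, z_bulk]), -h / 2.0, h / 2.0)
    xy = rng.uniform(0.0, params.lateral_extent, size=(n, 2))
    pts = np.column_stack([xy, z])
    labels = ("top",) * n_top + ("bottom",) * n_bot + ("bulk",) * n_bulk

    top = Plane(normal=np.array([0.0, 0.0, 1.0]), offset=h / 2.0)
    bottom = Plane(normal=np.array([0.0, 0.0, -1.0]), offset=h / 2.0)
    if params.plane_tilt_deg:
        rot = _tilt_matrix(params.plane_tilt_deg)
        pts = pts @ rot.T
        top = Plane(normal=rot @ top.normal, offset=top.offset)
        bottom = Plane(normal=rot @ bottom.normal, offset=bottom.offset)

    model = ParticleModel(
        points=pts / (_SCENE_PIXEL_SIZE / 10.0), pixel_size=_SCENE_PIXEL_SIZE, labels=labels
    )
    return FilmScene(model=model, labels=labels, top=top, bottom=bottom, params=params)


#: Preset scene parameters emulating a surfactant titration.  Adsorbed
#: totals fall monotonically along the series; the surfactant-free film
#: is top-biased (most particles on the face opposite sample
#: application) and uses broad jitter so its histogram spreads over the
#: outer bins, while surfactant conditions keep a tight ~8-nm adsorption
#: layer until, at the CMC, adsorption vanishes entirely.
PRESETS: dict[str, FilmSceneParams] = {
    "no_surfactant": FilmSceneParams(f_top=0.55, f_bottom=0.30, jitter_sigma=33.0),
    "ffc8_1to100": FilmSceneParams(f_top=0.30, f_bottom=0.20, jitter_sigma=8.0),
    "ffc8_1to10": FilmSceneParams(f_top=0.10, f_bottom=0.10, jitter_sigma=8.0),
    "ffc8_cmc": FilmSceneParams(f_top=0.0, f_bottom=0.0, jitter_sigma=8.0),
}


def preset_scene(name: str, n: int = 1000, seed: int = 0) -> FilmSceneParams:
    """Scene parameters for a named titration condition.

    Presets: ``no_surfactant``, ``ffc8_1to100``, ``ffc8_1to10``,
    ``ffc8_cmc``; unknown names raise ``KeyError``.
    """
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(base, n_particles=n, seed=seed)


_COMPOSITIONS = {
    # residue pools biased by hydropathy sign
    "hydrophobic-rich": "ILVFMCA" * 3 + "GTSWYPHEQDNKR",
    "hydrophilic-rich": "RKDENQH" * 3 + "GTSWYPAMCILVF",
    "uniform": "ACDEFGHIKLMNPQRSTVWY",
}


def generate_chain(length: int, composition: str = "uniform", seed: int = 0) -> str:
    """A random residue sequence with the requested compositional bias.

    ``hydrophobic-rich`` chains have positive mean hydropathy,
    ``hydrophilic-rich`` negative, ``uniform`` draws every residue with
    equal weight.  Deterministic under the seed.
    """
    if length <= 0:
        raise ValueError("chain length must be positive")
    try:
        pool = _COMPOSITIONS[composition]
    except KeyError:
        raise KeyError(f"unknown composition {composition!r}; choose from {sorted(_COMPOSITIONS)}") from None
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(pool), size=length))
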