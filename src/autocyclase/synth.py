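"""Synthetic study-shaped data: noisy LC/MS time courses and gel lanes.

The generator emulates the two quantitation modalities of the study:
extracted-ion-chromatogram time courses (multiplicative noise whose SD
scales with abundance, plus a small additive floor, in replicate) and
SDS-PAGE densitometry lanes (Coomassie-type stains bind per unit mass,
so band intensity is mass-weighted molar amount).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import RateParams, ReactionNetwork, TimeCourse, simulate_deterministic


@dataclass(frozen=True)
class NoiseModel:
    """Replicate measurement noise for synthetic time courses.

    Multiplicative Gaussian with relative SD ``relative_sd`` plus an
    additive Gaussian floor of SD ``floor_sd`` (M); negative draws are
    clipped to zero and flagged in the time-course metadata.
    """

    relative_sd: float = 0.02
    floor_sd: float = 1e-9
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0 or self.floor_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_timecourses(network: ReactionNetwork, params: RateParams,
                         c0_list, t_grid, noise: NoiseModel
                         ) -> dict[float, list[TimeCourse]]:
    """Noisy replicate time courses for each starting concentration.

    Solves the deterministic network once per C0 and overlays independent
    replicate noise.  Identical seeds give bit-identical datasets; each
    (C0, replicate) pair consumes an independent child stream of the
    seed so replicates are independent.
    """
    root = np.random.default_rng(noise.seed)
    out: dict[float, list[TimeCourse]] = {}
    for c0 in c0_list:
        truth = simulate_deterministic(network, params, c0, np.asarray(t_grid, float))
        reps = []
        for r in range(noise.n_replicates):
            rng = np.random.default_rng(root.integers(2 ** 31))
            mult = rng.normal(1.0, noise.relative_sd, size=truth.conc.shape) \
                if noise.relative_sd > 0 else 1.0
            add = rng.normal(0.0, noise.floor_sd, size=truth.conc.shape) \
                if noise.floor_sd > 0 else 0.0
            noisy = truth.conc * mult + add
            n_clipped = int(np.sum(noisy < 0))
            tc = TimeCourse(times=truth.times, species=truth.species,
                            conc=np.clip(noisy, 0.0, None), c0=c0,
                            params=params, provenance="synthetic",
                            seed=noise.seed, network=network)
            tc.meta["replicate"] = r
            tc.meta["n_clipped"] = n_clipped
            reps.append(tc)
        out[float(c0)] = reps
    return out


@dataclass(frozen=True)
class GelBand:
    species: str
    mass_da: float
    molar_amount: float


@dataclass(frozen=True)
class GelLane:
    """One densitometry lane: intensity proportional to mass x molar amount."""

    bands: tuple[GelBand, ...]
    normalisation: str
    intensities: tuple[float, ...] = field(default=())

    @property
    def relative_intensities(self) -> dict[str, float]:
        total = sum(self.intensities)
        return {b.species: i / total for b, i in zip(self.bands, self.intensities)}


def generate_gel_lane(bands, normalisation: str = "all_bands",
                      enzyme_species: str = "E") -> GelLane:
    """Mass-weighted band intensities for one lane.

    ``bands`` is an iterable of (species, mass_da, molar_amount).  With
    ``normalisation="exclude_enzyme"`` the released-enzyme band is left
    out of the intensity total (its absolute intensity is still listed).
    """
    if normalisation not in ("all_bands", "exclude_enzyme"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    bands = tuple(GelBand(*b) if not isinstance(b, GelBand) else b for b in bands)
    if not bands:
        raise ValueError("empty lane")
    for b in bands:
        if b.mass_da <= 0:
            raise ValueError(f"band {b.species}: mass must be > 0")
        if b.molar_amount < 0:
            raise ValueError(f"band {b.species}: amount must be >= 0")
    kept = [b for b in bands
            if not (normalisation == "exclude_enzyme" and b.species == enzyme_species)]
    if all(b.mass_da * b.molar_amount == 0 for b in kept):
        raise ValueError("all-zero lane")
    intensities = tuple(b.mass_da * b.molar_amount for b in kept)
    return GelLane(bands=tuple(kept), normalisation=normalisation,
                   intensities=intensities)


def apply_in_vivo_hydrolysis(c0: float, loss_fraction: float) -> tuple[float, float]:
    """Pre-reaction loss of starting material to in vivo hydrolysis.

    Returns (effective C0, pre-hydrolysed pool), both in the units of
    ``c0``.  Dynamic linkers are hydrolysed in the expression host before
    the reaction starts; the lost pool shows up on gels as pre-cleaved
    species but never enters the cyclisation network.
    """
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must be in [0, 1)")
    return c0 * (1.0 - loss_fraction), c0 * loss_fraction
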