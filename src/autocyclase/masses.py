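"""Peptide mass and m/z arithmetic for cyclic and linear products.

Masses are computed from the standard residue composition tables shipped
with :mod:`pyteomics`.  A linear peptide carries one water (its termini);
a head-to-tail cyclic peptide carries none.  Each disulfide bond removes
two hydrogens.  Both monoisotopic and average scales are always returned
because published "calculated" masses of intact peptides are frequently
average-mass values while high-resolution observations are monoisotopic.
"""

from __future__ import annotations

from typing import NamedTuple

from pyteomics import mass as _pmass

#: Proton mass used for charge-state arithmetic, Da.
PROTON_DA = 1.00728

#: Mass of one water, monoisotopic / average, Da.
WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)

#: Mass of the two hydrogens lost per disulfide bond, Da.
DISULFIDE_MONO = _pmass.calculate_mass(formula="H2")
DISULFIDE_AVG = _pmass.calculate_mass(formula="H2", average=True)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# residue (amino-acid minus water) masses on both scales
RESIDUE_MONO = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_AA}
RESIDUE_AVG = {
    aa: _pmass.calculate_mass(sequence=aa, average=True) - WATER_AVG
    for aa in STANDARD_AA
}


class PeptideMass(NamedTuple):
    """Monoisotopic and average mass of one peptide, Da."""

    mono: float
    average: float


def peptide_mass(sequence: str, *, cyclic: bool = False, n_disulfides: int = 0) -> PeptideMass:
    """Mass of a peptide built from the 20 standard residues.

    Parameters
    ----------
    sequence
        One-letter amino-acid string.
    cyclic
        If true the peptide is head-to-tail closed and carries no terminal
        water.
    n_disulfides
        Number of disulfide bonds; each removes two hydrogens.

    Returns
    -------
    PeptideMass
        ``(mono, average)`` in Da.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    if 2 * n_disulfides > sequence.count("C"):
        raise ValueError(
            f"{n_disulfides} disulfides require {2 * n_disulfides} cysteines, "
            f"sequence has {sequence.count('C')}"
        )
    mono = avg = 0.0
    for ch in sequence:
        try:
            mono += RESIDUE_MONO[ch]
            avg += RESIDUE_AVG[ch]
        except KeyError:
            raise ValueError(f"unknown residue letter {ch!r}") from None
    if not cyclic:
        mono += WATER_MONO
        avg += WATER_AVG
    mono -= n_disulfides * DISULFIDE_MONO
    avg -= n_disulfides * DISULFIDE_AVG
    return PeptideMass(mono, avg)


def mz_for_charge(mass_da: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion.

    ``(mass + z * 1.00728) / z`` for integer ``z >= 1``.
    """
    if not isinstance(z, (int,)) or isinstance(z, bool):
        raise TypeError("charge z must be an integer")
    if z < 1:
        raise ValueError("charge z must be >= 1")
    return (mass_da + z * PROTON_DA) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Invert :func:`mz_for_charge`: neutral mass from an observed m/z."""
    if z < 1:
        raise ValueError("charge z must be >= 1")
    return mz * z - z * PROTON_DA
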