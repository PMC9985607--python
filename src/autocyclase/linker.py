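"""Tethering model: linker span, effective concentration, critical concentration.

The linker must span the distance from the sortase recognition site to
the enzyme's active site (~35-45 Angstrom across the body of sortase A),
which at an extended-chain contour of 3.5 A/residue corresponds to
roughly ten residues.  Treating the flexible tether (linker plus the
enzyme's disordered N-terminal residues) as a Gaussian chain gives the
effective local concentration of the recognition site at the active
site (Jacobson-Stockmayer-type end closure):

    Ceff = (3 / (2 pi <r^2>))**1.5 / N_A,   <r^2> = n_kuhn * b**2

with b the Kuhn length and n_kuhn = contour length / b.  The substrate
concentration at which the intermolecular (tandem-forming) flux matches
the intramolecular one — equating initial fluxes through a common
saturable recognition step with Michaelis constant Km — is

    C* = Km * Ceff / (Km + Ceff)

so C* -> Km when the tether is efficient (Ceff >> Km): raising the
enzyme's Km raises the onset of polymerisation proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AVOGADRO = 6.02214076e23

#: Extended-chain contour length per residue, Angstrom.
DEFAULT_CONTOUR_A = 3.5
#: Kuhn length for GS-rich flexible linkers, Angstrom.
DEFAULT_KUHN_A = 7.6
#: Disordered sortase N-terminal residues that add to the tether.
DEFAULT_ENZYME_NTERM_RES = 5


@dataclass(frozen=True)
class LinkerModelResult:
    """Bundle of tethering-model outputs (units in field names)."""

    span_A: float
    per_residue_A: float
    n_res_required: int
    n_flex: int
    kuhn_length_A: float
    ceff_M: float
    km_M: float | None
    c_star_M: float | None
    model: str = "gaussian-chain"


def required_linker_residues(span_A: float, per_residue_A: float = DEFAULT_CONTOUR_A) -> int:
    """Residues needed to span ``span_A`` at an extended-chain contour."""
    if span_A < 0:
        raise ValueError("span must be >= 0")
    if per_residue_A <= 0:
        raise ValueError("per-residue length must be > 0")
    return math.ceil(span_A / per_residue_A)


def effective_concentration(n_flex: int,
                            kuhn_length_A: float = DEFAULT_KUHN_A,
                            contour_per_residue_A: float = 3.8) -> float:
    """Gaussian-chain effective molarity of the tethered recognition site.

    ``n_flex`` counts flexible residues in the tether (linker plus any
    disordered enzyme N-terminus).  Result in mol/L.  Raises when the
    chain is shorter than one Kuhn segment, where the Gaussian closure
    is meaningless.
    """
    if n_flex < 1:
        raise ValueError("n_flex must be >= 1")
    if kuhn_length_A <= 0 or contour_per_residue_A <= 0:
        raise ValueError("lengths must be > 0")
    contour = n_flex * contour_per_residue_A
    if contour < kuhn_length_A:
        raise ValueError(
            f"tether contour {contour:.1f} A is shorter than one Kuhn segment "
            f"({kuhn_length_A:.1f} A); the Gaussian-chain closure does not apply")
    r2 = contour * kuhn_length_A  # (L/b) * b^2, Angstrom^2
    per_A3 = (3.0 / (2.0 * math.pi * r2)) ** 1.5   # chains per Angstrom^3
    return per_A3 * 1e27 / AVOGADRO                # mol/L


def critical_concentration(ceff_M: float, km_M: float) -> float:
    """Substrate concentration where inter- and intramolecular fluxes match.

    C* = Km * Ceff / (Km + Ceff); C* -> Km for Ceff >> Km and C* -> Ceff
    for Ceff -> 0, always below both.
    """
    if ceff_M <= 0 or km_M <= 0:
        raise ValueError("Ceff and Km must be > 0")
    return km_M * ceff_M / (km_M + ceff_M)


def linker_model(span_A: float = 35.0,
                 per_residue_A: float = DEFAULT_CONTOUR_A,
                 n_linker: int | None = None,
                 enzyme_nterm_res: int = DEFAULT_ENZYME_NTERM_RES,
                 kuhn_length_A: float = DEFAULT_KUHN_A,
                 contour_per_residue_A: float = 3.8,
                 km_M: float | None = None) -> LinkerModelResult:
    """Evaluate the full tethering model in one call.

    When ``n_linker`` is omitted the required span-derived count is used;
    the disordered enzyme N-terminus adds ``enzyme_nterm_res`` residues
    to the flexible tether.
    """
    n_req = required_linker_residues(span_A, per_residue_A)
    n_flex = (n_linker if n_linker is not None else n_req) + enzyme_nterm_res
    ceff = effective_concentration(n_flex, kuhn_length_A, contour_per_residue_A)
    c_star = critical_concentration(ceff, km_M) if km_M is not None else None
    return LinkerModelResult(
        span_A=span_A, per_residue_A=per_residue_A, n_res_required=n_req,
        n_flex=n_flex, kuhn_length_A=kuhn_length_A, ceff_M=ceff,
        km_M=km_M, c_star_M=c_star)
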