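"""Parsing of autocyclase fusion constructs and derivation of cyclic products.

An autocyclase is a six-module fusion protein that cyclises its own target:

    cap | TEV site (ENLYFQ/G) | target | recognition (LPXTG) | linker
        | [thrombin site (LVPR/S)] | sortase A body | His tag

TEV cleavage exposes the target's N-terminal glycine (the nucleophile);
sortase A then cleaves its own LPXTG recognition site between T and G and
ligates the LPXT acyl fragment head-to-tail onto that glycine.  The cyclic
product therefore retains the LPXT scar, while the recognition site's
terminal G departs with the linker/enzyme byproduct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

from .masses import STANDARD_AA, PeptideMass, peptide_mass

TEV_MOTIF = "ENLYFQG"
RECOGNITION_RE = re.compile(r"LP[A-Z]TG")
THROMBIN_MOTIF = "LVPRS"
MIN_HIS = 6


class ConstructParseError(ValueError):
    """A required module of the fusion could not be located."""


@dataclass(frozen=True)
class LinkerSpec:
    """A linker joining the recognition site to the sortase body.

    ``dynamic`` marks GGS-repeat style linkers designed to stay disordered.
    """

    name: str
    sequence: str
    dynamic: bool = False

    @property
    def n_res(self) -> int:
        return len(self.sequence)


#: The five named linker designs (subscript = residue count, D = dynamic).
NAMED_LINKERS: dict[str, LinkerSpec] = {
    "L7": LinkerSpec("L7", "AAALEGT"),
    "L12": LinkerSpec("L12", "AAALEGTLVPRS"),
    "L7D": LinkerSpec("L7D", "GS" + "GGS" + "GG", dynamic=True),
    "L14D": LinkerSpec("L14D", "GS" + "GGS" * 4, dynamic=True),
    "L19D": LinkerSpec("L19D", "GS" + "GGS" * 4 + "LVPRS", dynamic=True),
}

Segment = tuple[int, int]  # half-open [start, end) indices into full_sequence


@dataclass(frozen=True)
class AutocyclaseConstruct:
    """A parsed autocyclase with located module boundaries.

    The stored partition (``cap`` .. ``his_tag``) is contiguous and covers
    the full sequence.  Note one deliberate overlap between accessors: the
    TEV *motif* is seven residues (ENLYFQG) but cleavage falls between Q
    and G, and the exposed G is the target's first residue.  The partition
    therefore assigns only ENLYFQ to the protease-site segment, while
    :attr:`tev_site` reports the full seven-residue motif span.
    """

    full_sequence: str
    cap: Segment
    tev6: Segment
    target: Segment
    recognition: Segment
    linker_seg: Segment
    enzyme: Segment
    his_tag: Segment
    linker: LinkerSpec
    thrombin_site: Segment | None = None
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        order = [self.cap, self.tev6, self.target, self.recognition,
                 self.linker_seg, self.enzyme, self.his_tag]
        pos = 0
        for seg in order:
            if seg[0] != pos:
                raise ValueError(f"segments not contiguous at index {pos}")
            pos = seg[1]
        if pos != len(self.full_sequence):
            raise ValueError("segments do not cover the full sequence")

    def _s(self, seg: Segment) -> str:
        return self.full_sequence[seg[0]:seg[1]]

    @property
    def tev_site(self) -> Segment:
        """Seven-residue ENLYFQG motif span (overlaps the target's G)."""
        return (self.tev6[0], self.tev6[1] + 1)

    @property
    def tev_cleavage_point(self) -> int:
        """Index of the first residue after the TEV scissile bond (the G)."""
        return self.tev6[1]

    @property
    def cap_seq(self) -> str:
        return self._s(self.cap)

    @property
    def target_seq(self) -> str:
        """The sequence to be cyclised; starts with the nucleophilic G."""
        return self._s(self.target)

    @property
    def recognition_seq(self) -> str:
        return self._s(self.recognition)

    @property
    def scar(self) -> str:
        """LPXT — the four recognition residues retained in the product."""
        return self.recognition_seq[:4]

    @property
    def enzyme_seq(self) -> str:
        return self._s(self.enzyme)

    @property
    def his_seq(self) -> str:
        return self._s(self.his_tag)


def _identify_linker(seq: str, start: int, stop: int,
                     linker: str | LinkerSpec | None) -> LinkerSpec | None:
    """Find the linker beginning at ``start`` (end of recognition site).

    Tries, in order: an explicitly supplied linker, the named designs
    (longest first), then a generic span terminated by a thrombin site.
    Returns None when nothing plausible fits before ``stop``.
    """
    region = seq[start:stop]
    if isinstance(linker, LinkerSpec):
        return linker if region.startswith(linker.sequence) else None
    if isinstance(linker, str):
        return LinkerSpec("custom", linker) if region.startswith(linker) else None
    for spec in sorted(NAMED_LINKERS.values(), key=lambda s: -s.n_res):
        if region.startswith(spec.sequence):
            return spec
    p = region.find(THROMBIN_MOTIF)
    if p >= 0:
        cand = region[:p + len(THROMBIN_MOTIF)]
        if len(cand) < len(region):  # must leave room for the enzyme body
            return LinkerSpec("custom", cand, dynamic="GGS" in cand)
    return None


def parse_construct(seq: str, linker: str | LinkerSpec | None = None) -> AutocyclaseConstruct:
    """Locate all modules of an autocyclase fusion sequence.

    Parameters
    ----------
    seq
        One-letter amino-acid sequence of the intact fusion.
    linker
        Optional explicit linker (sequence or :class:`LinkerSpec`) for
        constructs whose linker is neither a named design nor terminated
        by a thrombin site.

    Raises
    ------
    ConstructParseError
        If any mandatory motif (TEV site, LPXTG, His tag) is absent, or
        the recognition site is not followed by an identifiable linker.
    """
    seq = seq.strip().upper()
    bad = set(seq) - set(STANDARD_AA)
    if bad:
        raise ConstructParseError(f"non-standard residue letters: {sorted(bad)}")

    tev = seq.find(TEV_MOTIF)
    if tev < 0:
        raise ConstructParseError("TEV site not found (ENLYFQG)")
    g_pos = tev + 6  # the nucleophilic glycine

    n_his = 0
    while n_his < len(seq) and seq[-(n_his + 1)] == "H":
        n_his += 1
    if n_his < MIN_HIS:
        raise ConstructParseError(
            f"His-tag not found (need >= {MIN_HIS} terminal H, found {n_his})")
    his_start = len(seq) - n_his

    matches = [m for m in RECOGNITION_RE.finditer(seq, g_pos + 1, his_start)]
    if not matches:
        raise ConstructParseError("recognition site not found (LPXTG)")

    chosen = None
    linker_spec = None
    warnings: list[str] = []
    for m in reversed(matches):  # prefer the match adjacent to linker/enzyme
        if m.end() >= his_start:
            continue
        spec = _identify_linker(seq, m.end(), his_start, linker)
        if spec is not None:
            chosen, linker_spec = m, spec
            break
    if chosen is None:
        if matches[-1].end() >= his_start:
            raise ConstructParseError(
                "recognition site terminal G not followed by a linker")
        raise ConstructParseError(
            "linker could not be identified after the recognition site "
            "(pass linker= explicitly for custom designs)")
    for m in matches:
        if m.span() != chosen.span():
            warnings.append(
                f"additional LPXTG-like motif {m.group()} at {m.start()} ignored")

    lk_start = chosen.end()
    lk_end = lk_start + linker_spec.n_res
    if lk_end >= his_start:
        raise ConstructParseError("no enzyme body between linker and His tag")
    thrombin = None
    p = seq.find(THROMBIN_MOTIF, lk_start, lk_end)
    if p >= 0:
        thrombin = (p, p + len(THROMBIN_MOTIF))

    return AutocyclaseConstruct(
        full_sequence=seq,
        cap=(0, tev),
        tev6=(tev, g_pos),
        target=(g_pos, chosen.start()),
        recognition=chosen.span(),
        linker_seg=(lk_start, lk_end),
        enzyme=(lk_end, his_start),
        his_tag=(his_start, len(seq)),
        linker=linker_spec,
        thrombin_site=thrombin,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class CyclicProduct:
    """A head-to-tail cyclic transpeptidation product.

    ``sequence`` is written from the nucleophilic N-terminal G through the
    T of the LPXT scar; ``order`` counts target units (n > 1 for products
    of tandem autocyclases).
    """

    sequence: str
    order: int
    n_disulfides: int
    mass: PeptideMass

    @property
    def mass_mono(self) -> float:
        return self.mass.mono

    @property
    def mass_avg(self) -> float:
        return self.mass.average


@dataclass(frozen=True)
class ProductSet:
    """Products of one transpeptidation outcome of a parsed construct."""

    cyclic: CyclicProduct
    byproduct: str            # G + linker + enzyme + tag, retained on SrtA
    linear: str               # hydrolysed open-chain counterpart
    linear_mass: PeptideMass


def derive_products(construct: AutocyclaseConstruct, order: int = 1,
                    n_disulfides: int | None = None) -> ProductSet:
    """Derive the cyclic product (and byproducts) of a parsed construct.

    The cyclic sequence is the ``order``-fold concatenation of
    (target + LPXT), head-to-tail closed; the recognition site's fifth
    residue (G) departs with the enzyme byproduct.  ``n_disulfides``
    defaults to the fully-oxidised count, ``cysteines // 2``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    unit = construct.target_seq + construct.scar
    cyc_seq = unit * order
    if n_disulfides is None:
        n_disulfides = cyc_seq.count("C") // 2
    cyclic = CyclicProduct(
        sequence=cyc_seq,
        order=order,
        n_disulfides=n_disulfides,
        mass=peptide_mass(cyc_seq, cyclic=True, n_disulfides=n_disulfides),
    )
    byproduct = (construct.recognition_seq[4]
                 + construct.full_sequence[construct.linker_seg[0]:])
    return ProductSet(
        cyclic=cyclic,
        byproduct=byproduct,
        linear=cyc_seq,
        linear_mass=peptide_mass(cyc_seq, cyclic=False, n_disulfides=n_disulfides),
    )


# ---------------------------------------------------------------------------
# Synthetic example constructs
# ---------------------------------------------------------------------------

#: Synthetic target sequences (nucleophilic G first) for three disulfide-rich
#: cyclic peptides.  These are reconstructions built from the native peptide
#: sequences and the LPGTG recognition site such that the derived cyclic
#: products reproduce the published product masses; they are stand-ins for
#: the original expression constructs, which are not redistributed here.
SYNTHETIC_PEPTIDE_TARGETS: dict[str, tuple[str, int]] = {
    # name: (target sequence, disulfide count of the folded product)
    "cSFTI": ("GRCTKSIPPICFPD", 1),
    "cKB1": ("GVCGETCVGGTCNTPGCTCSWPVCTRN", 3),
    "cVc1.1": ("GCCSDPRCNYDHPEIC", 2),
}

_ENZYME_STUB = "AKPQIPKDKSKVAGYIE"  # synthetic sortase-body placeholder


def example_construct(name: str, linker: str = "L19D") -> str:
    """Full synthetic autocyclase sequence for one of the example peptides."""
    try:
        target, _ = SYNTHETIC_PEPTIDE_TARGETS[name]
    except KeyError:
        raise KeyError(
            f"unknown example {name!r}; choose from {sorted(SYNTHETIC_PEPTIDE_TARGETS)}"
        ) from None
    lk = NAMED_LINKERS[linker].sequence if linker in NAMED_LINKERS else linker
    # target starts with G, which doubles as the TEV motif's seventh residue
    return "M" + TEV_MOTIF[:-1] + target + "LPGTG" + lk + _ENZYME_STUB + "H" * 10


def read_fasta(path) -> dict[str, str]:
    """Read a single- or multi-record FASTA into an ordered id -> sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    """Write an id -> sequence map as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
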