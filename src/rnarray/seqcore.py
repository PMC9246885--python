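"""Alphabets, strand arithmetic and the chimeric-oligo model.

Every sequence in this package is stored and displayed 5'->3'. Surface
attachment is a 3' flag on the oligo, never a reversal of the string, so the
shared linker/primer-hybridization block of a surface probe always appears at
the *end* of its sequence string.

Chemistry is tracked per segment (DNA, RNA or 2'-O-methyl RNA), not per base:
all species handled here are block chimeras such as the psoralen-labelled
2'-O-methyl RNA primer extended with an RNA tail by T7 RNA polymerase. U and T
are distinct characters; cross-chemistry comparisons go through
:func:`normalize_tu` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, Tuple

__all__ = [
    "Chemistry",
    "Label5",
    "Label3",
    "Segment",
    "ChimericOligo",
    "PrimerSpec",
    "DEFAULT_PRIMER",
    "AlphabetError",
    "ComplementarityError",
    "LengthError",
    "RoleError",
    "revcomp",
    "complement",
    "normalize_tu",
    "predicted_product",
    "assemble_solution_template",
]


class Chemistry(str, Enum):
    """Backbone/sugar chemistry of one contiguous segment."""

    DNA = "DNA"
    RNA = "RNA"
    OME = "OMe"  # 2'-O-methyl RNA (nuclease resistant; primer chemistry)


class Label5(str, Enum):
    NONE = "none"
    PSORALEN = "psoralen"
    CY3 = "Cy3"
    CY5 = "Cy5"
    FAM = "FAM"


class Label3(str, Enum):
    NONE = "none"
    SURFACE = "surface"


_ALPHABET = {
    Chemistry.DNA: frozenset("ACGT"),
    Chemistry.RNA: frozenset("ACGU"),
    Chemistry.OME: frozenset("ACGU"),
}

# Base-pairing partner expressed in the *output* chemistry.
_PAIR = {"A": "T", "T": "A", "U": "A", "C": "G", "G": "C"}


class AlphabetError(ValueError):
    """A character is not valid for the declared chemistry."""


class ComplementarityError(ValueError):
    """Two strands that must form a perfect duplex do not."""


class LengthError(ValueError):
    """A segment has an inadmissible length."""


class RoleError(ValueError):
    """An operation was applied to a probe of the wrong role."""


def _check_alphabet(seq: str, chem: Chemistry) -> None:
    allowed = _ALPHABET[chem]
    for i, base in enumerate(seq):
        if base not in allowed:
            raise AlphabetError(
                f"invalid {chem.value} character {base!r} at position {i} "
                f"(allowed: {''.join(sorted(allowed))})"
            )


def normalize_tu(seq: str) -> str:
    """Map U->T so sequences of different chemistries can be compared.

    This is the only sanctioned way to equate RNA and DNA spellings.
    """
    return seq.replace("U", "T")


def complement(seq: str, in_chem: Chemistry, out_chem: Chemistry) -> str:
    """Base-by-base complement (no reversal), re-expressed in ``out_chem``."""
    _check_alphabet(seq, in_chem)
    t_or_u = "U" if out_chem is not Chemistry.DNA else "T"
    out = []
    for base in seq:
        partner = _PAIR[base]
        out.append(t_or_u if partner == "T" else partner)
    return "".join(out)


def revcomp(seq: str, in_chem: Chemistry, out_chem: Chemistry) -> str:
    """Reverse complement of ``seq``, translated between chemistries.

    ``revcomp(revcomp(s, a, b), b, a) == s`` for any valid ``s``.

    Parameters
    ----------
    seq : str
        Sequence written 5'->3' in the alphabet of ``in_chem``.
    in_chem, out_chem : Chemistry
        Input and output chemistries; T<->U translation is applied as needed.
    """
    return complement(seq, in_chem, out_chem)[::-1]


@dataclass(frozen=True)
class Segment:
    """One contiguous block of uniform chemistry within a chimeric oligo."""

    sequence: str
    chemistry: Chemistry

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LengthError("segments must be non-empty")
        _check_alphabet(self.sequence, self.chemistry)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ChimericOligo:
    """A nucleic acid strand as ordered 5'->3' segments with terminal labels.

    Examples
    --------
    The extension product of the array primer is a psoralen-labelled chimera
    of one 2'-O-methyl segment (the primer) and one RNA segment (the
    polymerase extension)::

        ChimericOligo(
            segments=(Segment("UAGGGACACGGCGAA", Chemistry.OME),
                      Segment("GGAAAUUGGACCUGGGUUGA", Chemistry.RNA)),
            label5=Label5.PSORALEN,
        )
    """

    segments: Tuple[Segment, ...]
    label5: Label5 = Label5.NONE
    label3: Label3 = Label3.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise LengthError("a chimeric oligo needs at least one segment")
        self.label5, self.label3  # enum coercion is the caller's job

    @property
    def sequence(self) -> str:
        """Concatenated 5'->3' sequence across segments (mixed T/U spelling)."""
        return "".join(seg.sequence for seg in self.segments)

    def __len__(self) -> int:
        return sum(len(seg) for seg in self.segments)

    @classmethod
    def single(
        cls,
        sequence: str,
        chemistry: Chemistry,
        label5: Label5 = Label5.NONE,
        label3: Label3 = Label3.NONE,
    ) -> "ChimericOligo":
        return cls((Segment(sequence, chemistry),), label5, label3)

    # -- tab-delimited chimera dialect: name, label5, "chem:seq|chem:seq" ----

    def to_fields(self) -> str:
        return "|".join(f"{seg.chemistry.value}:{seg.sequence}" for seg in self.segments)

    @classmethod
    def from_fields(cls, spec: str, label5: str = "none", label3: str = "none") -> "ChimericOligo":
        segments = []
        for part in spec.split("|"):
            chem_name, _, seq = part.partition(":")
            segments.append(Segment(seq, Chemistry(chem_name)))
        return cls(tuple(segments), Label5(label5), Label3(label3))


MIN_PRIMER_LEN = 12  # selectivity floor for complex template libraries


@dataclass(frozen=True)
class PrimerSpec:
    """The universal 5'-psoralen 2'-O-methyl RNA primer.

    The psoralen moiety intercalates at the duplex terminus and crosslinks
    under 365 nm light, permanently tethering the primer (and later the RNA
    extension) to the template probe. Primers shorter than 12 nt cannot be
    made selective on libraries of >1e5 unique templates.
    """

    oligo: ChimericOligo
    name: str = "P15"

    def __post_init__(self) -> None:
        if len(self.oligo.segments) != 1 or self.oligo.segments[0].chemistry is not Chemistry.OME:
            raise ValueError("primer must be a single 2'-O-methyl RNA segment")
        if self.oligo.label5 is not Label5.PSORALEN:
            raise ValueError("primer must carry a 5' psoralen label")
        if len(self.oligo) < MIN_PRIMER_LEN:
            raise LengthError(
                f"primer length {len(self.oligo)} below the {MIN_PRIMER_LEN} nt selectivity floor"
            )

    @classmethod
    def from_sequence(cls, sequence: str, name: str = "P15") -> "PrimerSpec":
        return cls(ChimericOligo.single(sequence, Chemistry.OME, label5=Label5.PSORALEN), name)

    @property
    def sequence(self) -> str:
        return self.oligo.sequence

    def __len__(self) -> int:
        return len(self.oligo)

    def complement_block(self) -> str:
        """The DNA primer-complement block as it appears in template probes."""
        return revcomp(self.sequence, Chemistry.OME, Chemistry.DNA)


#: The published array primer: 5'-Ps-UAGGGACACGGCGAA (2'-O-methyl RNA, 15 nt).
DEFAULT_PRIMER = PrimerSpec.from_sequence("UAGGGACACGGCGAA", name="P15")


def predicted_product(template, primer: PrimerSpec) -> ChimericOligo:
    """Predict the T7 RNA polymerase extension product of ``primer`` on ``template``.

    The polymerase extends the crosslinked primer 3'-ward, copying the
    template's variable region, so the product is the primer segment followed
    by the RNA reverse complement of the variable region; total length is
    primer length + variable length.

    Parameters
    ----------
    template : TemplateSpec
        Must have role ``"transcribable"``; its primer-complement block must
        be a perfect Watson-Crick match to ``primer``.
    primer : PrimerSpec

    Raises
    ------
    RoleError
        If the template is an untranscribable control.
    ComplementarityError
        If primer and template block mismatch (positions are listed).
    LengthError
        If the variable region is empty.
    """
    if getattr(template, "role", None) != "transcribable":
        raise RoleError(
            f"probe {getattr(template, 'probe_id', '?')!r} has role "
            f"{getattr(template, 'role', None)!r}; only transcribable templates are extended"
        )
    if not template.variable:
        raise LengthError("template has an empty variable region: nothing to transcribe")
    block = template.primer_block
    expected = primer.complement_block()
    if len(block) != len(expected):
        raise ComplementarityError(
            f"primer-complement block length {len(block)} != primer length {len(expected)}"
        )
    mismatches = [i for i, (a, b) in enumerate(zip(block, expected)) if a != b]
    if mismatches:
        raise ComplementarityError(
            f"primer/template mismatch at block positions {mismatches}"
        )
    rna = revcomp(template.variable, Chemistry.DNA, Chemistry.RNA)
    return ChimericOligo(
        (Segment(primer.sequence, Chemistry.OME), Segment(rna, Chemistry.RNA)),
        label5=Label5.PSORALEN,
    )


def assemble_solution_template(variable: str, primer: ChimericOligo | PrimerSpec) -> ChimericOligo:
    """Assemble the solution-phase DNA template used to replicate the array
    reaction in a tube.

    The strand, written 5'->3', is the variable region, then the DNA
    complement of the primer, then a dT 5-mer standing in for the surface
    linker.  With a 30 nt variable region and a 27 nt primer this yields the
    62 nt reference species; the matching extension product is 57 nt.
    """
    if isinstance(primer, PrimerSpec):
        primer = primer.oligo
    if len(primer.segments) != 1 or primer.segments[0].chemistry is not Chemistry.OME:
        raise ValueError("primer must be a single 2'-O-methyl RNA segment")
    if not variable:
        raise LengthError("variable region must be non-empty")
    _check_alphabet(variable, Chemistry.DNA)
    seq = variable + revcomp(primer.sequence, Chemistry.OME, Chemistry.DNA) + "TTTTT"
    return ChimericOligo.single(seq, Chemistry.DNA)
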