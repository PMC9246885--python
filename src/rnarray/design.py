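"""Construction and validation of transcribable template libraries.

A surface template probe, written 5'->3', is::

    [variable region] + [primer-complement block] + [dT linker] -3'-surface

The variable region is what the polymerase copies into RNA; the block
hybridizes and crosslinks the universal psoralen primer; the dT homopolymer
spaces the duplex off the glass and survives DNase treatment when short.
Untranscribable controls omit the block and instead carry the RNA-product
sequence as DNA, so the same labelled detection probe hybridizes them
directly (reference features / background features, depending on assay).

This module builds the published assay libraries: the ink-jet variant series
(linker lengths dT5..dT20 with terminal and central permutations, 60
replicates each) and the single-dA "walk" series used to read out positional
incorporation of labelled rU.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .seqcore import (
    Chemistry,
    ComplementarityError,
    DEFAULT_PRIMER,
    LengthError,
    PrimerSpec,
    RoleError,
    revcomp,
)

__all__ = [
    "TemplateSpec",
    "DesignTable",
    "CrosslinkReport",
    "SelectivityHit",
    "ConstraintError",
    "ConstructionError",
    "PLATFORM_LIMITS",
    "make_template",
    "make_control",
    "validate_crosslink_site",
    "primer_selectivity_screen",
    "agilent_series",
    "da_walk_series",
]


class ConstraintError(ValueError):
    """A design constraint (platform length, forbidden substring) is violated."""


class ConstructionError(ValueError):
    """A library could not be assembled consistently (e.g. duplicate ids)."""


#: Maximum full-sequence length per synthesis platform (None = unbounded).
PLATFORM_LIMITS: Dict[str, Optional[int]] = {
    "inkjet": 150,          # commercial ink-jet arrays accommodate up to 150mers
    "photolithography": None,  # limited only by the cycle budget
}


@dataclass(frozen=True)
class TemplateSpec:
    """One surface-bound DNA probe.

    ``full_sequence`` is derived: for transcribable probes it is
    ``variable + primer_block + T*linker_len``; for controls it is
    ``revcomp(variable) + T*linker_len`` (the product sequence as DNA, no
    primer complement).

    Optional annotations carry assay metadata: image channel and brightness
    level for image-encoding probes, the extension position of the single rU
    for dA-walk probes, and ``response_len`` — the overlap length with the
    labelled detection probe that drives hybridization signal (defaults to
    the variable-region length when unset).
    """

    probe_id: str
    variable: str
    linker_len: int = 5
    role: str = "transcribable"  # or "control"
    primer_name: str = "P15"
    primer_block: str = ""
    channel: Optional[str] = None
    level: Optional[int] = None
    ru_position: Optional[int] = None
    response_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ("transcribable", "control"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.linker_len < 0:
            raise LengthError("linker_len must be >= 0")
        if not self.variable:
            raise LengthError(f"probe {self.probe_id!r}: empty variable region")
        if self.role == "transcribable" and not self.primer_block:
            raise ConstraintError(
                f"probe {self.probe_id!r}: transcribable templates need a primer-complement block"
            )
        if self.role == "control" and self.primer_block:
            raise ConstraintError(
                f"probe {self.probe_id!r}: controls must not carry a primer-complement block"
            )

    @property
    def full_sequence(self) -> str:
        linker = "T" * self.linker_len
        if self.role == "transcribable":
            return self.variable + self.primer_block + linker
        return revcomp(self.variable, Chemistry.DNA, Chemistry.DNA) + linker

    @property
    def length(self) -> int:
        return len(self.full_sequence)

    @property
    def effective_response_len(self) -> int:
        return len(self.variable) if self.response_len is None else self.response_len


@dataclass
class DesignTable:
    """An ordered template library with replicate bookkeeping."""

    templates: List[TemplateSpec]
    replicate_count: int = 1
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ConstructionError("replicate_count must be >= 1")
        seen = set()
        for t in self.templates:
            if t.probe_id in seen:
                raise ConstructionError(f"duplicate probe_id {t.probe_id!r}")
            seen.add(t.probe_id)

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def get(self, probe_id: str) -> TemplateSpec:
        for t in self.templates:
            if t.probe_id == probe_id:
                return t
        raise KeyError(probe_id)

    def index(self) -> Dict[str, TemplateSpec]:
        return {t.probe_id: t for t in self.templates}

    def extend(self, others: Iterable[TemplateSpec]) -> "DesignTable":
        return DesignTable(
            self.templates + list(others), self.replicate_count, dict(self.metadata)
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in self.templates:
            rows.append(
                {
                    "probe_id": t.probe_id,
                    "role": t.role,
                    "linker_len": t.linker_len,
                    "variable": t.variable,
                    "full_sequence": t.full_sequence,
                    "primer_name": t.primer_name,
                    "primer_block": t.primer_block,
                    "channel": t.channel,
                    "level": t.level,
                    "ru_position": t.ru_position,
                    "response_len": t.response_len,
                }
            )
        return pd.DataFrame(rows)

    def randomized_layout(
        self,
        seed: int = 1,
        n_rows: Optional[int] = None,
        n_cols: Optional[int] = None,
    ):
        """Place ``replicate_count`` copies of every probe at random grid
        positions (probe positions on the surface are randomized, as in the
        published arrays). Returns an :class:`~rnarray.imagecode.ArrayLayout`.
        """
        from .imagecode import ArrayLayout  # local import: avoids module cycle

        total = len(self.templates) * self.replicate_count
        if n_cols is None:
            n_cols = int(np.ceil(np.sqrt(total)))
        if n_rows is None:
            n_rows = int(np.ceil(total / n_cols))
        if n_rows * n_cols < total:
            raise ConstructionError(
                f"grid {n_rows}x{n_cols} too small for {total} features"
            )
        rng = np.random.default_rng(seed)
        positions = [(r, c) for r in range(n_rows) for c in range(n_cols)]
        order = rng.permutation(len(positions))[:total]
        features = {}
        k = 0
        for t in self.templates:
            for _ in range(self.replicate_count):
                r, c = positions[order[k]]
                features[(r, c)] = t.probe_id
                k += 1
        return ArrayLayout(n_rows=n_rows, n_cols=n_cols, features=features)


def _check_platform(probe_id: str, full_sequence: str, platform: str) -> None:
    limit = PLATFORM_LIMITS.get(platform)
    if limit is not None and len(full_sequence) > limit:
        raise ConstraintError(
            f"probe {probe_id!r}: full sequence length {len(full_sequence)} exceeds the "
            f"{limit} nt limit of the {platform} platform"
        )


def make_template(
    variable: str,
    linker_len: int = 5,
    primer: PrimerSpec = DEFAULT_PRIMER,
    probe_id: Optional[str] = None,
    platform: str = "inkjet",
    **annotations,
) -> TemplateSpec:
    """Build a transcribable template for ``variable`` on a dT linker.

    The full sequence ends in the primer-complement block followed by the dT
    homopolymer, e.g. the green channel template on a dT5 linker is the 40 nt
    ``TCAACCCAGGTCCAATTTCCTTCGCCGTGTCCCTATTTTT``.
    """
    if probe_id is None:
        probe_id = f"t_{variable[:8]}_dT{linker_len}"
    spec = TemplateSpec(
        probe_id=probe_id,
        variable=variable,
        linker_len=linker_len,
        role="transcribable",
        primer_name=primer.name,
        primer_block=primer.complement_block(),
        **annotations,
    )
    _check_platform(probe_id, spec.full_sequence, platform)
    return spec


def make_control(
    variable: str,
    linker_len: int = 5,
    probe_id: Optional[str] = None,
    primer: PrimerSpec = DEFAULT_PRIMER,
    platform: str = "inkjet",
    **annotations,
) -> TemplateSpec:
    """Build the matched untranscribable control for ``variable``.

    The control carries the RNA-product sequence as DNA (the reverse
    complement of the variable region) with no primer complement, so it
    hybridizes the same labelled probe directly but is never extended.
    Construction asserts that the control does not accidentally contain the
    primer-complement block.
    """
    if probe_id is None:
        probe_id = f"c_{variable[:8]}_dT{linker_len}"
    spec = TemplateSpec(
        probe_id=probe_id,
        variable=variable,
        linker_len=linker_len,
        role="control",
        primer_name=primer.name,
        **annotations,
    )
    if primer.complement_block() in spec.full_sequence:
        raise ConstraintError(
            f"probe {probe_id!r}: control sequence contains the primer-complement block"
        )
    _check_platform(probe_id, spec.full_sequence, platform)
    return spec


def _pairs(a: str, b: str) -> bool:
    """Watson-Crick pairing with U:A allowed (RNA/DNA heteroduplex)."""
    return (
        (a in "TU" and b == "A")
        or (a == "A" and b in "TU")
        or (a == "G" and b == "C")
        or (a == "C" and b == "G")
    )


@dataclass(frozen=True)
class CrosslinkReport:
    """Outcome of the psoralen crosslink-site check on one template."""

    probe_id: str
    duplex_len: int
    all_watson_crick: bool
    terminal_pair_is_ua_or_ta: bool
    linker_first_base_is_t: bool

    @property
    def passed(self) -> bool:
        return (
            self.all_watson_crick
            and self.terminal_pair_is_ua_or_ta
            and self.linker_first_base_is_t
        )


def validate_crosslink_site(template: TemplateSpec, primer: PrimerSpec = DEFAULT_PRIMER) -> CrosslinkReport:
    """Check that the primer/template duplex supports psoralen crosslinking.

    Psoralen intercalates at the duplex terminus next to its tether and
    requires a T/A-type base pair there, with the first linker dT stacking on
    the other side; the whole primer must be in perfect duplex. The report
    carries the individual checks; ``passed`` is their conjunction.
    """
    if template.role != "transcribable":
        raise RoleError(f"probe {template.probe_id!r} is a control; no crosslink site")
    block = template.primer_block
    primer_seq = primer.sequence
    duplex_len = min(len(block), len(primer_seq))
    all_wc = len(block) == len(primer_seq) and all(
        _pairs(primer_seq[i], block[len(block) - 1 - i]) for i in range(duplex_len)
    )
    terminal = primer_seq[0] in "TU" and block[-1] == "A"
    after_block = len(template.variable) + len(block)
    full = template.full_sequence
    linker_t = len(full) > after_block and full[after_block] == "T"
    return CrosslinkReport(
        probe_id=template.probe_id,
        duplex_len=duplex_len,
        all_watson_crick=all_wc,
        terminal_pair_is_ua_or_ta=terminal,
        linker_first_base_is_t=linker_t,
    )


@dataclass(frozen=True)
class SelectivityHit:
    probe_id: str
    stretch_len: int
    offset: int  # 0-based offset of the match within the variable region


def primer_selectivity_screen(
    library: DesignTable | Sequence[TemplateSpec],
    primer: PrimerSpec = DEFAULT_PRIMER,
    min_flag_len: int = 12,
) -> List[SelectivityHit]:
    """Flag templates whose variable region could hybridize the primer.

    For each template the longest contiguous stretch of the primer whose
    complement occurs inside the variable region (on either strand) is
    found by exhaustive substring search; templates with a stretch of at
    least ``min_flag_len`` (default 12, the selectivity floor) are reported.
    The intended primer-complement block itself sits outside the variable
    region and is therefore never flagged.
    """
    if min_flag_len < 1:
        raise ValueError("min_flag_len must be >= 1")
    primer_dna = primer.sequence.replace("U", "T")
    hits: List[SelectivityHit] = []
    for t in library:
        var = t.variable
        found = None
        max_l = min(len(primer_dna), len(var))
        for length in range(max_l, min_flag_len - 1, -1):
            for start in range(len(primer_dna) - length + 1):
                sub = primer_dna[start : start + length]
                rc = revcomp(sub, Chemistry.DNA, Chemistry.DNA)
                off = var.find(rc)
                if off < 0:
                    off = var.find(sub)
                if off >= 0:
                    found = SelectivityHit(t.probe_id, length, off)
                    break
            if found:
                break
        if found:
            hits.append(found)
    return hits


def _distinct_rearrangements(bases: str) -> List[str]:
    """All distinct orderings of a 3-base multiset, identity included."""
    return sorted(set("".join(p) for p in itertools.permutations(bases)))


def agilent_series(
    base_variable: str,
    primer: PrimerSpec = DEFAULT_PRIMER,
    linker_lens: Sequence[int] = (5, 10, 15, 20),
    replicate_count: int = 60,
    seed: int = 1,
    platform: str = "inkjet",
    central_positions: Optional[Tuple[int, int, int]] = None,
) -> DesignTable:
    """Build the ink-jet variant series around one base template.

    For every linker length the series contains: the reference template; all
    distinct rearrangements of the 3 bases at the 3' terminus of the
    primer-complement block; all distinct rearrangements of 3 central
    variable-region positions (mismatch variants); and the matched
    untranscribable control. A single direct-hybridization reference probe is
    added once. Every probe is replicated ``replicate_count`` times at
    seeded random surface positions when a layout is requested.
    """
    if len(base_variable) < 7:
        raise ConstraintError("base variable region must be at least 7 nt")
    block = primer.complement_block()
    if central_positions is None:
        mid = len(base_variable) // 2
        central_positions = (mid - 1, mid, mid + 1)
    templates: List[TemplateSpec] = []
    for n in linker_lens:
        templates.append(
            make_template(base_variable, n, primer, probe_id=f"tmpl_dT{n:02d}", platform=platform)
        )
        # 3'-terminal permutations of the primer-complement block
        stem, tail = block[:-3], block[-3:]
        for i, arr in enumerate(_distinct_rearrangements(tail)):
            templates.append(
                TemplateSpec(
                    probe_id=f"tperm{i}_dT{n:02d}",
                    variable=base_variable,
                    linker_len=n,
                    role="transcribable",
                    primer_name=primer.name,
                    primer_block=stem + arr,
                )
            )
            _check_platform(templates[-1].probe_id, templates[-1].full_sequence, platform)
        # central mismatch permutations of the variable region
        i0, i1, i2 = central_positions
        centre = base_variable[i0] + base_variable[i1] + base_variable[i2]
        for i, arr in enumerate(_distinct_rearrangements(centre)):
            var = list(base_variable)
            var[i0], var[i1], var[i2] = arr[0], arr[1], arr[2]
            templates.append(
                make_template(
                    "".join(var), n, primer, probe_id=f"cperm{i}_dT{n:02d}", platform=platform
                )
            )
        templates.append(
            make_control(base_variable, n, probe_id=f"ctrl_dT{n:02d}", primer=primer, platform=platform)
        )
    # dedicated direct-hybridization reference for the labelled probe
    templates.append(
        make_control(
            base_variable,
            linker_lens[0],
            probe_id="refhyb",
            primer=primer,
            platform=platform,
        )
    )
    return DesignTable(
        templates,
        replicate_count=replicate_count,
        metadata={
            "platform": platform,
            "primer": primer.sequence,
            "seed": seed,
            "series": "agilent-variants",
        },
    )


def da_walk_series(
    linker_len: int = 5,
    primer: PrimerSpec = DEFAULT_PRIMER,
    n_units: int = 20,
    proximal_start: bool = True,
) -> DesignTable:
    """Build the single-dA walk series for positional rU incorporation.

    The variable region, read 3'->5' from the primer-complement block, is a
    run of ``n_units`` TGC repeats carrying exactly one dA: variant 0 places
    it at the very start (surface-proximal, extension position 1) and variant
    k (k = 1..n_units) immediately after the k-th dC, i.e. at extension
    position 3k+1 — one labelled rU at every third position of the 61 nt
    product, up to the 5'-distal end (position 61). Each template has a
    matched no-primer-complement control with the same annotation.

    ``proximal_start=False`` flips the convention so variant 0 sits at the
    distal end instead.
    """
    templates: List[TemplateSpec] = []
    repeats = "TGC" * n_units
    total = 3 * n_units + 1
    variants: List[Tuple[int, str]] = []  # (ru_position, variable read 3'->5')
    variants.append((1, "A" + repeats))
    for k in range(1, n_units + 1):
        read35 = "TGC" * k + "A" + "TGC" * (n_units - k)
        variants.append((3 * k + 1, read35))
    for pos, read35 in variants:
        if not proximal_start:
            read35 = read35[::-1]
            pos = total - pos + 1
        variable = read35[::-1]  # store 5'->3'
        templates.append(
            make_template(
                variable,
                linker_len,
                primer,
                probe_id=f"daA_pos{pos:02d}",
                platform="photolithography",
                ru_position=pos,
            )
        )
    controls = [
        make_control(
            t.variable,
            linker_len,
            probe_id=f"daC_pos{t.ru_position:02d}",
            primer=primer,
            platform="photolithography",
            ru_position=t.ru_position,
        )
        for t in templates
    ]
    return DesignTable(
        templates + controls,
        replicate_count=85,
        metadata={"platform": "photolithography", "primer": primer.sequence, "series": "dA-walk"},
    )
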