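"""Maskless-photolithography synthesis planning.

Converts an array layout plus its design table into an ordered cycle
schedule with per-cycle micromirror masks. Synthesis proceeds 3'->5'
(surface-proximal base first). Linker dT positions shared by every probe are
coupled as unmasked flood cycles with the acid-labile DMTr-dT monomer (acid
deprotection is not spatially addressed); all remaining positions use
photodeprotected BzNPPOC monomers addressed by boolean DMD masks, cycling
through a fixed base order and skipping cycles whose mask would be empty.
A replay simulator reconstructs the synthesized sequences from the plan and
serves as the round-trip verifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .design import DesignTable
from .imagecode import ArrayLayout

__all__ = [
    "MONOMER_SPECS",
    "Cycle",
    "SynthesisPlan",
    "SchedulingError",
    "schedule_synthesis",
    "replay",
    "synthesis_stats",
]


class SchedulingError(ValueError):
    """A feature sequence cannot be synthesized under the given base order."""


#: (photodeprotection dose J/cm^2, coupling time s) per monomer. BzNPPOC
#: nucleosides deprotect at 3 J/cm^2 and couple in 15 s; NPPOC-protected
#: hexaethylene glycol needs 6 J/cm^2 and 300 s; DMTr-dT is acid-deprotected
#: (no light dose) and couples in 120 s.
MONOMER_SPECS: Dict[str, Tuple[float, float]] = {
    "dA": (3.0, 15.0),
    "dC": (3.0, 15.0),
    "dG": (3.0, 15.0),
    "dT": (3.0, 15.0),
    "HEG": (6.0, 300.0),
    "dT-DMTr": (0.0, 120.0),
}

_CHAR_TO_MONOMER = {"A": "dA", "C": "dC", "G": "dG", "T": "dT", "E": "HEG"}
_MONOMER_TO_CHAR = {"dA": "A", "dC": "C", "dG": "G", "dT": "T", "HEG": "E", "dT-DMTr": "T"}

FLOOD = "FLOOD"


@dataclass(frozen=True)
class Cycle:
    """One synthesis cycle: a monomer coupled after (photo)deprotection."""

    monomer: str
    mask_id: Optional[str]  # None = flood (all-on) cycle
    dose: float  # J/cm^2
    coupling_time: float  # s

    @property
    def is_flood(self) -> bool:
        return self.mask_id is None


@dataclass
class SynthesisPlan:
    """Ordered cycles plus the mask stack, dimensions = layout grid."""

    cycles: List[Cycle]
    masks: Dict[str, np.ndarray]  # mask_id -> bool (n_rows, n_cols)
    grid: Tuple[int, int]

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def _feature_sequences(layout: ArrayLayout, design: DesignTable) -> Dict[Tuple[int, int], str]:
    index = design.index()
    seqs = {}
    for pos, pid in layout.features.items():
        try:
            seqs[pos] = index[pid].full_sequence
        except KeyError:
            raise SchedulingError(f"probe {pid!r} at {pos} not found in design table")
    return seqs


def schedule_synthesis(
    layout: ArrayLayout,
    design: DesignTable,
    base_order: str = "ACGT",
    flood_linker: bool = True,
) -> SynthesisPlan:
    """Plan the cycle schedule and mask stack for ``layout``.

    The shared 3' dT run (the minimum linker length over all placed probes,
    when ``flood_linker``) is emitted first as flood DMTr-dT cycles. The
    remaining positions are coupled by cycling through ``base_order``: the
    cycle for base b exposes exactly the features whose next unsynthesized
    (3'-most remaining) base is b; empty cycles are dropped; iteration ends
    when every feature is complete. Deterministic given its inputs.
    """
    seqs = _feature_sequences(layout, design)
    grid = (layout.n_rows, layout.n_cols)
    if not seqs:
        return SynthesisPlan([], {}, grid)
    index = design.index()
    n_flood = 0
    if flood_linker:
        # every full sequence ends in linker_len T's by construction; flood
        # couples only the run shared by all placed probes
        linker_lens = [index[pid].linker_len for pid in set(layout.features.values())]
        n_flood = min(linker_lens, default=0)
    masked_alphabet = set().union(*(set(s[: len(s) - n_flood]) for s in seqs.values()))
    bad = masked_alphabet - set(base_order)
    if bad:
        raise SchedulingError(
            f"sequence monomer(s) {sorted(bad)} absent from base order {base_order!r}"
        )

    cycles: List[Cycle] = []
    masks: Dict[str, np.ndarray] = {}
    for _ in range(n_flood):
        dose, t = MONOMER_SPECS["dT-DMTr"]
        cycles.append(Cycle("dT-DMTr", None, dose, t))
    # pointer = number of bases still to couple (from the 3' end, floods done)
    remaining = {pos: len(s) - n_flood for pos, s in seqs.items()}
    positions = sorted(seqs)
    order_idx = 0
    while any(n > 0 for n in remaining.values()):
        base = base_order[order_idx % len(base_order)]
        order_idx += 1
        active = [
            pos
            for pos in positions
            if remaining[pos] > 0 and seqs[pos][remaining[pos] - 1] == base
        ]
        if not active:
            continue
        mask = np.zeros(grid, dtype=bool)
        for r, c in active:
            mask[r, c] = True
        mask_id = f"cycle{len(cycles):04d}"
        masks[mask_id] = mask
        dose, t = MONOMER_SPECS[_CHAR_TO_MONOMER[base]]
        cycles.append(Cycle(_CHAR_TO_MONOMER[base], mask_id, dose, t))
        for pos in active:
            remaining[pos] -= 1
    return SynthesisPlan(cycles, masks, grid)


def replay(plan: SynthesisPlan, layout: ArrayLayout) -> Dict[Tuple[int, int], str]:
    """Simulate the plan coupling by coupling; return per-feature 5'->3'
    sequences. ``replay(schedule_synthesis(layout, design), layout)`` equals
    the design's full sequences — the round-trip verification oracle.
    """
    built: Dict[Tuple[int, int], List[str]] = {pos: [] for pos in layout.features}
    for cycle in plan.cycles:
        char = _MONOMER_TO_CHAR[cycle.monomer]
        if cycle.is_flood:
            for pos in built:
                built[pos].append(char)
        else:
            mask = plan.masks[cycle.mask_id]
            for (r, c) in built:
                if mask[r, c]:
                    built[(r, c)].append(char)
    return {pos: "".join(reversed(chars)) for pos, chars in built.items()}


def synthesis_stats(plan: SynthesisPlan) -> Dict[str, float]:
    """Cycle count plus total light dose and coupling time for the plan."""
    return {
        "n_cycles": plan.n_cycles,
        "total_dose": float(sum(c.dose for c in plan.cycles)),
        "total_coupling_time": float(sum(c.coupling_time for c in plan.cycles)),
    }
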