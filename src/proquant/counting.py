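"""Proportional count accumulation over unique feature positions.

Each unit contributes F_c = F_O / F_L to every feature whose unique
positions it overlaps, where F_O is the overlapped unique-base count and
F_L the unit's total length; unpaired/discordant reads contribute half
that, guarding against erroneous mappings. Bases in regions shared by
two or more features are ambiguous and earn no counts for anyone.
Uniquely mapped units accumulate directly; multimapped units are parked
as per-(template, feature) contributions for the EM stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from proquant.annotation import UniqueRegionIndex
from proquant.intake import AlignmentUnit


@dataclass
class CountState:
    """Per-feature accumulators built up across chunks.

    ``n_f0`` holds uniquely-mapped fractional counts (the EM anchor),
    ``n_align`` tallies units with any unique overlap (multimapped units
    included), ``mm_contribs`` parks (template, feature, F_c) triples for
    EM, and ``n_fk`` receives the EM-adjusted totals.
    """

    n_f0: dict[str, float] = field(default_factory=dict)
    n_align: dict[str, int] = field(default_factory=dict)
    mm_contribs: list[tuple[str, str, float]] = field(default_factory=list)
    n_fk: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.n_f0.values())


def overlap_unique(unit: AlignmentUnit, index: UniqueRegionIndex) -> dict[str, int]:
    """Bases of ``unit`` falling in each feature's unique intervals (F_O).

    Features with zero overlap are omitted; a contig (or strand lane)
    absent from the index yields an empty mapping.
    """
    key = (unit.contig, index.strand_key(unit.effective_strand))
    tree = index.trees.get(key)
    if tree is None:
        return {}
    out: dict[str, int] = {}
    for iv in tree.overlap(unit.start, unit.end):
        cut = min(unit.end, iv.end) - max(unit.start, iv.begin)
        if cut > 0:
            out[iv.data] = out.get(iv.data, 0) + cut
    return out


def proportional_count(f_o: int, unit: AlignmentUnit) -> float:
    """F_c = F_O / F_L for fragments, halved for lone reads; 0 <= F_c <= 1."""
    if unit.f_l <= 0:
        raise ValueError("unit has non-positive length")
    f_c = f_o / unit.f_l
    if unit.kind == "read":
        f_c /= 2.0
    return f_c


def accumulate(
    units: list[AlignmentUnit], index: UniqueRegionIndex, state: CountState
) -> CountState:
    """Add one chunk of units into ``state`` (order-independent).

    Uniquely mapped units go straight into ``n_f0``; multimapped units are
    appended to ``mm_contribs`` to be redistributed after all uniquely
    mapped records are in. ``n_align`` counts every retained unit with
    F_O > 0 regardless of later EM weighting.
    """
    for unit in units:
        overlaps = overlap_unique(unit, index)
        for fid, f_o in overlaps.items():
            f_c = proportional_count(f_o, unit)
            state.n_align[fid] = state.n_align.get(fid, 0) + 1
            if unit.is_multimapped:
                state.mm_contribs.append((unit.template_name, fid, f_c))
            else:
                state.n_f0[fid] = state.n_f0.get(fid, 0.0) + f_c
    return state
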