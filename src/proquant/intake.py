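"""Alignment record validation, fragment reconstruction, and chunked streaming.

Records are streamed one at a time from a coordinate-sorted SAM/BAM.
Each kept record becomes at most one countable *unit*: a properly paired
record with a plausible template length is reconstructed into a fragment
spanning leftmost to rightmost mate coordinate (emitted once, from the
TLEN > 0 mate, since the mate's coordinates are implied); anything else
kept is counted as a single read. Multimapped units (NH tag > 1) are
flagged so counting can defer them to the EM stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import pysam

from proquant.errors import AlignmentError

log = logging.getLogger(__name__)

UNSTRANDED_MARK = "."

# sentinel: the rightmost mate of a reconstructed fragment emits nothing
DEFER_TO_MATE = object()


@dataclass(frozen=True)
class AlignmentUnit:
    """One countable unit: a reconstructed pair fragment or a lone read.

    ``f_l`` is the total fragment length (|TLEN| for fragments, aligned
    reference span for reads) — the denominator of the proportional count.
    ``effective_strand`` is '.' for unstranded libraries.
    """

    contig: str
    start: int  # 0-based half-open span
    end: int
    effective_strand: str  # '+', '-' or '.'
    kind: str  # 'fragment' or 'read'
    f_l: int
    is_multimapped: bool
    template_name: str

    @property
    def span_length(self) -> int:
        return self.end - self.start


def _nh(rec: pysam.AlignedSegment) -> int:
    try:
        return int(rec.get_tag("NH"))
    except KeyError:
        return 1  # missing NH: treat as uniquely mapped


def validate_record(
    rec: pysam.AlignedSegment,
    min_mapq: int = 10,
    remove_multimapped: bool = False,
    use_secondary_multimaps: bool = False,
) -> tuple[bool, str | None]:
    """Apply the keep/discard rules; returns (keep, discard_reason).

    A record is kept if it is mapped, primary (secondary 0x100 and
    supplementary 0x800 are dropped), and has MAPQ >= min_mapq. With
    ``remove_multimapped``, NH > 1 records are dropped too. With
    ``use_secondary_multimaps``, secondary records belonging to NH > 1
    templates are admitted so the EM stage can weigh alternative loci.
    """
    if rec.is_unmapped:
        return False, "unmapped"
    if rec.is_supplementary:
        return False, "supplementary"
    nh = _nh(rec)
    if rec.is_secondary and not (use_secondary_multimaps and nh > 1 and not remove_multimapped):
        return False, "secondary"
    if rec.mapping_quality < min_mapq:
        return False, "low_mapq"
    if remove_multimapped and nh > 1:
        return False, "multimapped"
    return True, None


def _read_strand(rec: pysam.AlignedSegment) -> str:
    return "-" if rec.is_reverse else "+"


def _first_in_pair_strand(rec: pysam.AlignedSegment) -> str:
    if rec.is_read1 or not rec.is_paired:
        return "-" if rec.is_reverse else "+"
    return "-" if rec.mate_is_reverse else "+"


def _effective_strand(rec: pysam.AlignedSegment, kind: str, strandedness: str) -> str:
    if strandedness == "unstranded":
        return UNSTRANDED_MARK
    base = _first_in_pair_strand(rec) if kind == "fragment" else _read_strand(rec)
    if strandedness == "reverse":
        return "-" if base == "+" else "+"
    return base


def classify_unit(
    rec: pysam.AlignedSegment,
    max_fragment_size: int = 1000,
    strandedness: str = "unstranded",
):
    """Classify one kept record as a fragment unit, a read unit, or a defer.

    A record is processed as a fragment iff it is properly paired (0x2),
    its mate maps to the same contig, and 0 < |TLEN| < max_fragment_size;
    the leftmost mate (TLEN > 0) emits the fragment spanning
    [pos, pos + TLEN) and the rightmost mate returns :data:`DEFER_TO_MATE`.
    Every other kept record is a read unit covering its aligned reference
    span. Properly paired records with TLEN = 0 are demoted to reads.
    """
    tlen = rec.template_length
    pairable = (
        rec.is_paired
        and rec.is_proper_pair
        and rec.reference_id == rec.next_reference_id
    )
    if pairable and 0 < abs(tlen) < max_fragment_size:
        if tlen < 0:
            return DEFER_TO_MATE
        start = rec.reference_start
        return AlignmentUnit(
            contig=rec.reference_name,
            start=start,
            end=start + tlen,
            effective_strand=_effective_strand(rec, "fragment", strandedness),
            kind="fragment",
            f_l=tlen,
            is_multimapped=_nh(rec) > 1,
            template_name=rec.query_name,
        )
    if pairable and tlen == 0:
        log.debug("properly paired record %s has TLEN=0; demoted to read", rec.query_name)
    start, end = rec.reference_start, rec.reference_end
    return AlignmentUnit(
        contig=rec.reference_name,
        start=start,
        end=end,
        effective_strand=_effective_strand(rec, "read", strandedness),
        kind="read",
        f_l=end - start,
        is_multimapped=_nh(rec) > 1,
        template_name=rec.query_name,
    )


def stream_chunks(
    bam_path,
    min_mapq: int = 10,
    max_fragment_size: int = 1000,
    remove_multimapped: bool = False,
    keep_only_proper_pairs: bool = False,
    use_secondary_multimaps: bool = False,
    strandedness: str = "unstranded",
    chunk_size: int = 10_000_000,
    tallies: dict | None = None,
) -> Iterator[list[AlignmentUnit]]:
    """Yield validated, classified units in chunks of at most ``chunk_size``.

    ``tallies`` (if given) is filled in place with record accounting:
    every input record ends up kept-as-fragment, kept-as-read,
    deferred-to-mate, or discarded with a reason. Final counts are
    invariant to ``chunk_size``.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if tallies is None:
        tallies = {}
    tallies.setdefault("records", 0)
    tallies.setdefault("fragments", 0)
    tallies.setdefault("reads", 0)
    tallies.setdefault("deferred_to_mate", 0)
    tallies.setdefault("multimapped_units", 0)
    tallies.setdefault("discarded", {})

    try:
        afile = pysam.AlignmentFile(str(bam_path), require_index=False)
    except (OSError, ValueError) as exc:
        raise AlignmentError(f"cannot read alignment file {bam_path}: {exc}") from exc

    chunk: list[AlignmentUnit] = []
    with afile:
        for rec in afile.fetch(until_eof=True):
            tallies["records"] += 1
            keep, reason = validate_record(
                rec,
                min_mapq=min_mapq,
                remove_multimapped=remove_multimapped,
                use_secondary_multimaps=use_secondary_multimaps,
            )
            if not keep:
                tallies["discarded"][reason] = tallies["discarded"].get(reason, 0) + 1
                continue
            unit = classify_unit(
                rec, max_fragment_size=max_fragment_size, strandedness=strandedness
            )
            if unit is DEFER_TO_MATE:
                tallies["deferred_to_mate"] += 1
                continue
            if unit.kind == "read" and keep_only_proper_pairs:
                tallies["discarded"]["not_proper_pair"] = (
                    tallies["discarded"].get("not_proper_pair", 0) + 1
                )
                continue
            tallies["fragments" if unit.kind == "fragment" else "reads"] += 1
            if unit.is_multimapped:
                tallies["multimapped_units"] += 1
            chunk.append(unit)
            if len(chunk) >= chunk_size:
                yield chunk
                chunk = []
    if chunk:
        yield chunk
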