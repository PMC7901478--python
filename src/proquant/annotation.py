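"""GFF3 feature selection and the unique (non-overlapping) region index.

A genomic position earns counts only if it is covered by exactly one
annotated feature on the relevant strand. This module selects features of
one type from a GFF3 file, converts them to 0-based half-open coordinates,
and sweeps each (contig, strand) lane to find every feature's unique
intervals and unique positional length. Positions covered by two or more
features belong to no feature and never receive counts; TPM is later
normalized on the unique length, not the annotated span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from intervaltree import IntervalTree

from proquant.errors import AnnotationError

log = logging.getLogger(__name__)

# strand key used for all features/units when the library is unstranded
AGNOSTIC = "."


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature, possibly merged from several GFF3 rows.

    ``intervals`` are sorted, disjoint, 0-based half-open pieces; most
    prokaryotic genes have exactly one. ``start``/``end`` give the overall
    span.
    """

    feature_id: str
    contig: str
    strand: str  # '+' or '-'
    intervals: tuple[tuple[int, int], ...]
    feature_type: str

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass
class UniqueRegionIndex:
    """Per-feature unique intervals plus fast interval-tree lookup.

    ``strand_aware`` controls the lane key: when True, '+' and '-'
    features are swept separately; when False all features share one
    strand-agnostic lane.
    """

    strand_aware: bool
    feature_order: list[str] = field(default_factory=list)
    unique_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    unique_length: dict[str, int] = field(default_factory=dict)
    trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)

    def strand_key(self, strand: str) -> str:
        return strand if self.strand_aware else AGNOSTIC

    def contigs(self) -> set[str]:
        return {contig for contig, _ in self.trees}


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return tuple(merged)


def parse_features(
    gff3_path, feature_type: str = "gene", attribute_tag: str = "ID"
) -> list[FeatureRecord]:
    """Read a GFF3 file and return one :class:`FeatureRecord` per feature id.

    Rows whose type column equals ``feature_type`` are selected and keyed by
    the value of ``attribute_tag``. Coordinates are converted from GFF3
    1-based inclusive to 0-based half-open. Rows sharing an id (multi-part
    features) are merged into one record; an id recurring on different
    contigs or strands is ambiguous and raises. Comment lines and any
    ``##FASTA`` trailer are ignored.
    """
    if not feature_type or not attribute_tag:
        raise AnnotationError("feature_type and attribute_tag must be non-empty")

    pieces: dict[str, list[tuple[int, int]]] = {}
    identity: dict[str, tuple[str, str]] = {}
    order: list[str] = []

    try:
        handle = open(gff3_path, "rt", encoding="utf-8")
    except OSError as exc:
        raise AnnotationError(f"cannot read GFF3 file {gff3_path}: {exc}") from exc

    with handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gff3_path}: line {lineno}: expected 9 tab-separated columns, "
                    f"found {len(fields)}"
                )
            if fields[2] != feature_type:
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(
                    f"{gff3_path}: line {lineno}: malformed GFF3 row ({exc})"
                ) from exc
            if feat.start is None or feat.end is None or feat.start > feat.end:
                raise AnnotationError(
                    f"{gff3_path}: line {lineno}: invalid coordinates "
                    f"{fields[3]}..{fields[4]}"
                )
            if feat.strand not in ("+", "-"):
                raise AnnotationError(
                    f"{gff3_path}: line {lineno}: strand must be '+' or '-', "
                    f"got {feat.strand!r}"
                )
            values = feat.attributes.get(attribute_tag, [])
            if not values:
                raise AnnotationError(
                    f"{gff3_path}: line {lineno}: selected {feature_type} row "
                    f"lacks attribute {attribute_tag!r}"
                )
            fid = values[0]
            here = (feat.seqid, feat.strand)
            if fid in identity:
                if identity[fid] != here:
                    raise AnnotationError(
                        f"{gff3_path}: line {lineno}: feature id {fid!r} recurs on a "
                        f"different contig or strand ({identity[fid]} vs {here})"
                    )
            else:
                identity[fid] = here
                order.append(fid)
                pieces[fid] = []
            # GFF3 1-based inclusive -> 0-based half-open
            pieces[fid].append((feat.start - 1, feat.end))

    records = []
    for fid in order:
        contig, strand = identity[fid]
        records.append(
            FeatureRecord(
                feature_id=fid,
                contig=contig,
                strand=strand,
                intervals=_merge_intervals(pieces[fid]),
                feature_type=feature_type,
            )
        )
    return records


def build_unique_index(
    features: list[FeatureRecord], strand_aware: bool
) -> UniqueRegionIndex:
    """Sweep each (contig, strand) lane and keep singly-covered positions.

    For every position covered by >= 2 features on the same lane, the
    position belongs to no feature. A feature entirely shadowed by others
    legitimately ends with unique_length 0.
    """
    index = UniqueRegionIndex(strand_aware=strand_aware)
    lanes: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for feat in features:
        index.feature_order.append(feat.feature_id)
        index.unique_intervals[feat.feature_id] = []
        index.unique_length[feat.feature_id] = 0
        key = (feat.contig, feat.strand if strand_aware else AGNOSTIC)
        lanes.setdefault(key, [])
        for start, end in feat.intervals:
            lanes[key].append((start, end, feat.feature_id))

    for lane_key, ivs in lanes.items():
        # boundary sweep: END events sort before START at equal coordinate
        # because intervals are half-open
        events: list[tuple[int, int, str]] = []
        for start, end, fid in ivs:
            events.append((start, 1, fid))
            events.append((end, 0, fid))
        events.sort()
        active: dict[str, int] = {}
        prev_pos: int | None = None
        for pos, kind, fid in events:
            if prev_pos is not None and pos > prev_pos and len(active) == 1:
                owner = next(iter(active))
                segs = index.unique_intervals[owner]
                if segs and segs[-1][1] == prev_pos:
                    segs[-1] = (segs[-1][0], pos)
                else:
                    segs.append((prev_pos, pos))
            if kind == 0:
                active[fid] -= 1
                if active[fid] == 0:
                    del active[fid]
            else:
                active[fid] = active.get(fid, 0) + 1
            prev_pos = pos
        index.trees[lane_key] = IntervalTree()

    # fill trees and lengths from the computed unique intervals
    feature_lane = {
        f.feature_id: (f.contig, f.strand if strand_aware else AGNOSTIC) for f in features
    }
    for fid, segs in index.unique_intervals.items():
        index.unique_length[fid] = sum(end - start for start, end in segs)
        lane = feature_lane[fid]
        tree = index.trees.setdefault(lane, IntervalTree())
        for start, end in segs:
            tree.addi(start, end, fid)
    return index
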