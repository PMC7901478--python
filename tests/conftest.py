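"""Shared fixtures and helpers for building in-memory alignment records."""

from __future__ import annotations

import pysam
import pytest

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
)


def make_record(
    name="t1",
    flag=0,
    pos=100,
    mapq=30,
    cigar="100M",
    mate_pos=None,
    tlen=0,
    nh=None,
):
    """One pysam record on chr1 with the given SAM fields."""
    rec = pysam.AlignedSegment(HEADER)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = 0 if not flag & 0x4 else -1
    rec.reference_start = pos
    rec.mapping_quality = mapq
    if not flag & 0x4:
        rec.cigarstring = cigar
    rec.next_reference_id = 0 if mate_pos is not None else -1
    rec.next_reference_start = mate_pos if mate_pos is not None else -1
    rec.template_length = tlen
    if nh is not None:
        rec.set_tag("NH", nh)
    return rec


def make_pair(name="p1", pos=100, frag_len=250, read_len=100, nh=None, mapq=30):
    """A proper FR pair; returns (leftmost, rightmost) records."""
    right_pos = pos + frag_len - read_len
    left = make_record(
        name, flag=0x1 | 0x2 | 0x20 | 0x40, pos=pos, mapq=mapq,
        cigar=f"{read_len}M", mate_pos=right_pos, tlen=frag_len, nh=nh,
    )
    right = make_record(
        name, flag=0x1 | 0x2 | 0x10 | 0x80, pos=right_pos, mapq=mapq,
        cigar=f"{read_len}M", mate_pos=pos, tlen=-frag_len, nh=nh,
    )
    return left, right


def write_sam(records, path):
    records = sorted(records, key=lambda r: (r.reference_start, r.query_name, r.flag))
    with pysam.AlignmentFile(str(path), "w", header=HEADER) as out:
        for rec in records:
            out.write(rec)
    return path


def write_gff3(genes, path, contig="chr1", contig_len=100000):
    """genes: iterable of (fid, strand, start0, end0) in half-open coords."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for fid, strand, start, end in genes:
            fh.write(
                f"{contig}\ttest\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={fid}\n"
            )
    return path


@pytest.fixture
def sam_writer(tmp_path):
    def _write(records, name="reads.sam"):
        return write_sam(records, tmp_path / name)

    return _write


@pytest.fixture
def gff3_writer(tmp_path):
    def _write(genes, name="ann.gff3"):
        return write_gff3(genes, tmp_path / name)

    return _write
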