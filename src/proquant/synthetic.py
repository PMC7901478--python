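"""Synthetic GFF3 + SAM fixtures with known ground truth, and a per-base oracle.

The generator writes desk-scale annotation/alignment pairs for the
situations that make prokaryotic counting hard: operons whose fragments
span gene junctions, same-strand overlapping gene pairs, a long gene
whose 3' read-through barely reaches a small downstream neighbor,
duplicated loci producing NH=2 multimappers, singleton/discordant
records, and mirrored stranded layouts. Expected uniquely-mapped counts
are computed analytically from the layout at generation time, never by
the quantifier under test.

``oracle_counts`` is the test suite's independent referee: it re-reads
the GFF3 and SAM as plain text (no pysam, no gffutils, no shared code
with the main path) and recomputes uniquely-mapped counts by explicit
per-position enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

SCENARIOS = (
    "operon",
    "overlap_pair",
    "neighbor_readthrough",
    "multimap",
    "singleton_mix",
    "stranded_mirror",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic data set.

    ``gap`` is the intergenic spacing in bases, except for
    ``overlap_pair`` where it is the length of the shared interval.
    ``depth`` is fragments per gene; ``strandedness`` is the simulated
    library dialect (unstranded, forward, or reverse).
    """

    scenario: str
    n_genes: int = 3
    gene_len: int = 300
    gap: int = 20
    depth: int = 10
    fragment_len: int = 250
    seed: int = 0
    strandedness: str = "unstranded"
    read_len: int = 100


# --- internal layout containers -------------------------------------------

@dataclass(frozen=True)
class _Gene:
    fid: str
    strand: str
    start: int
    end: int


@dataclass
class _Template:
    """One sequencing template: a proper pair, a singleton, or an NH>1 pair."""

    name: str
    contig: str
    start: int  # leftmost fragment coordinate, 0-based
    frag_len: int
    gene_strand: str  # transcript strand the template originates from
    kind: str = "pair"  # 'pair' or 'singleton'
    nh: int = 1
    secondary_starts: tuple[int, ...] = ()  # alternative loci (secondary records)


def _first_strand(gene_strand: str, strandedness: str) -> str:
    """Strand the first-in-pair read must carry for this library dialect."""
    if strandedness == "reverse":
        return "-" if gene_strand == "+" else "+"
    return gene_strand  # forward dialect (and arbitrary for unstranded)


def _pair_segments(header, tpl: _Template, start: int, spec: FixtureSpec, secondary: bool):
    """Two AlignedSegments for one proper pair at one locus."""
    tid = 0
    rlen = min(spec.read_len, tpl.frag_len)
    left, right = start, start + tpl.frag_len - rlen
    first_on_plus = _first_strand(tpl.gene_strand, tpl.strandedness_eff) == "+"
    segs = []
    for is_left in (True, False):
        a = pysam.AlignedSegment(header)
        a.query_name = tpl.name
        a.reference_id = tid
        a.reference_start = left if is_left else right
        a.mapping_quality = 30
        a.cigarstring = f"{rlen}M"
        a.next_reference_id = tid
        a.next_reference_start = right if is_left else left
        a.template_length = tpl.frag_len if is_left else -tpl.frag_len
        flag = 0x1 | 0x2
        # first-in-pair sits leftmost iff it is on '+'
        is_first = is_left == first_on_plus
        flag |= 0x40 if is_first else 0x80
        this_reverse = not is_left
        if this_reverse:
            flag |= 0x10
        if is_left:  # mate is the rightmost, reverse read
            flag |= 0x20
        if secondary:
            flag |= 0x100
        a.flag = flag
        if tpl.nh > 1:
            a.set_tag("NH", tpl.nh)
        segs.append(a)
    return segs


def _singleton_segment(header, tpl: _Template, spec: FixtureSpec):
    a = pysam.AlignedSegment(header)
    a.query_name = tpl.name
    a.reference_id = 0
    a.reference_start = tpl.start
    a.mapping_quality = 30
    rlen = tpl.frag_len
    a.cigarstring = f"{rlen}M"
    flag = 0x1 | 0x8 | 0x40  # paired, mate unmapped, first in pair
    if _first_strand(tpl.gene_strand, tpl.strandedness_eff) == "-":
        flag |= 0x10
    a.flag = flag
    a.next_reference_id = 0
    a.next_reference_start = tpl.start
    a.template_length = 0
    return a


def _build_layout(spec: FixtureSpec) -> tuple[list[_Gene], list[_Template]]:
    rng = np.random.default_rng(spec.seed)
    genes: list[_Gene] = []
    templates: list[_Template] = []
    gl, fl, gap, depth = spec.gene_len, spec.fragment_len, spec.gap, spec.depth
    contig = "chr1"

    def uniform_start(lo: int, hi: int) -> int:
        # inclusive bounds for the leftmost fragment coordinate
        if hi < lo:
            raise ValueError(
                f"impossible geometry in scenario {spec.scenario!r}: "
                f"no room to place a {fl} bp fragment"
            )
        return int(rng.integers(lo, hi + 1))

    if spec.scenario == "operon":
        if gap < 0:
            raise ValueError("operon scenario requires gap >= 0")
        # every third gene is short, mimicking small interior operonic genes;
        # the polycistronic transcript extends past the terminal CDS bounds,
        # so fragment starts tile uniformly beyond both operon ends and
        # per-base coverage is flat across all genes
        cursor = fl + 100
        for i in range(spec.n_genes):
            length = max(gl // 4, 80) if i % 3 == 2 else gl
            genes.append(_Gene(f"g{i + 1:02d}", "+", cursor, cursor + length))
            cursor += length + gap
        lo, hi = genes[0].start - fl + 1, genes[-1].end - 1
        for j in range(spec.n_genes * depth):
            templates.append(_Template(f"frag{j:05d}", contig, uniform_start(lo, hi), fl, "+"))

    elif spec.scenario == "overlap_pair":
        shared = gap
        if not 0 < shared < gl:
            raise ValueError("overlap_pair requires 0 < gap < gene_len (shared interval)")
        ga = _Gene("gA", "+", 100, 100 + gl)
        gb = _Gene("gB", "+", ga.end - shared, ga.end - shared + gl)
        genes = [ga, gb]
        lo, hi = ga.start, gb.end - fl
        for j in range(2 * depth):
            templates.append(_Template(f"frag{j:05d}", contig, uniform_start(lo, hi), fl, "+"))

    elif spec.scenario == "neighbor_readthrough":
        if gap < 1:
            raise ValueError("neighbor_readthrough requires gap >= 1")
        big = _Gene("gBig", "+", 100, 100 + max(gl, 2 * fl))
        small_len = max(gl // 5, 100)
        small = _Gene("gSmall", "+", big.end + gap, big.end + gap + small_len)
        genes = [big, small]
        for j in range(depth):  # body fragments, wholly inside the big gene
            templates.append(
                _Template(f"body{j:05d}", contig, uniform_start(big.start, big.end - fl), fl, "+")
            )
        # read-through: 3' fragments barely reaching the small gene
        reach = max(3, fl // 20)
        lo = small.start - fl + 1
        for j in range(depth):
            templates.append(
                _Template(f"rt{j:05d}", contig, uniform_start(lo, lo + reach - 1), fl, "+")
            )

    elif spec.scenario == "multimap":
        anchor = _Gene("gUniq", "+", 100, 100 + gl)
        da_start = anchor.end + max(gap, 1) + 400
        dup_a = _Gene("gDupA", "+", da_start, da_start + gl)
        dup_b = _Gene("gDupB", "+", dup_a.end + 1000, dup_a.end + 1000 + gl)
        genes = [anchor, dup_a, dup_b]
        for j in range(depth):
            templates.append(
                _Template(f"anc{j:05d}", contig, uniform_start(anchor.start, anchor.end - fl), fl, "+")
            )
        for j in range(depth):  # unique support biased toward copy A
            templates.append(
                _Template(f"ua{j:05d}", contig, uniform_start(dup_a.start, dup_a.end - fl), fl, "+")
            )
        for j in range(max(depth // 5, 1)):
            templates.append(
                _Template(f"ub{j:05d}", contig, uniform_start(dup_b.start, dup_b.end - fl), fl, "+")
            )
        for j in range(depth):  # NH=2 templates: primary at copy A, secondary at copy B
            off = int(rng.integers(0, gl - fl + 1))
            templates.append(
                _Template(
                    f"mm{j:05d}", contig, dup_a.start + off, fl, "+",
                    nh=2, secondary_starts=(dup_b.start + off,),
                )
            )

    elif spec.scenario == "singleton_mix":
        g = _Gene("gA", "+", 100, 100 + max(gl, fl + 10))
        genes = [g]
        for j in range(depth):
            templates.append(
                _Template(f"pair{j:05d}", contig, uniform_start(g.start, g.end - fl), fl, "+")
            )
        rlen = min(spec.read_len, g.end - g.start)
        for j in range(depth):
            templates.append(
                _Template(
                    f"sing{j:05d}", contig, uniform_start(g.start, g.end - rlen), rlen, "+",
                    kind="singleton",
                )
            )

    elif spec.scenario == "stranded_mirror":
        if gap < 0:
            raise ValueError("stranded_mirror requires gap >= 0")
        gp = _Gene("gPlus", "+", 100, 100 + gl)
        gm = _Gene("gMinus", "-", gp.end + gap, gp.end + gap + gl)
        genes = [gp, gm]
        for g in genes:
            for j in range(depth):
                templates.append(
                    _Template(
                        f"{g.fid}_f{j:05d}", contig,
                        uniform_start(g.start, g.end - fl), fl, g.strand,
                    )
                )
        templates.sort(key=lambda t: (t.start, t.name))

    else:
        raise ValueError(f"unknown scenario {spec.scenario!r}; choose one of {SCENARIOS}")

    return genes, templates


# --- analytic expected counts (generation-side, not the tool under test) --

AMBIG = object()


def _ownership(genes: list[_Gene], strand_aware: bool) -> dict[str, dict[int, object]]:
    owner: dict[str, dict[int, object]] = {}
    for g in genes:
        lane = g.strand if strand_aware else "."
        lane_map = owner.setdefault(lane, {})
        for pos in range(g.start, g.end):
            lane_map[pos] = AMBIG if pos in lane_map else g.fid
    return owner


def _expected_counts(
    genes: list[_Gene], templates: list[_Template], strand_aware: bool
) -> dict[str, float]:
    """Analytic N_f0: per-base assignment of every uniquely mapped template."""
    owner = _ownership(genes, strand_aware)
    counts = {g.fid: 0.0 for g in genes}
    for tpl in templates:
        if tpl.nh > 1:
            continue  # multimapped: no contribution to uniquely-mapped counts
        weight = 1.0 / tpl.frag_len
        if tpl.kind == "singleton":
            weight /= 2.0
        lane = tpl.gene_strand if strand_aware else "."
        lane_map = owner.get(lane, {})
        for pos in range(tpl.start, tpl.start + tpl.frag_len):
            fid = lane_map.get(pos)
            if fid is not None and fid is not AMBIG:
                counts[fid] += weight
    return counts


# --- file emission ---------------------------------------------------------

def _write_gff3(genes: list[_Gene], contig: str, contig_len: int, path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {contig_len}\n")
        for g in genes:
            fh.write(
                f"{contig}\tproquant\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.fid};Name={g.fid}\n"
            )


def _write_sam(genes, templates, spec: FixtureSpec, contig: str, contig_len: int, path: Path):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": contig_len}]}
    )
    segments = []
    for tpl in templates:
        tpl.strandedness_eff = spec.strandedness  # dialect used when laying flags
        if tpl.kind == "singleton":
            segments.append(_singleton_segment(header, tpl, spec))
        else:
            segments.extend(_pair_segments(header, tpl, tpl.start, spec, secondary=False))
            for alt in tpl.secondary_starts:
                segments.extend(_pair_segments(header, tpl, alt, spec, secondary=True))
    segments.sort(key=lambda a: (a.reference_start, a.query_name, a.flag))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            out.write(seg)


def make_fixture(spec: FixtureSpec, out_dir) -> tuple[Path, Path, Path]:
    """Write fixture.gff3, fixture.sam and truth.tsv; returns their paths.

    truth.tsv holds the analytically expected uniquely-mapped count per
    feature (for quantification settings matching the spec's library
    dialect). Identical (spec, seed) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes, templates = _build_layout(spec)
    contig = "chr1"
    contig_len = max(g.end for g in genes)
    for t in templates:
        contig_len = max(contig_len, t.start + t.frag_len)
        for alt in t.secondary_starts:
            contig_len = max(contig_len, alt + t.frag_len)
    contig_len += 1000

    gff3 = out_dir / "fixture.gff3"
    sam = out_dir / "fixture.sam"
    truth = out_dir / "truth.tsv"
    _write_gff3(genes, contig, contig_len, gff3)
    _write_sam(genes, templates, spec, contig, contig_len, sam)
    expected = _expected_counts(genes, templates, strand_aware=spec.strandedness != "unstranded")
    with open(truth, "wt", encoding="utf-8") as fh:
        fh.write("featureID\texpected_unique_count\n")
        for g in genes:
            fh.write(f"{g.fid}\t{expected[g.fid]:.9f}\n")
    return gff3, sam, truth


def random_fixture(seed: int, out_dir) -> tuple[Path, Path, dict]:
    """A randomized desk-scale fixture for property tests.

    Random gene layouts (possibly overlapping, mixed strands) with a mix
    of proper pairs, singletons, oversized pairs (demoted to reads) and
    NH=2 multimappers. Returns (gff3, sam, options) where options carry
    the strandedness the fixture was generated for.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contig = "chr1"
    strandedness = ["unstranded", "forward", "reverse"][int(rng.integers(0, 3))]

    n_genes = int(rng.integers(2, 13))
    genes = []
    cursor = 100
    for i in range(n_genes):
        length = int(rng.integers(120, 600))
        # sometimes overlap the previous gene, sometimes leave a gap
        shift = int(rng.integers(-length // 2, 250))
        start = max(0, cursor + shift)
        strand = "+" if rng.random() < 0.7 else "-"
        genes.append(_Gene(f"g{i + 1:02d}", strand, start, start + length))
        cursor = start + length
    span_lo = min(g.start for g in genes)
    span_hi = max(g.end for g in genes)

    templates: list[_Template] = []
    n_units = int(rng.integers(20, 121))
    for j in range(n_units):
        src = genes[int(rng.integers(0, n_genes))]
        kind_draw = rng.random()
        frag_len = int(rng.integers(80, 400))
        lo = max(0, src.start - frag_len + 1)
        hi = max(lo, src.end - 1)
        start = int(rng.integers(lo, hi + 1))
        if kind_draw < 0.10:
            rlen = int(rng.integers(40, 150))
            templates.append(
                _Template(f"s{j:05d}", contig, start, rlen, src.strand, kind="singleton")
            )
        elif kind_draw < 0.15:
            # oversized template length: both mates demoted to lone reads
            templates.append(
                _Template(f"o{j:05d}", contig, start, int(rng.integers(1100, 1500)),
                          src.strand)
            )
        elif kind_draw < 0.25:
            other = genes[int(rng.integers(0, n_genes))]
            alt = max(0, min(other.start + 5, span_hi))
            templates.append(
                _Template(f"m{j:05d}", contig, start, frag_len, src.strand,
                          nh=2, secondary_starts=(alt,))
            )
        else:
            templates.append(_Template(f"p{j:05d}", contig, start, frag_len, src.strand))
    templates.sort(key=lambda t: (t.start, t.name))

    contig_len = span_hi + 2000
    for t in templates:
        contig_len = max(contig_len, t.start + t.frag_len + 100)
        for alt in t.secondary_starts:
            contig_len = max(contig_len, alt + t.frag_len + 100)

    spec = FixtureSpec(scenario="random", seed=seed, strandedness=strandedness)
    gff3 = out_dir / "fixture.gff3"
    sam = out_dir / "fixture.sam"
    _write_gff3(genes, contig, contig_len, gff3)
    _write_sam(genes, templates, spec, contig, contig_len, sam)
    options = {"strandedness": strandedness}
    return gff3, sam, options


# --- independent per-base oracle ------------------------------------------

def _oracle_parse_gff3(path, feature_type: str, attribute_tag: str):
    genes = {}
    order = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[2] != feature_type:
                continue
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    key, val = item.split("=", 1)
                    attrs[key.strip()] = val
            fid = attrs[attribute_tag]
            iv = (int(cols[3]) - 1, int(cols[4]))  # to 0-based half-open
            if fid in genes:
                genes[fid]["intervals"].append(iv)
            else:
                genes[fid] = {"contig": cols[0], "strand": cols[6], "intervals": [iv]}
                order.append(fid)
    return genes, order


def _cigar_ref_len(cigar: str) -> int:
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                total += int(num)
            num = ""
    return total


def oracle_counts(
    gff3_path,
    sam_path,
    feature_type: str = "gene",
    attribute_tag: str = "ID",
    strandedness: str = "unstranded",
    min_mapq: int = 10,
    max_fragment_size: int = 1000,
    keep_only_proper_pairs: bool = False,
) -> dict[str, float]:
    """Uniquely-mapped counts by brute-force per-position enumeration.

    Builds per-position unique ownership by counting covering features at
    every base, then walks every kept uniquely mapped unit base by base,
    adding 1/F_L (halved for lone reads) to the owner of each position.
    Text-parsing only; shares no code with the quantification path.
    """
    genes, order = _oracle_parse_gff3(gff3_path, feature_type, attribute_tag)
    strand_aware = strandedness != "unstranded"

    owner: dict[tuple[str, str], dict[int, object]] = {}
    for fid in order:
        g = genes[fid]
        lane = (g["contig"], g["strand"] if strand_aware else ".")
        lane_map = owner.setdefault(lane, {})
        covered = set()
        for s, e in g["intervals"]:
            covered.update(range(s, e))
        for pos in covered:
            lane_map[pos] = AMBIG if pos in lane_map else fid

    counts = {fid: 0.0 for fid in order}
    with open(sam_path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            cols = line.rstrip("\n").split("\t")
            flag = int(cols[1])
            if flag & 0x4 or flag & 0x100 or flag & 0x800:
                continue
            if int(cols[4]) < min_mapq:
                continue
            nh = 1
            for opt in cols[11:]:
                if opt.startswith("NH:i:"):
                    nh = int(opt[5:])
            if nh > 1:
                continue  # multimapped units never enter N_f0
            rname, pos0, cigar, rnext, tlen = cols[2], int(cols[3]) - 1, cols[5], cols[6], int(cols[8])
            proper = bool(flag & 0x1) and bool(flag & 0x2) and rnext in ("=", rname)
            if proper and 0 < abs(tlen) < max_fragment_size:
                if tlen < 0:
                    continue  # counted from the leftmost mate
                span, f_l, kind = (pos0, pos0 + tlen), tlen, "fragment"
            else:
                ref_len = _cigar_ref_len(cigar)
                span, f_l, kind = (pos0, pos0 + ref_len), ref_len, "read"
            if kind == "read" and keep_only_proper_pairs:
                continue
            if f_l <= 0:
                continue
            if strand_aware:
                if flag & 0x1 and kind == "fragment":
                    if flag & 0x40:
                        base = "-" if flag & 0x10 else "+"
                    else:
                        base = "-" if flag & 0x20 else "+"
                else:
                    base = "-" if flag & 0x10 else "+"
                if strandedness == "reverse":
                    base = "-" if base == "+" else "+"
                lane = (rname, base)
            else:
                lane = (rname, ".")
            lane_map = owner.get(lane, {})
            weight = 1.0 / f_l
            if kind == "read":
                weight /= 2.0
            for p in range(span[0], span[1]):
                fid = lane_map.get(p)
                if fid is not None and fid is not AMBIG:
                    counts[fid] += weight
    return counts
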