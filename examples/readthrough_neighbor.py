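"""Proportional counting suppresses spurious neighbor-gene counts.

A long gene's unannotated 3' UTR reads through toward a small gene 20 bp
downstream. Whole-count assignment gives the small gene one full count
per read-through fragment; proportional assignment gives it only the
sliver of each fragment that actually overlaps it.
"""

import tempfile

import pysam

from proquant import FixtureSpec, RunConfig, make_fixture, quantify

workdir = tempfile.mkdtemp()
spec = FixtureSpec(scenario="neighbor_readthrough", depth=30, seed=8)
gff3, sam, _ = make_fixture(spec, workdir)
result = quantify(RunConfig(gff3=gff3, bam=sam))
counts = {r.feature_id: r.counts for r in result.rows}

# whole-count comparison: every overlapped gene gets a full count
spans = {}
for line in open(gff3):
    if not line.startswith("#"):
        cols = line.split("\t")
        spans[cols[8].split("ID=")[1].split(";")[0]] = (int(cols[3]) - 1, int(cols[4]))
whole = {fid: 0 for fid in spans}
with pysam.AlignmentFile(str(sam)) as afile:
    for rec in afile.fetch(until_eof=True):
        if rec.template_length > 0:
            s, e = rec.reference_start, rec.reference_start + rec.template_length
            for fid, (gs, ge) in spans.items():
                whole[fid] += s < ge and gs < e

print(f"{'gene':8s} {'proportional':>12s} {'whole-count':>12s}")
for fid in spans:
    print(f"{fid:8s} {counts[fid]:12.2f} {whole[fid]:12d}")
print(
    "\nEvery one of the 30 read-through fragments overlaps gSmall, so"
    " whole-count assignment hands it 30 counts; proportionally it earns"
    f" only {counts['gSmall']:.2f} — the few bases per fragment that truly"
    " lie on it."
)
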