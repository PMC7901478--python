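"""Rescue multimapped records at a duplicated locus with EM.

The fixture has an anchor gene, two duplicated gene copies with uneven
unique-read support (10 vs 2 fragments), and 10 NH=2 templates mapping
to both copies. With secondary alignments admitted, EM splits each
multimapped template across the copies in proportion to their
uniquely-mapped abundance instead of discarding it.
"""

import tempfile

from proquant import FixtureSpec, RunConfig, make_fixture, quantify

workdir = tempfile.mkdtemp()
gff3, sam, _ = make_fixture(FixtureSpec(scenario="multimap", seed=3), workdir)

for label, options in [
    ("discard multimappers  ", dict(remove_multimapped=True)),
    ("EM, primary locus only", dict(em_iterations=10)),
    ("EM over both loci     ", dict(em_iterations=10, use_secondary_multimaps=True)),
]:
    result = quantify(RunConfig(gff3=gff3, bam=sam, **options))
    counts = {r.feature_id: round(r.counts, 2) for r in result.rows}
    print(f"{label}: {counts}")

print(
    "\nDiscarding loses the 10 ambiguous templates entirely. Primary-only EM"
    " returns them all to the primary copy. Admitting secondary records lets"
    " EM split each template 10:2 between the copies (≈0.83 vs ≈0.17 each),"
    " matching their unique-read support."
)
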