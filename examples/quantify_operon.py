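"""Quantify a synthetic 11-gene operon and show per-gene uniformity.

Genes transcribed together on one polycistronic mRNA should have the
same depth-normalized expression. Fragments spanning gene junctions are
split proportionally over each gene's unique positions, so even the
short interior genes stay near the operon median.
"""

import math
import tempfile

import numpy as np

from proquant import FixtureSpec, RunConfig, make_fixture, quantify

workdir = tempfile.mkdtemp()
gff3, sam, truth = make_fixture(
    FixtureSpec(scenario="operon", n_genes=11, depth=50, seed=42), workdir
)
result = quantify(RunConfig(gff3=gff3, bam=sam))

print(result.table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

per_bp = {r.feature_id: r.counts / r.uniq_len for r in result.rows}
median = float(np.median(list(per_bp.values())))
print("\nlog2(count per unique bp / operon median):")
for fid, value in per_bp.items():
    print(f"  {fid}: {math.log2(value / median):+.3f}")
print(
    "\nValues near 0 mean each gene — including the short ones (g03, g06,"
    " g09) — is counted in proportion to its length, as expected for genes"
    " transcribed together."
)
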