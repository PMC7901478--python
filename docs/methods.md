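# Methods

## The quantification model

proquant estimates gene-level expression for prokaryotic RNA-seq from a
genome alignment (SAM/BAM) and a GFF3 annotation. Prokaryotic genomes are
gene-dense and heavily operonic: a single polycistronic mRNA covers several
CDSs, so a large share of read pairs are *multigene fragments* — uniquely
mapped, but overlapping two or more annotated features. Whole-count
strategies either discard these (undercounting small interior operonic
genes) or assign a full count to every overlapped feature (inflating
close-proximity monocistronic neighbors). proquant instead assigns each
fragment a proportional count per feature:

    F_c = F_O / F_L

where `F_L` is the total fragment length (|TLEN| for a reconstructed pair,
the aligned reference span for a lone read) and `F_O` is the number of
bases of the fragment lying in the feature's **unique positions** —
genomic positions covered by exactly one annotated feature on the relevant
strand. Positions covered by two or more features are ambiguous and earn
counts for no one. Units that cannot be reconstructed as proper pairs
(singletons, discordant or oversized pairs) contribute `F_c / 2`, since
such mappings are more likely to be erroneous.

Feature counts are sums of these contributions, `N_f = Σ F_c`. TPM is
computed on each feature's unique positional length:
`rate_f = N_f / uniq_len_f`, `TPM_f = rate_f / Σ_g rate_g × 10⁶`.

## Multimapper rescue by EM

Records whose `NH` tag exceeds 1 are parked rather than counted. After all
uniquely mapped records are accumulated (`N_{f,0}`), each multimapped
record `r` with contributions `N_{r,f}` is redistributed over its features
in proportion to current abundance:

    a_{r,f} = N_f / N_{r,F},   N_{r,F} = Σ_{f∈rF} N_f
    N̄_{Rmm,f} = Σ_{r∈Rmm} a_{r,f} · N_{r,f}
    N_{f,k} = N_{f,0} + N̄_{Rmm,f,k},   k = 1 … K

The first cycle is anchored on uniquely-mapped counts only; later cycles
recompute the weights from the previous cycle's totals. Weights over a
record always sum to 1. If every feature a record overlaps currently has
zero counts, the record is split equally among them (maximum-entropy
fallback, logged) rather than dropped, which keeps mass accounting
testable. There is no early stopping: a fixed `K` keeps runs
deterministic; the per-iteration delta `Σ_f |N_{f,k} − N_{f,k−1}|` is
exposed for diagnostics and typically falls below 1e−3 within about ten
iterations on the synthetic data sets used in the tests.

By default only primary records are read, so a multimapper is represented
by its primary locus and EM redistributes among the features overlapping
that locus. The opt-in `--use_secondary_multimaps` flag also admits
secondary (0x100) records of `NH>1` templates, letting EM weigh the
alternative loci against each other. The default stays primary-only
because secondary alignments frequently carry degraded MAPQ and their
availability depends on aligner settings.

## Record handling

- Records are discarded if unmapped (0x4), secondary (0x100, unless opted
  in as above), supplementary (0x800), or `MAPQ < min_mapq`
  (default 10, inclusive threshold). `--remove_multimapped` additionally
  discards `NH>1` records, which is equivalent to running zero EM
  iterations except for the per-feature alignment tally. A missing `NH`
  tag means uniquely mapped.
- A record is reconstructed as a **fragment** iff it is properly paired
  (0x2), its mate maps to the same contig, and `0 < |TLEN| <
  max_fragment_size` (default 1000, exclusive). Only the leftmost mate
  (TLEN > 0) emits the fragment, spanning `[pos, pos+TLEN)`; the mate's
  information is implied and the mate record is skipped. The span is
  leftmost-to-rightmost: the unsequenced inner gap of a pair counts as
  overlap, and no CIGAR-level gap handling is done (the method is not
  splice aware; N operations are treated as aligned span).
- Everything else kept is a **read** covering its aligned reference span
  (soft-clipped bases excluded). A properly paired record with TLEN = 0
  is demoted to a read. `--keep_only_proper_pairs` drops read units
  entirely.
- Strandedness: `no` ignores strand (one strand-agnostic lane per
  contig); `yes` (forward dialect) takes the strand of the first-in-pair
  read for fragments and of the read itself for lone reads; `reverse`
  takes the opposite. The unique-region index is built per strand only
  when the run is stranded.
- Coordinates are 0-based half-open everywhere internally; GFF3 (1-based
  inclusive) is converted at parse time and SAM positions at intake.

## Parameters

| option | default | meaning |
| --- | --- | --- |
| `--feature_type` | `gene` | GFF3 type column selected for counting |
| `--attribute_type` | `ID` | attribute naming each feature |
| `--min_mapq` | 10 | minimum mapping quality, inclusive |
| `--max_fragment_size` | 1000 | exclusive bound on \|TLEN\| (bases) for pairing |
| `--stranded` | `no` | `no`/`yes`/`reverse` library dialect |
| `--em_iterations` | 1 | EM cycles for multimapper rescue |
| `--remove_multimapped` | off | drop NH>1 records instead of rescuing |
| `--keep_only_proper_pairs` | off | drop all lone-read units |
| `--chunk_size` | 10,000,000 | units held in memory per chunk |

Rows sharing one attribute value (multi-part features) merge into a
single feature whose unique set is computed from the union of its
intervals. Features on contigs absent from the alignment header are kept
and reported with zero counts; features fully shadowed by others get
unique length 0 and, necessarily, zero counts (reported, not omitted, so
the output schema is stable across runs). Output counts and TPM are
printed at 2 decimal places; the table lists features in annotation
order, making repeated runs byte-identical.

## Synthetic data generator

`proquant.synthetic` writes desk-scale GFF3+SAM fixtures for the
situations that motivate proportional counting: `operon` (genes
transcribed together, fragments tiling the whole locus including
junction-spanning multigene fragments; every third gene is short to
represent small interior operonic genes, and fragment starts tile past
the operon ends the way polycistronic transcript ends extend beyond the
terminal CDS bounds, so per-base coverage is flat across the operon),
`overlap_pair` (two same-strand genes sharing an interior interval),
`neighbor_readthrough` (3′ read-through fragments of a long gene barely
reaching — by at most fragment_len/20 bases — a small downstream
neighbor), `multimap` (a duplicated locus with NH=2 records at both
copies and asymmetric unique support), `singleton_mix` (pairs plus
mate-unmapped singletons), and `stranded_mirror` (the same layout emitted
in forward and reverse library dialects). Defaults are 3 genes of 300 bp,
20 bp gaps, 250 bp fragments at depth 10 per gene — typical prokaryotic
gene and insert sizes at a depth small enough to hand-check.

The generator records an analytic truth table (per-base arithmetic on the
known layout, never the quantifier under test). A separate brute-force
oracle re-reads the emitted files as plain text and recomputes
uniquely-mapped counts by per-position enumeration; it shares no code
with the quantification path and is the referee for the test suite.

What the fixtures deliberately do not model: sequencing errors and
quality scores, alignment ambiguity beyond explicit NH tags, fragment
length variability within a library, GC or positional bias, and real
operon structure inferred from data. Tests passing on these fixtures
establish that the counting and EM arithmetic is correct and invariant
to chunking, record order and strand dialect — not that the method's
biological assumptions hold on any particular real library.

## Numerical notes and edge cases

- Accumulation is pure summation, so results are independent of chunk
  size and of record order within coordinates; no tolerance is needed
  beyond float addition order (tests allow 1e−9 against per-base
  oracles, observed agreement ~1e−12).
- A fragment whose mates overlap each other uses the span-based
  `F_L = |TLEN|`, smaller than the summed read lengths; double-covered
  bases are not double-counted.
- Features spanning a circular-contig origin are treated as ordinary
  linear intervals.
- TPM of an all-zero run is all zeros (no 0/0); features with zero
  unique length have rate 0 by definition.

## Known limitations

Not splice aware, so unsuited to eukaryotic genomes with spliced genes.
No transcript-level abundance model, fragment-length bias model, or
positional bias correction. One sample per run; no matrix merging or
differential expression. The alignment tally column counts every
retained unit overlapping the feature, including multimapped units
regardless of their EM weight.
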