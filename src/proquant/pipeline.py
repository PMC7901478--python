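"""End-to-end quantification: parse, index, stream, count, EM, TPM, write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from proquant.annotation import build_unique_index, parse_features
from proquant.counting import CountState, accumulate
from proquant.em import em_iterate
from proquant.errors import AlignmentError
from proquant.intake import stream_chunks
from proquant.report import QuantRow, build_table, compute_tpm, write_table

log = logging.getLogger(__name__)

STRANDEDNESS_ALIASES = {"no": "unstranded", "yes": "forward", "reverse": "reverse"}


@dataclass
class RunConfig:
    """All quantification options with their documented defaults."""

    gff3: Path
    bam: Path
    output_dir: Path | None = None
    feature_type: str = "gene"
    attribute_type: str = "ID"
    strandedness: str = "unstranded"  # unstranded | forward | reverse
    min_mapq: int = 10
    max_fragment_size: int = 1000
    remove_multimapped: bool = False
    em_iterations: int = 1
    keep_only_proper_pairs: bool = False
    use_secondary_multimaps: bool = False
    chunk_size: int = 10_000_000

    def __post_init__(self):
        self.strandedness = STRANDEDNESS_ALIASES.get(self.strandedness, self.strandedness)
        if self.strandedness not in ("unstranded", "forward", "reverse"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")
        if self.min_mapq < 0 or self.max_fragment_size < 1 or self.chunk_size < 1:
            raise ValueError("numeric options out of range")
        if self.em_iterations < 0:
            raise ValueError("em_iterations must be >= 0")
        if self.remove_multimapped and self.em_iterations:
            log.warning("--remove_multimapped set; em_iterations is ignored")


@dataclass
class QuantResult:
    """Quantification output plus run diagnostics."""

    table: pd.DataFrame
    rows: list[QuantRow]
    tallies: dict
    em_deltas: list[float] = field(default_factory=list)


def _warn_contig_mismatch(bam_path, index) -> None:
    try:
        with pysam.AlignmentFile(str(bam_path), require_index=False) as afile:
            bam_contigs = set(afile.references or [])
    except (OSError, ValueError) as exc:
        raise AlignmentError(f"cannot read alignment file {bam_path}: {exc}") from exc
    ann_contigs = index.contigs()
    only_bam = bam_contigs - ann_contigs
    if only_bam:
        log.warning(
            "contigs present in alignment but absent from annotation "
            "(their units count against no feature): %s", sorted(only_bam)
        )


def quantify(config: RunConfig) -> QuantResult:
    """Run the full pipeline and return the per-feature table.

    Deterministic: identical config and inputs give identical results,
    independent of chunk size and of record order within coordinates.
    """
    features = parse_features(config.gff3, config.feature_type, config.attribute_type)
    index = build_unique_index(features, strand_aware=config.strandedness != "unstranded")
    _warn_contig_mismatch(config.bam, index)

    state = CountState()
    tallies: dict = {}
    for chunk in stream_chunks(
        config.bam,
        min_mapq=config.min_mapq,
        max_fragment_size=config.max_fragment_size,
        remove_multimapped=config.remove_multimapped,
        keep_only_proper_pairs=config.keep_only_proper_pairs,
        use_secondary_multimaps=config.use_secondary_multimaps,
        strandedness=config.strandedness,
        chunk_size=config.chunk_size,
        tallies=tallies,
    ):
        accumulate(chunk, index, state)

    iterations = 0 if config.remove_multimapped else config.em_iterations
    state, deltas = em_iterate(state, iterations)

    tpm = compute_tpm(state.n_fk, index.unique_length)
    rows = [
        QuantRow(
            feature_id=fid,
            uniq_len=index.unique_length[fid],
            num_alignments=state.n_align.get(fid, 0),
            counts=state.n_fk.get(fid, 0.0),
            tpm=tpm[fid],
        )
        for fid in index.feature_order
    ]
    log.info(
        "processed %d records: %d fragments, %d reads, %d multimapped units, "
        "%d deferred mates, discarded %s",
        tallies.get("records", 0), tallies.get("fragments", 0), tallies.get("reads", 0),
        tallies.get("multimapped_units", 0), tallies.get("deferred_to_mate", 0),
        tallies.get("discarded", {}),
    )
    return QuantResult(table=build_table(rows), rows=rows, tallies=tallies, em_deltas=deltas)


def run(config: RunConfig) -> Path:
    """Quantify and write ``<bam_basename>.counts.txt`` into output_dir."""
    result = quantify(config)
    out_dir = Path(config.output_dir) if config.output_dir else Path(".")
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(config.bam).name
    for suffix in (".bam", ".sam"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    out_path = out_dir / f"{stem}.counts.txt"
    write_table(result.rows, out_path)
    return out_path
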