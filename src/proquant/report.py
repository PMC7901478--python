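"""TPM normalization and the five-column output table.

TPM uses each feature's *unique* positional length as the effective
length: rate_f = N_f / uniq_len_f, tpm_f = rate_f / sum(rates) * 1e6.
The table has one row per annotated feature in annotation order —
feature id, unique length, number of overlapping alignments, fractional
count, TPM — and is byte-deterministic for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from proquant.errors import OutputError

HEADER = ["featureID", "uniq_len", "num_alignments", "counts", "tpm"]


@dataclass(frozen=True)
class QuantRow:
    feature_id: str
    uniq_len: int
    num_alignments: int
    counts: float
    tpm: float


def compute_tpm(
    counts: dict[str, float], uniq_len: dict[str, int]
) -> dict[str, float]:
    """Length-normalized relative abundance summing to 1e6.

    Features with zero unique length get rate 0 (they can hold no
    counts); if every count is zero, all TPM values are zero.
    """
    rates = {
        fid: (counts.get(fid, 0.0) / uniq_len[fid] if uniq_len[fid] > 0 else 0.0)
        for fid in uniq_len
    }
    total = sum(rates.values())
    if total <= 0.0:
        return {fid: 0.0 for fid in uniq_len}
    return {fid: rates[fid] / total * 1e6 for fid in uniq_len}


def build_table(rows: list[QuantRow]) -> pd.DataFrame:
    """Rows as a DataFrame with the output schema (annotation order)."""
    return pd.DataFrame(
        [(r.feature_id, r.uniq_len, r.num_alignments, r.counts, r.tpm) for r in rows],
        columns=HEADER,
    )


def write_table(rows: list[QuantRow], out_path) -> None:
    """Write the tab-delimited table; counts and TPM at 2 decimal places."""
    try:
        with open(out_path, "wt", encoding="utf-8") as handle:
            handle.write("\t".join(HEADER) + "\n")
            for r in rows:
                handle.write(
                    f"{r.feature_id}\t{r.uniq_len}\t{r.num_alignments}\t"
                    f"{r.counts:.2f}\t{r.tpm:.2f}\n"
                )
    except OSError as exc:
        raise OutputError(f"cannot write output table {out_path}: {exc}") from exc
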