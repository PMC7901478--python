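"""Expectation-maximization rescue of multimapped record contributions.

A multimapped record r carries proportional contributions N_{r,f} to the
features f it overlaps (at its reported loci). Rather than discarding
them, each iteration splits every record over its features in proportion
to current feature abundance:

    a_{r,f} = N_f / N_{r,F},   N_{r,F} = sum over f in rF of N_f,
    Nbar_{Rmm,f} = sum over r of a_{r,f} * N_{r,f},
    N_{f,k} = N_{f,0} + Nbar_{Rmm,f,k}        for k = 1 .. K,

anchored at k=1 on the uniquely-mapped-only counts N_{f,0}; each later
cycle recomputes the weights from the previous cycle's N_{f,k}. The
weights over a record always sum to 1. With no multimapped records (or
K = 0) the adjustment is the identity.
"""

from __future__ import annotations

import logging

from proquant.counting import CountState

log = logging.getLogger(__name__)


def em_record_weights(
    contribs: dict[str, float], counts: dict[str, float]
) -> dict[str, float]:
    """Relative abundance weights a_{r,f} for one record's features.

    ``contribs`` maps the record's features to their N_{r,f}; ``counts``
    supplies the current per-feature totals. If every overlapped feature
    currently has zero counts the record is split equally (maximum-entropy
    fallback; logged).
    """
    n_rf_total = sum(counts.get(fid, 0.0) for fid in contribs)
    if n_rf_total <= 0.0:
        log.debug("record over %s has no abundance anchor; splitting equally", list(contribs))
        w = 1.0 / len(contribs)
        return {fid: w for fid in contribs}
    return {fid: counts.get(fid, 0.0) / n_rf_total for fid in contribs}


def group_by_template(
    mm_contribs: list[tuple[str, str, float]]
) -> dict[str, dict[str, float]]:
    """Pool (template, feature, N_rf) triples into one record per template."""
    records: dict[str, dict[str, float]] = {}
    for template, fid, n_rf in mm_contribs:
        rec = records.setdefault(template, {})
        rec[fid] = rec.get(fid, 0.0) + n_rf
    return records


def em_iterate(state: CountState, iterations: int = 1) -> tuple[CountState, list[float]]:
    """Run K EM cycles over the parked multimapped contributions.

    Finalizes ``state.n_fk`` and returns the per-iteration convergence
    deltas (sum over features of |N_{f,k} - N_{f,k-1}|, with N_{f,0} as
    the baseline for the first delta). K = 0 leaves N_{f,k} = N_{f,0}.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    state.n_fk = dict(state.n_f0)
    if iterations == 0 or not state.mm_contribs:
        return state, []
    records = group_by_template(state.mm_contribs)
    history = [dict(state.n_f0)]
    current = dict(state.n_f0)
    for _ in range(iterations):
        adjustment: dict[str, float] = {}
        for contribs in records.values():
            weights = em_record_weights(contribs, current)
            for fid, n_rf in contribs.items():
                adjustment[fid] = adjustment.get(fid, 0.0) + weights[fid] * n_rf
        current = dict(state.n_f0)
        for fid, extra in adjustment.items():
            current[fid] = current.get(fid, 0.0) + extra
        history.append(dict(current))
    state.n_fk = current
    return state, convergence_series(history)


def convergence_series(history: list[dict[str, float]]) -> list[float]:
    """Per-iteration delta_k = sum over features of |N_{f,k} - N_{f,k-1}|."""
    deltas = []
    for prev, curr in zip(history, history[1:]):
        fids = set(prev) | set(curr)
        deltas.append(sum(abs(curr.get(f, 0.0) - prev.get(f, 0.0)) for f in fids))
    return deltas
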