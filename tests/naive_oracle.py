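"""Independent brute-force reference for run detection.

Deliberately naive and self-contained: its own dinucleotide table and
a character-by-character walk, with no code shared with the package's
vectorized scanner.  Used to cross-check every scan result.
"""

from __future__ import annotations

PAIR_CLASS = {}
for _d in ("GC", "CG"):
    PAIR_CLASS[_d] = "gc"
for _d in ("GT", "TG", "CA", "AC"):
    PAIR_CLASS[_d] = "gt"
for _d in ("AT", "TA"):
    PAIR_CLASS[_d] = "at"


def oracle_scan(seq: str, model, params, sequence_id: str = "seq1"):
    """Enumerate every maximal break-free run by direct inspection and
    filter by length and score percent.  Returns plain dicts."""
    seq_u = seq.upper()
    scores = {"gc": model.score_gc, "gt": model.score_gt, "at": model.score_at}
    max_step = max(scores.values())

    def step_of(i: int):
        cls = PAIR_CLASS.get(seq_u[i : i + 2])
        if cls is None or scores[cls] == 0:
            return None  # break (non-alternating, non-ACGT, or rated 0)
        return cls

    hits = []
    run_start = None
    for i in range(len(seq_u)):  # step i joins positions i and i+1
        broken = i == len(seq_u) - 1 or step_of(i) is None
        if not broken:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            end = i + 1  # run covers [run_start, i+1)
            classes = [step_of(j) for j in range(run_start, end - 1)]
            n = len(classes)
            raw = sum(scores[c] for c in classes)
            percent = 100.0 * raw / (n * max_step)
            if end - run_start >= params.min_length \
                    and percent >= params.min_score_percent:
                hits.append({
                    "sequence_id": sequence_id,
                    "start": run_start,
                    "end": end,
                    "sequence": seq[run_start:end],
                    "raw_score": raw,
                    "score_percent": percent,
                    "gc_richness": 100.0 * classes.count("gc") / n,
                    "gt_richness": 100.0 * classes.count("gt") / n,
                })
            run_start = None
    return hits
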