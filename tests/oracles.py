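"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: the chi-squared oracle
is the textbook formula written out directly, and the alignment oracle
evaluates every ungapped offset of every reference exhaustively (best
local segment per diagonal by maximum-subarray), instead of seeding and
extending.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist

_CODE = {b: i for i, b in enumerate("ACGT")}
_RC = str.maketrans("ACGTN", "TGCAN")


def chi2_textbook(observed) -> tuple[float, int, float]:
    """Pearson chi-squared statistic, df and p, straight from the formula."""
    obs = np.asarray(observed, dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    expected = row[:, None] * col[None, :] / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(chi2_dist.sf(stat, df))


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq], dtype=np.int8)


def _best_segment(read: np.ndarray, ref: np.ndarray, diag: int, match: int, mismatch: int):
    """Best ungapped local segment on one diagonal (maximum subarray)."""
    L, R = len(read), len(ref)
    q_lo = max(0, -diag)
    q_hi = min(L, R - diag)
    if q_hi <= q_lo:
        return None
    q = np.arange(q_lo, q_hi)
    hits = (read[q] == ref[q + diag]) & (read[q] < 4) & (ref[q + diag] < 4)
    scores = np.where(hits, match, -mismatch)
    best, best_seg = 0, None
    cur, cur_start = 0, 0
    for j, s in enumerate(scores):
        if cur <= 0:
            cur, cur_start = s, j
        else:
            cur += s
        if cur > best:
            best = cur
            best_seg = (cur_start, j)
    if best_seg is None:
        return None
    a, b = best_seg
    seg_hits = int(hits[a : b + 1].sum())
    return {
        "score": int(best),
        "q_lo": int(q_lo + a),
        "length": int(b - a + 1),
        "matches": seg_hits,
    }


def exhaustive_align(seq: str, refs: dict[str, str], categories: dict[str, str], params):
    """Best passing alignment over every offset of every reference, both strands.

    Mirrors the mapper's acceptance filters and tie rules (same-category
    ties -> lexicographically smallest accession, forward strand preferred;
    cross-category ties -> ambiguous).  Returns (status, accession, score).
    """
    candidates = []
    for strand, s in (("+", seq), ("-", seq.translate(_RC)[::-1])):
        read = _encode(s)
        for acc, ref_seq in refs.items():
            ref = _encode(ref_seq)
            for diag in range(-(len(read) - 1), len(ref)):
                seg = _best_segment(
                    read, ref, diag, params.match_score, params.mismatch_penalty
                )
                if seg is None:
                    continue
                identity = seg["matches"] / seg["length"]
                if (
                    seg["length"] >= params.min_aligned_length
                    and identity >= params.min_identity - 1e-12
                ):
                    candidates.append((seg["score"], acc, strand))
    if not candidates:
        return ("unassigned", None, None)
    best = max(c[0] for c in candidates)
    top = [c for c in candidates if c[0] == best]
    accs = sorted({c[1] for c in top})
    if len({categories[a] for a in accs}) > 1:
        return ("ambiguous", None, None)
    return ("assigned", accs[0], best)
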