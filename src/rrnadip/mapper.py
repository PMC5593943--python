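"""Seed-and-extend assignment of clean reads to rRNA reference accessions.

Each read (and its reverse complement) is scanned for exact k-mer seed
matches against an exhaustive index of the reference catalog; seed hits on
the same diagonal are merged into maximal runs and extended without gaps in
both directions under X-drop termination.  The best-scoring alignment that
passes the identity and length cut-offs wins.  This is a deliberately small,
fully self-contained stand-in for a BLASTN-style local search: rRNA reads
are highly similar to their references, so ungapped extension suffices and
keeps the scoring model auditable.

Ties are resolved without reference to read order: if the best score is
attained by several accessions of the same category the lexicographically
smallest accession is chosen (category-level counts are unaffected either
way); if it is attained across different categories the read is discarded
as ambiguous and tallied separately, so that category counts are never
corrupted by arbitrary cross-category ties.  N bases never seed and always
count as mismatches during extension.

The batch path (:func:`assign_all`) and the single-read path
(:func:`align_read`) share one implementation, so their results are
identical by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog import Catalog, Category
from .counts import CountTable

_NEG = np.int64(1) << 40  # sentinel "minus infinity" score

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class MapperError(ValueError):
    """Problem building the seed index or running the aligner."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (incl. N) as 4, uint8."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and acceptance parameters of the seed-and-extend search.

    Defaults are BLASTN-like, sized for 125 bp reads: an 11-base seed,
    +1/-2 match/mismatch scoring, X-drop 12, and acceptance cut-offs of
    90% identity over at least 50 aligned bases.

    ``seed_stride`` spaces the query-side seed probes (word stepping, as
    BLASTN does); the reference index itself stays exhaustive, so any
    exact match of length >= k + seed_stride - 1 is guaranteed to seed.
    The last window of each read is always probed.  Set it to 1 for
    per-position seeding.
    """

    k: int = 11
    match_score: int = 1
    mismatch_penalty: int = 2
    xdrop: int = 12
    min_identity: float = 0.90
    min_aligned_length: int = 50
    seed_stride: int = 4

    def __post_init__(self) -> None:
        if self.k < 4 or self.k > 31:
            raise ValueError("seed size k must be in [4, 31]")
        if not 1 <= self.seed_stride <= self.k:
            raise ValueError("seed_stride must be in [1, k]")
        if self.match_score <= 0 or self.mismatch_penalty <= 0:
            raise ValueError("match score and mismatch penalty must be positive")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_aligned_length < self.k:
            raise ValueError("min_aligned_length must be at least k")
        if self.xdrop <= 0:
            raise ValueError("xdrop must be positive")


@dataclass(frozen=True)
class CleanRead:
    """A quality-passed read tagged with its sample condition and assay."""

    read_id: str
    sequence: str
    condition: str
    assay: str


@dataclass(frozen=True)
class HitAssignment:
    """The single accepted alignment of one read (at most one per read)."""

    read_id: str
    accession: str
    score: int
    identity: float
    aligned_length: int
    strand: str  # "+" or "-"


class SeedIndex:
    """Exhaustive k-mer index over the forward strands of a reference catalog.

    Every k-mer occurrence of every reference is retrievable as an
    (accession, offset) pair; k-mers containing N are not indexed.
    """

    def __init__(self, catalog: Catalog, k: int):
        short = [r.accession for r in catalog if r.length < k]
        if short:
            raise MapperError(
                f"references shorter than seed size {k}: {', '.join(short)}"
            )
        self.k = k
        self.accessions: tuple[str, ...] = catalog.accessions
        self.categories: tuple[Category, ...] = tuple(
            r.category for r in catalog
        )
        encoded = [encode_sequence(r.sequence) for r in catalog]
        self.lengths = np.array([len(e) for e in encoded], dtype=np.int64)
        self.starts = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.concat = (
            np.concatenate(encoded) if encoded else np.empty(0, dtype=np.uint8)
        )
        codes_parts, acc_parts, pos_parts = [], [], []
        for acc_id, enc in enumerate(encoded):
            codes, valid = _kmer_codes(enc[None, :], k)
            codes, valid = codes[0], valid[0]
            pos = np.nonzero(valid)[0]
            codes_parts.append(codes[pos])
            pos_parts.append(pos)
            acc_parts.append(np.full(len(pos), acc_id, dtype=np.int32))
        all_codes = np.concatenate(codes_parts)
        order = np.argsort(all_codes, kind="stable")
        self.codes_sorted = all_codes[order]
        self.hit_acc = np.concatenate(acc_parts)[order]
        self.hit_pos = np.concatenate(pos_parts)[order].astype(np.int64)
        # direct-address table (code -> slice of the sorted arrays) for small k
        if k <= 12:
            space = 1 << (2 * k)
            counts = np.bincount(
                self.codes_sorted.astype(np.int64), minlength=space
            )
            self._first = np.concatenate(
                [[0], np.cumsum(counts)]
            ).astype(np.int64)
        else:
            self._first = None

    @property
    def n_kmers(self) -> int:
        return len(self.codes_sorted)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (accession, offset) occurrences of an exact k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        enc = encode_sequence(kmer)
        if (enc > 3).any():
            return []
        code, _ = _kmer_codes(enc[None, :], self.k)
        code = code[0, 0]
        lo = np.searchsorted(self.codes_sorted, code, side="left")
        hi = np.searchsorted(self.codes_sorted, code, side="right")
        return [
            (self.accessions[self.hit_acc[i]], int(self.hit_pos[i]))
            for i in range(lo, hi)
        ]


def build_index(catalog: Catalog, k: int = 11) -> SeedIndex:
    """Build the exhaustive forward-strand seed index for a catalog."""
    return SeedIndex(catalog, k)


def _kmer_codes(rows: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes (base-4) and validity for every k-window of each row.

    Windows containing a non-ACGT symbol get the out-of-alphabet sentinel
    code 4**k, which never occurs in the index.  Computed as a rolling
    polynomial (k vectorized passes) to avoid materializing the window view.
    """
    n, L = rows.shape
    if L < k:
        return (
            np.empty((n, 0), dtype=np.uint64),
            np.empty((n, 0), dtype=bool),
        )
    W = L - k + 1
    codes = np.zeros((n, W), dtype=np.uint64)
    valid = np.ones((n, W), dtype=bool)
    for t in range(k):
        col = rows[:, t : t + W]
        codes <<= np.uint64(2)
        codes |= col.astype(np.uint64)
        valid &= col < 4
    codes[~valid] = np.uint64(4) ** np.uint64(k)
    return codes, valid


def _xdrop_gain(scores: np.ndarray, xdrop: int) -> tuple[np.ndarray, np.ndarray]:
    """Best prefix gain under X-drop termination, per row.

    ``scores`` holds the per-position extension scores in scan order
    (already shifted so the anchor boundary is at column 0); blocked
    positions carry ``-_NEG``.  Returns (gain, n_extended) per row, where
    gain > 0 implies the extension advanced ``n_extended`` positions.
    """
    n, L = scores.shape
    if L == 0:
        z = np.zeros(n, dtype=np.int64)
        return z, z.copy()
    cum = np.cumsum(scores, axis=1)
    best = np.maximum(np.maximum.accumulate(cum, axis=1), 0)
    stopped = (best - cum) >= xdrop
    any_stop = stopped.any(axis=1)
    first_stop = np.where(any_stop, stopped.argmax(axis=1), L)
    allowed = np.arange(L)[None, :] < first_stop[:, None]
    cum_allowed = np.where(allowed, cum, -_NEG)
    j = cum_allowed.argmax(axis=1)
    gain = np.take_along_axis(cum_allowed, j[:, None], axis=1)[:, 0]
    positive = gain > 0
    return (
        np.where(positive, gain, 0),
        np.where(positive, j + 1, 0).astype(np.int64),
    )


def _chunk_candidates(
    Q: np.ndarray,
    lengths: np.ndarray,
    index: SeedIndex,
    params: AlignmentParams,
):
    """Seed, merge into diagonal runs, and extend; returns candidate arrays.

    ``Q`` stacks forward and reverse-complement rows per read (row 2i is
    read i forward, row 2i+1 its reverse complement), padded with N.
    """
    k = params.k
    stride = params.seed_stride
    codes, _ = _kmer_codes(Q, k)
    if codes.size == 0:
        return None
    W = codes.shape[1]
    sentinel = np.uint64(4) ** np.uint64(k)
    n_rows = Q.shape[0]
    probe_cols = np.arange(0, W, stride, dtype=np.int64)
    prow = np.repeat(np.arange(n_rows, dtype=np.int64), len(probe_cols))
    pq = np.tile(probe_cols, n_rows)
    pc = codes[:, probe_cols].ravel()
    # always probe the last window of each read (tail coverage)
    last_w = lengths[np.arange(n_rows) // 2] - k
    extra = (last_w >= 0) & (last_w % stride != 0)
    if extra.any():
        erow = np.nonzero(extra)[0].astype(np.int64)
        prow = np.concatenate([prow, erow])
        pq = np.concatenate([pq, last_w[extra]])
        pc = np.concatenate([pc, codes[erow, last_w[extra]]])
    sel_valid = pc != sentinel
    if not sel_valid.any():
        return None
    prow, pq, c = prow[sel_valid], pq[sel_valid], pc[sel_valid]
    if index._first is not None:
        ci = c.astype(np.int64)
        lo = index._first[ci]
        cnt = index._first[ci + 1] - lo
    else:
        lo = np.searchsorted(index.codes_sorted, c, side="left")
        cnt = np.searchsorted(index.codes_sorted, c, side="right") - lo
    sel = cnt > 0
    if not sel.any():
        return None
    rows, qpos, lo, cnt = prow[sel], pq[sel], lo[sel], cnt[sel]
    total = int(cnt.sum())
    rep = np.repeat(np.arange(len(cnt)), cnt)
    offs = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    hit = lo[rep] + offs
    hrow = rows[rep]
    hq = qpos[rep].astype(np.int64)
    hacc = index.hit_acc[hit].astype(np.int64)
    hdiag = index.hit_pos[hit] - hq

    # single composite sort key: (row, accession, diagonal, seed start)
    max_ref = int(index.lengths.max(initial=1))
    dspan = np.int64(max_ref + W + 1)
    key = ((hrow.astype(np.int64) * len(index.accessions) + hacc) * dspan
           + (hdiag + W)) * np.int64(W + 1) + hq
    order = np.argsort(key, kind="stable")
    hrow, hq, hacc, hdiag = hrow[order], hq[order], hacc[order], hdiag[order]
    new_run = np.ones(total, dtype=bool)
    if total > 1:
        # gaps of at most seed_stride between probes on one diagonal imply
        # one contiguous exact-match region (overlapping k-mers)
        same = (
            (hrow[1:] == hrow[:-1])
            & (hacc[1:] == hacc[:-1])
            & (hdiag[1:] == hdiag[:-1])
            & (hq[1:] - hq[:-1] <= stride)
        )
        new_run[1:] = ~same
    starts = np.nonzero(new_run)[0]
    ends = np.append(starts[1:], total) - 1
    return (
        hrow[starts],  # strand-matrix row of each run
        hacc[starts],
        hdiag[starts],
        hq[starts],  # first seed start (q0)
        hq[ends],  # last seed start (q1)
    )


def _extend_runs(
    Q: np.ndarray,
    lengths: np.ndarray,
    index: SeedIndex,
    params: AlignmentParams,
    r_row: np.ndarray,
    r_acc: np.ndarray,
    r_diag: np.ndarray,
    q0: np.ndarray,
    q1: np.ndarray,
):
    """Ungapped X-drop extension of every seed run; returns scored candidates.

    Runs that already span their whole read (an exact full-length match)
    cannot extend in either direction — the read ends block both sides —
    so they bypass the extension matrices entirely.
    """
    k = params.k
    m, p = params.match_score, params.mismatch_penalty
    rlen_all = lengths[r_row // 2]
    full = (q0 == 0) & (q1 == rlen_all - k)
    if full.any():
        part = ~full
        fr = _full_run_candidates(r_row[full], r_acc[full], r_diag[full],
                                  rlen_all[full], params)
        if part.any():
            pr = _extend_runs(Q, lengths, index, params,
                              r_row[part], r_acc[part], r_diag[part],
                              q0[part], q1[part])
            return tuple(np.concatenate([a, b]) for a, b in zip(fr, pr))
        return fr

    Lmax = Q.shape[1]
    i = np.arange(Lmax, dtype=np.int64)

    readlen = rlen_all[:, None]
    refpos = i[None, :] + r_diag[:, None]
    alen = index.lengths[r_acc][:, None]
    astart = index.starts[r_acc][:, None]
    in_bounds = (i[None, :] < readlen) & (refpos >= 0) & (refpos < alen)
    refchar = index.concat[astart + np.clip(refpos, 0, alen - 1)]
    qchar = Q[r_row]
    match = in_bounds & (qchar == refchar) & (qchar < 4) & (refchar < 4)
    S = np.where(match, np.int64(m), np.int64(-p))
    S[~in_bounds] = -_NEG
    match_cum = np.cumsum(match, axis=1, dtype=np.int64)

    anchor_len = q1 - q0 + k
    ar = np.arange(len(r_row))

    # rightward: columns q1+k, q1+k+1, ...
    idx_r = (q1 + k)[:, None] + i[None, :]
    Sr = np.where(
        idx_r < Lmax,
        np.take_along_axis(S, np.minimum(idx_r, Lmax - 1), axis=1),
        -_NEG,
    )
    gain_r, ext_r = _xdrop_gain(Sr, params.xdrop)

    # leftward: columns q0-1, q0-2, ...
    idx_l = (q0 - 1)[:, None] - i[None, :]
    Sl = np.where(
        idx_l >= 0,
        np.take_along_axis(S, np.maximum(idx_l, 0), axis=1),
        -_NEG,
    )
    gain_l, ext_l = _xdrop_gain(Sl, params.xdrop)

    score = anchor_len * m + gain_r + gain_l
    seg_lo = q0 - ext_l
    seg_hi = q1 + k - 1 + ext_r
    matches = match_cum[ar, seg_hi] - np.where(
        seg_lo > 0, match_cum[ar, np.maximum(seg_lo - 1, 0)], 0
    )
    seg_len = seg_hi - seg_lo + 1
    identity = matches / seg_len
    keep = (seg_len >= params.min_aligned_length) & (
        identity >= params.min_identity - 1e-12
    )
    return (
        r_row[keep] // 2,  # read within chunk
        (r_row[keep] % 2).astype(np.int8),  # 0 = forward, 1 = reverse
        r_acc[keep],
        score[keep],
        identity[keep],
        seg_len[keep],
        r_diag[keep],
        seg_lo[keep],
    )


def _full_run_candidates(r_row, r_acc, r_diag, rlen, params):
    """Score candidates whose seed run spans the entire read (identity 1)."""
    score = rlen * params.match_score
    keep = rlen >= params.min_aligned_length  # identity is exactly 1
    return (
        r_row[keep] // 2,
        (r_row[keep] % 2).astype(np.int8),
        r_acc[keep],
        score[keep],
        np.ones(int(keep.sum())),
        rlen[keep],
        r_diag[keep],
        np.zeros(int(keep.sum()), dtype=np.int64),
    )


def _resolve_reads(
    n_reads: int,
    read_idx: np.ndarray,
    strand: np.ndarray,
    acc: np.ndarray,
    score: np.ndarray,
    identity: np.ndarray,
    seg_len: np.ndarray,
    diag: np.ndarray,
    seg_lo: np.ndarray,
    index: SeedIndex,
) -> list[tuple[str, tuple | None]]:
    """Pick at most one accession per read; order-free deterministic tie rule."""
    results: list[tuple[str, tuple | None]] = [("unassigned", None)] * n_reads
    if len(read_idx) == 0:
        return results
    # fast path: reads with exactly one passing candidate need no tie logic
    n_cand = np.bincount(read_idx, minlength=n_reads)
    single = n_cand[read_idx] == 1
    for j in np.nonzero(single)[0]:
        results[int(read_idx[j])] = (
            "assigned",
            (
                index.accessions[acc[j]],
                int(score[j]),
                float(identity[j]),
                int(seg_len[j]),
                "+" if strand[j] == 0 else "-",
            ),
        )
    multi = ~single
    if not multi.any():
        return results
    keep_idx = np.nonzero(multi)[0]
    # sort: per read, best score first; then deterministic preference order
    order = keep_idx[
        np.lexsort(
            (
                seg_lo[multi],
                diag[multi],
                strand[multi],
                acc[multi],
                -score[multi],
                read_idx[multi],
            )
        )
    ]
    r = read_idx[order]
    boundaries = np.nonzero(np.diff(r))[0] + 1
    groups = np.split(order, boundaries)
    accession_names = index.accessions
    categories = index.categories
    score_l = score.tolist()
    acc_l = acc.tolist()
    for grp in groups:
        grp_l = grp.tolist()
        first = grp_l[0]
        ridx = int(read_idx[first])
        best = score_l[first]
        top = [j for j in grp_l if score_l[j] == best]  # grp is score-sorted
        top_accs = {acc_l[j] for j in top}
        if len(top_accs) > 1:
            if len({categories[a] for a in top_accs}) > 1:
                results[ridx] = ("ambiguous", None)
                continue
            # lexicographically smallest accession among the tied best
            chosen_id = min(top_accs, key=lambda a: accession_names[a])
            cand = next(j for j in top if acc_l[j] == chosen_id)
        else:
            chosen_id = acc_l[first]
            cand = first  # preferred strand/diag comes first
        results[ridx] = (
            "assigned",
            (
                accession_names[chosen_id],
                int(score[cand]),
                float(identity[cand]),
                int(seg_len[cand]),
                "+" if strand[cand] == 0 else "-",
            ),
        )
    return results


def map_sequences(
    seqs: Sequence[str],
    index: SeedIndex,
    params: AlignmentParams | None = None,
    chunk_size: int = 2048,
) -> list[tuple[str, tuple | None]]:
    """Map raw sequences; returns per-read (status, payload) in input order.

    Status is "assigned" (payload: accession, score, identity,
    aligned_length, strand), "unassigned" or "ambiguous".
    """
    params = params or AlignmentParams(k=index.k)
    if params.k != index.k:
        raise MapperError(
            f"params.k={params.k} does not match the index seed size {index.k}"
        )
    out: list[tuple[str, tuple | None]] = []
    for start in range(0, len(seqs), chunk_size):
        out.extend(_map_chunk(seqs[start : start + chunk_size], index, params))
    return out


def _map_chunk(seqs, index, params):
    n = len(seqs)
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    Lmax = int(lengths.max(initial=0))
    if Lmax < params.k:
        return [("unassigned", None)] * n
    Q = np.full((2 * n, Lmax), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        enc = encode_sequence(s)
        Q[2 * i, : len(enc)] = enc
        rc = np.where(enc < 4, 3 - enc, 4)[::-1]
        Q[2 * i + 1, : len(enc)] = rc
    runs = _chunk_candidates(Q, lengths, index, params)
    if runs is None:
        return [("unassigned", None)] * n
    cand = _extend_runs(Q, lengths, index, params, *runs)
    return _resolve_reads(n, *cand, index=index)


def align_read(
    read: CleanRead | str,
    index: SeedIndex,
    params: AlignmentParams | None = None,
) -> HitAssignment | None:
    """Align one read; returns its accepted hit or None.

    Cross-category best-score ties resolve to None (the read would be
    discarded as ambiguous by :func:`assign_all`).
    """
    seq = read.sequence if isinstance(read, CleanRead) else read
    read_id = read.read_id if isinstance(read, CleanRead) else ""
    status, payload = map_sequences([seq], index, params)[0]
    if status != "assigned":
        return None
    accession, score, identity, aligned_length, strand = payload
    return HitAssignment(read_id, accession, score, identity, aligned_length, strand)


def assign_all(
    reads: Iterable[CleanRead],
    catalog: Catalog | None = None,
    params: AlignmentParams | None = None,
    index: SeedIndex | None = None,
    chunk_size: int = 4096,
) -> tuple[CountTable, dict]:
    """Assign a read stream to accessions and tally counts per library.

    Each read contributes exactly 1.0 to one (accession, condition, assay)
    cell or is tallied as unassigned / ambiguous; the run report carries
    the full accounting (assigned + unassigned + ambiguous == total).
    """
    params = params or AlignmentParams()
    if index is None:
        if catalog is None:
            raise MapperError("assign_all needs a catalog or a prebuilt index")
        index = build_index(catalog, params.k)
    table = CountTable()
    totals = {"total": 0, "assigned": 0, "unassigned": 0, "ambiguous": 0}
    buffer: list[CleanRead] = []

    def flush() -> None:
        if not buffer:
            return
        statuses = map_sequences([r.sequence for r in buffer], index, params, chunk_size)
        for read, (status, payload) in zip(buffer, statuses):
            totals["total"] += 1
            if status == "assigned":
                totals["assigned"] += 1
                table.add(payload[0], read.condition, read.assay, 1.0)
            else:
                totals[status] += 1
        buffer.clear()

    for read in reads:
        buffer.append(read)
        if len(buffer) >= chunk_size:
            flush()
    flush()
    if totals["total"] == 0:
        warnings.warn("empty read stream: returning an all-zero count table")
    assert (
        totals["assigned"] + totals["unassigned"] + totals["ambiguous"]
        == totals["total"]
    )
    report = {**totals, "params": asdict(params)}
    return table, report
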