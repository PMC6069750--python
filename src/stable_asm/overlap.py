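"""Head-tail overlap detection between whole reads.

Instead of decomposing reads into k-mers, candidate suffix/prefix overlaps
between read pairs are proposed by short exact anchors (7 nt by default) taken
from the first and last ``anchor_scope`` positions of each read and looked up
in an index of every anchor position of every read.  Each anchor hit implies a
single overlap length; the overlap region is then scored by Hamming distance
computed on packed 2-bit words with XOR, and kept only when it satisfies the
validity rules:

* mismatches <= ``max_error_frac`` x overlap length (default 10%) — guards
  against chimeric junctions;
* ``min_len_frac`` x longer read <= overlap <= ``max_len_frac`` x shorter read
  (defaults 20% and 90%) — rejects chance matches and uninformative
  near-duplicate overlaps respectively.

Reads of different lengths are supported throughout, which is what lets
assembled contigs from a previous iteration re-enter as input.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .io_encoding import ReadSet, TwoBitSeq, pack_2bit

logger = logging.getLogger(__name__)

# guard against float artifacts at exact fractional boundaries
# (e.g. 0.2 * 100 -> 20.000000000000004 must still give min_len = 20)
_EPS = 1e-9

_LOW_BITS = np.uint64(0x5555555555555555)
_ONE = np.uint64(1)


@dataclass(frozen=True)
class OverlapParams:
    """Tuning knobs for overlap detection (defaults follow the method's)."""

    anchor_len: int = 7
    anchor_scope: int = 5
    max_error_frac: float = 0.10
    min_len_frac: float = 0.20
    max_len_frac: float = 0.90
    #: which end-anchors propose candidates; "both" is a superset of either.
    anchor_sides: str = "both"

    def __post_init__(self):
        if not (0 < self.min_len_frac < self.max_len_frac <= 1):
            raise ValueError("need 0 < min_len_frac < max_len_frac <= 1")
        if not (0 <= self.max_error_frac < 1):
            raise ValueError("need 0 <= max_error_frac < 1")
        if self.anchor_len < 1 or self.anchor_scope < 1:
            raise ValueError("anchor_len and anchor_scope must be >= 1")
        if self.anchor_sides not in ("head", "tail", "both"):
            raise ValueError("anchor_sides must be 'head', 'tail' or 'both'")


class OverlapTriple(NamedTuple):
    """A validated head-tail overlap: tail of read ``i`` matches head of ``j``."""

    i: int
    j: int
    k: int
    mismatches: int


def hamming_2bit(a, b) -> int:
    """Mismatch count between two equal-length 2-bit sequences.

    Packs both into uint64 words, XORs them, collapses each 2-bit symbol to a
    single indicator bit and popcounts.
    """
    ca = a.codes if isinstance(a, TwoBitSeq) else np.asarray(a, dtype=np.uint8)
    cb = b.codes if isinstance(b, TwoBitSeq) else np.asarray(b, dtype=np.uint8)
    if ca.shape[0] != cb.shape[0]:
        raise ValueError(f"length mismatch: {ca.shape[0]} vs {cb.shape[0]}")
    x = pack_2bit(ca) ^ pack_2bit(cb)
    hits = (x | (x >> _ONE)) & _LOW_BITS
    return int(np.bitwise_count(hits).sum())


def overlap_bounds(len_i: int, len_j: int, params: OverlapParams) -> tuple[int, int]:
    """(min_len, max_len) admissible for a pair of read lengths.

    min_len is a fraction of the longer read, max_len a fraction of the
    shorter.  min_len > max_len means no overlap is admissible for the pair.
    """
    longer = max(len_i, len_j)
    shorter = min(len_i, len_j)
    min_len = math.ceil(params.min_len_frac * longer - _EPS)
    max_len = math.floor(params.max_len_frac * shorter + _EPS)
    return min_len, max_len


def max_mismatches(k: int, params: OverlapParams) -> int:
    return math.floor(params.max_error_frac * k + _EPS)


def validate_overlap(
    len_i: int, len_j: int, k: int, mismatches: int, params: OverlapParams
) -> bool:
    """True iff a k-length overlap with the given mismatch count is valid."""
    min_len, max_len = overlap_bounds(len_i, len_j, params)
    return min_len <= k <= max_len and mismatches <= max_mismatches(k, params)


def _anchor_keys(codes: np.ndarray, anchor_len: int) -> np.ndarray:
    """Integer key of every anchor_len-mer of a code array (base-4 value)."""
    windows = np.lib.stride_tricks.sliding_window_view(
        codes.astype(np.int64), anchor_len
    )
    weights = 4 ** np.arange(anchor_len, dtype=np.int64)
    return windows @ weights


def build_anchor_index(
    reads: ReadSet, params: Optional[OverlapParams] = None
) -> dict[int, list[tuple[int, int]]]:
    """Map each anchor value to its (read index, offset) occurrences.

    Every position 0..len-anchor_len of every read is indexed.  Reads shorter
    than the anchor are skipped with a warning (they cannot take part in
    anchored overlap detection).
    """
    params = params or OverlapParams()
    index: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for ridx, read in enumerate(reads):
        if len(read) < params.anchor_len:
            logger.warning(
                "read %r (%d nt) shorter than anchor (%d nt); excluded from assembly",
                read.read_id, len(read), params.anchor_len,
            )
            continue
        for off, key in enumerate(_anchor_keys(read.seq.codes, params.anchor_len).tolist()):
            index[key].append((ridx, off))
    return dict(index)


def _expand_hits(
    sorted_keys: np.ndarray, query_keys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Join queries against a sorted key table.

    Returns (query row repeated per hit, flat position into the sorted table).
    """
    lo = np.searchsorted(sorted_keys, query_keys, side="left")
    hi = np.searchsorted(sorted_keys, query_keys, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    qrow = np.repeat(np.arange(query_keys.shape[0]), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    flat = np.repeat(lo, counts) + (np.arange(total) - np.repeat(starts, counts))
    return qrow, flat


def find_overlaps(
    reads: ReadSet, params: Optional[OverlapParams] = None
) -> list[OverlapTriple]:
    """All valid head-tail overlaps, at most one triple per ordered pair.

    Candidate shifts: an anchor of read j's head (offset q) hitting read i at
    offset p — or an anchor of read i's tail hitting read j — implies overlap
    k = len_i - p + q.  Duplicate shifts proposed by several anchors are
    deduplicated before Hamming evaluation.  When several k survive validation
    for one ordered pair, the one with fewest mismatches wins, ties broken by
    the longer (more informative) overlap.

    The search is a vectorized join: every anchor position of every read goes
    into a sorted key table, the first/last ``anchor_scope`` anchors of each
    read are looked up against it, and the implied overlap regions are scored
    per overlap length with one XOR + per-symbol nonzero count per group.
    """
    params = params or OverlapParams()
    al, scope = params.anchor_len, params.anchor_scope
    n = len(reads)
    if n == 0:
        return []
    lengths = np.array([len(r) for r in reads], dtype=np.int64)
    usable = lengths >= al
    n_short = int((~usable).sum())
    if n_short:
        logger.warning(
            "%d reads shorter than the %d nt anchor; excluded from assembly",
            n_short, al,
        )
    if not usable.any():
        return []
    max_len = int(lengths.max())
    # padded code matrix; pad value never read (column index < read length)
    codes_mat = np.zeros((n, max_len), dtype=np.uint8)
    for r, read in enumerate(reads):
        codes_mat[r, : lengths[r]] = read.seq.codes

    # flat anchor table over all usable reads
    key_parts, read_parts, off_parts = [], [], []
    hq_key, hq_read, hq_off = [], [], []  # head-side query anchors
    tq_key, tq_read, tq_off = [], [], []  # tail-side query anchors
    for r in range(n):
        if not usable[r]:
            continue
        keys = _anchor_keys(codes_mat[r, : lengths[r]], al)
        m = keys.shape[0]
        key_parts.append(keys)
        read_parts.append(np.full(m, r, dtype=np.int64))
        off_parts.append(np.arange(m, dtype=np.int64))
        w = min(scope, m)
        if params.anchor_sides in ("head", "both"):
            hq_key.append(keys[:w])
            hq_read.append(np.full(w, r, dtype=np.int64))
            hq_off.append(np.arange(w, dtype=np.int64))
        if params.anchor_sides in ("tail", "both"):
            tq_key.append(keys[m - w :])
            tq_read.append(np.full(w, r, dtype=np.int64))
            tq_off.append(np.arange(m - w, m, dtype=np.int64))
    all_keys = np.concatenate(key_parts)
    all_reads = np.concatenate(read_parts)
    all_offs = np.concatenate(off_parts)
    order = np.argsort(all_keys, kind="stable")
    skeys, sreads, soffs = all_keys[order], all_reads[order], all_offs[order]

    cand_i, cand_j, cand_k = [], [], []
    if hq_key:
        # anchors of read j's head hitting (i, p): pair (i, j), k = len_i - p + q
        qkey = np.concatenate(hq_key)
        qread = np.concatenate(hq_read)
        qoff = np.concatenate(hq_off)
        qrow, flat = _expand_hits(skeys, qkey)
        i_arr, p_arr = sreads[flat], soffs[flat]
        j_arr, q_arr = qread[qrow], qoff[qrow]
        keep = i_arr != j_arr
        cand_i.append(i_arr[keep])
        cand_j.append(j_arr[keep])
        cand_k.append((lengths[i_arr] - p_arr + q_arr)[keep])
    if tq_key:
        # anchors of read i's tail hitting (j, q): pair (i, j), k = len_i - p + q
        qkey = np.concatenate(tq_key)
        qread = np.concatenate(tq_read)
        qoff = np.concatenate(tq_off)
        qrow, flat = _expand_hits(skeys, qkey)
        j_arr, q_arr = sreads[flat], soffs[flat]
        i_arr, p_arr = qread[qrow], qoff[qrow]
        keep = i_arr != j_arr
        cand_i.append(i_arr[keep])
        cand_j.append(j_arr[keep])
        cand_k.append((lengths[i_arr] - p_arr + q_arr)[keep])
    if not cand_i:
        return []
    I = np.concatenate(cand_i)
    J = np.concatenate(cand_j)
    K = np.concatenate(cand_k)
    if I.size == 0:
        return []

    # length-bound validity (vectorized overlap_bounds)
    li, lj = lengths[I], lengths[J]
    longer = np.maximum(li, lj)
    shorter = np.minimum(li, lj)
    lo_b = np.ceil(params.min_len_frac * longer - _EPS).astype(np.int64)
    hi_b = np.minimum(
        np.floor(params.max_len_frac * shorter + _EPS).astype(np.int64), shorter
    )
    keep = (K >= np.maximum(lo_b, 1)) & (K <= hi_b)
    I, J, K = I[keep], J[keep], K[keep]
    if I.size == 0:
        return []

    # dedupe candidate shifts proposed by several anchors
    trip = (I * n + J) * (max_len + 1) + K
    _, uidx = np.unique(trip, return_index=True)
    I, J, K = I[uidx], J[uidx], K[uidx]

    # Hamming per candidate, grouped by overlap length: XOR the code matrices
    # and count nonzero symbols (the packed-word form of the same metric is
    # hamming_2bit, used for scalar queries)
    mm = np.empty(I.shape[0], dtype=np.int64)
    span = np.arange(max_len, dtype=np.int64)
    for k in np.unique(K).tolist():
        sel = K == k
        ia, jb = I[sel], J[sel]
        cols = (lengths[ia] - k)[:, None] + span[None, :k]
        tails = codes_mat[ia[:, None], cols]
        heads = codes_mat[jb][:, :k]
        mm[sel] = np.count_nonzero(tails ^ heads, axis=1)
    limit = np.floor(params.max_error_frac * K + _EPS).astype(np.int64)
    keep = mm <= limit
    I, J, K, mm = I[keep], J[keep], K[keep], mm[keep]
    if I.size == 0:
        return []

    # best k per ordered pair: fewest mismatches, tie -> longer overlap
    pair = I * n + J
    order = np.lexsort((int(K.max()) - K, mm, pair))
    pair_sorted = pair[order]
    _, first = np.unique(pair_sorted, return_index=True)
    sel = order[first]
    return [
        OverlapTriple(int(I[s]), int(J[s]), int(K[s]), int(mm[s])) for s in sel
    ]


def dump_triples_tsv(triples: list[OverlapTriple], path) -> None:
    """Debug dump: one triple per line (0-based read indices)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tk\tmismatches\n")
        for t in triples:
            fh.write(f"{t.i}\t{t.j}\t{t.k}\t{t.mismatches}\n")
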