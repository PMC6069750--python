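"""Shared test utilities: independent oracles and sequence generators."""

from __future__ import annotations

import math

import numpy as np

import stable_asm as sa

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n).tolist())


def naive_hamming(a: str, b: str) -> int:
    """Per-character mismatch count on the collapsed 2-bit alphabet."""
    ca = sa.encode_sequence(a).codes.tolist()
    cb = sa.encode_sequence(b).codes.tolist()
    assert len(ca) == len(cb)
    return sum(1 for x, y in zip(ca, cb) if x != y)


def brute_force_overlaps(reads: sa.ReadSet, params: sa.OverlapParams) -> dict:
    """O(n^2 * L) enumeration of anchored valid head-tail overlaps.

    For every ordered pair, every shift is tried, the validity rules applied,
    and a pair reported only if at least one exact anchor-length match exists
    within the first/last ``anchor_scope`` anchor windows consistent with the
    shift.  Returns {(i, j): (best k, mismatches)} with the same best-k rule
    as the implementation (fewest mismatches, tie -> longer overlap).
    """
    al, scope = params.anchor_len, params.anchor_scope
    out = {}
    n = len(reads)
    for i in range(n):
        ci = reads[i].seq.codes
        li = len(ci)
        if li < al:
            continue
        for j in range(n):
            if i == j:
                continue
            cj = reads[j].seq.codes
            lj = len(cj)
            if lj < al:
                continue
            lo, hi = sa.overlap_bounds(li, lj, params)
            best = None
            for k in range(max(lo, 1), min(hi, li, lj) + 1):
                mm = int(np.count_nonzero(ci[li - k :] != cj[:k]))
                if mm > math.floor(params.max_error_frac * k + 1e-9):
                    continue
                anchored = False
                for q in range(min(scope, lj - al + 1)):
                    p = li - k + q
                    if q + al <= k and p >= 0 and np.array_equal(
                        cj[q : q + al], ci[p : p + al]
                    ):
                        anchored = True
                        break
                if not anchored:
                    for s in range(min(scope, li - al + 1)):
                        p = li - al - s
                        q = k - (li - p)
                        if p >= 0 and 0 <= q and q + al <= lj and np.array_equal(
                            ci[p : p + al], cj[q : q + al]
                        ):
                            anchored = True
                            break
                if not anchored:
                    continue
                if best is None or (mm, -k) < (best[1], -best[0]):
                    best = (k, mm)
            if best is not None:
                out[(i, j)] = best
    return out


def planted_junction_reads(
    rng: np.random.Generator,
    n_reads: int = 50,
    read_len: int = 100,
    n_transcripts: int = 6,
    transcript_len: int = 400,
) -> sa.ReadSet:
    """Reads cut from a few random transcripts (true junctions) plus noise."""
    seqs: list[str] = []
    for _ in range(n_transcripts):
        t = random_seq(rng, transcript_len)
        pos = 0
        while pos + read_len <= transcript_len and len(seqs) < n_reads:
            seqs.append(t[pos : pos + read_len])
            pos += int(rng.integers(20, 70))
    while len(seqs) < n_reads:
        seqs.append(random_seq(rng, read_len))
    return sa.readset_from_sequences((f"r{i}", s) for i, s in enumerate(seqs[:n_reads]))


def tiling_reads(transcript: str, read_len: int, stagger: int) -> sa.ReadSet:
    """Error-free reads tiling a transcript at constant stagger."""
    starts = list(range(0, len(transcript) - read_len, stagger))
    starts.append(len(transcript) - read_len)
    return sa.readset_from_sequences(
        (f"r{i}", transcript[s : s + read_len]) for i, s in enumerate(starts)
    )
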