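"""Redundancy removal and read-support weighting of assembled transcripts.

Traversal output still carries redundancy the path-level rules cannot see —
in particular forward/reverse duplicates of the same transcript (overlap
detection is strand-naive) and near-identical paths from different sources.
``cluster_transcripts`` removes it with greedy centroid clustering: sequences
are visited longest-first and each joins the first representative it aligns
to at >= ``identity_threshold`` identity over its own length (containment
counts by default), in either orientation.  Identity comes from a semi-global
alignment (free end gaps on the longer sequence) with unit costs.

``weight_transcripts`` then assigns every raw read to at most one surviving
transcript by anchor-seeded ungapped end-to-end alignment; a transcript's
weight is the number of reads assigned to it.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional

import edlib

from .graph_assembly import NodePath
from .io_encoding import ReadSet, encode_sequence, revcomp
from .overlap import _anchor_keys, hamming_2bit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.95
    #: if True, a shorter sequence contained in a longer one at threshold
    #: identity over its own length joins that cluster
    containment_counts: bool = True

    def __post_init__(self):
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class AssembledTranscript:
    transcript_id: str
    sequence: str
    path: Optional[NodePath] = None
    weight: int = 0


def _identity(shorter: str, longer: str, floor: float = 0.0) -> float:
    """Identity of the best semi-global placement of shorter inside longer.

    ``floor`` bounds the search: identities below it are reported as 0.0,
    which lets edlib band the alignment.
    """
    limit = math.floor((1.0 - floor) * len(shorter)) if floor > 0 else -1
    d = edlib.align(shorter, longer, mode="HW", task="distance", k=limit)["editDistance"]
    if d < 0:
        return 0.0
    return 1.0 - d / len(shorter)


def cluster_transcripts(
    transcripts: list[AssembledTranscript], params: Optional[ClusterParams] = None
) -> list[AssembledTranscript]:
    """Greedy centroid clustering; returns cluster representatives.

    Deterministic: sequences are processed by descending length (input order
    breaking ties), and representatives are returned in input order.
    """
    params = params or ClusterParams()
    order = sorted(
        range(len(transcripts)), key=lambda i: (-len(transcripts[i].sequence), i)
    )
    reps: list[int] = []
    for idx in order:
        seq = transcripts[idx].sequence
        seq_rc = revcomp(seq)
        placed = False
        for ridx in reps:
            rep_seq = transcripts[ridx].sequence
            if not params.containment_counts and len(seq) < params.identity_threshold * len(rep_seq):
                continue
            thr = params.identity_threshold
            ident = max(
                _identity(seq, rep_seq, floor=thr),
                _identity(seq_rc, rep_seq, floor=thr),
            )
            if ident >= params.identity_threshold:
                placed = True
                break
        if not placed:
            reps.append(idx)
    return [transcripts[i] for i in sorted(reps)]


def weight_transcripts(
    transcripts: list[AssembledTranscript],
    reads: ReadSet,
    *,
    anchor_len: int = 7,
    anchor_scope: int = 5,
) -> tuple[list[AssembledTranscript], int]:
    """Assign each raw read to its best transcript; fill weights.

    A read's candidate placements come from exact anchor hits of its first and
    last ``anchor_scope`` anchors against an index of all transcript anchor
    positions; each placement is scored as the Hamming distance of the full
    read against the transcript window (ungapped, end-to-end on the read).
    The transcript with the fewest mismatches wins, ties going to the lowest
    transcript index.  Returns (weighted transcripts, unmapped read count).
    """
    weights = [0] * len(transcripts)
    if not transcripts:
        logger.info("no transcripts: all %d reads unmapped", len(reads))
        return [], len(reads)

    tcodes = [encode_sequence(t.sequence, record_id=t.transcript_id).codes for t in transcripts]
    index: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for ti, codes in enumerate(tcodes):
        if codes.shape[0] < anchor_len:
            continue
        for off, key in enumerate(_anchor_keys(codes, anchor_len).tolist()):
            index[key].append((ti, off))

    unmapped = 0
    for read in reads:
        rcodes = read.seq.codes
        rl = rcodes.shape[0]
        if rl < anchor_len:
            unmapped += 1
            continue
        keys = _anchor_keys(rcodes, anchor_len).tolist()
        n_anchor = len(keys)
        offsets = set(range(min(anchor_scope, n_anchor))) | set(
            range(max(0, n_anchor - anchor_scope), n_anchor)
        )
        cands: set[tuple[int, int]] = set()
        for q in offsets:
            for ti, p in index.get(keys[q], ()):
                start = p - q
                if 0 <= start and start + rl <= tcodes[ti].shape[0]:
                    cands.add((ti, start))
        best: Optional[tuple[int, int]] = None  # (mismatches, transcript index)
        for ti, start in sorted(cands):
            mm = hamming_2bit(rcodes, tcodes[ti][start : start + rl])
            if best is None or (mm, ti) < best:
                best = (mm, ti)
        if best is None:
            unmapped += 1
        else:
            weights[best[1]] += 1

    if unmapped:
        logger.info("%d of %d reads unmapped during weighting", unmapped, len(reads))
    return [replace(t, weight=w) for t, w in zip(transcripts, weights)], unmapped
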