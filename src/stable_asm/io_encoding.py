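"""Sequence I/O and the packed 2-bit nucleotide representation.

All downstream computation (anchor indexing, XOR-metric Hamming distance,
path merging) operates on 2-bit codes rather than ASCII bases.  A, C, G and T
map to four distinct codes and every ambiguity code (N, R, Y, ...) collapses
onto the code of C, which keeps the alphabet at exactly four symbols.  Reads
carrying many ambiguous bases are expected to be removed by upstream quality
filtering, so spurious matches caused by the C collapse are rare in practice.

Only the per-base code assignment is contractual; the packed word layout
(32 bases per little-endian ``uint64`` word, first base in the lowest bits)
is internal to this module and :func:`pack_2bit`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

CODE_A, CODE_C, CODE_G, CODE_T = 0, 1, 2, 3

#: ambiguity codes (IUPAC) that collapse onto the C code; U is folded in too.
AMBIGUOUS = "NURYSWKMBDHV"

_ENCODE_LUT = np.full(256, 0xFF, dtype=np.uint8)
for _ch, _code in zip("ACGT", (CODE_A, CODE_C, CODE_G, CODE_T)):
    _ENCODE_LUT[ord(_ch)] = _code
    _ENCODE_LUT[ord(_ch.lower())] = _code
for _ch in AMBIGUOUS:
    _ENCODE_LUT[ord(_ch)] = CODE_C
    _ENCODE_LUT[ord(_ch.lower())] = CODE_C

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

_WORD_SYMBOLS = 32
_SHIFTS = (2 * np.arange(_WORD_SYMBOLS, dtype=np.uint64)).astype(np.uint64)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class TwoBitSeq:
    """A nucleotide sequence held as one 2-bit code per base.

    Slicing returns a new :class:`TwoBitSeq` viewing the same buffer.
    """

    __slots__ = ("codes",)

    def __init__(self, codes: np.ndarray):
        self.codes = np.asarray(codes, dtype=np.uint8)

    @classmethod
    def from_string(cls, seq: str, record_id: Optional[str] = None) -> "TwoBitSeq":
        return encode_sequence(seq, record_id=record_id)

    def __len__(self) -> int:
        return self.codes.shape[0]

    def __getitem__(self, item) -> "TwoBitSeq":
        if isinstance(item, slice):
            return TwoBitSeq(self.codes[item])
        raise TypeError("TwoBitSeq supports slice indexing only")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TwoBitSeq):
            return NotImplemented
        return np.array_equal(self.codes, other.codes)

    def __hash__(self):
        return hash(self.codes.tobytes())

    def __repr__(self) -> str:
        s = self.to_string()
        return f"TwoBitSeq({s[:40] + '...' if len(s) > 40 else s!s})"

    def to_string(self) -> str:
        return bytes(_DECODE_LUT[self.codes]).decode("ascii")

    def packed(self) -> np.ndarray:
        return pack_2bit(self.codes)


def pack_2bit(codes: np.ndarray) -> np.ndarray:
    """Pack per-base 2-bit codes into uint64 words (32 bases per word).

    Trailing positions of the last word are zero-padded; two sequences of
    equal length therefore pack to words whose XOR is nonzero exactly at
    differing base positions.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    n = codes.shape[0]
    pad = (-n) % _WORD_SYMBOLS
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    words = codes.reshape(-1, _WORD_SYMBOLS).astype(np.uint64)
    return np.bitwise_or.reduce(words << _SHIFTS, axis=1)


def encode_sequence(seq: str, record_id: Optional[str] = None) -> TwoBitSeq:
    """Encode a nucleotide string to 2-bit codes (ambiguity codes -> C code).

    Raises ``ValueError`` for an empty sequence or a character that is not an
    IUPAC nucleotide code, naming ``record_id`` when given.
    """
    who = f" in record {record_id!r}" if record_id else ""
    if not seq:
        raise ValueError(f"empty sequence{who}")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    bad = codes == 0xFF
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(
            f"invalid nucleotide character {seq[pos]!r} at position {pos}{who}"
        )
    return TwoBitSeq(codes)


def decode_sequence(seq: TwoBitSeq) -> str:
    return seq.to_string()


def revcomp(seq: str) -> str:
    """Reverse complement of a plain nucleotide string (N self-complements)."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass
class Read:
    """One input sequence with its identifier, kept in 2-bit form."""

    read_id: str
    seq: TwoBitSeq
    source: str = "raw_input"  # or "previous_iteration"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSet:
    """Ordered reads; list positions are the node identities used downstream."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, idx: int) -> Read:
        return self.reads[idx]

    @property
    def uniform_length(self) -> Optional[int]:
        lengths = {len(r) for r in self.reads}
        if len(lengths) == 1:
            return lengths.pop()
        return None


def readset_from_sequences(
    items: Iterable[tuple[str, str]], source: str = "raw_input"
) -> ReadSet:
    """Build a ReadSet from ``(id, sequence)`` pairs."""
    return ReadSet(
        [Read(rid, encode_sequence(seq, record_id=rid), source=source) for rid, seq in items]
    )


def _open_text(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path) -> ReadSet:
    """Read a FASTQ (Phred+33) or FASTA file (auto-detected, plain or gzip).

    Quality strings are parsed and discarded: only base symbols take part in
    overlap detection.  Truncated records and empty sequences are rejected
    with the offending record named.
    """
    path = Path(path)
    handle = _open_text(path)
    with handle:
        first = handle.read(1)
        while first.isspace():
            first = handle.read(1)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            return ReadSet([])
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
        handle.seek(0)
        reads: list[Read] = []
        try:
            for rec in SeqIO.parse(handle, fmt):
                s = str(rec.seq)
                if not s:
                    raise ValueError(f"record {rec.id!r} has an empty sequence")
                reads.append(Read(rec.id, encode_sequence(s, record_id=rec.id)))
        except ValueError as exc:
            raise ValueError(f"{path}: record {len(reads) + 1}: {exc}") from exc
    return ReadSet(reads)


def write_fasta(transcripts, path) -> None:
    """Write assembled transcripts as 60-column FASTA.

    Header: ``>transcript_id length=<nt> weight=<read count>``.
    """
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id} length={len(t.sequence)} weight={t.weight}\n")
            for off in range(0, len(t.sequence), 60):
                fh.write(t.sequence[off : off + 60] + "\n")


def write_weights_tsv(transcripts, path) -> None:
    """Write the per-transcript read-support table (transcript_id, length, read_count)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tlength\tread_count\n")
        for t in transcripts:
            fh.write(f"{t.transcript_id}\t{len(t.sequence)}\t{t.weight}\n")
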