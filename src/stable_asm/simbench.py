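"""Synthetic transcriptomes, read simulation and TP/FPA/FPB classification.

The benchmark works entirely on synthetic data where the truth is known, so
reconstructions can be classified without external aligners:

* **TP** — a single semi-global match to some *expressed* reference covers at
  least ``tp_cover_frac`` (default 85%) of the reconstruction's length.
* **FPA** — a false positive that nevertheless matches a genuine annotated
  but non-expressed isoform, or any valid exon chain of one gene, as a single
  path covering >= ``fpa_cover_frac`` at >= ``fpa_identity`` identity: a
  biologically plausible transcript the sample never expressed.  Only
  decidable because the simulator owns the annotation; genes without
  alternative isoforms (the bacterial case) cannot produce FPAs.
* **FPB** — everything else: chimeras and junk joins.

Sensitivity is summarised per reference: a reference counts as full-length
when a single reconstruction covers >= ``full_frac`` (default 90%) of *its*
length, and as recovered-at-70% at the 0.70 floor.  S100 / S70 / FPR are the
corresponding percentages.

Both orientations are tried everywhere since the assembler is strand-naive.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import edlib
import numpy as np

from .io_encoding import Read, ReadSet, TwoBitSeq, encode_sequence, revcomp
from .postprocess import AssembledTranscript

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class SyntheticGene:
    gene_id: str
    #: 0-based half-open exon intervals on the synthetic genome, ordered
    exons: list[tuple[int, int]]
    #: each isoform is an increasing chain of exon indices sharing the first
    #: and last exon (so skipped-exon variants stay comparable)
    isoforms: list[tuple[int, ...]]
    #: indices into ``isoforms`` that are actually transcribed
    expressed: list[int]

    def isoform_id(self, idx: int) -> str:
        return f"{self.gene_id}.{idx + 1}"

    def splice(self, genome: str, chain: tuple[int, ...]) -> str:
        return "".join(genome[self.exons[e][0] : self.exons[e][1]] for e in chain)


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 150
    coverage: float = 20.0
    substitution_rate: float = 0.001
    rng_seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass(frozen=True)
class ClassificationParams:
    tp_cover_frac: float = 0.85
    full_frac: float = 0.90
    fpa_cover_frac: float = 0.90
    fpa_identity: float = 0.90

    def __post_init__(self):
        for v in (self.tp_cover_frac, self.full_frac, self.fpa_cover_frac, self.fpa_identity):
            if not (0 < v <= 1):
                raise ValueError("classification fractions must be in (0, 1]")


@dataclass
class BenchmarkReport:
    n_results: int
    n_refs: int
    n_fp: int
    n_fpa: int
    n_fpb: int
    n_full: int
    n_70: int
    s100: float
    s70: float
    fpr: float

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["s100_rounded"] = round_half_up(self.s100, 0)
        d["s70_rounded"] = round_half_up(self.s70, 0)
        d["fpr_rounded"] = round_half_up(self.fpr, 2 if self.fpr < 1 else 0)
        return d


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[c] for c in rng.integers(0, 4, size=length).tolist())


def make_transcriptome(
    n_genes: int,
    isoforms_per_gene: int,
    exon_length_range: tuple[int, int],
    exons_per_gene_range: tuple[int, int],
    expressed_fraction: float,
    seed: int,
    intron_length_range: tuple[int, int] = (60, 200),
    intergenic_length_range: tuple[int, int] = (100, 300),
) -> tuple[str, list[SyntheticGene], dict[str, str], dict[str, str]]:
    """Random genome + gene models + spliced transcript sequences.

    Returns ``(genome, genes, expressed, annotated)`` where the last two map
    transcript id to sequence.  Isoform 1 of each gene always uses the full
    exon chain; additional isoforms drop random internal exons, so with
    ``isoforms_per_gene = 1`` (the bacterial case) no FPA is constructible.
    """
    for lo, hi in (exon_length_range, exons_per_gene_range,
                   intron_length_range, intergenic_length_range):
        if lo > hi or lo < 1:
            raise ValueError("ranges must be non-empty with positive bounds")
    if n_genes < 1 or isoforms_per_gene < 1:
        raise ValueError("need at least one gene and one isoform per gene")
    min_exons = exons_per_gene_range[0]
    if isoforms_per_gene > 2 ** max(min_exons - 2, 0):
        raise ValueError(
            f"{isoforms_per_gene} distinct isoforms impossible with as few as "
            f"{min_exons} exons per gene"
        )
    if not (0 < expressed_fraction <= 1):
        raise ValueError("expressed_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    pos = 0
    genes: list[SyntheticGene] = []
    for gi in range(n_genes):
        spacer = int(rng.integers(intergenic_length_range[0], intergenic_length_range[1] + 1))
        parts.append(_random_seq(rng, spacer))
        pos += spacer
        n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        exons: list[tuple[int, int]] = []
        for e in range(n_exons):
            if e:
                intron = int(rng.integers(intron_length_range[0], intron_length_range[1] + 1))
                parts.append(_random_seq(rng, intron))
                pos += intron
            exon_len = int(rng.integers(exon_length_range[0], exon_length_range[1] + 1))
            parts.append(_random_seq(rng, exon_len))
            exons.append((pos, pos + exon_len))
            pos += exon_len

        chains: list[tuple[int, ...]] = [tuple(range(n_exons))]
        middle = list(range(1, n_exons - 1))
        attempts = 0
        while len(chains) < isoforms_per_gene:
            attempts += 1
            if attempts > 1000 * isoforms_per_gene:
                raise ValueError(
                    f"could not draw {isoforms_per_gene} distinct isoforms for "
                    f"{n_exons}-exon gene"
                )
            keep = rng.random(len(middle)) < 0.5
            chain = (0, *(m for m, kp in zip(middle, keep) if kp), n_exons - 1)
            if chain not in chains:
                chains.append(chain)
        n_expr = min(len(chains), max(1, round(expressed_fraction * len(chains))))
        expressed_idx = sorted(
            int(i) for i in rng.choice(len(chains), size=n_expr, replace=False)
        )
        genes.append(SyntheticGene(f"g{gi + 1:04d}", exons, chains, expressed_idx))

    genome = "".join(parts)
    expressed = {
        g.isoform_id(i): g.splice(genome, g.isoforms[i])
        for g in genes for i in g.expressed
    }
    annotated = {
        g.isoform_id(i): g.splice(genome, chain)
        for g in genes for i, chain in enumerate(g.isoforms)
    }
    return genome, genes, expressed, annotated


def simulate_reads(
    transcripts: Mapping[str, str], params: Optional[ReadSimParams] = None
) -> tuple[ReadSet, list[tuple[str, str, int]]]:
    """Uniform-coverage single-end reads with i.i.d. substitution noise.

    Per transcript, ``ceil(coverage * length / read_length)`` reads start at
    uniform random positions.  Returns the reads plus a truth table of
    ``(read_id, transcript_id, start)`` for downstream checks.  Transcripts
    shorter than one read are skipped with a warning.
    """
    params = params or ReadSimParams()
    rng = np.random.default_rng(params.rng_seed)
    rl = params.read_length
    reads: list[Read] = []
    truth: list[tuple[str, str, int]] = []
    for tid, seq in transcripts.items():
        length = len(seq)
        if length < rl:
            logger.warning(
                "transcript %r (%d nt) shorter than read length %d; skipped",
                tid, length, rl,
            )
            continue
        codes = encode_sequence(seq, record_id=tid).codes
        n_reads = math.ceil(params.coverage * length / rl)
        starts = rng.integers(0, length - rl + 1, size=n_reads)
        for ri, start in enumerate(starts.tolist()):
            window = codes[start : start + rl].copy()
            if params.substitution_rate > 0:
                hit = np.nonzero(rng.random(rl) < params.substitution_rate)[0]
                if hit.size:
                    shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
                    window[hit] = (window[hit] + shift) % 4
            rid = f"{tid}|r{ri}"
            reads.append(Read(rid, TwoBitSeq(window)))
            truth.append((rid, tid, start))
    return ReadSet(reads), truth


def _matched_fraction(result: str, target: str) -> float:
    """Fraction of ``result`` accounted for by its best single semi-global
    match against ``target``, best of both orientations.

    When the result fits inside the target the full result aligns and edits
    are charged against it; when the result is longer, only the target's
    extent can match and uncovered result flanks count as unmatched.
    """
    best = 0.0
    for query in (result, revcomp(result)):
        if len(query) <= len(target):
            d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
            frac = 1.0 - d / len(result)
        else:
            d = edlib.align(target, query, mode="HW", task="distance")["editDistance"]
            frac = (len(target) - d) / len(result)
        best = max(best, frac)
    return best


def _reference_coverage(ref: str, result: str) -> float:
    """Fraction of ``ref`` recovered by a single match with ``result``."""
    best = 0.0
    for query in (result, revcomp(result)):
        if len(ref) <= len(query):
            d = edlib.align(ref, query, mode="HW", task="distance")["editDistance"]
            frac = 1.0 - d / len(ref)
        else:
            d = edlib.align(query, ref, mode="HW", task="distance")["editDistance"]
            frac = (len(query) - d) / len(ref)
        best = max(best, frac)
    return best


def _exon_chain_targets(
    genes: list[SyntheticGene], genome: str, cap_per_gene: int = 4096
) -> list[str]:
    """Sequences of every valid exon chain (first-to-last exon) per gene."""
    targets: list[str] = []
    for gene in genes:
        n_exons = len(gene.exons)
        if n_exons <= 2:
            targets.extend(gene.splice(genome, c) for c in gene.isoforms)
            continue
        middle = list(range(1, n_exons - 1))
        if 2 ** len(middle) > cap_per_gene:
            logger.warning(
                "gene %s: %d exons, too many chains to enumerate; using "
                "annotated isoforms only", gene.gene_id, n_exons,
            )
            targets.extend(gene.splice(genome, c) for c in gene.isoforms)
            continue
        for r in range(len(middle) + 1):
            for combo in itertools.combinations(middle, r):
                targets.append(gene.splice(genome, (0, *combo, n_exons - 1)))
    return targets


def classify_reconstructions(
    results: list[AssembledTranscript],
    expressed: Mapping[str, str],
    annotated: Mapping[str, str],
    genes: list[SyntheticGene],
    genome: str,
    params: Optional[ClassificationParams] = None,
) -> tuple[BenchmarkReport, list[dict]]:
    """Label every reconstruction TP / FPA / FPB and summarise sensitivity.

    Returns the report and a per-result label table (dicts with
    ``transcript_id``, ``label`` and ``match_frac``).
    """
    params = params or ClassificationParams()
    expressed_seqs = list(expressed.values())
    expressed_set = set(expressed_seqs)
    fpa_targets = [s for s in annotated.values() if s not in expressed_set]
    fpa_targets += [
        s for s in _exon_chain_targets(genes, genome)
        if s not in expressed_set
    ]
    # dedupe, preserving order
    fpa_targets = list(dict.fromkeys(fpa_targets))
    fpa_floor = params.fpa_cover_frac * params.fpa_identity

    labels: list[dict] = []
    n_fpa = n_fpb = 0
    for t in results:
        tp_frac = max(
            (_matched_fraction(t.sequence, ref) for ref in expressed_seqs),
            default=0.0,
        )
        if tp_frac >= params.tp_cover_frac:
            label = "TP"
            frac = tp_frac
        else:
            fpa_frac = max(
                (_matched_fraction(t.sequence, target) for target in fpa_targets),
                default=0.0,
            )
            if fpa_frac >= fpa_floor:
                label = "FPA"
                frac = fpa_frac
                n_fpa += 1
            else:
                label = "FPB"
                frac = max(tp_frac, fpa_frac)
                n_fpb += 1
        labels.append(
            {"transcript_id": t.transcript_id, "label": label, "match_frac": frac}
        )

    n_full = n_70 = 0
    for ref in expressed_seqs:
        cov = max((_reference_coverage(ref, t.sequence) for t in results), default=0.0)
        if cov >= params.full_frac:
            n_full += 1
        if cov >= 0.70:
            n_70 += 1

    n_results = len(results)
    n_fp = n_fpa + n_fpb
    s100, s70, fpr = compute_metrics(n_results, n_fp, n_full, n_70, len(expressed_seqs))
    report = BenchmarkReport(
        n_results=n_results, n_refs=len(expressed_seqs), n_fp=n_fp,
        n_fpa=n_fpa, n_fpb=n_fpb, n_full=n_full, n_70=n_70,
        s100=s100, s70=s70, fpr=fpr,
    )
    return report, labels


def compute_metrics(
    n_results: int, n_fp: int, n_full: int, n_70: int, n_refs: int
) -> tuple[float, float, float]:
    """(S100, S70, FPR) as raw percentages; 0/0 is defined as 0.

    S100 = 100 * full-length references / references, S70 likewise at the 70%
    floor, FPR = 100 * false positives / reconstructions.
    """
    if n_fp > n_results:
        raise ValueError("n_fp cannot exceed n_results")
    if not (n_full <= n_70 <= max(n_refs, n_70)):
        raise ValueError("need n_full <= n_70")
    s100 = 100.0 * n_full / n_refs if n_refs else 0.0
    s70 = 100.0 * n_70 / n_refs if n_refs else 0.0
    fpr = 100.0 * n_fp / n_results if n_results else 0.0
    return s100, s70, fpr


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places (printing convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
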