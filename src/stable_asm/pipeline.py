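"""Block-iterative orchestration of the assembler.

To keep memory flat on large inputs the read set is randomly split into
blocks of ``block_size`` sequences; each block is assembled independently
(overlap detection -> graph traversal -> clustering), the merged block
outputs are clustered and become the input of the next iteration — possible
because overlap detection handles variable-length sequences — and iteration
stops once the dataset is smaller than one block, when a final single-block
pass produces the reported transcripts.  The minimum transcript length is
only enforced on that final pass: a short intermediate contig may still be
extended by a later iteration.  Weighting always runs against the original
raw reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .graph_assembly import TraversalParams, build_graph, merge_path, traverse
from .io_encoding import Read, ReadSet, encode_sequence
from .overlap import OverlapParams, find_overlaps
from .postprocess import (
    AssembledTranscript,
    ClusterParams,
    cluster_transcripts,
    weight_transcripts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    #: sequences per block; 0 forces single-block mode
    block_size: int = 50_000
    rng_seed: int = 0
    overlap: OverlapParams = field(default_factory=OverlapParams)
    traversal: TraversalParams = field(default_factory=TraversalParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    #: safety cap on iterations regardless of shrinkage
    max_iterations: int = 20

    def __post_init__(self):
        if self.block_size < 0:
            raise ValueError("block_size must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "block_size": self.block_size,
            "rng_seed": self.rng_seed,
            "max_iterations": self.max_iterations,
            "overlap": vars(self.overlap).copy(),
            "traversal": vars(self.traversal).copy(),
            "cluster": vars(self.cluster).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        overlap = OverlapParams(**d.pop("overlap", {}))
        traversal = TraversalParams(**d.pop("traversal", {}))
        cluster = ClusterParams(**d.pop("cluster", {}))
        return cls(overlap=overlap, traversal=traversal, cluster=cluster, **d)


@dataclass
class IterationState:
    iteration: int
    input_count: int
    output_count: int


@dataclass
class AssemblyResult:
    transcripts: list[AssembledTranscript]
    n_unmapped: int
    iterations: list[IterationState]


def split_blocks(reads: ReadSet, k: int, seed: int) -> list[ReadSet]:
    """Seeded random permutation of the reads, chunked into blocks of <= k."""
    if k < 1:
        raise ValueError("block size must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(reads))
    return [
        ReadSet([reads[int(i)] for i in perm[off : off + k]])
        for off in range(0, len(reads), k)
    ]


def assemble_block(
    block: ReadSet,
    config: Optional[PipelineConfig] = None,
    *,
    min_length: Optional[int] = None,
) -> list[AssembledTranscript]:
    """Assemble one block: overlaps -> graph traversal -> clustering.

    ``min_length`` overrides the traversal's reporting floor (the iterative
    driver passes 0 for intermediate iterations).  Weighting is deferred to
    the driver's final pass.
    """
    config = config or PipelineConfig()
    if not len(block):
        return []
    tparams = (
        config.traversal
        if min_length is None
        else replace(config.traversal, min_length=min_length)
    )
    triples = find_overlaps(block, config.overlap)
    graph = build_graph(len(block), triples)
    paths = traverse(graph, block, tparams)
    logger.info(
        "block: %d reads, %d triples, %d arcs, %d paths",
        len(block), len(triples), graph.n_arcs, len(paths),
    )
    transcripts = [
        AssembledTranscript(f"p{idx}", merge_path(p, graph, block), path=p)
        for idx, p in enumerate(paths)
    ]
    return cluster_transcripts(transcripts, config.cluster)


def _as_readset(transcripts: list[AssembledTranscript]) -> ReadSet:
    return ReadSet(
        [
            Read(t.transcript_id, encode_sequence(t.sequence, record_id=t.transcript_id),
                 source="previous_iteration")
            for t in transcripts
        ]
    )


def run_iterative(
    reads: ReadSet, config: Optional[PipelineConfig] = None
) -> AssemblyResult:
    """Full block-iterative assembly of a read set.

    Single-block mode (block_size 0, or fewer reads than one block) runs
    exactly one assembly pass.  Otherwise each iteration splits the current
    sequence set into blocks with a seeded permutation, assembles them,
    merges and clusters the outputs, and feeds them forward; iteration stops
    when the set fits a single block (final pass, minimum length enforced),
    when two consecutive iterations produce the identical sequence set
    (logged, not an error), or at ``max_iterations``.
    """
    config = config or PipelineConfig()
    states: list[IterationState] = []
    current = reads
    results: list[AssembledTranscript] = []
    prev_sequences: Optional[list[str]] = None

    for iteration in range(config.max_iterations):
        n_in = len(current)
        final = (
            config.block_size == 0
            or n_in < config.block_size
            or iteration == config.max_iterations - 1
        )
        if final:
            results = assemble_block(current, config)
            states.append(IterationState(iteration, n_in, len(results)))
            break
        blocks = split_blocks(current, config.block_size, config.rng_seed + iteration)
        merged: list[AssembledTranscript] = []
        for block in blocks:
            merged.extend(assemble_block(block, config, min_length=0))
        merged = cluster_transcripts(merged, config.cluster)
        states.append(IterationState(iteration, n_in, len(merged)))
        logger.info(
            "iteration %d: %d sequences in, %d out", iteration, n_in, len(merged)
        )
        sequences = sorted(t.sequence for t in merged)
        if prev_sequences is not None and sequences == prev_sequences:
            logger.info("no progress between iterations; stopping")
            results = [
                t for t in merged if len(t.sequence) > config.traversal.min_length
            ]
            break
        prev_sequences = sequences
        current = _as_readset(merged)

    results = [
        replace(t, transcript_id=f"t{idx + 1:06d}") for idx, t in enumerate(results)
    ]
    weighted, unmapped = weight_transcripts(
        results, reads, anchor_len=config.overlap.anchor_len,
        anchor_scope=config.overlap.anchor_scope,
    )
    return AssemblyResult(weighted, unmapped, states)
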