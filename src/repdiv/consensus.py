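"""UMI-based collapsing of reads into per-molecule consensus sequences.

Raw Ig-seq reads are grouped by exact unique-molecular-identifier (UMI)
match, each group is collapsed into a majority-vote consensus, and consensus
sequences with a mean Phred quality of over 20 are retained.  This plays the
error-correction role that MIGEC plays in a full production pipeline, reduced
to the operations the downstream statistics actually require: no 1-mismatch
UMI merging, no paired-read assembly.

Consensus rule: reads whose length differs from the group's modal length are
dropped from voting; at each position the base with most votes wins, ties
broken by the higher summed Phred at that position and then alphabetically.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)


class FastqFormatError(ValueError):
    """Raised for a structurally malformed FASTQ record."""


@dataclasses.dataclass
class UmiGroup:
    umi: str
    reads: List[Tuple[str, str]]  # (sequence, quality string), UMI removed

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclasses.dataclass
class ConsensusSequence:
    umi: str
    seq_nt: str
    support: int
    mean_phred: float


@dataclasses.dataclass
class CollapseStats:
    n_reads: int = 0
    n_groups: int = 0
    n_rejected_small: int = 0
    n_rejected_quality: int = 0
    n_length_outliers: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_groups - self.n_rejected_small - self.n_rejected_quality


_VALID = set("ACGTN")


def _parse_fastq(path: str | Path) -> Iterable[Tuple[str, str, str]]:
    """Yield (header, sequence, quality); raise on malformed records."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FastqFormatError(
            f"{path}: {len(lines)} lines is not a multiple of 4 (truncated record?)"
        )
    for idx in range(0, len(lines), 4):
        rec = idx // 4
        header, seq, plus, qual = lines[idx : idx + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FastqFormatError(f"record {rec}: missing '@'/'+' markers")
        if len(seq) != len(qual):
            raise FastqFormatError(f"record {rec}: sequence and quality lengths differ")
        if set(seq) - _VALID:
            raise FastqFormatError(f"record {rec}: non-ACGTN characters in sequence")
        yield header[1:], seq, qual


def group_by_umi(
    fastq_path: str | Path, umi_start: int = 0, umi_length: int = 14
) -> List[UmiGroup]:
    """Group reads by exact UMI match.

    The UMI occupies ``[umi_start, umi_start + umi_length)`` of each read and
    is stripped; the remainder is the sequence region.  Groups are returned
    in order of first appearance, so the output is deterministic for a given
    input file.
    """
    groups: Dict[str, UmiGroup] = {}
    for rec, (header, seq, qual) in enumerate(_parse_fastq(fastq_path)):
        if len(seq) < umi_start + umi_length:
            raise FastqFormatError(f"record {rec}: read too short to contain the UMI")
        umi = seq[umi_start : umi_start + umi_length]
        body = seq[:umi_start] + seq[umi_start + umi_length :]
        bqual = qual[:umi_start] + qual[umi_start + umi_length :]
        if umi not in groups:
            groups[umi] = UmiGroup(umi=umi, reads=[])
        groups[umi].reads.append((body, bqual))
    return list(groups.values())


def build_consensus(
    group: UmiGroup, min_reads_per_umi: int = 2
) -> Optional[ConsensusSequence]:
    """Collapse one UMI group into a consensus, or ``None`` if under-supported.

    Support is the full group size; reads that are not of the modal length
    are excluded from voting only.  ``mean_phred`` averages the qualities of
    the consensus-supporting bases (reads agreeing with the consensus call
    at each position).
    """
    if min_reads_per_umi < 1:
        raise ValueError("min_reads_per_umi must be >= 1")
    if group.size < min_reads_per_umi:
        return None

    lengths = [len(s) for s, _ in group.reads]
    modal = max(set(lengths), key=lambda l: (lengths.count(l), -l))
    voting = [(s, q) for (s, q), l in zip(group.reads, lengths) if l == modal]

    seqs = np.frombuffer("".join(s for s, _ in voting).encode(), dtype=np.uint8).reshape(
        len(voting), modal
    )
    quals = (
        np.frombuffer("".join(q for _, q in voting).encode(), dtype=np.uint8).reshape(
            len(voting), modal
        )
        - 33
    )

    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    counts = np.stack([(seqs == b).sum(axis=0) for b in alphabet])
    qsums = np.stack([((seqs == b) * quals).sum(axis=0) for b in alphabet])
    # rank by vote count, then summed Phred; argmax over the A<C<G<T<N axis
    # resolves remaining ties alphabetically
    big = quals.sum() + 1
    winner = np.argmax(counts * big + qsums, axis=0)
    cons = alphabet[winner].tobytes().decode()

    supporting = seqs == alphabet[winner][None, :]
    mean_phred = float(quals[supporting].mean()) if supporting.any() else 0.0
    return ConsensusSequence(
        umi=group.umi, seq_nt=cons, support=group.size, mean_phred=mean_phred
    )


def quality_filter(cons: ConsensusSequence, min_mean_phred: float = 20.0) -> bool:
    """Keep a consensus iff its mean Phred is strictly over the threshold."""
    return cons.mean_phred > min_mean_phred


def collapse_fastq(
    fastq_path: str | Path,
    min_reads_per_umi: int = 2,
    min_mean_phred: float = 20.0,
    umi_start: int = 0,
    umi_length: int = 14,
) -> Tuple[List[ConsensusSequence], CollapseStats]:
    """Full collapse: group reads, build consensuses, apply the quality filter."""
    groups = group_by_umi(fastq_path, umi_start=umi_start, umi_length=umi_length)
    stats = CollapseStats(
        n_reads=sum(g.size for g in groups), n_groups=len(groups)
    )
    kept: List[ConsensusSequence] = []
    for g in groups:
        lengths = [len(s) for s, _ in g.reads]
        modal = max(set(lengths), key=lambda l: (lengths.count(l), -l))
        stats.n_length_outliers += sum(1 for l in lengths if l != modal)
        cons = build_consensus(g, min_reads_per_umi=min_reads_per_umi)
        if cons is None:
            stats.n_rejected_small += 1
            continue
        if not quality_filter(cons, min_mean_phred=min_mean_phred):
            stats.n_rejected_quality += 1
            continue
        kept.append(cons)
    logger.info(
        "collapsed %d reads -> %d UMI groups -> %d consensuses "
        "(%d under-supported, %d low quality)",
        stats.n_reads,
        stats.n_groups,
        len(kept),
        stats.n_rejected_small,
        stats.n_rejected_quality,
    )
    return kept, stats


def write_consensus_fasta(
    consensuses: Iterable[ConsensusSequence], path: str | Path
) -> None:
    """FASTA with ``umi=``, ``support=``, ``meanq=`` carried in the header."""
    with open(path, "w") as fh:
        for i, c in enumerate(consensuses):
            fh.write(
                f">c{i} umi={c.umi} support={c.support} meanq={c.mean_phred:.2f}\n"
                f"{c.seq_nt}\n"
            )


def write_rejection_log(stats: CollapseStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for field in dataclasses.fields(stats):
            fh.write(f"{field.name}\t{getattr(stats, field.name)}\n")
        fh.write(f"n_kept\t{stats.n_kept}\n")
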