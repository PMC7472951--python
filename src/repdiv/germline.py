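"""Synthetic germline V/J reference segments.

The analysis needs a germline reference to align against; real analyses use
the IMGT mouse IGH set.  For simulation and testing we generate random but
structurally faithful segments: V genes are in-frame, stop-free, and end
shortly after the conserved Cys codon that opens the CDR3; J genes carry the
conserved Trp codon that closes it, followed by an in-frame linker into the
constant region.  The anchor codon offset is recorded on each segment so
CDR3 extraction has exact coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, List

import numpy as np
from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}
# all 61 sense codons, used to build in-frame, stop-free scaffolds
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_CYS_CODONS = ("TGT", "TGC")
_TRP_CODON = "TGG"


@dataclasses.dataclass(frozen=True)
class GermlineSegment:
    """A named germline V or J gene segment.

    ``anchor_codon`` is the 0-based offset of the conserved CDR3 anchor:
    the 2nd-CYS codon for V segments, the J-TRP codon for J segments.
    """

    name: str
    kind: str  # "V" or "J"
    seq_nt: str
    anchor_codon: int

    def __post_init__(self) -> None:
        if self.kind not in ("V", "J"):
            raise ValueError(f"kind must be 'V' or 'J', got {self.kind!r}")
        if set(self.seq_nt) - set("ACGT"):
            raise ValueError(f"segment {self.name}: non-ACGT characters in sequence")
        if not 0 <= self.anchor_codon <= len(self.seq_nt) - 3:
            raise ValueError(f"segment {self.name}: anchor codon outside sequence")
        aa = str(Seq(self.anchor_seq).translate())
        expected = "C" if self.kind == "V" else "W"
        if aa != expected:
            raise ValueError(
                f"segment {self.name}: anchor codon translates to {aa!r}, expected {expected!r}"
            )

    @property
    def anchor_seq(self) -> str:
        return self.seq_nt[self.anchor_codon : self.anchor_codon + 3]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n))


def _too_similar(a: str, b: str, max_identity: float = 0.8) -> bool:
    if len(a) != len(b):
        return False
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a) > max_identity


def generate_germline_reference(n_v: int, n_j: int, seed: int) -> List[GermlineSegment]:
    """Generate ``n_v`` V and ``n_j`` J segments, deterministically for a seed.

    V segments are 285-300 nt (95-100 codons), in frame from position 0,
    stop-free, with the Cys anchor placed three codons before the end (the
    two trailing codons are the germline-templated start of the CDR3).
    J segments are 45-60 nt (15-20 codons) with 2-4 codons of CDR3 template
    before the Trp anchor and a stop-free linker after it.  Segments of a
    kind are pairwise non-identical (and kept below 80% mutual identity so
    that assignment is unambiguous).
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need at least one V and one J segment")
    rng = np.random.default_rng(seed)
    segments: List[GermlineSegment] = []

    v_seqs: List[str] = []
    for i in range(n_v):
        for _ in range(100):
            n_codons = int(rng.integers(95, 101))  # 285-300 nt
            body = _random_codons(rng, n_codons - 3)
            anchor = str(rng.choice(_CYS_CODONS))
            tail = _random_codons(rng, 2)
            seq = body + anchor + tail
            if all(not _too_similar(seq, other) and seq != other for other in v_seqs):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not generate a dissimilar V segment (seed={seed})")
        v_seqs.append(seq)
        segments.append(
            GermlineSegment(name=f"IGHV1-S{i + 1}", kind="V", seq_nt=seq, anchor_codon=len(seq) - 9)
        )

    j_seqs: List[str] = []
    for i in range(n_j):
        for _ in range(100):
            n_codons = int(rng.integers(15, 21))  # 45-60 nt
            n_head = int(rng.integers(2, 5))  # CDR3-templated codons before Trp
            head = _random_codons(rng, n_head)
            linker = _random_codons(rng, n_codons - n_head - 1)
            seq = head + _TRP_CODON + linker
            if all(not _too_similar(seq, other) and seq != other for other in j_seqs):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not generate a dissimilar J segment (seed={seed})")
        j_seqs.append(seq)
        segments.append(
            GermlineSegment(name=f"IGHJ{i + 1}", kind="J", seq_nt=seq, anchor_codon=3 * n_head)
        )

    return segments


def write_germline_fasta(segments: Iterable[GermlineSegment], path: str | Path) -> None:
    """Write segments as FASTA with ``>NAME|KIND|anchor=NN`` headers."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.name}|{seg.kind}|anchor={seg.anchor_codon}\n{seg.seq_nt}\n")


def read_germline_fasta(path: str | Path) -> List[GermlineSegment]:
    """Read a structured germline FASTA written by :func:`write_germline_fasta`."""
    from Bio import SeqIO

    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            name, kind, anchor_field = rec.id.split("|")
            anchor = int(anchor_field.removeprefix("anchor="))
        except ValueError as exc:
            raise ValueError(
                f"malformed germline header {rec.id!r}; expected NAME|KIND|anchor=NN"
            ) from exc
        segments.append(
            GermlineSegment(name=name, kind=kind, seq_nt=str(rec.seq).upper(), anchor_codon=anchor)
        )
    return segments
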