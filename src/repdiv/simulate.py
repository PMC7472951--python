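"""Ground-truth repertoire, read and spectratype simulation.

The simulator emulates the generative structure that the downstream analysis
assumes for immunized-mouse spleen Ig-seq samples: a set of activated naive
B-cell clones (each a V segment + non-templated junction insert + J segment,
productive by construction), clonal expansion under a configurable clone-size
law, somatic hypermutation as independent per-base substitutions, mRNA
sampling, 14-nt UMI tagging, and per-base sequencing errors with matching
Phred qualities.  Every molecule carries ground-truth labels (ancestor,
mutation positions, CDR3) so each pipeline stage can be checked exactly.

Reads are simulated single-end over the full variable region; the UMI
occupies the first ``umi_length`` bases of each read and the molecule
sequence follows immediately.  Ground-truth labels ride only in the FASTQ
header comment (after the first whitespace) — analysis stages never read
them.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from repdiv.germline import GermlineSegment

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default per-base somatic hypermutation rates by isotype.  IgG transcripts
#: come from class-switched, affinity-matured cells and carry substantially
#: more V-region mutations than IgM.
DEFAULT_SHM_RATE = {"IgG": 0.015, "IgM": 0.003}


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one simulated sample.

    Defaults describe a typical immunized-mouse plasma-cell IgG sample at
    the moderate sequencing depth this analysis targets: a few hundred
    activated naive clones, geometric clone-size skew, IgG-level SHM,
    ~Q30 sequencing error, and 14-nt UMIs.
    """

    n_naive_clones: int = 250
    clone_size_law: str = "geometric"  # uniform | geometric | power_law
    clone_size_param: float = 0.98  # geometric ratio, or power-law exponent
    shm_rate: Optional[float] = None  # default resolved from isotype
    isotype: str = "IgG"
    n_molecules: int = 800
    reads_per_molecule: int = 3
    seq_error_rate: float = 0.001
    umi_length: int = 14
    seed: int = 0
    min_cdr3_aa_hamming: int = 0  # enforce ancestor CDR3 separation (0 = off)

    def __post_init__(self) -> None:
        if self.isotype not in ("IgG", "IgM"):
            raise ValueError("isotype must be IgG or IgM")
        if self.shm_rate is None:
            self.shm_rate = DEFAULT_SHM_RATE[self.isotype]
        if not 0 <= self.shm_rate < 1:
            raise ValueError("shm_rate must be in [0, 1)")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        if self.n_naive_clones > self.n_molecules:
            raise ValueError("n_naive_clones cannot exceed n_molecules")
        if self.clone_size_law not in ("uniform", "geometric", "power_law"):
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")
        if self.reads_per_molecule < 1:
            raise ValueError("reads_per_molecule must be >= 1")


@dataclasses.dataclass(frozen=True)
class Ancestor:
    """A naive-clone founder sequence with its construction coordinates."""

    ancestor_id: int
    seq_nt: str
    v_name: str
    j_name: str
    v_len: int
    junction_len: int
    j_len: int
    cdr3_start: int  # first nt after the V Cys anchor codon
    cdr3_end: int  # first nt of the J Trp anchor codon

    @property
    def cdr3_nt(self) -> str:
        return self.seq_nt[self.cdr3_start : self.cdr3_end]


@dataclasses.dataclass(frozen=True)
class Molecule:
    """One sampled mRNA molecule with full ground truth."""

    molecule_id: int
    seq_nt: str
    ancestor_id: int
    v_name: str
    j_name: str
    cdr3_nt: str
    n_mutations: int
    mutation_positions: Tuple[int, ...]
    n_v_mutations: int  # mutations inside the templated V region
    n_j_mutations: int  # mutations inside the templated J region


@dataclasses.dataclass
class TrueRepertoire:
    """Simulator ground truth for one sample."""

    molecules: List[Molecule]
    ancestors: Dict[int, Ancestor]
    clone_sizes: Dict[int, int]
    config: SimulationConfig

    def __post_init__(self) -> None:
        assert sum(self.clone_sizes.values()) == len(self.molecules)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Largest-remainder (Hamilton) rounding: floor the quotas, then hand the
    leftover units to the largest fractional remainders (ties to the lower
    index).  Used so that e.g. a uniform law over 4 clones and 100 molecules
    yields exactly 25 each.
    """
    quotas = weights / weights.sum() * total
    sizes = np.floor(quotas).astype(int)
    remainder = total - sizes.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - sizes), kind="stable")
        sizes[order[:remainder]] += 1
    return sizes


def _clone_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    k, n = config.n_naive_clones, config.n_molecules
    if config.clone_size_law == "uniform":
        weights = np.ones(k)
    elif config.clone_size_law == "geometric":
        r = config.clone_size_param
        weights = r ** np.arange(k, dtype=float)
    else:  # power_law
        alpha = config.clone_size_param
        weights = (np.arange(k, dtype=float) + 1.0) ** (-alpha)
    # every clone gets at least one molecule; the remainder follows the law
    sizes = np.ones(k, dtype=int) + _largest_remainder(weights, n - k)
    assert sizes.sum() == n
    return sizes


_JUNCTION_LENGTHS = np.array([0, 3, 6, 9, 12])
_JUNCTION_WEIGHTS = np.array([0.04, 0.10, 0.30, 0.36, 0.20])


def _junction_length(rng: np.random.Generator) -> int:
    """Draw a junction insert length in 0-12 nt, biased to multiples of 3.

    90% of draws land on {0,3,6,9,12} with weights peaking around 6-9 nt:
    TdT N-additions average a handful of nucleotides and empty junctions
    are uncommon, while selection for productive rearrangements favours
    in-frame inserts.  (Out-of-frame draws are rejected downstream by the
    productivity retry loop anyway; the bias just makes retries rare.)
    """
    if rng.random() < 0.9:
        return int(rng.choice(_JUNCTION_LENGTHS, p=_JUNCTION_WEIGHTS))
    return int(rng.integers(0, 13))


def _make_ancestor(
    ancestor_id: int,
    v_segs: Sequence[GermlineSegment],
    j_segs: Sequence[GermlineSegment],
    rng: np.random.Generator,
    existing_cdr3_aa: List[str],
    min_sep: int,
    seed: int,
    max_tries: int = 200,
) -> Ancestor:
    for _ in range(max_tries):
        v = v_segs[int(rng.integers(len(v_segs)))]
        j = j_segs[int(rng.integers(len(j_segs)))]
        jl = _junction_length(rng)
        junction = "".join(np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, jl)].astype(str))
        seq = v.seq_nt + junction + j.seq_nt
        cdr3_start = v.anchor_codon + 3
        cdr3_end = len(v.seq_nt) + jl + j.anchor_codon
        cdr3 = seq[cdr3_start:cdr3_end]
        if len(cdr3) % 3 != 0:
            continue
        if "*" in Seq(seq[: len(seq) - len(seq) % 3]).translate():
            continue
        cdr3_aa = str(Seq(cdr3).translate())
        if min_sep > 0 and any(
            len(prev) == len(cdr3_aa)
            and sum(a != b for a, b in zip(prev, cdr3_aa)) < min_sep
            for prev in existing_cdr3_aa
        ):
            continue
        existing_cdr3_aa.append(cdr3_aa)
        return Ancestor(
            ancestor_id=ancestor_id,
            seq_nt=seq,
            v_name=v.name,
            j_name=j.name,
            v_len=len(v.seq_nt),
            junction_len=jl,
            j_len=len(j.seq_nt),
            cdr3_start=cdr3_start,
            cdr3_end=cdr3_end,
        )
    raise RuntimeError(
        f"failed to build a productive ancestor after {max_tries} tries (seed={seed})"
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> Tuple[str, np.ndarray]:
    """Apply iid per-base substitutions at ``rate``; return (sequence, positions)."""
    if rate == 0:
        return seq, np.empty(0, dtype=int)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # substitute with one of the three other bases, uniformly
        for pos in hits:
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = choices[int(rng.integers(3))]
    return arr.tobytes().decode(), hits


def simulate_repertoire(
    germline: Sequence[GermlineSegment], config: SimulationConfig
) -> TrueRepertoire:
    """Simulate a sample's molecules with full ground truth.

    Draws ``n_naive_clones`` productive ancestors, assigns clone sizes under
    the configured law (largest-remainder rounding, minimum one molecule per
    clone), and derives each molecule from its ancestor by substitution-only
    SHM at ``shm_rate`` per base.
    """
    v_segs = [s for s in germline if s.kind == "V"]
    j_segs = [s for s in germline if s.kind == "J"]
    if not v_segs or not j_segs:
        raise ValueError("germline must contain at least one V and one J segment")
    rng = np.random.default_rng(config.seed)

    ancestors: Dict[int, Ancestor] = {}
    seen_seqs = set()
    cdr3_pool: List[str] = []
    for aid in range(config.n_naive_clones):
        while True:
            anc = _make_ancestor(
                aid, v_segs, j_segs, rng, cdr3_pool, config.min_cdr3_aa_hamming, config.seed
            )
            if anc.seq_nt not in seen_seqs:
                break
        seen_seqs.add(anc.seq_nt)
        ancestors[aid] = anc

    sizes = _clone_sizes(config, rng)
    molecules: List[Molecule] = []
    mid = 0
    for aid, size in enumerate(sizes):
        anc = ancestors[aid]
        for _ in range(size):
            seq, positions = _mutate(anc.seq_nt, config.shm_rate, rng)
            n_v = int(np.count_nonzero(positions < anc.v_len))
            n_j = int(np.count_nonzero(positions >= anc.v_len + anc.junction_len))
            molecules.append(
                Molecule(
                    molecule_id=mid,
                    seq_nt=seq,
                    ancestor_id=aid,
                    v_name=anc.v_name,
                    j_name=anc.j_name,
                    cdr3_nt=seq[anc.cdr3_start : anc.cdr3_end],
                    n_mutations=int(positions.size),
                    mutation_positions=tuple(int(p) for p in positions),
                    n_v_mutations=n_v,
                    n_j_mutations=n_j,
                )
            )
            mid += 1

    return TrueRepertoire(
        molecules=molecules,
        ancestors=ancestors,
        clone_sizes={aid: int(s) for aid, s in enumerate(sizes)},
        config=config,
    )


def _phred_string(n: int, error_rate: float, rng: np.random.Generator) -> Tuple[str, np.ndarray]:
    """Per-base qualities consistent with the simulated error rate.

    The nominal quality is -10 log10(rate) (capped at Q40 for error-free
    simulation) with small integer jitter, so a run at rate r produces
    consensus mean-Phred values centred on the corresponding Q.
    """
    nominal = 40.0 if error_rate <= 0 else min(40.0, -10.0 * np.log10(error_rate))
    quals = np.clip(np.rint(rng.normal(nominal, 2.0, size=n)), 2, 41).astype(int)
    return "".join(chr(q + 33) for q in quals), quals


def simulate_reads(
    rep: TrueRepertoire, config: SimulationConfig, out: str | Path
) -> int:
    """Write UMI-tagged FASTQ reads for every molecule; return the read count.

    Each molecule receives a distinct random UMI (collisions are redrawn and
    logged).  Read layout: ``UMI (umi_length nt) + molecule sequence``.  The
    UMI field itself is emitted error-free — exact-match UMI grouping is the
    documented contract of the consensus stage — while the sequence region
    gets independent per-base substitutions at ``seq_error_rate``.
    """
    rng = np.random.default_rng(config.seed + 1 if config.seed is not None else None)
    n_mol = len(rep.molecules)
    umis: List[str] = []
    seen = set()
    collisions = 0
    for _ in range(n_mol):
        while True:
            umi = "".join(
                np.frombuffer(b"ACGT", dtype="S1")[
                    rng.integers(0, 4, config.umi_length)
                ].astype(str)
            )
            if umi not in seen:
                break
            collisions += 1
        seen.add(umi)
        umis.append(umi)
    if collisions:
        logger.info("redrew %d colliding UMIs", collisions)

    n_reads = 0
    with open(out, "w") as fh:
        for mol, umi in zip(rep.molecules, umis):
            for r in range(config.reads_per_molecule):
                seq, _ = _mutate(mol.seq_nt, config.seq_error_rate, rng)
                qual_seq, _ = _phred_string(len(seq), config.seq_error_rate, rng)
                qual_umi, _ = _phred_string(config.umi_length, 0.0, rng)
                fh.write(
                    f"@r{n_reads} mol={mol.molecule_id} anc={mol.ancestor_id}\n"
                    f"{umi}{seq}\n+\n{qual_umi}{qual_seq}\n"
                )
                n_reads += 1
    return n_reads


def write_ground_truth(rep: TrueRepertoire, path: str | Path) -> None:
    """Tab-separated ground-truth table (one row per molecule)."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tancestor_id\tv_name\tj_name\tcdr3_nt\tn_mutations\n")
        for m in rep.molecules:
            fh.write(
                f"{m.molecule_id}\t{m.ancestor_id}\t{m.v_name}\t{m.j_name}\t"
                f"{m.cdr3_nt}\t{m.n_mutations}\n"
            )


def truth_annotations(rep: TrueRepertoire):
    """Annotation records read directly off the ground truth (oracle view).

    Bypasses consensus and alignment entirely: every molecule becomes an
    annotation with its recorded V/J origin, CDR3 and templated mutation
    counts.  Molecules whose mutated CDR3 is out of frame or encodes a stop
    are dropped, mirroring the productive-only convention downstream.
    Useful for simulator-consistency checks and statistics-path studies
    that do not exercise the read-level stages.
    """
    from repdiv.annotate import AnnotatedSequence

    out = []
    for m in rep.molecules:
        if len(m.cdr3_nt) % 3 != 0:
            continue
        aa = str(Seq(m.cdr3_nt).translate())
        if not aa or "*" in aa:
            continue
        out.append(
            AnnotatedSequence(
                sequence_id=f"m{m.molecule_id}",
                seq_nt=m.seq_nt,
                v_call=m.v_name,
                j_call=m.j_name,
                v_identity=1.0 if m.n_v_mutations == 0 else 0.0,
                j_identity=1.0 if m.n_j_mutations == 0 else 0.0,
                n_v_mutations=m.n_v_mutations,
                cdr3_nt=m.cdr3_nt,
                cdr3_aa=aa,
                productive=True,
            )
        )
    return out


def default_primer_offsets(
    germline: Sequence[GermlineSegment], base: int = 100
) -> Dict[str, int]:
    """Deterministic per-V primer offsets placing amplicons in ~430-545 bp.

    The offset models everything the fragment analyzer sees beyond the
    variable region itself (5' primer landing, constant-region stub, dye);
    V genes get slightly different offsets, as framework-1 primers do.
    """
    v_names = sorted(s.name for s in germline if s.kind == "V")
    return {name: base + 4 * (i % 10) for i, name in enumerate(v_names)}


def simulate_spectratype(
    rep: TrueRepertoire, primer_offsets: Mapping[str, int]
):
    """Fragment-length peak table of a repertoire's amplicons.

    Each molecule's amplicon length is its variable-region length plus the
    V-specific primer offset; identical lengths merge into one peak whose
    area is the molecule count.
    """
    from repdiv.spectratype import PeakTable

    counts: Dict[int, float] = {}
    for mol in rep.molecules:
        try:
            offset = primer_offsets[mol.v_name]
        except KeyError:
            raise KeyError(f"no primer offset for V gene {mol.v_name!r}") from None
        length = len(mol.seq_nt) + int(offset)
        counts[length] = counts.get(length, 0.0) + 1.0
    peaks = sorted(counts.items())
    return PeakTable(sample_id=f"sim-seed{rep.config.seed}", peaks=peaks)
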