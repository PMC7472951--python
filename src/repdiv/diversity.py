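"""Clonotype construction and repertoire diversity statistics.

Clone definitions
-----------------
* ``CDR3``  — sequences sharing a CDR3 amino-acid sequence are one clone;
* ``CDR3VJ`` — CDR3 amino-acid sequence plus V and J gene call;
* ``NT``   — full nucleotide sequence (the finest partition).

These are nested: the NT partition refines CDR3VJ, which refines CDR3, so
clone richness satisfies n_cdr3 <= n_cdr3vj <= n_distinct_nt on any sample.

Summary statistics
------------------
* large (dominant) clones: nucleotide-level clones whose frequency strictly
  exceeds 0.5% of the sample's molecules;
* VJ100: distinct nucleotide sequences with zero deviation from germline in
  the templated V and J regions (the non-templated junction is free to
  differ) — a proxy for naive-derived, unmutated molecules;
* Shannon index H = -sum p_i ln p_i (natural log) and inverse Simpson
  D = 1 / sum p_i^2, the ecology-derived evenness-sensitive indices;
* CDR3 amino-acid length spectrum with a normality test (Shapiro-Wilk by
  default);
* V/J gene usage fractions.

Abundances are counted in UMI-collapsed molecules, not raw reads — the UMI
stage exists precisely to remove PCR amplification bias from these counts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from repdiv.annotate import AnnotatedSequence

DEFINITIONS = ("CDR3", "CDR3VJ", "NT")


@dataclasses.dataclass
class ClonotypeTable:
    """Partition of a sample's molecules under one clone definition."""

    definition: str
    counts: Dict[object, int]  # clone key -> molecule count
    total_molecules: int

    def __post_init__(self) -> None:
        if self.definition not in DEFINITIONS:
            raise ValueError(f"unknown clone definition {self.definition!r}")
        assert sum(self.counts.values()) == self.total_molecules

    @property
    def richness(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        if self.total_molecules == 0:
            return np.empty(0)
        return np.asarray(list(self.counts.values()), dtype=float) / self.total_molecules


def build_clonotypes(
    seqs: Sequence[AnnotatedSequence], definition: str
) -> ClonotypeTable:
    """Aggregate molecules into clones under the chosen definition.

    Molecule counts come from ``duplicate_count`` (UMI-collapsed molecules
    per distinct sequence).  Empty input gives an empty table of richness 0.
    """
    counts: Dict[object, int] = {}
    total = 0
    for s in seqs:
        if definition == "CDR3":
            key: object = s.cdr3_aa
        elif definition == "CDR3VJ":
            key = (s.cdr3_aa, s.v_call, s.j_call)
        elif definition == "NT":
            key = s.seq_nt
        else:
            raise ValueError(f"unknown clone definition {definition!r}")
        counts[key] = counts.get(key, 0) + s.duplicate_count
        total += s.duplicate_count
    return ClonotypeTable(definition=definition, counts=counts, total_molecules=total)


def count_large_clones(nt_table: ClonotypeTable, threshold: float = 0.005) -> int:
    """Clones whose frequency strictly exceeds ``threshold`` (default 0.5%).

    The dominance rule is strict ("exceeded"): a clone at exactly the
    threshold does not count.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if nt_table.definition != "NT":
        raise ValueError("large clones are defined on the nucleotide-level table")
    total = nt_table.total_molecules
    if total == 0:
        return 0
    return sum(1 for c in nt_table.counts.values() if c / total > threshold)


def count_vj100(seqs: Sequence[AnnotatedSequence]) -> int:
    """Distinct nucleotide sequences with 100% germline V and J identity.

    Junction (CDR3) variation is allowed — it is non-templated, so an
    unmutated naive-derived molecule can still carry any junction.
    """
    distinct = {
        s.seq_nt
        for s in seqs
        if s.v_identity == 1.0 and s.j_identity == 1.0
    }
    return len(distinct)


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("negative frequencies")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def shannon_index(freqs) -> float:
    """Shannon diversity H = -sum p ln p, natural log, with 0 ln 0 := 0."""
    p = _check_freqs(freqs)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inverse_simpson(freqs) -> float:
    """Inverse Simpson concentration D = 1 / sum p^2."""
    p = _check_freqs(freqs)
    return float(1.0 / (p**2).sum())


@dataclasses.dataclass
class Cdr3LengthSummary:
    histogram: Dict[int, int]  # CDR3 aa length -> molecule count
    test_name: str
    statistic: Optional[float]
    pvalue: Optional[float]
    applicable: bool

    @property
    def total(self) -> int:
        return sum(self.histogram.values())


def cdr3_length_summary(
    seqs: Sequence[AnnotatedSequence], test: str = "shapiro"
) -> Cdr3LengthSummary:
    """CDR3 amino-acid length spectrum plus a normality test.

    The histogram weights each distinct sequence by its molecule count.
    The test (Shapiro-Wilk by default, D'Agostino via ``test='normaltest'``)
    runs on the per-molecule length sample; it is reported not-applicable
    for degenerate input (all lengths equal, or fewer than 3 molecules).
    """
    hist: Dict[int, int] = {}
    lengths: List[int] = []
    for s in seqs:
        L = len(s.cdr3_aa)
        hist[L] = hist.get(L, 0) + s.duplicate_count
        lengths.extend([L] * s.duplicate_count)
    if len(lengths) < 3 or len(set(lengths)) == 1:
        return Cdr3LengthSummary(hist, test, None, None, applicable=False)
    if test == "shapiro":
        stat, p = sps.shapiro(lengths)
    elif test == "normaltest":
        stat, p = sps.normaltest(lengths)
    else:
        raise ValueError(f"unknown normality test {test!r}")
    return Cdr3LengthSummary(hist, test, float(stat), float(p), applicable=True)


def gene_usage(
    seqs: Sequence[AnnotatedSequence],
) -> Tuple[pd.Series, pd.Series]:
    """Molecule-weighted V and J gene usage fractions (each sums to 1)."""
    v: Dict[str, int] = {}
    j: Dict[str, int] = {}
    for s in seqs:
        v[s.v_call] = v.get(s.v_call, 0) + s.duplicate_count
        j[s.j_call] = j.get(s.j_call, 0) + s.duplicate_count
    v_frac = pd.Series(v, dtype=float).sort_index()
    j_frac = pd.Series(j, dtype=float).sort_index()
    return v_frac / v_frac.sum(), j_frac / j_frac.sum()


def subsample_molecules(
    table: ClonotypeTable, n: int, rng: np.random.Generator
) -> ClonotypeTable:
    """Rarefaction helper (extension, not used by default reports): draw
    ``n`` molecules without replacement and rebuild the clone table."""
    if n > table.total_molecules:
        raise ValueError("cannot subsample more molecules than present")
    keys = list(table.counts)
    pool = np.repeat(np.arange(len(keys)), [table.counts[k] for k in keys])
    chosen = rng.choice(pool, size=n, replace=False)
    counts: Dict[object, int] = {}
    for idx in chosen:
        counts[keys[idx]] = counts.get(keys[idx], 0) + 1
    return ClonotypeTable(definition=table.definition, counts=counts, total_molecules=n)


@dataclasses.dataclass
class DiversityReport:
    """Per-sample diversity battery (the five headline measures plus indices)."""

    sample_id: str
    group: str = ""
    isotype: str = ""
    cell_type: str = ""
    n_molecules: int = 0
    n_distinct_nt: int = 0
    n_cdr3: int = 0
    n_cdr3vj: int = 0
    n_large_clones: int = 0
    n_vj100: int = 0
    n_clusters: int = -1  # filled by the network stage; -1 = not computed
    shannon: float = math.nan
    inv_simpson: float = math.nan

    MEASURES = (
        "n_cdr3",
        "n_cdr3vj",
        "n_clusters",
        "n_vj100",
        "n_large_clones",
        "shannon",
        "inv_simpson",
    )

    def to_dict(self) -> Dict[str, object]:
        return dataclasses.asdict(self)


def summarize_sample(
    seqs: Sequence[AnnotatedSequence],
    sample_id: str = "sample",
    group: str = "",
    isotype: str = "",
    cell_type: str = "",
    large_clone_threshold: float = 0.005,
) -> DiversityReport:
    """Compute the diversity battery for one sample's annotated sequences.

    Shannon and inverse Simpson are computed on nucleotide-level clone
    frequencies (the finest partition, hence the most conservative evenness
    measure).  ``n_clusters`` is left unset; the network stage fills it.
    """
    nt = build_clonotypes(seqs, "NT")
    cdr3 = build_clonotypes(seqs, "CDR3")
    cdr3vj = build_clonotypes(seqs, "CDR3VJ")
    report = DiversityReport(
        sample_id=sample_id,
        group=group,
        isotype=isotype,
        cell_type=cell_type,
        n_molecules=nt.total_molecules,
        n_distinct_nt=nt.richness,
        n_cdr3=cdr3.richness,
        n_cdr3vj=cdr3vj.richness,
        n_large_clones=count_large_clones(nt, threshold=large_clone_threshold),
        n_vj100=count_vj100(seqs),
    )
    if nt.total_molecules > 0:
        report.shannon = shannon_index(nt.frequencies)
        report.inv_simpson = inverse_simpson(nt.frequencies)
    return report


def write_report(report: DiversityReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def reports_to_frame(reports: Sequence[DiversityReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
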