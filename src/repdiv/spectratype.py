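"""Spectratype (fragment length distribution) analysis.

Capillary-electrophoresis spectratyping resolves amplified heavy-chain
variable regions by length; each distinct fragment length is a peak whose
area is proportional to abundance.  This module reads Peak Scanner-style
CSV exports (columns ``length_bp,area``), counts peak richness, compares
groups by unique/common peak sets, and summarizes peak distributions with
the same Shannon and inverse Simpson indices used for clonotypes.

Abundance proxy: peak area (the conventional choice); pass height data in
the ``area`` column if height is preferred.  Lengths are assumed already
rounded to integer bp; a binning tolerance is available for fractional
inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd

from repdiv.diversity import inverse_simpson, shannon_index

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PeakTable:
    """One sample's spectratype: (length_bp, area) peaks, lengths unique."""

    sample_id: str
    peaks: List[Tuple[int, float]]

    def __post_init__(self) -> None:
        lengths = [l for l, _ in self.peaks]
        if len(lengths) != len(set(lengths)):
            raise ValueError(f"{self.sample_id}: duplicate peak lengths")
        if any(a < 0 for _, a in self.peaks):
            raise ValueError(f"{self.sample_id}: negative peak area")
        self.peaks = sorted(self.peaks)

    @property
    def lengths(self) -> Set[int]:
        return {l for l, _ in self.peaks}

    @property
    def total_area(self) -> float:
        return sum(a for _, a in self.peaks)


def read_peak_table(
    path: str | Path,
    sample_id: str | None = None,
    noise_floor: float = 0.0,
    bin_tolerance: float = 0.0,
) -> PeakTable:
    """Read a ``length_bp,area`` CSV into a :class:`PeakTable`.

    Duplicate lengths are merged by summing area (logged); rows with area
    at or below ``noise_floor`` (after merging) are dropped and counted.
    ``bin_tolerance`` > 0 rounds fractional lengths to the nearest integer
    before merging (for raw fragment-analyzer exports).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("length_bp", "area") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty peak table", path)
        return PeakTable(sample_id=sample_id or str(path), peaks=[])
    lengths = pd.to_numeric(df["length_bp"], errors="raise")
    areas = pd.to_numeric(df["area"], errors="raise")
    if (areas < 0).any():
        raise ValueError(f"{path}: negative peak area")
    if bin_tolerance > 0:
        lengths = lengths.round()
    if (lengths % 1 != 0).any():
        raise ValueError(
            f"{path}: fractional length_bp values; set bin_tolerance > 0 to round"
        )
    merged: Dict[int, float] = {}
    for l, a in zip(lengths.astype(int), areas.astype(float)):
        merged[l] = merged.get(l, 0.0) + a
    n_dup = len(df) - len(merged)
    if n_dup:
        logger.info("%s: merged %d duplicate-length rows", path, n_dup)
    kept = {l: a for l, a in merged.items() if a > noise_floor}
    n_noise = len(merged) - len(kept)
    if n_noise:
        logger.info("%s: dropped %d peaks at/below noise floor %g", path, n_noise, noise_floor)
    return PeakTable(sample_id=sample_id or str(path), peaks=sorted(kept.items()))


def peak_richness(table: PeakTable) -> int:
    """Number of distinct peak lengths in the table."""
    return len(table.peaks)


def pool_peak_tables(tables: Sequence[PeakTable], sample_id: str = "pooled") -> PeakTable:
    """Pool samples: union of lengths, areas summed per length."""
    merged: Dict[int, float] = {}
    for t in tables:
        for l, a in t.peaks:
            merged[l] = merged.get(l, 0.0) + a
    return PeakTable(sample_id=sample_id, peaks=sorted(merged.items()))


def unique_and_common_peaks(
    group_a: Sequence[PeakTable], group_b: Sequence[PeakTable]
) -> Tuple[int, int, int]:
    """(n_unique_a, n_unique_b, n_common) between two groups' pooled peak sets.

    Each group's peak set is the union of its members' lengths; by
    construction n_unique_x + n_common equals the group's pooled richness
    (asserted).
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    set_a: Set[int] = set().union(*(t.lengths for t in group_a))
    set_b: Set[int] = set().union(*(t.lengths for t in group_b))
    common = set_a & set_b
    n_unique_a = len(set_a - set_b)
    n_unique_b = len(set_b - set_a)
    assert n_unique_a + len(common) == len(set_a)
    assert n_unique_b + len(common) == len(set_b)
    return n_unique_a, n_unique_b, len(common)


def spectratype_diversity(table: PeakTable) -> Tuple[float, float]:
    """(Shannon, inverse Simpson) of the peak area distribution."""
    total = table.total_area
    if total <= 0 or not table.peaks:
        raise ValueError(f"{table.sample_id}: no positive peak area")
    freqs = [a / total for _, a in table.peaks]
    return shannon_index(freqs), inverse_simpson(freqs)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    pd.DataFrame(table.peaks, columns=["length_bp", "area"]).to_csv(path, index=False)


def spectratype_summary(tables: Sequence[PeakTable]) -> pd.DataFrame:
    """Per-sample richness and diversity indices as a tidy frame."""
    rows = []
    for t in tables:
        shannon, inv_simp = spectratype_diversity(t)
        rows.append(
            {
                "sample_id": t.sample_id,
                "richness": peak_richness(t),
                "shannon": shannon,
                "inv_simpson": inv_simp,
            }
        )
    return pd.DataFrame(rows)
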