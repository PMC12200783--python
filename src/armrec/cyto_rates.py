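"""Genome-wide recombination rates from MLH1-focus counts.

Each MLH1 focus on a pachytene bivalent marks one reciprocal crossover, and
one crossover corresponds to 50 cM of genetic map. A species' genome-wide
genetic map length is therefore ``mean foci per cell x 50`` cM, and its
recombination rate is that map length divided by the physical genome size in
Mbp. Genome sizes given as C-values (pg of DNA) convert to Mbp with the
standard factor 978 Mbp/pg.

Foci are counted on autosomal bivalents only: the XY pair recombines under a
different double-strand-break dynamic and is excluded, so the haploid
autosome number of an XY male is ``(2n - 2) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PG_TO_MBP",
    "CellRecord",
    "CrossSpeciesReport",
    "GenomeSize",
    "Karyotype",
    "SpeciesSummary",
    "cross_species_summary",
    "map_length_cm",
    "pg_to_mbp",
    "rate_cm_per_mb",
    "round_half_up",
    "summarize_species",
    "table1_frame",
    "table2_frame",
]

#: megabase pairs per picogram of DNA
PG_TO_MBP = 978.0

#: centimorgans of genetic map per crossover (one focus = one exchange = 50 cM)
CM_PER_CROSSOVER = 50.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (reporting-boundary convention)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CellRecord:
    """One pachytene spermatocyte's autosomal MLH1-focus counts.

    ``per_bivalent_foci``, when present, holds one count per autosomal
    bivalent and must sum to ``foci_total``.
    """

    species_id: str
    animal_id: str
    cell_id: str
    foci_total: int
    per_bivalent_foci: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.foci_total < 0 or int(self.foci_total) != self.foci_total:
            raise ValueError(
                f"cell {self.cell_id}: foci_total must be a non-negative integer"
            )
        if self.per_bivalent_foci is not None:
            pb = tuple(int(v) for v in self.per_bivalent_foci)
            if any(v < 0 for v in pb):
                raise ValueError(f"cell {self.cell_id}: negative per-bivalent count")
            if sum(pb) != self.foci_total:
                raise ValueError(
                    f"cell {self.cell_id}: per-bivalent counts sum to {sum(pb)}, "
                    f"foci_total is {self.foci_total}"
                )
            object.__setattr__(self, "per_bivalent_foci", pb)


@dataclass(frozen=True)
class Karyotype:
    """Chromosome complement of a species as seen from an XY male meiosis.

    ``autosome_haploid_aN2`` is the haploid autosome count (2n - 2)/2 and
    ``arm_haploid_aFN2`` the haploid number of autosomal chromosome arms
    (the autosomal fundamental-number basis).
    """

    species_id: str
    diploid_2n: int
    autosome_haploid_aN2: int
    arm_haploid_aFN2: int

    def __post_init__(self) -> None:
        if self.diploid_2n % 2 != 0 or self.diploid_2n < 4:
            raise ValueError(
                f"{self.species_id}: diploid number {self.diploid_2n} must be even and >= 4"
            )
        if self.autosome_haploid_aN2 != (self.diploid_2n - 2) // 2:
            raise ValueError(
                f"{self.species_id}: aN/2 must equal (2n - 2)/2 for an XY male"
            )
        if self.arm_haploid_aFN2 < self.autosome_haploid_aN2:
            raise ValueError(
                f"{self.species_id}: arm number aFN/2 ({self.arm_haploid_aFN2}) cannot be "
                f"smaller than chromosome number aN/2 ({self.autosome_haploid_aN2})"
            )

    @classmethod
    def from_counts(cls, species_id: str, diploid_2n: int, arm_haploid_aFN2: int) -> "Karyotype":
        """Build from 2n and aFN/2, deriving aN/2 = (2n - 2)/2."""
        if diploid_2n % 2 != 0:
            raise ValueError(f"{species_id}: odd diploid number {diploid_2n}")
        return cls(
            species_id=species_id,
            diploid_2n=diploid_2n,
            autosome_haploid_aN2=(diploid_2n - 2) // 2,
            arm_haploid_aFN2=arm_haploid_aFN2,
        )


@dataclass(frozen=True)
class GenomeSize:
    """Physical genome size, in Mbp and optionally as a C-value in pg."""

    species_id: str
    size_mbp: float
    c_value_pg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size_mbp <= 0:
            raise ValueError(f"{self.species_id}: genome size must be positive")

    @classmethod
    def from_pg(cls, species_id: str, c_value_pg: float) -> "GenomeSize":
        return cls(species_id=species_id, size_mbp=pg_to_mbp(c_value_pg), c_value_pg=c_value_pg)

    def consistent(self, rel_tol: float = 0.01) -> bool:
        """Whether the pg and Mbp figures agree within ``rel_tol`` relative difference."""
        if self.c_value_pg is None:
            return True
        return abs(self.size_mbp - PG_TO_MBP * self.c_value_pg) / self.size_mbp <= rel_tol


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species focus summary plus derived map length and rate.

    All fields are kept at full precision; rounding to the granularity of a
    report table happens only in :func:`table1_frame` / :func:`table2_frame`.
    ``rate_cm_per_mb`` is ``None`` when no genome size was supplied.
    """

    species_id: str
    n_cells: int
    min_foci: int
    max_foci: int
    mean_foci: float
    sd_foci: float
    map_cm: float
    rate_cm_per_mb: Optional[float] = None
    genome_mbp: Optional[float] = None


@dataclass(frozen=True)
class CrossSpeciesReport:
    """Pooled view across species summaries."""

    n_species: int
    n_cells_total: int
    mean_rate_cm_per_mb: Optional[float]
    #: (max mean foci - min mean foci) / grand mean foci, as a percentage
    mean_foci_relative_spread_pct: float


def pg_to_mbp(pg: float) -> float:
    """Convert a C-value in picograms to megabase pairs (978 Mbp/pg)."""
    if pg < 0:
        raise ValueError("C-value cannot be negative")
    return PG_TO_MBP * pg


def map_length_cm(mean_foci: float) -> float:
    """Genetic map length in cM implied by a mean crossover (focus) count."""
    if mean_foci < 0:
        raise ValueError("mean focus count cannot be negative")
    return CM_PER_CROSSOVER * mean_foci


def rate_cm_per_mb(map_cm: float, genome_mbp: float) -> float:
    """Genome-wide recombination rate in cM/Mb."""
    if genome_mbp <= 0:
        raise ValueError("genome size must be positive")
    return map_cm / genome_mbp


def summarize_species(
    cells: Sequence[CellRecord], genome: Optional[GenomeSize] = None
) -> SpeciesSummary:
    """Summarize one species' cells into counts, moments, map length and rate.

    SD uses the sample (n - 1) denominator, hence at least two cells are
    required. All cells must share one species; supplying a genome size of a
    different species is an error.
    """
    if len(cells) < 2:
        raise ValueError("at least two cells are required (sample SD undefined)")
    species = {c.species_id for c in cells}
    if len(species) != 1:
        raise ValueError(f"cells mix species: {sorted(species)}")
    (species_id,) = species
    if genome is not None and genome.species_id != species_id:
        raise ValueError(
            f"genome size is for {genome.species_id}, cells are {species_id}"
        )
    counts = np.array([c.foci_total for c in cells], dtype=float)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    map_cm = map_length_cm(mean)
    rate = None if genome is None else rate_cm_per_mb(map_cm, genome.size_mbp)
    return SpeciesSummary(
        species_id=species_id,
        n_cells=len(cells),
        min_foci=int(counts.min()),
        max_foci=int(counts.max()),
        mean_foci=mean,
        sd_foci=sd,
        map_cm=map_cm,
        rate_cm_per_mb=rate,
        genome_mbp=None if genome is None else genome.size_mbp,
    )


def cross_species_summary(summaries: Sequence[SpeciesSummary]) -> CrossSpeciesReport:
    """Pool species summaries: total cells, unweighted mean rate, mean-foci spread.

    The mean rate is the plain average over species (one species, one vote),
    not weighted by cell counts. The between-species spread of mean focus
    counts is (max - min)/grand mean, in percent.
    """
    if not summaries:
        raise ValueError("no species summaries supplied")
    means = np.array([s.mean_foci for s in summaries], dtype=float)
    grand = float(means.mean())
    spread = 0.0 if grand == 0 else float((means.max() - means.min()) / grand * 100.0)
    rates = [s.rate_cm_per_mb for s in summaries]
    mean_rate = None if any(r is None for r in rates) else float(np.mean(rates))
    return CrossSpeciesReport(
        n_species=len(summaries),
        n_cells_total=int(sum(s.n_cells for s in summaries)),
        mean_rate_cm_per_mb=mean_rate,
        mean_foci_relative_spread_pct=spread,
    )


def table1_frame(
    summaries: Sequence[SpeciesSummary], karyotypes: Optional[dict[str, Karyotype]] = None
) -> pd.DataFrame:
    """Karyotype-and-foci report table (means and SDs rounded to 1 decimal)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"species_id": s.species_id}
        if karyotypes is not None:
            k = karyotypes[s.species_id]
            row["diploid_2n"] = k.diploid_2n
            row["arm_haploid_aFN2"] = k.arm_haploid_aFN2
        row.update(
            n_cells=s.n_cells,
            min_foci=s.min_foci,
            max_foci=s.max_foci,
            mean_foci=round_half_up(s.mean_foci, 1),
            sd_foci=round_half_up(s.sd_foci, 1),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def table2_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Genome-size-and-rate report table.

    Rounding convention: Mbp and cM to the nearest integer, rate to two
    decimals, mean foci to one decimal — applied here only, never upstream.
    """
    rows = []
    for s in summaries:
        if s.genome_mbp is None or s.rate_cm_per_mb is None:
            raise ValueError(f"{s.species_id}: summary lacks a genome size")
        rows.append(
            {
                "species_id": s.species_id,
                "genome_mbp": int(round_half_up(s.genome_mbp)),
                "mean_foci": round_half_up(s.mean_foci, 1),
                "map_cm": int(round_half_up(s.map_cm)),
                "rate_cm_per_mb": round_half_up(s.rate_cm_per_mb, 2),
            }
        )
    return pd.DataFrame(rows)
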