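"""Crossover-minimum constraints against karyotype structure.

Faithful meiosis-I segregation requires at least one crossover per bivalent;
a stricter regime requires one per chromosome arm. With MLH1 foci as
crossover markers, a cell's total focus count can be tested against the
haploid autosome number (aN/2) and the haploid autosomal arm number (aFN/2)
of its species. "Below the minimum" is a strict inequality: a cell with
exactly aFN/2 foci can still satisfy one crossover per arm.

Species-level regime calls compare the *mean* focus count to the two
thresholds (as plotted in focus-vs-karyotype scatter figures), while the
per-cell fraction below the arm minimum is reported separately because the
two statistics answer different questions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cyto_rates import CellRecord, Karyotype, SpeciesSummary

__all__ = [
    "ArmDeficitReport",
    "DeficitFlags",
    "Regime",
    "RegimeCall",
    "ZeroFocusReport",
    "cell_deficit",
    "classify_regime",
    "deficit_frame",
    "fraction_below_arm_minimum",
    "plot_foci_vs_karyotype",
    "zero_focus_bivalent_frequency",
]


class Regime(str, Enum):
    """Which structural crossover minimum a species' mean focus count meets."""

    ARM_MINIMUM_MET = "arm_minimum_met"
    CHROMOSOME_MINIMUM_ONLY = "chromosome_minimum_only"
    BELOW_CHROMOSOME_MINIMUM = "below_chromosome_minimum"


@dataclass(frozen=True)
class DeficitFlags:
    species_id: str
    cell_id: str
    foci_total: int
    below_chromosome_min: bool
    below_arm_min: bool


@dataclass(frozen=True)
class RegimeCall:
    species_id: str
    regime: Regime
    mean_foci: float
    aN2: int
    aFN2: int


@dataclass(frozen=True)
class ArmDeficitReport:
    """Fraction of cells with fewer foci than their species' arm number."""

    pooled: float
    per_species: dict[str, float]
    n_cells: int

    @property
    def species_averaged(self) -> float:
        """Unweighted mean of the per-species fractions."""
        return float(np.mean(list(self.per_species.values())))


@dataclass(frozen=True)
class ZeroFocusReport:
    """Frequency of bivalents carrying no MLH1 focus.

    ``pooled`` is ``None`` when no cell carried per-bivalent counts — an
    explicitly not-computable result, deliberately distinct from zero.
    """

    pooled: Optional[float]
    per_species: dict[str, float]
    n_bivalents: int

    @property
    def computable(self) -> bool:
        return self.pooled is not None


def cell_deficit(cell: CellRecord, karyotype: Karyotype) -> DeficitFlags:
    """Flag whether a cell falls below the per-chromosome / per-arm minimum."""
    if cell.species_id != karyotype.species_id:
        raise ValueError(
            f"cell is {cell.species_id}, karyotype is {karyotype.species_id}"
        )
    return DeficitFlags(
        species_id=cell.species_id,
        cell_id=cell.cell_id,
        foci_total=cell.foci_total,
        below_chromosome_min=cell.foci_total < karyotype.autosome_haploid_aN2,
        below_arm_min=cell.foci_total < karyotype.arm_haploid_aFN2,
    )


def fraction_below_arm_minimum(
    cells: Sequence[CellRecord], karyotypes: Mapping[str, Karyotype]
) -> ArmDeficitReport:
    """Pooled and per-species fraction of cells below the one-CO-per-arm floor."""
    if not cells:
        raise ValueError("no cells supplied")
    below_total = 0
    per_species_counts: dict[str, list[int]] = {}
    for cell in cells:
        try:
            k = karyotypes[cell.species_id]
        except KeyError:
            raise ValueError(f"no karyotype for species {cell.species_id}") from None
        below = cell.foci_total < k.arm_haploid_aFN2
        below_total += below
        n_below, n_all = per_species_counts.setdefault(cell.species_id, [0, 0])
        per_species_counts[cell.species_id] = [n_below + below, n_all + 1]
    per_species = {
        sp: n_below / n_all for sp, (n_below, n_all) in per_species_counts.items()
    }
    return ArmDeficitReport(
        pooled=below_total / len(cells),
        per_species=per_species,
        n_cells=len(cells),
    )


def classify_regime(summary: SpeciesSummary, karyotype: Karyotype) -> RegimeCall:
    """Classify a species by where its mean focus count sits between aN/2 and aFN/2."""
    if summary.species_id != karyotype.species_id:
        raise ValueError(
            f"summary is {summary.species_id}, karyotype is {karyotype.species_id}"
        )
    mean = summary.mean_foci
    if mean >= karyotype.arm_haploid_aFN2:
        regime = Regime.ARM_MINIMUM_MET
    elif mean >= karyotype.autosome_haploid_aN2:
        regime = Regime.CHROMOSOME_MINIMUM_ONLY
    else:
        regime = Regime.BELOW_CHROMOSOME_MINIMUM
    return RegimeCall(
        species_id=summary.species_id,
        regime=regime,
        mean_foci=mean,
        aN2=karyotype.autosome_haploid_aN2,
        aFN2=karyotype.arm_haploid_aFN2,
    )


def zero_focus_bivalent_frequency(cells: Sequence[CellRecord]) -> ZeroFocusReport:
    """Frequency of focus-less bivalents among all scored bivalents.

    Only cells with per-bivalent counts contribute; with none present the
    result is marked not computable rather than silently reported as zero.
    """
    zero_total = 0
    n_total = 0
    per_species_counts: dict[str, list[int]] = {}
    for cell in cells:
        if cell.per_bivalent_foci is None:
            continue
        zeros = sum(1 for v in cell.per_bivalent_foci if v == 0)
        n = len(cell.per_bivalent_foci)
        zero_total += zeros
        n_total += n
        z, tot = per_species_counts.setdefault(cell.species_id, [0, 0])
        per_species_counts[cell.species_id] = [z + zeros, tot + n]
    if n_total == 0:
        return ZeroFocusReport(pooled=None, per_species={}, n_bivalents=0)
    per_species = {sp: z / tot for sp, (z, tot) in per_species_counts.items()}
    return ZeroFocusReport(
        pooled=zero_total / n_total, per_species=per_species, n_bivalents=n_total
    )


def deficit_frame(
    cells: Sequence[CellRecord], karyotypes: Mapping[str, Karyotype]
) -> pd.DataFrame:
    """Per-cell deficit flags as a tidy table."""
    flags = [cell_deficit(c, karyotypes[c.species_id]) for c in cells]
    return pd.DataFrame(
        {
            "species_id": [f.species_id for f in flags],
            "cell_id": [f.cell_id for f in flags],
            "foci_total": [f.foci_total for f in flags],
            "below_chromosome_min": [f.below_chromosome_min for f in flags],
            "below_arm_min": [f.below_arm_min for f in flags],
        }
    )


def plot_foci_vs_karyotype(
    summaries: Sequence[SpeciesSummary],
    karyotypes: Mapping[str, Karyotype],
    ax_pair=None,
):
    """Two-panel scatter of mean foci (± SD) against aN/2 and aFN/2.

    The y = x line marks one crossover per chromosome (left panel) or per
    chromosome arm (right panel); points above it meet the corresponding
    minimum on average. Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax_pair is None:
        fig, ax_pair = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    else:
        fig = ax_pair[0].figure
    for ax, attr, label in (
        (ax_pair[0], "autosome_haploid_aN2", "haploid autosomes aN/2"),
        (ax_pair[1], "arm_haploid_aFN2", "haploid autosomal arms aFN/2"),
    ):
        xs = [getattr(karyotypes[s.species_id], attr) for s in summaries]
        ys = [s.mean_foci for s in summaries]
        errs = [s.sd_foci for s in summaries]
        ax.errorbar(xs, ys, yerr=errs, fmt="o", capsize=3)
        for x, y, s in zip(xs, ys, summaries):
            ax.annotate(s.species_id, (x, y), textcoords="offset points", xytext=(5, 3))
        lo = min(min(xs), min(ys)) - 3
        hi = max(max(xs), max(ys)) + 3
        ax.plot([lo, hi], [lo, hi], color="k", lw=1)
        ax.set_xlabel(label)
    ax_pair[0].set_ylabel("mean MLH1 foci per cell")
    fig.tight_layout()
    return fig
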