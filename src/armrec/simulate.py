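"""Synthetic per-cell focus counts and comparative databases.

No raw per-cell counts or machine-readable comparative database accompany
the study tables, so every pipeline stage is exercised on synthetic data
generated here.

Cell generator
--------------
The published evidence constrains per-cell totals (mean, SD, range per
species) and one per-bivalent feature (fewer than 1% of bivalents lack a
focus). The generator therefore targets those printed summaries rather than
a mechanistic model: each autosomal bivalent receives an obligate focus with
probability ``1 - zero_focus_prob``, and a cell-level number of *extra* foci
— drawn from a binomial/Poisson/negative-binomial law moment-matched to the
target mean and SD — is spread over bivalents with probability proportional
to ``bivalent_weights`` (default: linearly decreasing, a crude proxy for
chromosome size). Crossover interference is deliberately not modeled.

Database generator
------------------
Each clade contributes ``species_per_group`` species whose rates scatter
around ``base_rate + signal_strength * recency`` (recency scaled to [0, 1],
1 = youngest clade) with Gaussian noise; genome sizes scatter log-normally
around the clade-typical size. Defaults reproduce the nine-clade study
conditions in :mod:`armrec.reference`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .comparative import DbRecord, DivergencePoint, db_record_rate
from .cyto_rates import CellRecord, Karyotype
from . import reference

__all__ = [
    "CellSimParams",
    "DbSimParams",
    "GroupSpec",
    "default_armadillo_params",
    "default_db_params",
    "simulate_armadillo_cells",
    "simulate_cells",
    "simulate_db",
]


@dataclass(frozen=True)
class CellSimParams:
    """Targets for one species' simulated spermatocytes."""

    species_id: str
    karyotype: Karyotype
    target_mean: float
    target_sd: float
    n_cells: int
    zero_focus_prob: float = 0.005
    bivalent_weights: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_focus_prob <= 0.05:
            raise ValueError("zero_focus_prob must lie in [0, 0.05]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.target_sd <= 0:
            raise ValueError("target SD must be positive")
        a = self.karyotype.autosome_haploid_aN2
        if self.target_mean < a * (1.0 - self.zero_focus_prob):
            raise ValueError(
                f"{self.species_id}: target mean {self.target_mean} is below the "
                f"obligate-crossover floor {a * (1 - self.zero_focus_prob):.2f}"
            )
        if self.bivalent_weights is not None:
            w = tuple(float(v) for v in self.bivalent_weights)
            if len(w) != a:
                raise ValueError("bivalent_weights must have one entry per bivalent")
            if any(v <= 0 for v in w):
                raise ValueError("bivalent_weights must be positive")
            object.__setattr__(self, "bivalent_weights", w)


@dataclass(frozen=True)
class GroupSpec:
    """One clade of the synthetic comparative database."""

    label: str
    divergence_mya: float
    base_rate: float
    genome_mbp_mean: Optional[float] = None
    superorder: Optional[str] = None

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError(f"{self.label}: base rate must be positive")
        if self.divergence_mya <= 0:
            raise ValueError(f"{self.label}: divergence time must be positive")


@dataclass(frozen=True)
class DbSimParams:
    groups: tuple[GroupSpec, ...]
    species_per_group: int = 9
    rate_noise_sd: float = 0.05
    genome_size_range_mbp: tuple[float, float] = (2000.0, 4500.0)
    genome_cv: float = 0.10
    signal_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.species_per_group < 1:
            raise ValueError("species_per_group must be >= 1")
        lo, hi = self.genome_size_range_mbp
        if lo <= 0 or hi <= lo:
            raise ValueError("genome_size_range_mbp must be a positive interval")


def _extras_sampler(mean: float, var: float):
    """Sampler of non-negative integers with (approximately) given moments.

    Chooses binomial (var < mean), Poisson (var = mean) or negative binomial
    (var > mean). Binomial N rounds to the nearest feasible integer, which
    bounds the variance mismatch by one part in N.
    """
    if mean < 0 or var < 0:
        raise ValueError("moments must be non-negative")
    if mean == 0:
        return lambda rng, size: np.zeros(size, dtype=np.int64)
    rel = (var - mean) / mean
    if abs(rel) < 1e-9:
        return lambda rng, size: rng.poisson(mean, size)
    if var < mean:
        n = max(int(round(mean * mean / (mean - var))), int(np.ceil(mean)) + 1)
        p = mean / n
        return lambda rng, size: rng.binomial(n, p, size)
    # negative binomial: numpy's parameterization (n successes, prob p)
    p = mean / var
    n = mean * mean / (var - mean)
    return lambda rng, size: rng.negative_binomial(n, p, size)


def simulate_cells(params: CellSimParams) -> list[CellRecord]:
    """Simulate spermatocytes with per-bivalent MLH1-focus counts.

    Deterministic given ``params.seed``. The cell-total distribution matches
    the target mean exactly in expectation and the target SD up to the
    integer-moment-matching error (well under 0.1 for the study species).
    """
    a = params.karyotype.autosome_haploid_aN2
    eps = params.zero_focus_prob
    rng = np.random.default_rng(params.seed)

    obligate_mean = a * (1.0 - eps)
    obligate_var = a * eps * (1.0 - eps)
    extra_mean = params.target_mean - obligate_mean
    extra_var = params.target_sd**2 - obligate_var
    if extra_var <= 0:
        raise ValueError(
            f"{params.species_id}: target SD too small for the obligate-focus noise"
        )
    sampler = _extras_sampler(extra_mean, extra_var)

    weights = params.bivalent_weights
    if weights is None:
        # linearly decreasing sizes: largest bivalent ~ a, smallest ~ 1
        weights = tuple(float(a - i) for i in range(a))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    obligate = (rng.random((params.n_cells, a)) >= eps).astype(np.int64)
    extras_total = sampler(rng, params.n_cells)
    records = []
    for i in range(params.n_cells):
        extra_alloc = rng.multinomial(extras_total[i], w)
        per_biv = obligate[i] + extra_alloc
        records.append(
            CellRecord(
                species_id=params.species_id,
                animal_id=f"{params.species_id}_a1",
                cell_id=f"{params.species_id}_c{i + 1:05d}",
                foci_total=int(per_biv.sum()),
                per_bivalent_foci=tuple(int(v) for v in per_biv),
            )
        )
    return records


def default_armadillo_params(seed: int = 0, n_cells: Optional[dict[str, int]] = None) -> list[CellSimParams]:
    """Per-species parameter sets matching the published armadillo summaries.

    ``n_cells`` overrides the published per-species cell counts (30/36/37/31)
    e.g. for large calibration runs.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(reference.ARMADILLO_SPECIES))
    params = []
    for sp, sub in zip(reference.ARMADILLO_SPECIES, seeds):
        row = reference.FOCUS_SUMMARY[sp]
        params.append(
            CellSimParams(
                species_id=sp,
                karyotype=reference.KARYOTYPES[sp],
                target_mean=row["mean"],
                target_sd=row["sd"],
                n_cells=int(n_cells[sp]) if n_cells else int(row["n_cells"]),
                seed=int(sub),
            )
        )
    return params


def simulate_armadillo_cells(
    seed: int = 0, n_cells: Optional[dict[str, int]] = None
) -> list[CellRecord]:
    """The default four-species armadillo dataset (134 cells), one flat list."""
    cells: list[CellRecord] = []
    for p in default_armadillo_params(seed, n_cells):
        cells.extend(simulate_cells(p))
    return cells


def default_db_params(seed: int = 0, **overrides) -> DbSimParams:
    """Nine-clade mammal database parameterized from the study group table."""
    groups = tuple(
        GroupSpec(
            label=label,
            superorder=superorder,
            divergence_mya=mya,
            base_rate=rate,
            genome_mbp_mean=genome,
        )
        for label, superorder, mya, rate, genome in reference.MAMMAL_GROUP_TABLE
    )
    return DbSimParams(groups=groups, seed=seed, **overrides)


def simulate_db(params: DbSimParams) -> tuple[list[DbRecord], list[DivergencePoint]]:
    """Simulate a species-level database plus its clade divergence table.

    Species rates are ``base_rate + signal_strength * recency + noise``
    (clipped to stay positive); methods cycle through chiasmata/MLH1/linkage
    with linkage rows flagged deep-coverage so all records are included.
    """
    rng = np.random.default_rng(params.seed)
    times = np.array([g.divergence_mya for g in params.groups], dtype=float)
    span = times.max() - times.min()
    records: list[DbRecord] = []
    divergence = []
    method_cycle = ("mlh1", "chiasmata", "linkage")
    for gi, g in enumerate(params.groups):
        divergence.append(DivergencePoint(group_label=g.label, divergence_mya=g.divergence_mya))
        recency = 0.0 if span == 0 else (times.max() - g.divergence_mya) / span
        loc = g.base_rate + params.signal_strength * recency
        for si in range(params.species_per_group):
            rate = loc + rng.normal(0.0, params.rate_noise_sd)
            rate = max(rate, 0.02)
            if g.genome_mbp_mean is not None:
                genome = g.genome_mbp_mean * float(
                    np.exp(rng.normal(0.0, params.genome_cv))
                )
            else:
                genome = float(rng.uniform(*params.genome_size_range_mbp))
            method = method_cycle[si % len(method_cycle)]
            map_cm = rate * genome
            if method == "linkage":
                rec = DbRecord(
                    species_id=f"{g.label}_sp{si + 1:02d}",
                    order_label=g.label,
                    superorder_label=g.superorder or g.label,
                    method=method,
                    genome_mbp=genome,
                    map_cm=map_cm,
                    deep_coverage=True,
                )
            else:
                rec = DbRecord(
                    species_id=f"{g.label}_sp{si + 1:02d}",
                    order_label=g.label,
                    superorder_label=g.superorder or g.label,
                    method=method,
                    genome_mbp=genome,
                    crossover_count=map_cm / 50.0,
                )
            records.append(db_record_rate(rec))
    return records, divergence
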