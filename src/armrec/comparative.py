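"""Cross-mammal recombination-rate database and the phylogeny correlation.

Species enter the database with a crossover count (mean chiasmata or MLH1
foci) or a linkage-map length. Counts convert to map length at 50 cM per
crossover, and rates are map length over genome size in Mbp. Linkage-map
entries are only *included* in aggregate statistics when the map is known to
have deep marker coverage; shallow maps systematically understate the true
map length.

Clade-level means (one species, one vote; one clade, one point) are then
correlated with clade divergence times by Spearman rank correlation. Sign
convention: divergence times are negated before ranking, so a **positive**
rho means younger clades recombine more — the direction usually described as
"lower recombination rates in more basal clades".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cyto_rates import CM_PER_CROSSOVER
from .stats_core import SpearmanResult, spearman

__all__ = [
    "METHODS",
    "DbRecord",
    "DivergencePoint",
    "GroupPoint",
    "attach_divergence",
    "clade_average",
    "collapse_duplicate_species",
    "db_record_rate",
    "divergence_correlation",
    "group_means",
    "leave_one_out_sensitivity",
    "plot_rate_strip",
]

logger = logging.getLogger(__name__)

#: accepted measurement methods for a database entry
METHODS = ("chiasmata", "mlh1", "linkage")


@dataclass(frozen=True)
class DbRecord:
    """One species' entry in the comparative recombination database."""

    species_id: str
    order_label: str
    superorder_label: str
    method: str
    genome_mbp: float
    crossover_count: Optional[float] = None
    map_cm: Optional[float] = None
    rate_cm_per_mb: Optional[float] = None
    deep_coverage: Optional[bool] = None
    included: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"{self.species_id}: unknown method {self.method!r}; allowed: {METHODS}"
            )
        if self.genome_mbp <= 0:
            raise ValueError(f"{self.species_id}: genome size must be positive")


@dataclass(frozen=True)
class GroupPoint:
    """One clade's point in the divergence-vs-rate analysis."""

    group_label: str
    mean_rate_cm_per_mb: float
    mean_map_cm: float
    n_species: int
    divergence_mya: Optional[float] = None


@dataclass(frozen=True)
class DivergencePoint:
    group_label: str
    divergence_mya: float

    def __post_init__(self) -> None:
        if self.divergence_mya <= 0:
            raise ValueError(f"{self.group_label}: divergence time must be positive")


def db_record_rate(record: DbRecord) -> DbRecord:
    """Fill a record's map length and rate; apply the linkage inclusion rule.

    Chiasma/MLH1 rows derive map_cm = 50 x crossover_count; linkage rows must
    supply map_cm directly and are marked ``included=False`` unless deep
    coverage is known. Excluded rows still carry their rate (for reporting)
    but never enter aggregates.
    """
    if record.crossover_count is None and record.map_cm is None:
        raise ValueError(
            f"{record.species_id}: neither crossover count nor map length given"
        )
    map_cm = record.map_cm
    if map_cm is None:
        map_cm = CM_PER_CROSSOVER * float(record.crossover_count)
    rate = map_cm / record.genome_mbp
    included = record.included
    if record.method == "linkage" and record.deep_coverage is not True:
        included = False
    return replace(record, map_cm=map_cm, rate_cm_per_mb=rate, included=included)


def collapse_duplicate_species(records: Sequence[DbRecord]) -> list[DbRecord]:
    """Average duplicate species (e.g. measured by several methods) into one record.

    Rates and map lengths are averaged over the species' included entries;
    the merge is logged so double counting is visible in the run log.
    """
    by_species: dict[str, list[DbRecord]] = {}
    order = []
    for r in records:
        if r.species_id not in by_species:
            order.append(r.species_id)
        by_species.setdefault(r.species_id, []).append(r)
    out = []
    for sp in order:
        group = by_species[sp]
        if len(group) == 1:
            out.append(group[0])
            continue
        usable = [r for r in group if r.included] or group
        merged = replace(
            usable[0],
            method=usable[0].method,
            crossover_count=None,
            map_cm=float(np.mean([r.map_cm for r in usable])),
            genome_mbp=float(np.mean([r.genome_mbp for r in usable])),
            rate_cm_per_mb=float(np.mean([r.rate_cm_per_mb for r in usable])),
            included=any(r.included for r in group),
        )
        logger.info(
            "species %s appears %d times (%s); averaged into one record",
            sp,
            len(group),
            ",".join(r.method for r in group),
        )
        out.append(merged)
    return out


GroupKey = Union[str, Callable[[DbRecord], str]]


def _group_key(level: GroupKey) -> Callable[[DbRecord], str]:
    if callable(level):
        return level
    if level == "order":
        return lambda r: r.order_label
    if level == "superorder":
        return lambda r: r.superorder_label
    raise ValueError("level must be 'order', 'superorder' or a callable")


def group_means(records: Sequence[DbRecord], level: GroupKey = "order") -> list[GroupPoint]:
    """Unweighted per-clade mean rate and map length over included records."""
    key = _group_key(level)
    groups: dict[str, list[DbRecord]] = {}
    order = []
    for r in records:
        if not r.included:
            continue
        if r.rate_cm_per_mb is None or r.map_cm is None:
            raise ValueError(f"{r.species_id}: record lacks a rate; run db_record_rate first")
        label = key(r)
        if label not in groups:
            order.append(label)
        groups.setdefault(label, []).append(r)
    if not groups:
        raise ValueError("no included records to group")
    return [
        GroupPoint(
            group_label=label,
            mean_rate_cm_per_mb=float(np.mean([r.rate_cm_per_mb for r in groups[label]])),
            mean_map_cm=float(np.mean([r.map_cm for r in groups[label]])),
            n_species=len(groups[label]),
        )
        for label in order
    ]


def attach_divergence(
    points: Sequence[GroupPoint],
    divergence: Union[Mapping[str, float], Sequence[DivergencePoint]],
) -> list[GroupPoint]:
    """Join divergence times (Mya) onto group points by clade label."""
    if not isinstance(divergence, Mapping):
        divergence = {d.group_label: d.divergence_mya for d in divergence}
    out = []
    for p in points:
        if p.group_label not in divergence:
            raise ValueError(f"no divergence time for group {p.group_label}")
        out.append(replace(p, divergence_mya=float(divergence[p.group_label])))
    return out


def _response(points: Sequence[GroupPoint], response: str) -> list[float]:
    if response == "rate":
        return [p.mean_rate_cm_per_mb for p in points]
    if response == "map_cm":
        return [p.mean_map_cm for p in points]
    raise ValueError("response must be 'rate' or 'map_cm'")


def divergence_correlation(
    points: Sequence[GroupPoint], response: str = "rate"
) -> SpearmanResult:
    """Spearman correlation of clade recency against mean rate (or map length).

    Divergence times are negated before ranking, so positive rho reads
    "more recently diverged clades have higher recombination".
    """
    if len(points) < 3:
        raise ValueError("at least 3 groups are required")
    for p in points:
        if p.divergence_mya is None:
            raise ValueError(f"group {p.group_label} has no divergence time")
    recency = [-p.divergence_mya for p in points]
    return spearman(recency, _response(points, response))


def leave_one_out_sensitivity(
    points: Sequence[GroupPoint], response: str = "rate", alpha: float = 0.05
) -> pd.DataFrame:
    """Drop each clade in turn and re-run the divergence correlation.

    The ``significance_changed`` flag marks drops where the p-value crosses
    ``alpha`` relative to the full set — the clades the correlation hinges on.
    """
    if len(points) < 4:
        raise ValueError("at least 4 groups are required for leave-one-out")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    full = divergence_correlation(points, response)
    full_significant = full.p_value <= alpha
    rows = []
    for i, dropped in enumerate(points):
        subset = [p for j, p in enumerate(points) if j != i]
        res = divergence_correlation(subset, response)
        rows.append(
            {
                "dropped_group": dropped.group_label,
                "rho": res.rho,
                "p_value": res.p_value,
                "significance_changed": (res.p_value <= alpha) != full_significant,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["full_rho"] = full.rho
    df.attrs["full_p_value"] = full.p_value
    df.attrs["alpha"] = alpha
    return df


def clade_average(
    records: Sequence[DbRecord],
    clade: Union[str, Callable[[DbRecord], bool]],
) -> float:
    """Unweighted mean rate over included species of one clade.

    ``clade`` is either a label matched against order and superorder, or a
    predicate over records.
    """
    if callable(clade):
        pred = clade
    else:
        pred = lambda r: clade in (r.order_label, r.superorder_label)
    selected = [r for r in records if r.included and pred(r)]
    if not selected:
        raise ValueError("clade filter matches no included record")
    return float(np.mean([r.rate_cm_per_mb for r in selected]))


def plot_rate_strip(records: Sequence[DbRecord], level: GroupKey = "order", ax=None):
    """Strip plot of species rates by clade, ordered by clade mean. Returns the figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    key = _group_key(level)
    included = [r for r in records if r.included]
    labels = sorted({key(r) for r in included}, key=lambda lab: np.mean(
        [r.rate_cm_per_mb for r in included if key(r) == lab]
    ))
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(labels) + 1.5))
    else:
        fig = ax.figure
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for y, lab in enumerate(labels):
        xs = [r.rate_cm_per_mb for r in included if key(r) == lab]
        ax.scatter(xs, y + rng.uniform(-0.12, 0.12, len(xs)), s=14, alpha=0.8)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("recombination rate (cM/Mb)")
    fig.tight_layout()
    return fig
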