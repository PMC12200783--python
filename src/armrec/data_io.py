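"""CSV input/output for the five pipeline table schemas.

Dialect: UTF-8, comma-separated, one header row, "." decimal separator;
per-bivalent focus lists are ";"-delimited inside one cell. Unknown columns
are preserved on read but ignored.

Error policy: a missing required column aborts the read with a
:class:`SchemaError`; a bad row raises :class:`RowError` naming the row,
unless ``permissive=True``, in which case bad rows are skipped and reported
through the module logger (silent row dropping would corrupt cell counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .comparative import METHODS, DbRecord, DivergencePoint, GroupPoint
from .cyto_rates import PG_TO_MBP, CellRecord, GenomeSize, Karyotype

__all__ = [
    "RowError",
    "SchemaError",
    "TableSchema",
    "read_cell_counts",
    "read_divergence",
    "read_genome_sizes",
    "read_karyotypes",
    "read_recomb_db",
    "write_cell_counts",
    "write_divergence",
    "write_genome_sizes",
    "write_group_points",
    "write_karyotypes",
    "write_recomb_db",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A required column is missing or the file is structurally unusable."""


class RowError(ValueError):
    """A data row violates the schema; carries the 1-based data-row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class TableSchema:
    """Declared columns of one CSV table."""

    name: str
    required_columns: tuple[tuple[str, str], ...]
    optional_columns: tuple[tuple[str, str], ...] = ()

    def check(self, df: pd.DataFrame) -> None:
        for col, _ in self.required_columns:
            if col not in df.columns:
                raise SchemaError(f"{self.name}: missing required column '{col}'")
        counts = pd.Index(df.columns).value_counts()
        dupes = [c for c, _ in self.required_columns if counts.get(c, 0) > 1]
        if dupes:
            raise SchemaError(f"{self.name}: duplicated column(s) {dupes}")


CELLS_SCHEMA = TableSchema(
    "cell_counts",
    (("species_id", "id"), ("animal_id", "id"), ("cell_id", "id"), ("foci_total", "count")),
    (("per_bivalent", "';'-delimited counts"),),
)
KARYOTYPES_SCHEMA = TableSchema(
    "karyotypes",
    (("species_id", "id"), ("diploid_2n", "count"), ("arm_haploid_aFN2", "count")),
    (("display_name", "text"),),
)
GENOMES_SCHEMA = TableSchema(
    "genome_sizes",
    (("species_id", "id"),),
    (("c_value_pg", "pg"), ("size_mbp", "Mbp")),
)
DB_SCHEMA = TableSchema(
    "recomb_db",
    (
        ("species_id", "id"),
        ("order", "clade"),
        ("superorder", "clade"),
        ("method", "one of " + "/".join(METHODS)),
    ),
    (
        ("crossover_count", "mean count"),
        ("map_cm", "cM"),
        ("genome_mbp", "Mbp"),
        ("c_value_pg", "pg"),
        ("deep_coverage", "bool, linkage rows"),
    ),
)
DIVERGENCE_SCHEMA = TableSchema(
    "divergence",
    (("group_label", "clade"), ("divergence_mya", "Mya")),
)


def _read_csv(path: PathLike, schema: TableSchema) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema.check(df)
    return df


def _blank(value: str) -> bool:
    return value is None or str(value).strip() == ""


def _parse_int(value: str, what: str) -> int:
    try:
        f = float(value)
    except ValueError:
        raise ValueError(f"{what} '{value}' is not a number") from None
    if f != int(f):
        raise ValueError(f"{what} '{value}' is not an integer")
    return int(f)


def _parse_count(value: str, what: str) -> int:
    n = _parse_int(value, what)
    if n < 0:
        raise ValueError(f"{what} '{value}' is negative")
    return n


def _rows(df: pd.DataFrame, permissive: bool, build):
    """Apply ``build`` per row, enforcing the permissive-row policy."""
    out = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(build(i, row._asdict()))
        except (ValueError, KeyError) as exc:
            err = exc if isinstance(exc, RowError) else RowError(i, str(exc))
            if not permissive:
                raise err from None
            n_rejected += 1
            logger.warning("rejected %s", err)
    if n_rejected:
        logger.warning("%d row(s) rejected in permissive mode", n_rejected)
    return out


# ---------------------------------------------------------------------------
# cell counts
# ---------------------------------------------------------------------------

def read_cell_counts(path: PathLike, permissive: bool = False) -> list[CellRecord]:
    df = _read_csv(path, CELLS_SCHEMA)

    def build(i: int, row: dict) -> CellRecord:
        total = _parse_count(row["foci_total"], "foci_total")
        per_biv = None
        if "per_bivalent" in row and not _blank(row["per_bivalent"]):
            parts = str(row["per_bivalent"]).split(";")
            per_biv = tuple(_parse_count(p, "per-bivalent count") for p in parts)
            if sum(per_biv) != total:
                raise RowError(
                    i,
                    f"per-bivalent counts sum to {sum(per_biv)} but foci_total is {total}",
                )
        return CellRecord(
            species_id=row["species_id"],
            animal_id=row["animal_id"],
            cell_id=row["cell_id"],
            foci_total=total,
            per_bivalent_foci=per_biv,
        )

    return _rows(df, permissive, build)


def write_cell_counts(records: Sequence[CellRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "animal_id": [r.animal_id for r in records],
            "cell_id": [r.cell_id for r in records],
            "foci_total": [r.foci_total for r in records],
            "per_bivalent": [
                "" if r.per_bivalent_foci is None else ";".join(map(str, r.per_bivalent_foci))
                for r in records
            ],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------

def read_karyotypes(path: PathLike, permissive: bool = False) -> list[Karyotype]:
    df = _read_csv(path, KARYOTYPES_SCHEMA)

    def build(i: int, row: dict) -> Karyotype:
        n2 = _parse_count(row["diploid_2n"], "diploid_2n")
        afn2 = _parse_count(row["arm_haploid_aFN2"], "arm_haploid_aFN2")
        return Karyotype.from_counts(row["species_id"], n2, afn2)

    return _rows(df, permissive, build)


def write_karyotypes(records: Sequence[Karyotype], path: PathLike) -> None:
    pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "diploid_2n": [r.diploid_2n for r in records],
            "arm_haploid_aFN2": [r.arm_haploid_aFN2 for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genome sizes
# ---------------------------------------------------------------------------

def read_genome_sizes(path: PathLike, permissive: bool = False) -> list[GenomeSize]:
    df = _read_csv(path, GENOMES_SCHEMA)
    has_pg = "c_value_pg" in df.columns
    has_mbp = "size_mbp" in df.columns
    if not (has_pg or has_mbp):
        raise SchemaError("genome_sizes: need at least one of c_value_pg / size_mbp")

    def build(i: int, row: dict) -> GenomeSize:
        pg = None if not has_pg or _blank(row.get("c_value_pg", "")) else float(row["c_value_pg"])
        mbp = None if not has_mbp or _blank(row.get("size_mbp", "")) else float(row["size_mbp"])
        if pg is None and mbp is None:
            raise RowError(i, "neither c_value_pg nor size_mbp given")
        if mbp is None:
            return GenomeSize.from_pg(row["species_id"], pg)
        g = GenomeSize(species_id=row["species_id"], size_mbp=mbp, c_value_pg=pg)
        if not g.consistent():
            logger.warning(
                "row %d (%s): pg and Mbp disagree by more than 1%% "
                "(%.1f vs %.1f Mbp); keeping the Mbp value",
                i,
                g.species_id,
                PG_TO_MBP * (pg or 0.0),
                mbp,
            )
        return g

    return _rows(df, permissive, build)


def write_genome_sizes(records: Sequence[GenomeSize], path: PathLike) -> None:
    pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "c_value_pg": ["" if r.c_value_pg is None else r.c_value_pg for r in records],
            "size_mbp": [r.size_mbp for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# comparative database + divergence table
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(value: str, what: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"{what} '{value}' is not a boolean")


def read_recomb_db(
    path: PathLike, permissive: bool = False, derive_rates: bool = True
) -> list[DbRecord]:
    """Read the species-level database; by default rates are derived and the
    linkage deep-coverage inclusion rule applied immediately."""
    from .comparative import db_record_rate

    df = _read_csv(path, DB_SCHEMA)

    def build(i: int, row: dict) -> DbRecord:
        method = str(row["method"]).strip().lower()
        if method not in METHODS:
            raise RowError(i, f"unknown method '{row['method']}'; allowed: {METHODS}")
        genome = None
        if not _blank(row.get("genome_mbp", "")):
            genome = float(row["genome_mbp"])
        elif not _blank(row.get("c_value_pg", "")):
            genome = PG_TO_MBP * float(row["c_value_pg"])
        if genome is None or genome <= 0:
            raise RowError(i, "genome size missing or non-positive")
        count = None if _blank(row.get("crossover_count", "")) else float(row["crossover_count"])
        map_cm = None if _blank(row.get("map_cm", "")) else float(row["map_cm"])
        if count is None and map_cm is None:
            raise RowError(i, "neither crossover_count nor map_cm given")
        deep = (
            None
            if _blank(row.get("deep_coverage", ""))
            else _parse_bool(row["deep_coverage"], "deep_coverage")
        )
        rec = DbRecord(
            species_id=row["species_id"],
            order_label=row["order"],
            superorder_label=row["superorder"],
            method=method,
            genome_mbp=genome,
            crossover_count=count,
            map_cm=map_cm,
            deep_coverage=deep,
        )
        return db_record_rate(rec) if derive_rates else rec

    return _rows(df, permissive, build)


def write_recomb_db(records: Sequence[DbRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "order": [r.order_label for r in records],
            "superorder": [r.superorder_label for r in records],
            "method": [r.method for r in records],
            "crossover_count": ["" if r.crossover_count is None else r.crossover_count for r in records],
            "map_cm": ["" if r.map_cm is None else r.map_cm for r in records],
            "genome_mbp": [r.genome_mbp for r in records],
            "deep_coverage": ["" if r.deep_coverage is None else str(r.deep_coverage).lower() for r in records],
        }
    ).to_csv(path, index=False)


def read_divergence(path: PathLike, permissive: bool = False) -> list[DivergencePoint]:
    df = _read_csv(path, DIVERGENCE_SCHEMA)

    def build(i: int, row: dict) -> DivergencePoint:
        return DivergencePoint(
            group_label=row["group_label"], divergence_mya=float(row["divergence_mya"])
        )

    return _rows(df, permissive, build)


def write_divergence(records: Sequence[DivergencePoint], path: PathLike) -> None:
    pd.DataFrame(
        {
            "group_label": [r.group_label for r in records],
            "divergence_mya": [r.divergence_mya for r in records],
        }
    ).to_csv(path, index=False)


def write_group_points(points: Sequence[GroupPoint], path: PathLike) -> None:
    pd.DataFrame(
        {
            "group_label": [p.group_label for p in points],
            "divergence_mya": ["" if p.divergence_mya is None else p.divergence_mya for p in points],
            "mean_rate_cm_per_mb": [p.mean_rate_cm_per_mb for p in points],
            "mean_map_cm": [p.mean_map_cm for p in points],
            "n_species": [p.n_species for p in points],
        }
    ).to_csv(path, index=False)
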