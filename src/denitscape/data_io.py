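"""Tabular and placement I/O with schema validation.

All tables are tab-separated with a mandatory header, UTF-8, decimal
point ".". Missing values may be encoded as an empty string or "NA" on
input; "NA" is written on output. Placements are accepted either as
jplace (the JSON placement standard, read-only) plus an edge-to-clade
mapping, or as a simplified pre-accumulated TSV with columns
read_id / gene_family / clade / mass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("denitscape")

NA_VALUES = ["", "NA"]
MASS_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class UniquenessError(ValueError):
    """A key column contains duplicated values."""


class DataError(ValueError):
    """Row-level content violates an invariant."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declared semantics for one table column."""

    name: str
    dtype: str = "str"  # one of: str, float, int, bool
    required: bool = True


@dataclass(frozen=True)
class TableSchema:
    """Column specification plus an optional unique-key constraint."""

    columns: Sequence[ColumnSpec]
    key: str | None = None

    @property
    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]


GENOME_SCHEMA = TableSchema(
    columns=[
        ColumnSpec("genome_id"),
        ColumnSpec("assembly_type"),
        ColumnSpec("completeness", "float"),
        ColumnSpec("contamination", "float"),
        ColumnSpec("gunc_pass", "bool"),
        ColumnSpec("phylum"),
        ColumnSpec("genome_size", "float"),
        ColumnSpec("has_nirK", "bool"),
        ColumnSpec("has_nirS", "bool"),
        ColumnSpec("has_nor", "bool"),
        ColumnSpec("has_nosZ", "bool"),
        ColumnSpec("nosZ_clade"),
        ColumnSpec("is_anammox", "bool"),
        ColumnSpec("is_archaeal_nitrifier", "bool"),
        ColumnSpec("max_growth_rate", "float", required=False),
        ColumnSpec("n_ribosomal_proteins", "float", required=False),
        ColumnSpec("n_transporters", "float", required=False),
        ColumnSpec("n_transcription_factors", "float", required=False),
        ColumnSpec("n_substrates", "float", required=False),
        ColumnSpec("n_inorganic_donors", "float", required=False),
        ColumnSpec("n_inorganic_acceptors", "float", required=False),
    ],
    key="genome_id",
)

SAMPLE_SCHEMA = TableSchema(
    columns=[
        ColumnSpec("sample_id"),
        ColumnSpec("biome"),
        ColumnSpec("habitat_class"),
        ColumnSpec("total_reads", "float"),
        ColumnSpec("read_length", "float", required=False),
        ColumnSpec("latitude", "float", required=False),
    ],
    key="sample_id",
)

GENE_COUNT_SCHEMA = TableSchema(
    columns=[
        ColumnSpec("sample_id"),
        ColumnSpec("nirK", "float"),
        ColumnSpec("nirS", "float"),
        ColumnSpec("nosZI", "float"),
        ColumnSpec("nosZII", "float"),
        ColumnSpec("reads", "float"),
        ColumnSpec("read_length", "float", required=False),
    ],
    key="sample_id",
)

PLACEMENT_TSV_COLUMNS = ["read_id", "gene_family", "clade", "mass"]


def _coerce(series: pd.Series, spec: ColumnSpec, path: Path) -> pd.Series:
    if spec.dtype == "str":
        return series.astype("string")
    if spec.dtype == "bool":
        mapped = series.map(
            {
                True: True, False: False,
                "True": True, "False": False,
                "true": True, "false": False,
                "1": True, "0": False, 1: True, 0: False,
            }
        )
        bad = mapped.isna() & series.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise DataError(
                f"{path}: column {spec.name!r} has non-boolean value "
                f"{series[bad.idxmax()]!r} at line {line}"
            )
        return mapped.astype("boolean")
    try:
        return pd.to_numeric(series, errors="raise")
    except (ValueError, TypeError):
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() & series.notna()
        line = int(bad.idxmax()) + 2
        raise DataError(
            f"{path}: column {spec.name!r} has unparseable numeric value "
            f"{series[bad.idxmax()]!r} at line {line}"
        ) from None


def load_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Load and validate a TSV table against ``schema``.

    Row order is preserved; missing optional values are kept as NA, not
    dropped. Raises :class:`SchemaError` for a missing required column,
    :class:`UniquenessError` for a duplicated key and :class:`DataError`
    for unparseable cell values (with the offending line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=NA_VALUES, keep_default_na=False
    )
    missing = [name for name in schema.required_names if name not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for spec in schema.columns:
        if spec.name in df.columns:
            df[spec.name] = _coerce(df[spec.name], spec, path)
    if schema.key is not None and schema.key in df.columns:
        dup = df[schema.key][df[schema.key].duplicated()]
        if len(dup):
            raise UniquenessError(
                f"{path}: duplicated {schema.key} value(s): "
                f"{', '.join(map(str, dup.unique()[:5]))}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV; missing values become "NA"."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    return path


def load_placements(
    path: str | Path,
    edge_to_clade: Mapping[int, str] | None = None,
    known_clades: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read per-read clade mass fractions from jplace or simplified TSV.

    Returns a tidy frame with columns read_id, gene_family, clade, mass
    (one row per read per clade). Per-read masses must sum to at most
    ``1 + 1e-6``. jplace input requires ``edge_to_clade`` mapping each
    edge number to a clade label; the "like_weight_ratio" field is taken
    as the placement mass.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".jplace" or path.read_text(encoding="utf-8").lstrip()[:1] == "{":
        records = _load_jplace(path, edge_to_clade)
    else:
        records = pd.read_csv(
            path, sep="\t", na_values=NA_VALUES, keep_default_na=False
        )
        missing = [c for c in PLACEMENT_TSV_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(
                f"{path}: placement TSV missing column(s): {', '.join(missing)}"
            )
        records["mass"] = pd.to_numeric(records["mass"])
    if records.empty:
        logger.warning("%s: empty placement file", path)
        return records
    sums = records.groupby("read_id")["mass"].sum()
    over = sums[sums > 1 + MASS_TOL]
    if len(over):
        raise DataError(
            f"{path}: placement mass exceeds 1 for read(s): "
            f"{', '.join(map(str, over.index[:5]))}"
        )
    if known_clades is not None:
        known = set(known_clades)
        unknown = sorted(set(records["clade"]) - known)
        if unknown:
            raise DataError(
                f"{path}: unknown clade label(s) {unknown}; "
                f"known labels: {sorted(known)}"
            )
    return records


def _load_jplace(path: Path, edge_to_clade: Mapping[int, str] | None) -> pd.DataFrame:
    doc = json.loads(path.read_text(encoding="utf-8"))
    if "version" not in doc:
        raise SchemaError(f"{path}: jplace file lacks a 'version' field")
    if edge_to_clade is None:
        raise ValueError("jplace input requires an edge_num -> clade mapping")
    fields = doc["fields"]
    i_edge = fields.index("edge_num")
    i_mass = fields.index("like_weight_ratio")
    gene_family = doc.get("metadata", {}).get("gene_family", "unknown")
    rows = []
    for pq in doc.get("placements", []):
        names = pq.get("nm") or [[n, 1] for n in pq.get("n", [])]
        for name, _mult in names:
            for placement in pq["p"]:
                edge = int(placement[i_edge])
                if edge not in edge_to_clade:
                    raise DataError(
                        f"{path}: edge {edge} absent from the edge->clade mapping"
                    )
                rows.append(
                    {
                        "read_id": name,
                        "gene_family": gene_family,
                        "clade": edge_to_clade[edge],
                        "mass": float(placement[i_mass]),
                    }
                )
    frame = pd.DataFrame(rows, columns=PLACEMENT_TSV_COLUMNS)
    if not frame.empty:
        # a read may hit several edges within one clade: accumulate
        frame = (
            frame.groupby(["read_id", "gene_family", "clade"], as_index=False)["mass"]
            .sum()
        )
    return frame


def load_edge_mapping(path: str | Path) -> dict[int, str]:
    """Read a two-column TSV (edge_num, clade) into a mapping."""
    df = pd.read_csv(Path(path), sep="\t")
    if not {"edge_num", "clade"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns edge_num and clade")
    return dict(zip(df["edge_num"].astype(int), df["clade"].astype(str)))


def load_config(path: str | Path) -> dict[str, str]:
    """Read a flat key=value configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed config line {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
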