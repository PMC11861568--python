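"""Readers and writers for screen plate data, count tables, GMT libraries
and result tables.

All delimited files are tab-separated with a header line, "." as the
decimal point, and deterministic row/column order so that repeated runs
are byte-identical. Readers validate aggressively and never silently
drop rows: every exclusion is either an error naming the offending row
or a counted warning.

Schemas
-------
plate map      : plate_id, well, role, gene_id, control_type
measurements   : plate_id, well, replicate, rlu
count table    : gene_id + one integer column per sample
GMT            : term <tab> description <tab> gene1 <tab> gene2 ...
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PLATEMAP_COLUMNS = ["plate_id", "well", "role", "gene_id", "control_type"]
MEASUREMENT_COLUMNS = ["plate_id", "well", "replicate", "rlu"]

WELL_ROLES = {"test", "negative_control", "empty"}
CONTROL_TYPES = {"GFP", "Scrambled", "AllStars"}

_WELL_RE = re.compile(r"^([A-P])([1-9][0-9]?)$")

PACKAGE_VERSION = "0.1.0"


def parse_well(well: str) -> tuple[int, int]:
    """Parse a 384-well address like ``"A1"`` into 0-based (row, column).

    Rows run A..P, columns 1..24 (returned 0-based).
    """
    m = _WELL_RE.match(str(well))
    if not m:
        raise ValidationError(f"malformed well address {well!r} (expected e.g. 'A1'..'P24')")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2))
    if not 1 <= col <= 24:
        raise ValidationError(f"well column out of range in {well!r} (1..24)")
    return row, col - 1


def format_well(row: int, col: int) -> str:
    """Inverse of :func:`parse_well`; inputs are 0-based indices."""
    if not (0 <= row < 16 and 0 <= col < 24):
        raise ValidationError(f"well indices out of range: row={row}, col={col}")
    return f"{chr(ord('A') + row)}{col + 1}"


@dataclass
class ScreenDataset:
    """An arrayed screen: one plate map shared by all replicates plus raw
    per-well luminescence measurements.

    Attributes
    ----------
    platemap:
        One row per (plate_id, well); columns ``PLATEMAP_COLUMNS``.
        ``gene_id`` is empty for non-test wells, ``control_type`` empty
        for non-control wells.
    measurements:
        One row per (plate_id, well, replicate); columns
        ``MEASUREMENT_COLUMNS``. ``rlu`` is the raw luminescence, > 0.
    """

    platemap: pd.DataFrame
    measurements: pd.DataFrame

    def validate(self) -> None:
        pm, ms = self.platemap, self.measurements
        for col in PLATEMAP_COLUMNS:
            if col not in pm.columns:
                raise SchemaError(f"plate map missing column {col!r}")
        for col in MEASUREMENT_COLUMNS:
            if col not in ms.columns:
                raise SchemaError(f"measurements missing column {col!r}")

        for i, row in enumerate(pm.itertuples(index=False), start=2):
            parse_well(row.well)
            if row.role not in WELL_ROLES:
                raise ValidationError(f"plate map row {i}: unknown role {row.role!r}")
            if row.role == "test" and not row.gene_id:
                raise ValidationError(f"plate map row {i}: test well without gene_id")
            if row.role == "negative_control" and row.control_type not in CONTROL_TYPES:
                raise ValidationError(
                    f"plate map row {i}: control well with unknown control_type "
                    f"{row.control_type!r}"
                )

        dup = pm.duplicated(subset=["plate_id", "well"])
        if dup.any():
            raise ValidationError(
                f"plate map: duplicate (plate_id, well) at row {dup.idxmax() + 2}"
            )
        test = pm[pm["role"] == "test"]
        gdup = test["gene_id"].duplicated()
        if gdup.any():
            raise ValidationError(
                f"plate map: gene {test.loc[gdup.idxmax(), 'gene_id']!r} mapped to "
                "more than one test well"
            )

        mapped = set(zip(pm["plate_id"], pm["well"]))
        dup = ms.duplicated(subset=["plate_id", "well", "replicate"])
        if dup.any():
            raise ValidationError(
                f"measurements: duplicate (plate_id, well, replicate) at row {dup.idxmax() + 2}"
            )
        for i, row in enumerate(ms.itertuples(index=False), start=2):
            if (row.plate_id, row.well) not in mapped:
                raise ValidationError(
                    f"measurements row {i}: well {row.well!r} on plate {row.plate_id!r} "
                    "is not in the plate map"
                )
            if not row.rlu > 0:
                raise ValidationError(f"measurements row {i}: nonpositive RLU {row.rlu}")

        reps = sorted(ms["replicate"].unique())
        if reps and reps != list(range(reps[0], reps[0] + len(reps))):
            raise ValidationError(f"replicate ids are not contiguous: {reps}")

    @property
    def replicates(self) -> list[int]:
        return sorted(self.measurements["replicate"].unique())

    @property
    def genes(self) -> list[str]:
        test = self.platemap[self.platemap["role"] == "test"]
        return sorted(test["gene_id"].unique())


def _sorted_platemap(pm: pd.DataFrame) -> pd.DataFrame:
    key = pm["well"].map(parse_well)
    return (
        pm.assign(_rk=[k[0] for k in key], _ck=[k[1] for k in key])
        .sort_values(["plate_id", "_rk", "_ck"], kind="mergesort")
        .drop(columns=["_rk", "_ck"])
        .reset_index(drop=True)
    )


def write_screen(dataset: ScreenDataset, platemap_path, measurements_path) -> None:
    """Write a screen as the two canonical TSVs with deterministic ordering."""
    dataset.validate()
    pm = _sorted_platemap(dataset.platemap)
    pm.to_csv(platemap_path, sep="\t", index=False)
    key = dataset.measurements["well"].map(parse_well)
    ms = (
        dataset.measurements.assign(_rk=[k[0] for k in key], _ck=[k[1] for k in key])
        .sort_values(["replicate", "plate_id", "_rk", "_ck"], kind="mergesort")
        .drop(columns=["_rk", "_ck"])
        .reset_index(drop=True)
    )
    ms.to_csv(measurements_path, sep="\t", index=False, float_format="%.17g")


def read_screen(platemap_path, measurements_path) -> ScreenDataset:
    """Read and cross-validate a plate map / measurements file pair."""
    pm = pd.read_csv(platemap_path, sep="\t", dtype=str, keep_default_na=False)
    for col in PLATEMAP_COLUMNS:
        if col not in pm.columns:
            raise SchemaError(f"{platemap_path}: plate map missing column {col!r}")
    ms = pd.read_csv(
        measurements_path, sep="\t", dtype={"plate_id": str, "well": str},
        float_precision="round_trip",
    )
    for col in MEASUREMENT_COLUMNS:
        if col not in ms.columns:
            raise SchemaError(f"{measurements_path}: measurements missing column {col!r}")
    try:
        ms["replicate"] = ms["replicate"].astype(int)
        ms["rlu"] = ms["rlu"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{measurements_path}: non-numeric replicate or rlu: {exc}")
    ds = ScreenDataset(platemap=pm, measurements=ms)
    ds.validate()
    return ds


def read_counts(path) -> pd.DataFrame:
    """Read a gene × sample count table (TSV, first column ``gene_id``).

    Returns a DataFrame indexed by gene_id with integer sample columns.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: count table has no sample columns")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    df = df.set_index("gene_id")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = int(values.index.get_loc(values.index[values.isna()][0]))
            raise ValidationError(f"{path}: non-numeric count in column {col!r} (row {row + 2})")
        if (values < 0).any():
            gene = values.index[values < 0][0]
            raise ValidationError(f"{path}: negative count for gene {gene!r} in column {col!r}")
        df[col] = values.astype(int)
    return df


def write_counts(table: pd.DataFrame, path) -> None:
    table.sort_index().rename_axis("gene_id").to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set library into an ordered ``{term: members}`` dict."""
    library: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT record has {len(fields)} fields, expected at least 3 "
                    "(name, description, >=1 gene)",
                    line_number=lineno,
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"gene set {name!r} is empty", line_number=lineno)
            if name in library:
                raise ParseError(f"duplicate gene set name {name!r}", line_number=lineno)
            library[name] = genes
    return library


def write_gmt(library: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in library.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")


def config_hash(params: dict) -> str:
    """Stable short hash of a JSON-serialisable parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(out_dir, stage: str, params: dict, seed: int | None = None) -> Path:
    """Write the JSON sidecar recording inputs, config hash, seed and version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "stage": stage,
        "version": PACKAGE_VERSION,
        "config_hash": config_hash(params),
        "seed": seed,
        "params": {k: str(v) for k, v in sorted(params.items())},
    }
    path = out_dir / f"{stage}_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def write_table(df: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    """Write a result table as TSV with deterministic row order."""
    out = df.copy()
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
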