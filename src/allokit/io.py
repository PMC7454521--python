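"""CSV interchange: schemas, readers, writers.

All stages exchange long-format UTF-8 CSV with a header row; a leading
comment line ``# allokit:<schema>/<version>`` versions the layout without
breaking ordinary CSV readers.  Unknown columns are preserved on
round-trip and row order is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import SchemaError

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class TableSchema:
    name: str
    version: int
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()

    @property
    def tag(self) -> str:
        return f"# allokit:{self.name}/{self.version}"


MELT_SCHEMA = TableSchema(
    "melt", 1, ("variant_id", "urea_M", "wavelength_nm", "signal"), ("replicate",)
)
KINETICS_SCHEMA = TableSchema(
    "kinetics", 1, ("variant_id", "substrate_uM", "v0"), ("replicate",)
)
PROGRESS_SCHEMA = TableSchema(
    "progress", 1, ("variant_id", "substrate_uM", "time_s", "rfu"), ("replicate",)
)
GROWTH_SCHEMA = TableSchema(
    "growth",
    1,
    ("variant_id", "time_hr"),
    ("sample_id", "replicate", "log2_ratio", "abundance", "is_vector_control"),
)
ABUNDANCE_SCHEMA = TableSchema(
    "abundance", 1, ("variant_id", "igps_intensity", "loading_intensity"), ("replicate",)
)
CYCLES_SCHEMA = TableSchema("cycles", 1, ("property", "single1", "single2", "double"))

SCHEMAS = {
    s.name: s
    for s in (
        MELT_SCHEMA,
        KINETICS_SCHEMA,
        PROGRESS_SCHEMA,
        GROWTH_SCHEMA,
        ABUNDANCE_SCHEMA,
        CYCLES_SCHEMA,
    )
}


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a CSV against a schema; missing required columns raise a
    :class:`SchemaError` naming the first missing column.  CRLF and LF
    files parse identically."""
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    for col in schema.required:
        if col not in df.columns:
            raise SchemaError(
                f"{Path(path).name}: missing required column '{col}' "
                f"(schema {schema.name}/{schema.version})"
            )
    return df


def write_table(df: pd.DataFrame, path, schema: TableSchema | None = None) -> None:
    """Write a CSV with the schema tag comment line and stable float
    formatting (so identical inputs produce byte-identical files)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema is not None:
        for col in schema.required:
            if col not in df.columns:
                raise SchemaError(f"refusing to write: missing required column '{col}'")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if schema is not None:
            fh.write(schema.tag + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
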