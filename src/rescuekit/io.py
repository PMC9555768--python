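"""Reading and writing the delimited text formats used by the pipeline.

DEG tables are TSV (default) or CSV with a header row; column names and the
fold-change scale are configurable through :class:`DEGDialect` so tables
exported from different DEG callers can be consumed unchanged. Point
patterns are long tables with one row per cell. Configs are YAML or JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rescue import DEGTable
from .spatial import SectionPattern

__all__ = [
    "DEGDialect",
    "read_deg_table",
    "write_deg_table",
    "read_point_table",
    "write_point_table",
    "patterns_to_dataframe",
    "load_config",
]

POINT_COLUMNS = ["x_um", "y_um", "section", "embryo", "genotype", "segment"]


@dataclass(frozen=True)
class DEGDialect:
    """Column mapping and fold-change scale of a DEG table on disk.

    ``fc_scale="linear"`` declares signed linear fold changes (sign carries
    direction, magnitude >= 1), converted to log2 on read as
    ``sign(fc) * log2(|fc|)``.
    """

    gene: str = "gene_id"
    fc: str = "log2fc"
    pp: str = "pp"
    fc_scale: str = "log2"
    sep: str | None = None  # None: infer from extension (.csv -> ',', else tab)

    def __post_init__(self) -> None:
        if self.fc_scale not in ("log2", "linear"):
            raise ValueError("fc_scale must be 'log2' or 'linear'")


def _sep_for(path: Path, dialect: DEGDialect) -> str:
    if dialect.sep is not None:
        return dialect.sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_deg_table(
    path: str | Path,
    dialect: DEGDialect | None = None,
    contrast_name: str | None = None,
    universe_size: int | None = None,
) -> DEGTable:
    """Read one contrast's DEG table from delimited text.

    Raises with the offending line number on unparseable numerics, names
    duplicated genes, and rejects posterior probabilities outside [0, 1].
    ``universe_size`` defaults to the record count.
    """
    path = Path(path)
    dialect = dialect or DEGDialect()
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (dialect.gene, dialect.fc, dialect.pp):
        if col not in df.columns:
            raise ValueError(
                f"{path.name}: missing column {col!r}; found {list(df.columns)}"
            )
    out = pd.DataFrame({"gene_id": df[dialect.gene].astype(str)})
    for col, name in ((dialect.fc, "log2fc"), (dialect.pp, "pp")):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path.name}: unparseable value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise ValueError(f"{path.name}: missing value in column {col!r} at line {line}")
        out[name] = vals.to_numpy(float)
    if dialect.fc_scale == "linear":
        fc = out["log2fc"].to_numpy()
        if (fc == 0).any():
            raise ValueError(f"{path.name}: linear fold change of 0 is undefined")
        out["log2fc"] = np.sign(fc) * np.log2(np.abs(fc))
    return DEGTable(
        contrast_name=contrast_name or path.stem,
        data=out,
        universe_size=universe_size,
    )


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.data.to_csv(path, sep=sep, index=False)


def patterns_to_dataframe(patterns) -> pd.DataFrame:
    """Flatten section patterns into the long one-row-per-cell table."""
    frames = []
    for p in patterns:
        frames.append(
            pd.DataFrame(
                {
                    "x_um": p.points[:, 0],
                    "y_um": p.points[:, 1],
                    "section": p.section_index,
                    "embryo": p.embryo_id,
                    "genotype": p.genotype,
                    "segment": p.segment,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=POINT_COLUMNS
    )


def write_point_table(patterns, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    patterns_to_dataframe(patterns).to_csv(path, sep=sep, index=False)


def read_point_table(path: str | Path) -> pd.DataFrame:
    """Read a one-row-per-cell point table (TSV default, CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # keep_default_na: the genotype label "null" must stay a string
    df = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=[""])
    missing = set(POINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path.name}: config must be a mapping")
    return cfg
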