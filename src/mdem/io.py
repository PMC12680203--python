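"""Table readers/writers (CSV, ARFF), model serialization, run config.

CSV goes through pandas (header row required).  ARFF support is a small
reader/writer for the numeric + nominal subset of the format, which is
all these workflows use; nominal class labels keep their declaration
order.  Models serialize to JSON with counts, powered sums and class
order — enough to resume incremental evolution exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classifier import MDEMModel

__all__ = [
    "read_table",
    "write_table",
    "read_arff",
    "write_arff",
    "save_model",
    "load_model",
    "RunConfig",
]


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"csv", "arff"}:
        return suffix
    raise ValueError(f"cannot infer table format from {path!r}; pass format=")


def read_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a labeled table; row order preserved, numerics parsed as float."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "arff":
        return read_arff(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_table(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "arff":
        write_arff(df, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


_ATTR_RE = re.compile(r"@attribute\s+(?:'([^']+)'|\"([^\"]+)\"|(\S+))\s+(.+)", re.IGNORECASE)


def read_arff(path: str | Path) -> pd.DataFrame:
    """Parse an ARFF file with numeric and nominal attributes.

    Nominal values are kept as strings in declaration order; '?' cells
    become NaN for numeric attributes and None for nominal ones.
    """
    names: list[str] = []
    kinds: list[str] = []
    rows: list[list] = []
    in_data = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        if not in_data:
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                m = _ATTR_RE.match(line)
                if not m:
                    raise ValueError(f"{path}: malformed @attribute on line {lineno}")
                name = next(g for g in m.groups()[:3] if g is not None)
                decl = m.group(4).strip()
                names.append(name)
                kinds.append("nominal" if decl.startswith("{") else "numeric")
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            raise ValueError(f"{path}: unexpected header line {lineno}: {line!r}")
        values = [v.strip().strip("'\"") for v in line.split(",")]
        if len(values) != len(names):
            raise ValueError(
                f"{path}: line {lineno} has {len(values)} values, expected {len(names)}"
            )
        row = []
        for (v, kind, name) in zip(values, kinds, names):
            if v == "?":
                row.append(float("nan") if kind == "numeric" else None)
            elif kind == "numeric":
                try:
                    row.append(float(v))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: unparseable numeric cell at line {lineno}, "
                        f"column {name!r}: {v!r}"
                    ) from exc
            else:
                row.append(v)
        rows.append(row)
    if not names:
        raise ValueError(f"{path}: no @attribute declarations found")
    return pd.DataFrame(rows, columns=names)


def write_arff(df: pd.DataFrame, path: str | Path, relation: str = "table") -> None:
    lines = [f"@relation {relation}", ""]
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            lines.append(f"@attribute {col} numeric")
        else:
            levels = ",".join(str(v) for v in pd.unique(df[col].dropna()))
            lines.append(f"@attribute {col} {{{levels}}}")
    lines += ["", "@data"]
    for _, row in df.iterrows():
        lines.append(",".join("?" if pd.isna(v) else str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def save_model(model: MDEMModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path: str | Path) -> MDEMModel:
    return MDEMModel.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunConfig:
    """One run of the pipeline, loadable from a YAML key/value file."""

    input_path: str = ""
    input_format: str | None = None
    class_column: str = "class"
    positive_label: object = None
    missing_markers: dict = field(default_factory=dict)
    outlier_factor: float = 3.0
    extreme_factor: float = 6.0
    scaling_mode: str = "global"  # or "per-fold"
    order: int = 1
    evolve: bool = True
    k: int = 5
    stratified: bool = False
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.scaling_mode not in {"global", "per-fold"}:
            raise ValueError("scaling_mode must be 'global' or 'per-fold'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
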