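"""Table readers/writers for expression profiles, Ct tables and fits.

Three input dialects are supported for expression tables:

``long``
    CSV/TSV with columns ``gene_id,time,level`` and optional
    ``repeat_id`` (default ``"R1"``) and ``tech_error``.
``wide``
    First column gene ids, remaining column headers numeric times; one
    biological repeat per file (set by ``repeat_id``).
``xlsx``
    A workbook with one wide-format sheet per biological repeat; the
    sheet-name -> repeat-id mapping is configurable so layout drift is a
    config change, not a code change.

Auto-detection never silently coerces: ambiguous files raise and ask
for an explicit dialect.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError
from .types import ExpressionProfile

__all__ = [
    "read_expression_table",
    "read_ct_table",
    "profiles_to_frame",
    "frame_to_profiles",
    "write_profiles",
]

_LONG_REQUIRED = {"gene_id", "time", "level"}


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[out.isna() & df[col].notna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise TableFormatError(f"{path}: non-numeric values in '{col}' at rows {rows}")
    return out


def frame_to_profiles(df: pd.DataFrame, source: str = "<frame>") -> list[ExpressionProfile]:
    """Validate a long-format frame and split it into profiles.

    Duplicate (gene, repeat, time) rows raise with the offending row
    numbers.
    """
    missing = _LONG_REQUIRED - set(df.columns)
    if missing:
        raise TableFormatError(f"{source}: missing columns {sorted(missing)}")
    df = df.copy()
    if "repeat_id" not in df.columns:
        df["repeat_id"] = "R1"
    df["time"] = _numeric(df, "time", source)
    df["level"] = _numeric(df, "level", source)
    dup = df.duplicated(subset=["gene_id", "repeat_id", "time"], keep=False)
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:8])
        raise TableFormatError(f"{source}: duplicate (gene, repeat, time) rows at {rows}")
    profiles = []
    for (gene, rep), grp in df.groupby(["gene_id", "repeat_id"], sort=True):
        grp = grp.sort_values("time")
        errs = grp["tech_error"].to_numpy(float) if "tech_error" in grp.columns else None
        profiles.append(
            ExpressionProfile(
                str(gene), str(rep),
                grp["time"].to_numpy(float), grp["level"].to_numpy(float),
                errs,
            )
        )
    return profiles


def _wide_to_profiles(df: pd.DataFrame, repeat_id: str, source) -> list[ExpressionProfile]:
    if df.shape[1] < 2:
        raise TableFormatError(f"{source}: wide table needs a gene column plus time columns")
    gene_col = df.columns[0]
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except (TypeError, ValueError) as exc:
        raise TableFormatError(f"{source}: wide column headers must be numeric times") from exc
    if not np.all(np.diff(np.sort(times)) > 0):
        raise TableFormatError(f"{source}: duplicate time columns")
    order = np.argsort(times)
    profiles = []
    for _, row in df.iterrows():
        levels = pd.to_numeric(row.iloc[1:], errors="coerce").to_numpy(float)
        keep = ~np.isnan(levels[order])
        profiles.append(
            ExpressionProfile(str(row[gene_col]), repeat_id, times[order][keep], levels[order][keep])
        )
    return profiles


def read_expression_table(
    path,
    dialect: str = "auto",
    repeat_id: str = "R1",
    xlsx_layout: dict[str, str] | None = None,
) -> list[ExpressionProfile]:
    """Read an expression table in any supported dialect.

    ``xlsx_layout`` maps sheet names to repeat ids (default: every sheet,
    repeat id = sheet name).
    """
    path = Path(path)
    if dialect == "auto":
        if path.suffix.lower() == ".xlsx":
            dialect = "xlsx"
        else:
            head = _read_delimited(path)
            if _LONG_REQUIRED <= set(head.columns):
                dialect = "long"
            else:
                try:
                    [float(c) for c in head.columns[1:]]
                    dialect = "wide"
                except (TypeError, ValueError):
                    raise TableFormatError(
                        f"{path}: cannot auto-detect dialect (neither long columns "
                        f"{sorted(_LONG_REQUIRED)} nor numeric wide headers); pass dialect="
                    ) from None

    if dialect == "long":
        return frame_to_profiles(_read_delimited(path), str(path))
    if dialect == "wide":
        return _wide_to_profiles(_read_delimited(path), repeat_id, path)
    if dialect == "xlsx":
        book = pd.read_excel(path, sheet_name=None)
        layout = xlsx_layout or {name: name for name in book}
        profiles = []
        for sheet, rep in layout.items():
            if sheet not in book:
                raise TableFormatError(f"{path}: sheet {sheet!r} not found")
            profiles.extend(_wide_to_profiles(book[sheet], str(rep), f"{path}:{sheet}"))
        return profiles
    raise TableFormatError(f"unknown dialect {dialect!r}")


def read_ct_table(path) -> pd.DataFrame:
    """Read a tidy Ct table (gene_id,time,repeat_id,tech_rep,ct)."""
    path = Path(path)
    df = _read_delimited(path)
    missing = {"gene_id", "time", "repeat_id", "ct"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    df["time"] = _numeric(df, "time", path)
    df["ct"] = _numeric(df, "ct", path)
    return df


def profiles_to_frame(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    """Long-format frame (gene_id,repeat_id,time,level[,tech_error])."""
    rows = []
    any_err = any(p.tech_errors is not None for p in profiles)
    for p in profiles:
        errs = p.tech_errors if p.tech_errors is not None else np.full(len(p), np.nan)
        for t, lv, e in zip(p.times, p.levels, errs):
            rec = dict(gene_id=p.gene_id, repeat_id=p.repeat_id, time=t, level=lv)
            if any_err:
                rec["tech_error"] = e
            rows.append(rec)
    return pd.DataFrame(rows)


def write_profiles(profiles: list[ExpressionProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)
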