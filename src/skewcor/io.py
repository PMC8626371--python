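"""Reading and writing measurement and result tables.

The canonical input is a tab-delimited (or CSV, or spreadsheet) table
with one row per sample, a first column of sample identifiers, one
intensity column per measured isotopologue, and optionally a ``time``
column (hours) that marks the table as a labelling time course.

Isotopologue columns are named in the label grammar: the literal
``No label`` for the unlabelled species, otherwise space-separated
``<count><element><mass number>`` tokens such as ``2C13`` or
``2C13 1N15``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chem import IsotopeTable, LabelSpec, default_isotope_table
from .correction import CorrectionResult
from .errors import InvalidLabelError, MeasurementError

_DIALECTS = {"tsv": "\t", "csv": ","}
_EXT_DIALECT = {
    ".tsv": "tsv",
    ".tab": "tsv",
    ".txt": "tsv",
    ".csv": "csv",
    ".xlsx": "xlsx",
}


@dataclass
class MeasurementTable:
    """Samples x isotopologues intensities plus experiment metadata."""

    data: pd.DataFrame  # columns are canonical label names
    labels: tuple[LabelSpec, ...]
    time: pd.Series | None = None  # hours, indexed like data (optional)
    dialect: str = "tsv"

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect:
        if dialect not in {"tsv", "csv", "xlsx"}:
            raise MeasurementError(f"unknown dialect {dialect!r}")
        return dialect
    d = _EXT_DIALECT.get(path.suffix.lower())
    if d is None:
        raise MeasurementError(
            f"cannot infer table dialect from extension {path.suffix!r}; "
            "pass dialect='tsv'|'csv'|'xlsx'"
        )
    return d


def read_measurements(
    path: str | Path,
    dialect: str | None = None,
    table: IsotopeTable | None = None,
) -> MeasurementTable:
    """Read and validate an isotopologue intensity table.

    Column names must parse in the label grammar (``No label``, ``2C13``,
    ``2C13 1N15``...); a ``time`` column (case-insensitive) is split off
    as time-course metadata.  Intensities must be finite and >= 0.
    """
    path = Path(path)
    if not path.exists():
        raise MeasurementError(f"no such file: {path}")
    d = _infer_dialect(path, dialect)
    if d == "xlsx":
        raw = pd.read_excel(path, index_col=0)
    else:
        raw = pd.read_csv(path, sep=_DIALECTS[d], index_col=0)
    table = table or default_isotope_table()

    time = None
    labels: list[LabelSpec] = []
    rename: dict[str, str] = {}
    for col in raw.columns:
        if str(col).strip().lower() == "time":
            time = raw[col].astype(float)
            continue
        try:
            spec = LabelSpec.parse(str(col), table)
        except InvalidLabelError as exc:
            raise MeasurementError(
                f"column {col!r} in {path.name} is not a valid isotopologue "
                f"label ({exc}); valid names: 'No label' or space-separated "
                "'<count><element><mass number>' tokens like '2C13 1N15'"
            ) from exc
        if spec in labels:
            raise MeasurementError(f"duplicate isotopologue column {col!r}")
        labels.append(spec)
        rename[col] = spec.name

    try:
        data = raw[list(rename)].rename(columns=rename).astype(float)
    except (TypeError, ValueError) as exc:
        raise MeasurementError(
            f"non-numeric intensity in {path.name}: {exc}"
        ) from exc
    if data.isna().any().any():
        raise MeasurementError(f"missing intensity in {path.name}")
    neg = data.lt(0)
    if neg.any().any():
        sample = neg.any(axis=1).idxmax()
        col = neg.loc[sample].idxmax()
        raise MeasurementError(
            f"negative intensity at sample {sample!r}, column {col!r}"
        )
    return MeasurementTable(data=data, labels=tuple(labels), time=time, dialect=d)


def _write_frame(df: pd.DataFrame, path: Path, dialect: str) -> None:
    out = df.copy()
    out.index.name = out.index.name or "sample"
    if dialect == "xlsx":
        out.to_excel(path)
    else:
        out.to_csv(path, sep=_DIALECTS[dialect])


def write_results(
    result: CorrectionResult,
    path: str | Path,
    dialect: str | None = None,
    time: pd.Series | None = None,
) -> list[Path]:
    """Write corrected intensities (and fractions, and a warnings log).

    The corrected table goes to *path*; when the result carries relative
    fractions they go to ``<stem>_fractions<ext>``; warnings, if any, to
    ``<stem>.log``.  Output is deterministic: identical inputs produce
    byte-identical files.  Returns the paths written.
    """
    path = Path(path)
    d = _infer_dialect(path, dialect)
    written = [path]
    corrected = result.corrected
    if time is not None:
        corrected = corrected.copy()
        corrected.insert(0, "time", time)
    _write_frame(corrected, path, d)
    if result.fractions is not None:
        fpath = path.with_name(path.stem + "_fractions" + path.suffix)
        fractions = result.fractions
        if time is not None:
            fractions = fractions.copy()
            fractions.insert(0, "time", time)
        _write_frame(fractions, fpath, d)
        written.append(fpath)
    if result.warnings:
        lpath = path.with_suffix(".log")
        lpath.write_text("".join(w + "\n" for w in result.warnings))
        written.append(lpath)
    return written


def read_compound_map(path: str | Path) -> dict[str, str]:
    """Two-column text file mapping compound names to formulas."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MeasurementError(
                f"compound map line needs 'name formula': {line!r}"
            )
        out[parts[0]] = parts[1].strip()
    return out
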