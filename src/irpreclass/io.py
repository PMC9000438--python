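"""Readers and writers for portable spectrum formats.

Supported formats:

* CSV matrix — one shared wavenumber axis plus one spectrum per row
  (``orientation="rows"``) or per column (``orientation="columns"``).
  Comma-separated, ``.`` decimal, UTF-8, header mandatory.
* JCAMP-DX 4.24 subset — single spectra, uncompressed AFFN tables only
  (``XYDATA=(X++(Y..Y))`` or ``XYPOINTS=(XY..XY)``).  SQZ/DIF/DUP
  compressed dialects are rejected with an explicit error.
* TSV results table for preclassification output.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import (
    IntegrityError,
    ParseError,
    ShapeError,
    UnsupportedDialectError,
)
from .spectra import SpectralDataset, Spectrum

if TYPE_CHECKING:  # pragma: no cover
    from .msc import PreclassResult

__all__ = [
    "read_csv_dataset",
    "write_csv_dataset",
    "read_jcamp_spectrum",
    "write_jcamp_spectrum",
    "write_results_table",
    "read_results_table",
]

# full round-trip precision for float64
_FLOAT_FMT = "{:.17g}"


def _parse_float(cell: str, row_label: str, col_label: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"non-numeric cell {cell!r} at row {row_label!r}, column {col_label!r}"
        ) from None


def _read_rows(path: Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh) if row]


def read_csv_dataset(path, orientation: str = "rows") -> SpectralDataset:
    """Read a CSV spectrum matrix.

    ``orientation="rows"``: header is ``id,<wn1>,<wn2>,...`` and each
    following row is one spectrum.  ``orientation="columns"``: header is
    ``wavenumber,<id1>,<id2>,...`` and each following row is one channel.
    """
    if orientation not in ("rows", "columns"):
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    path = Path(path)
    rows = _read_rows(path)
    if len(rows) < 2:
        raise ShapeError(f"{path}: need a header and at least one data row")
    header, data = rows[0], rows[1:]
    width = len(header)
    for k, row in enumerate(data):
        if len(row) != width:
            raise ShapeError(
                f"{path}: row {k + 2} has {len(row)} cells, expected {width}"
            )
    if orientation == "rows":
        axis = np.array(
            [_parse_float(c, "header", f"column {j + 2}") for j, c in enumerate(header[1:])]
        )
        ids = [row[0] for row in data]
        matrix = np.array(
            [
                [_parse_float(c, row[0], header[j + 1]) for j, c in enumerate(row[1:])]
                for row in data
            ]
        )
    else:
        ids = list(header[1:])
        axis = np.array(
            [_parse_float(row[0], f"row {k + 2}", header[0]) for k, row in enumerate(data)]
        )
        matrix = np.array(
            [
                [_parse_float(c, f"row {k + 2}", ids[j]) for j, c in enumerate(row[1:])]
                for k, row in enumerate(data)
            ]
        ).T
    return SpectralDataset(axis, matrix, ids)


def write_csv_dataset(dataset: SpectralDataset, path, orientation: str = "rows") -> None:
    """Write a dataset as a CSV matrix (inverse of :func:`read_csv_dataset`)."""
    if orientation not in ("rows", "columns"):
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    path = Path(path)
    fmt = _FLOAT_FMT.format
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        if orientation == "rows":
            w.writerow(["id"] + [fmt(x) for x in dataset.axis])
            for i, sid in enumerate(dataset.ids):
                w.writerow([sid] + [fmt(x) for x in dataset.matrix[i]])
        else:
            w.writerow(["wavenumber"] + list(dataset.ids))
            for j, wn in enumerate(dataset.axis):
                w.writerow([fmt(wn)] + [fmt(x) for x in dataset.matrix[:, j]])


# characters legal inside an AFFN numeric table (E/e exponents included);
# anything alphabetic beyond that signals SQZ/DIF/DUP pseudo-digits
_AFFN_LINE = re.compile(r"^[\s0-9+\-.,;Ee]*$")


def _jcamp_headers(lines: list[str]) -> dict[str, str]:
    headers: dict[str, str] = {}
    for ln in lines:
        if ln.startswith("##"):
            key, _, val = ln[2:].partition("=")
            headers[key.strip().upper().replace(" ", "")] = val.strip()
    return headers


def read_jcamp_spectrum(path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (uncompressed AFFN subset).

    The axis is reconstructed from FIRSTX/LASTX/NPOINTS (or DELTAX);
    XFACTOR/YFACTOR are applied.  The tabulated per-line X values are
    used only as a consistency aid, per the JCAMP-DX convention.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text(encoding="utf-8").splitlines()]
    headers = _jcamp_headers(lines)
    title = headers.get("TITLE", path.stem)

    data_kind = None
    start = None
    for i, ln in enumerate(lines):
        u = ln.upper()
        if u.startswith("##XYDATA"):
            data_kind, start = "xydata", i
            break
        if u.startswith("##XYPOINTS"):
            data_kind, start = "xypoints", i
            break
    if data_kind is None:
        raise ParseError(f"{path}: no ##XYDATA or ##XYPOINTS block found")
    if data_kind == "xydata" and "(X++(Y..Y))" not in lines[start].replace(" ", ""):
        raise UnsupportedDialectError(
            f"{path}: only XYDATA=(X++(Y..Y)) is supported, got {lines[start]!r}"
        )

    table: list[str] = []
    for ln in lines[start + 1 :]:
        if ln.startswith("##"):
            break
        if ln.strip():
            table.append(ln)
    for ln in table:
        if not _AFFN_LINE.match(ln):
            raise UnsupportedDialectError(
                f"{path}: compressed (SQZ/DIF/DUP) JCAMP-DX data are not supported: {ln!r}"
            )

    xfactor = float(headers.get("XFACTOR", "1"))
    yfactor = float(headers.get("YFACTOR", "1"))

    if data_kind == "xypoints":
        xs, ys = [], []
        for ln in table:
            for pair in re.split(r"[;]", ln):
                nums = [t for t in re.split(r"[\s,]+", pair.strip()) if t]
                if not nums:
                    continue
                if len(nums) != 2:
                    raise ParseError(f"{path}: malformed XY pair {pair!r}")
                xs.append(float(nums[0]) * xfactor)
                ys.append(float(nums[1]) * yfactor)
        x = np.array(xs)
        y = np.array(ys)
    else:
        ys = []
        for ln in table:
            nums = [t for t in re.split(r"[\s,]+", ln.strip()) if t]
            ys.extend(float(t) for t in nums[1:])  # first number is the line's X
        y = np.array(ys) * yfactor
        try:
            firstx = float(headers["FIRSTX"])
            lastx = float(headers["LASTX"])
        except KeyError as e:
            raise ParseError(f"{path}: missing required header ##{e.args[0]}") from None
        npoints = int(headers.get("NPOINTS", len(ys)))
        if "DELTAX" in headers and npoints > 1:
            deltax = float(headers["DELTAX"])
        elif npoints > 1:
            deltax = (lastx - firstx) / (npoints - 1)
        else:
            deltax = 0.0
        x = firstx + deltax * np.arange(npoints)

    if "NPOINTS" in headers and int(headers["NPOINTS"]) != y.size:
        raise IntegrityError(
            f"{path}: NPOINTS={headers['NPOINTS']} but {y.size} Y values were read"
        )
    return Spectrum(x, y, title)


def write_jcamp_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as minimal JCAMP-DX ``XYDATA=(X++(Y..Y))`` (AFFN)."""
    path = Path(path)
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    n = wn.size
    deltax = (wn[-1] - wn[0]) / (n - 1) if n > 1 else 0.0
    out = [
        f"##TITLE={spectrum.id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={_FLOAT_FMT.format(wn[0])}",
        f"##LASTX={_FLOAT_FMT.format(wn[-1])}",
        f"##DELTAX={_FLOAT_FMT.format(deltax)}",
        f"##NPOINTS={n}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, n, per_line):
        chunk = ab[i : i + per_line]
        x = wn[0] + deltax * i
        out.append(
            " ".join([_FLOAT_FMT.format(x)] + [_FLOAT_FMT.format(v) for v in chunk])
        )
    out.append("##END=")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


_RESULT_COLUMNS = ["id", "a", "b", "rmse", "threshold", "label"]


def write_results_table(results: list["PreclassResult"], path) -> None:
    """Write preclassification results as a TSV, one row per spectrum.

    Numeric fields carry 12 significant digits; row order is input order.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        f"{r.fit.a:.12g}",
                        f"{r.fit.b:.12g}",
                        f"{r.fit.rmse:.12g}",
                        f"{r.threshold:.12g}",
                        r.label,
                    ]
                )
                + "\n"
            )


def read_results_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: results table missing columns {missing}")
    return df
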