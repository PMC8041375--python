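"""File readers and writers: work files, ΔΔG CSV tables, benchmark CSV.

Formats
-------
Work files: plain text, one work value (kJ/mol) per line, ``#`` comments
allowed, one file per direction.

ΔΔG CSV: columns ``reference,target,value_kJmol,uncertainty_kJmol,source``
where reference/target are '+'-joined mutation codes and the empty string
denotes the wild type, e.g. ``"",L37A+G79S,5.20,0.40,calc``.

Benchmark CSV: columns ``id,calc_kJmol,exp_kJmol[,distance_A]``.

All files are UTF-8 with '.' decimal separators; an optional ``kcal``
flag converts values by the factor 4.184 on read and write.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .cycles import DDGTable, MutationSet
from .errors import DuplicateEdgeError, InputError
from .estimators import FreeEnergyEstimate

__all__ = [
    "KCAL",
    "read_work_file",
    "write_work_file",
    "read_ddg_csv",
    "write_ddg_csv",
    "read_benchmark_csv",
]

#: kJ per kcal.
KCAL = 4.184

PathLike = Union[str, Path]

DDG_COLUMNS = ["reference", "target", "value_kJmol", "uncertainty_kJmol", "source"]


def read_work_file(path: PathLike, kcal: bool = False) -> np.ndarray:
    """Read one work value per line (kJ/mol; kcal/mol with ``kcal=True``)."""
    values: List[float] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise InputError(f"{path}:{lineno}: not a number: {line!r}") from None
    if not values:
        raise InputError(f"{path}: no work values found")
    out = np.asarray(values, dtype=float)
    return out * KCAL if kcal else out


def write_work_file(path: PathLike, values, kcal: bool = False) -> None:
    values = np.asarray(values, dtype=float)
    if kcal:
        values = values / KCAL
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# work values, one per line, %s\n" % ("kcal/mol" if kcal else "kJ/mol"))
        for v in values:
            handle.write(f"{float(v)!r}\n")


def read_ddg_csv(path: PathLike, kcal: bool = False) -> DDGTable:
    """Read a ΔΔG table; failures carry the offending line number."""
    table = DDGTable()
    scale = KCAL if kcal else 1.0
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:4]] != DDG_COLUMNS[:4]:
            raise InputError(
                f"{path}: expected header {','.join(DDG_COLUMNS)}, got {reader.fieldnames}"
            )
        for row in reader:
            lineno = reader.line_num
            try:
                reference = MutationSet.from_code(row["reference"] or "")
                target = MutationSet.from_code(row["target"] or "")
                value = float(row["value_kJmol"]) * scale
                unc_text = (row.get("uncertainty_kJmol") or "").strip()
                unc = float(unc_text) * scale if unc_text else 0.0
            except (ValueError, TypeError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
            source = (row.get("source") or "input").strip() or "input"
            try:
                table.add(reference, target, FreeEnergyEstimate(value, unc, source))
            except (ValueError, DuplicateEdgeError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
    if len(table) == 0:
        raise InputError(f"{path}: table contains no entries")
    return table


def write_ddg_csv(path: PathLike, table: DDGTable, kcal: bool = False) -> None:
    scale = 1.0 / KCAL if kcal else 1.0
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(DDG_COLUMNS)
        for ref, tgt, est in table.edges():
            writer.writerow(
                [
                    ref.label,
                    tgt.label,
                    repr(float(est.value * scale)),
                    repr(float(est.uncertainty * scale)),
                    est.method,
                ]
            )


def read_benchmark_csv(
    path: PathLike, kcal: bool = False
) -> Tuple[List[Tuple[str, float, float]], Dict[str, float]]:
    """Read ``id,calc_kJmol,exp_kJmol[,distance_A]`` rows.

    Returns the (id, calc, exp) rows and a distances map holding the
    pairs for which a distance column value was present.
    """
    scale = KCAL if kcal else 1.0
    rows: List[Tuple[str, float, float]] = []
    distances: Dict[str, float] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        required = {"id", "calc_kJmol", "exp_kJmol"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"{path}: expected columns id,calc_kJmol,exp_kJmol[,distance_A], "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            lineno = reader.line_num
            pair_id = (row["id"] or "").strip()
            if not pair_id:
                raise InputError(f"{path}:{lineno}: empty id")
            try:
                calc = float(row["calc_kJmol"]) * scale
                exp = float(row["exp_kJmol"]) * scale
            except (ValueError, TypeError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
            rows.append((pair_id, calc, exp))
            dist_text = (row.get("distance_A") or "").strip()
            if dist_text:
                try:
                    distances[pair_id] = float(dist_text)
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: bad distance {dist_text!r}"
                    ) from None
    if not rows:
        raise InputError(f"{path}: no data rows")
    return rows, distances
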