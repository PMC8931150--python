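"""Readers and writers for the pipeline's tabular formats.

Inputs are comma-separated UTF-8 with a mandatory header (plate-export
style); outputs are tab-separated with floats at 3 decimal places.  The
separation avoids decimal-comma ambiguity in locales that use it.

Formats
-------
Ct table (CSV):       specimen_id,gene_role,biological_replicate,technical_replicate,ct,run_id
                      (empty ct field = no amplification)
ddPCR wells (CSV):    specimen_id,gene_role,n_positive,n_negative[,droplet_volume_nl][,biological_replicate]
Standard curves (CSV): gene_role,input_ng,ct
Truth table (CSV):    specimen_id,true_sex
CNV results (TSV out): specimen_id  method  biological_replicate  cnv  calibrator_id  run_id
Sex calls (TSV out):  specimen_id  method  cnv  predicted_sex  in_band  flags
"""

from __future__ import annotations

import csv
import logging
import tomllib
from pathlib import Path
from typing import Iterable, Sequence

from .ddpcr_quant import CnvResult, DdpcrWell, DEFAULT_DROPLET_VOLUME_NL
from .qpcr_quant import CtRecord
from .sex_calling import SexCall
from .synthetic_data import SimulationConfig

__all__ = [
    "SchemaError",
    "RowError",
    "read_ct_table",
    "read_wells",
    "read_curve_table",
    "read_truth",
    "read_cnv_table",
    "write_results",
    "write_calls",
    "read_sim_config",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input file lacks a required column."""


class RowError(ValueError):
    """One or more rows failed to parse (collected with line numbers)."""


def _check_header(fieldnames: Sequence[str] | None, required: Sequence[str],
                  path: str | Path) -> None:
    present = set(fieldnames or [])
    missing = [c for c in required if c not in present]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def _collect(errors: list[str], strict: bool) -> None:
    if errors:
        msg = "; ".join(errors)
        if strict:
            raise RowError(msg)
        logger.warning("skipped malformed rows: %s", msg)


def read_ct_table(path: str | Path, strict: bool = False) -> list[CtRecord]:
    """Parse a qPCR plate export. Empty Ct fields become missing values;
    malformed rows are reported with line numbers (fatal under strict)."""
    records: list[CtRecord] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames,
                      ["specimen_id", "gene_role", "biological_replicate",
                       "technical_replicate", "ct"], path)
        for lineno, row in enumerate(reader, start=2):
            try:
                raw_ct = (row.get("ct") or "").strip()
                records.append(
                    CtRecord(
                        specimen_id=row["specimen_id"].strip(),
                        gene_role=row["gene_role"].strip(),
                        biological_replicate=int(row["biological_replicate"]),
                        technical_replicate=int(row["technical_replicate"]),
                        ct=float(raw_ct) if raw_ct else None,
                        run_id=(row.get("run_id") or "").strip(),
                    )
                )
            except (KeyError, ValueError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
    _collect(errors, strict)
    return records


def read_wells(path: str | Path, strict: bool = False) -> list[DdpcrWell]:
    """Parse a ddPCR well export of thresholded droplet counts."""
    wells: list[DdpcrWell] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames,
                      ["specimen_id", "gene_role", "n_positive", "n_negative"],
                      path)
        for lineno, row in enumerate(reader, start=2):
            try:
                vol = row.get("droplet_volume_nl")
                rep = row.get("biological_replicate")
                wells.append(
                    DdpcrWell(
                        specimen_id=row["specimen_id"].strip(),
                        gene_role=row["gene_role"].strip(),
                        n_positive=int(row["n_positive"]),
                        n_negative=int(row["n_negative"]),
                        droplet_volume_nl=(
                            float(vol) if vol else DEFAULT_DROPLET_VOLUME_NL
                        ),
                        biological_replicate=int(rep) if rep else 1,
                    )
                )
            except (KeyError, ValueError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
    _collect(errors, strict)
    return wells


def read_curve_table(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Dilution-series points grouped by gene role: {role: [(ng, ct), ...]}."""
    out: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ["gene_role", "input_ng", "ct"], path)
        for row in reader:
            out.setdefault(row["gene_role"].strip(), []).append(
                (float(row["input_ng"]), float(row["ct"]))
            )
    return out


def read_truth(path: str | Path) -> dict[str, str]:
    """Morphological truth table: specimen_id -> "F"/"M"."""
    truth: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ["specimen_id", "true_sex"], path)
        for row in reader:
            truth[row["specimen_id"].strip()] = row["true_sex"].strip()
    return truth


def read_cnv_table(path: str | Path) -> list[CnvResult]:
    """Read back a TSV written by :func:`write_results`."""
    results: list[CnvResult] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _check_header(reader.fieldnames,
                      ["specimen_id", "method", "biological_replicate", "cnv"],
                      path)
        for row in reader:
            cal = (row.get("calibrator_id") or "").strip()
            results.append(
                CnvResult(
                    specimen_id=row["specimen_id"],
                    method=row["method"],
                    biological_replicate=int(row["biological_replicate"]),
                    cnv=float(row["cnv"]),
                    calibrator_id=cal or None,
                    run_id=(row.get("run_id") or "").strip(),
                )
            )
    return results


def write_results(results: Iterable[CnvResult], path: str | Path) -> None:
    """Write CNV results as a deterministic TSV (sorted by specimen then
    replicate, floats at 3 d.p.)."""
    rows = sorted(results, key=lambda r: (r.specimen_id, r.method,
                                          r.biological_replicate))
    if not rows:
        raise ValueError("no results to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["specimen_id", "method", "biological_replicate",
                         "cnv", "calibrator_id", "run_id"])
        for r in rows:
            writer.writerow([
                r.specimen_id, r.method, r.biological_replicate,
                f"{r.cnv:.3f}", r.calibrator_id or "", r.run_id,
            ])


def write_calls(calls: Iterable[SexCall], path: str | Path) -> None:
    """Write sex calls as a deterministic TSV."""
    rows = sorted(calls, key=lambda c: (c.specimen_id, c.method))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["specimen_id", "method", "cnv", "predicted_sex",
                         "in_band", "flags"])
        for c in rows:
            writer.writerow([
                c.specimen_id, c.method, f"{c.cnv:.3f}", c.predicted_sex,
                str(c.in_band).lower(), ",".join(c.flags),
            ])


def read_sim_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from TOML (keys match field names;
    curve pairs as two-element arrays)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    kwargs = dict(doc)
    for key in ("target_curve", "reference_curve"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)
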