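"""Readers and writers for the package's CSV/JSON dialects, plus packaged data.

All CSVs are UTF-8, comma-separated, header required, ``.`` decimal
separator. Readers reject malformed numerics with row-level errors rather
than coercing; writers emit deterministic column order. Printed-precision
formatting (partials at 2 decimals, OI at 1) lives only in the report
writer; everything held in memory is full precision.

Packaged data:

* ``aldehyde_thresholds.csv`` — the seven reference aldehydes with their
  panel-measured odor detection thresholds (mg/m³) and molecular weights.
* ``validation_mixtures.csv`` — the published validation set for the
  extended mixture curve: 21 binary samples (9 from the calibration
  aldehydes, 12 from four further aldehyde pairs) with component lnOAVs,
  panel-measured OI, and the originally reported partials and predictions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Sequence, Union

from .core import ComponentExposure, Odorant
from .mixture_model import (
    BinaryMixtureSample,
    PredictionRecord,
    QuadraticMixtureModel,
)

__all__ = [
    "MODEL_FORMAT_VERSION",
    "TableParseError",
    "ModelFormatError",
    "ValidationRow",
    "load_thresholds",
    "builtin_thresholds",
    "load_validation_fixture",
    "load_samples",
    "write_samples",
    "write_model",
    "read_model",
    "write_prediction_report",
]

MODEL_FORMAT_VERSION = 1

PathLike = Union[str, Path]


class TableParseError(ValueError):
    """A CSV row failed validation; message carries the 1-based line number."""


class ModelFormatError(ValueError):
    """A model JSON file is unreadable or has an incompatible version."""


def _parse_float(raw: str, field_name: str, line: int, *, required: bool = True) -> Optional[float]:
    text = (raw or "").strip()
    if not text:
        if required:
            raise TableParseError(f"line {line}: missing value for {field_name!r}")
        return None
    try:
        return float(text)
    except ValueError:
        raise TableParseError(
            f"line {line}: malformed number {text!r} for {field_name!r}"
        ) from None


def _reader(path: PathLike) -> Iterable[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        yield from csv.DictReader(fh)


def _require_columns(fieldnames: Optional[Sequence[str]], required: Sequence[str], path) -> None:
    missing = set(required) - set(fieldnames or [])
    if missing:
        raise TableParseError(f"{path}: missing required column(s) {sorted(missing)}")


# ---------------------------------------------------------------------------
# odorant threshold tables
# ---------------------------------------------------------------------------

def load_thresholds(path: PathLike) -> List[Odorant]:
    """Read an odorant reference table.

    Dialect: header ``name,cas,molecular_weight,threshold_mg_m3``; unknown
    extra columns are ignored; ``cas`` and ``molecular_weight`` may be empty.
    """
    odorants: List[Odorant] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ["name", "threshold_mg_m3"], path)
        for line, row in enumerate(reader, start=2):
            name = (row.get("name") or "").strip()
            if not name:
                raise TableParseError(f"line {line}: missing odorant name")
            threshold = _parse_float(row.get("threshold_mg_m3", ""), "threshold_mg_m3", line)
            if not (threshold > 0):
                raise TableParseError(
                    f"line {line}: threshold_mg_m3 must be > 0, got {threshold}"
                )
            mw = _parse_float(
                row.get("molecular_weight", ""), "molecular_weight", line, required=False
            )
            cas = (row.get("cas") or "").strip() or None
            odorants.append(
                Odorant(name=name, threshold=threshold, cas=cas, molecular_weight=mw)
            )
    return odorants


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("odorblend").joinpath("data", filename)))


def builtin_thresholds() -> List[Odorant]:
    """The packaged reference aldehydes (panel-measured thresholds, mg/m³)."""
    return load_thresholds(_data_path("aldehyde_thresholds.csv"))


def thresholds_by_name(odorants: Optional[Iterable[Odorant]] = None) -> Dict[str, Odorant]:
    return {o.name: o for o in (odorants if odorants is not None else builtin_thresholds())}


# ---------------------------------------------------------------------------
# validation fixture (published extended-model evaluation set)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationRow:
    """One published validation sample: inputs, measurement, reported values.

    ``printed_*`` fields are the values as originally reported (2-decimal
    partials, 1-decimal prediction) and are kept for cross-checking only;
    recomputation from ``ln_oav_a``/``ln_oav_b`` is the package's own path.
    """

    section: str
    odorant_a: str
    odorant_b: str
    ln_oav_a: float
    ln_oav_b: float
    printed_oi_a_m: float
    printed_oi_b_m: float
    printed_oi_pre: float
    oi_mea: float


def load_validation_fixture() -> List[ValidationRow]:
    """The 21-row packaged validation set (9 section-A + 12 section-B rows)."""
    rows: List[ValidationRow] = []
    with open(_data_path("validation_mixtures.csv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for line, row in enumerate(reader, start=2):
            rows.append(
                ValidationRow(
                    section=row["section"].strip(),
                    odorant_a=row["odorant_a"].strip(),
                    odorant_b=row["odorant_b"].strip(),
                    ln_oav_a=_parse_float(row["lnoav_a"], "lnoav_a", line),
                    ln_oav_b=_parse_float(row["lnoav_b"], "lnoav_b", line),
                    printed_oi_a_m=_parse_float(row["oi_a_m_printed"], "oi_a_m_printed", line),
                    printed_oi_b_m=_parse_float(row["oi_b_m_printed"], "oi_b_m_printed", line),
                    printed_oi_pre=_parse_float(row["oi_pre_printed"], "oi_pre_printed", line),
                    oi_mea=_parse_float(row["oi_mea"], "oi_mea", line),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# binary-mixture sample tables
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "mixture_id",
    "odorant_a",
    "conc_a_mg_m3",
    "odorant_b",
    "conc_b_mg_m3",
    "measured_oi",
]


def load_samples(path: PathLike, odorants: Optional[Iterable[Odorant]] = None) -> List[BinaryMixtureSample]:
    """Read a binary-mixture sample table against an odorant reference.

    ``measured_oi`` may be empty (prediction-only runs). Odorant names must
    resolve in the reference table (defaults to the packaged one).
    """
    lookup = thresholds_by_name(odorants)
    samples: List[BinaryMixtureSample] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, SAMPLE_COLUMNS[:5], path)
        for line, row in enumerate(reader, start=2):
            exposures = []
            for side in ("a", "b"):
                name = (row.get(f"odorant_{side}") or "").strip()
                if name not in lookup:
                    raise TableParseError(
                        f"line {line}: unknown odorant {name!r}; not in the reference table"
                    )
                conc = _parse_float(row.get(f"conc_{side}_mg_m3", ""), f"conc_{side}_mg_m3", line)
                exposures.append(ComponentExposure(lookup[name], conc))
            measured = _parse_float(row.get("measured_oi", ""), "measured_oi", line, required=False)
            samples.append(
                BinaryMixtureSample(
                    component_a=exposures[0],
                    component_b=exposures[1],
                    measured_oi=measured,
                    mixture_id=(row.get("mixture_id") or "").strip() or None,
                )
            )
    return samples


def write_samples(samples: Sequence[BinaryMixtureSample], path: PathLike) -> None:
    """Write samples in the dialect :func:`load_samples` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_COLUMNS)
        for i, s in enumerate(samples):
            writer.writerow(
                [
                    s.mixture_id or f"sample-{i:02d}",
                    s.component_a.odorant.name,
                    repr(s.component_a.concentration),
                    s.component_b.odorant.name,
                    repr(s.component_b.concentration),
                    "" if s.measured_oi is None else repr(float(s.measured_oi)),
                ]
            )


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def write_model(model: QuadraticMixtureModel, path: PathLike, input_digest: Optional[str] = None) -> None:
    """Serialize a mixture-curve model losslessly to JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "a2": model.a2,
        "a1": model.a1,
        "a0": model.a0,
        "n_points": model.n_points,
        "residual_sd": model.residual_sd,
        "confidence_level": model.confidence_level,
        "provenance": model.provenance,
        "xtx_inv": None if model.xtx_inv is None else [list(r) for r in model.xtx_inv],
        "input_digest": input_digest,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path: PathLike) -> QuadraticMixtureModel:
    """Read a model written by :func:`write_model`; rejects other versions."""
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid model JSON ({exc})") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {version!r} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    try:
        xtx_inv = payload["xtx_inv"]
        return QuadraticMixtureModel(
            a2=payload["a2"],
            a1=payload["a1"],
            a0=payload["a0"],
            n_points=payload["n_points"],
            residual_sd=payload["residual_sd"],
            confidence_level=payload["confidence_level"],
            provenance=payload["provenance"],
            xtx_inv=None if xtx_inv is None else tuple(tuple(r) for r in xtx_inv),
        )
    except KeyError as exc:
        raise ModelFormatError(f"{path}: missing field {exc} in model JSON") from exc


# ---------------------------------------------------------------------------
# prediction report
# ---------------------------------------------------------------------------

def write_prediction_report(records: Sequence[PredictionRecord], path: PathLike) -> None:
    """Write predictions at report precision (partials 2 dp, OI 1 dp).

    Columns: ``lnoav_a,lnoav_b,oi_a_m,oi_b_m,oi_pre,oi_mea,ratio``. The
    ratio column is the predictive coefficient when a measurement exists.
    """
    from .mixture_model import report_round_oi, round_half_away

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lnoav_a", "lnoav_b", "oi_a_m", "oi_b_m", "oi_pre", "oi_mea", "ratio"])
        for rec in records:
            rounded_pre = report_round_oi(rec.oi_pre)
            ratio = (
                rec.predictive_coefficient
                if rec.predictive_coefficient is not None
                else (rounded_pre / rec.oi_mea if rec.oi_mea else None)
            )
            writer.writerow(
                [
                    f"{rec.ln_oav_a:.2f}",
                    f"{rec.ln_oav_b:.2f}",
                    f"{round_half_away(rec.partials.oi_a_m, 2):.2f}",
                    f"{round_half_away(rec.partials.oi_b_m, 2):.2f}",
                    f"{rounded_pre:.1f}",
                    "" if rec.oi_mea is None else f"{rec.oi_mea:.1f}",
                    "" if ratio is None else f"{ratio:.4f}",
                ]
            )
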