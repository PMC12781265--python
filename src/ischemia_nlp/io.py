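"""Reading and writing corpora and classification outputs.

JSONL is the canonical interchange format (one object per line, streaming
friendly for warehouse-scale corpora); CSV is accepted because warehouse
extracts commonly arrive that way. Document records carry: report_id,
impression_text, full_report_text, site_id, gold_label.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .classify import CorpusSummary
from .core import DocumentClassification, ReportDocument

DOC_COLUMNS = ("report_id", "impression_text", "full_report_text", "site_id", "gold_label")


class InputFormatError(ValueError):
    """A malformed document record; carries the offending row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def _coerce_label(value) -> Optional[int]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    iv = int(value)
    if iv not in (0, 1):
        raise ValueError(f"gold_label must be 0 or 1, got {value!r}")
    return iv


def _coerce_text(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value)


def _doc_from_record(record: dict, row: int) -> ReportDocument:
    rid = _coerce_text(record.get("report_id"))
    if not rid:
        raise InputFormatError(row, "missing report_id")
    try:
        return ReportDocument(
            report_id=rid,
            impression_text=_coerce_text(record.get("impression_text")),
            full_report_text=_coerce_text(record.get("full_report_text")),
            site_id=_coerce_text(record.get("site_id")),
            gold_label=_coerce_label(record.get("gold_label")),
        )
    except ValueError as exc:
        raise InputFormatError(row, str(exc)) from exc


def read_documents(
    path: Union[str, Path], fmt: Optional[str] = None
) -> list[ReportDocument]:
    """Read a corpus from JSONL or CSV; format inferred from the suffix
    when not given. Raises :class:`InputFormatError` on the first bad row."""
    docs, errors = read_documents_lenient(path, fmt)
    if errors:
        row, message = errors[0]
        raise InputFormatError(row, message)
    return docs


def read_documents_lenient(
    path: Union[str, Path], fmt: Optional[str] = None
) -> tuple[list[ReportDocument], list[tuple[int, str]]]:
    """Like :func:`read_documents` but collects (row, message) for bad rows
    instead of raising, so one malformed report cannot abort a batch."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records: list[dict]
    if fmt == "csv":
        frame = pd.read_csv(path, dtype={"report_id": str, "site_id": str})
        records = frame.to_dict(orient="records")
    elif fmt == "jsonl":
        records = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    records.append({"__parse_error__": f"invalid JSON: {exc}"})
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'jsonl'")

    docs: list[ReportDocument] = []
    errors: list[tuple[int, str]] = []
    for row, record in enumerate(records, start=1):
        if "__parse_error__" in record:
            errors.append((row, record["__parse_error__"]))
            continue
        try:
            docs.append(_doc_from_record(record, row))
        except InputFormatError as exc:
            errors.append((exc.row, str(exc)))
    return docs, errors


def _doc_record(doc: ReportDocument) -> dict:
    return {
        "report_id": doc.report_id,
        "impression_text": doc.impression_text,
        "full_report_text": doc.full_report_text,
        "site_id": doc.site_id,
        "gold_label": doc.gold_label,
    }


def write_documents(
    docs: Iterable[ReportDocument], path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records = [_doc_record(d) for d in docs]
    if fmt == "csv":
        pd.DataFrame(records, columns=list(DOC_COLUMNS)).to_csv(path, index=False)
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for record in records:
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_classifications(
    results: Iterable[DocumentClassification], path: Union[str, Path]
) -> None:
    """Write classification records as JSONL:
    {report_id, ischemia, evidence, source_text_provenance}."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in results:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "ischemia": r.ischemia,
                        "evidence": r.evidence,
                        "source_text_provenance": r.source_text_provenance,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_predictions(path: Union[str, Path]) -> list[tuple[str, int]]:
    """Read (report_id, ischemia) pairs from a classification JSONL file."""
    out: list[tuple[str, int]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                record = json.loads(line)
                out.append((str(record["report_id"]), int(record["ischemia"])))
    return out


def read_gold_labels(path: Union[str, Path]) -> list[tuple[str, int]]:
    """Read (report_id, gold_label) pairs from a documents file, skipping
    unlabeled rows."""
    docs = read_documents(path)
    return [(d.report_id, d.gold_label) for d in docs if d.gold_label is not None]


def summary_dict(summary: CorpusSummary) -> dict:
    return {
        "n_total": summary.n_total,
        "n_classified": summary.n_classified,
        "n_errored": summary.n_errored,
        "n_positive": summary.n_positive,
        "prevalence": summary.prevalence,
        "errors": [list(e) for e in summary.errors],
    }
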