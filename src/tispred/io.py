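"""File formats: FASTA + annotation TSV in, sample/prediction/report files out.

The annotation file is two tab-separated columns, ``record_id<TAB>tis_pos``
with ``tis_pos`` 1-based; a leading ``#``-header line is optional.  Extracted
samples are written as a TSV (one candidate per row, window included) so
extraction can be audited independently of the encoding.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .evaluation import CvReport, METRIC_NAMES, format_metric
from .seqmodel import (
    FilterReport,
    InvalidRecordError,
    MrnaRecord,
    WindowSpec,
    enumerate_candidates,
    extract_window,
)

SAMPLE_COLUMNS = ["record_id", "atg_pos", "region", "frame", "label", "window"]


def read_fasta(path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no records")
    return seqs


def write_fasta(records: list[MrnaRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def read_annotations(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            try:
                out[parts[0]] = int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: tis_pos {parts[1]!r} is not an integer"
                ) from None
    if not out:
        raise ValueError(f"{path}: no annotations")
    return out


def write_annotations(records: list[MrnaRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#record_id\ttis_pos\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.tis_pos}\n")


def load_records(
    fasta_path, annotation_path
) -> tuple[list[MrnaRecord], dict[str, int]]:
    """Join sequences with annotations; count records rejected at construction.

    Returns valid records plus a per-reason count of rejected ones
    (``no_start_atg``, ``invalid_characters``, ``missing_annotation``).
    Annotation IDs absent from the FASTA are a hard error.
    """
    seqs = read_fasta(fasta_path)
    annot = read_annotations(annotation_path)
    unknown = set(annot) - set(seqs)
    if unknown:
        raise ValueError(f"annotated IDs missing from FASTA: {sorted(unknown)[:5]}")
    records: list[MrnaRecord] = []
    rejected = {"no_start_atg": 0, "invalid_characters": 0, "missing_annotation": 0}
    for rid, seq in seqs.items():
        if rid not in annot:
            rejected["missing_annotation"] += 1
            continue
        try:
            records.append(MrnaRecord(id=rid, sequence=seq, tis_pos=annot[rid]))
        except InvalidRecordError as exc:
            if "characters outside" in str(exc):
                rejected["invalid_characters"] += 1
            else:
                rejected["no_start_atg"] += 1
    return records, rejected


def extract_samples_table(
    records: list[MrnaRecord], window: WindowSpec, mode: str = "plain"
) -> pd.DataFrame:
    """One row per candidate with an extractable window (audit format)."""
    rows = []
    for rec in records:
        for site in enumerate_candidates(rec, mode=mode):
            w = extract_window(rec, site.atg_pos, window)
            if w is None:
                continue
            rows.append({
                "record_id": site.record_id,
                "atg_pos": site.atg_pos,
                "region": site.region.value,
                "frame": site.frame.value,
                "label": site.label.value,
                "window": w,
            })
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_filter_report(report: FilterReport, rejected: dict[str, int], path) -> None:
    payload = {
        "total_molecules": report.total + sum(rejected.values()),
        "kept": report.kept,
        "rejected_at_load": rejected,
        "discarded_at_filter": report.discarded,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def cv_report_to_frame(report: CvReport) -> pd.DataFrame:
    rows = []
    for i, fold in enumerate(report.folds):
        row = {"fold": i, "TP": fold.counts.TP, "FP": fold.counts.FP,
               "TN": fold.counts.TN, "FN": fold.counts.FN}
        for name in METRIC_NAMES:
            row[name] = format_metric(getattr(fold.metrics, name))
        rows.append(row)
    return pd.DataFrame(rows)


def write_cv_report(report: CvReport, out_dir, prefix: str = "cv") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cv_report_to_frame(report).to_csv(out_dir / f"{prefix}_folds.tsv",
                                      sep="\t", index=False)
    payload = {
        "n_folds": len(report.folds),
        "summary": report.summary(),
        "folds": [
            {
                "counts": vars(f.counts),
                "metrics": {k: v for k, v in f.metrics.as_dict().items()},
                "n_test_molecules": f.n_test_molecules,
                "n_test_samples": f.n_test_samples,
                "inaknow": None if f.inaknow is None else {
                    "downstream_total": f.inaknow.downstream_total,
                    "downstream_relabeled_positive":
                        f.inaknow.downstream_relabeled_positive,
                    "relabel_fraction": f.inaknow.relabel_fraction,
                    "post_balance_ratio": f.inaknow.post_balance_ratio,
                },
            }
            for f in report.folds
        ],
    }
    (out_dir / f"{prefix}_report.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    roc = np.vstack([f.roc for f in report.folds if len(f.roc)])
    pd.DataFrame(roc, columns=["fpr", "tpr"]).to_csv(
        out_dir / f"{prefix}_roc.tsv", sep="\t", index=False
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
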