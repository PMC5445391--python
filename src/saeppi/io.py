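"""Readers and writers for the plain-text formats the pipeline exchanges.

See ``docs/FORMATS.md`` for the exact column orders.  Every numeric
artifact is written with full ``repr`` precision and carries ``#``-prefixed
header lines recording the seed and a hash of the generating configuration,
so equal configurations produce byte-identical payloads.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset_builder import PairSample
from .sequence_codec import ProteinRecord


def config_hash(params: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -------------------------------------------------------------------- FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Multi-record FASTA; wrapped lines and lower-case residues accepted."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ----------------------------------------------------------------- TSV files


def read_localization(path) -> dict[str, list[str]]:
    """id -> list of compartment annotations (one row per annotation)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, comp = line.split("\t")[:2]
            out.setdefault(pid, []).append(comp)
    return out


def write_localization(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.compartment is not None:
                fh.write(f"{r.id}\t{r.compartment}\n")


def read_pairs(path) -> list[PairSample]:
    """Pair TSV: idA, idB, label, optional split column."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "idA":
                continue
            split = parts[3] if len(parts) > 3 else "pretrain"
            pairs.append(PairSample(parts[0], parts[1], int(parts[2]), split))
    return pairs


def write_pairs(pairs: list[PairSample], path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("idA\tidB\tlabel\tsplit\n")
        for p in pairs:
            fh.write(f"{p.idA}\t{p.idB}\t{p.label}\t{p.split}\n")


# ------------------------------------------------------------ feature matrix


def write_matrix(
    X: np.ndarray, pairs: list[PairSample], path, header: dict | None = None
) -> None:
    """Headered TSV: one row per pair, idA, idB, label, then the features."""
    X = np.asarray(X)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        cols = "\t".join(f"x{j}" for j in range(X.shape[1]))
        fh.write(f"idA\tidB\tlabel\t{cols}\n")
        for p, row in zip(pairs, X):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{p.idA}\t{p.idB}\t{p.label}\t{vals}\n")


def read_matrix(path) -> tuple[np.ndarray, list[PairSample], dict]:
    meta: dict[str, str] = {}
    ids: list[PairSample] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                k, _, v = line[2:].partition("=")
                meta[k] = v
                continue
            if not line or line.startswith("idA"):
                continue
            parts = line.split("\t")
            ids.append(PairSample(parts[0], parts[1], int(parts[2])))
            rows.append([float(v) for v in parts[3:]])
    X = np.array(rows) if rows else np.empty((0, 0))
    return X, ids, meta


# ------------------------------------------------------------------- metrics


def write_metrics_csv(report_folds: list[dict], path, header: dict | None = None) -> None:
    """Per-fold metrics CSV with a trailing summary (mean/sd) pair of rows."""
    names = ("accuracy", "sensitivity", "specificity", "precision")
    with open(path, "w", newline="") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        writer = csv.writer(fh)
        writer.writerow(["fold", *names])
        for i, fold in enumerate(report_folds):
            writer.writerow([i] + [_fmt(fold[n]) for n in names])
        defined = {n: [f[n] for f in report_folds if f[n] is not None] for n in names}
        writer.writerow(
            ["mean"] + [_fmt(np.mean(v)) if v else "NA" for v in defined.values()]
        )
        writer.writerow(
            ["sd"]
            + [_fmt(np.std(v, ddof=1)) if len(v) > 1 else _fmt(0.0) for v in defined.values()]
        )


def _fmt(v) -> str:
    return "NA" if v is None else repr(float(v))


def write_predictions(
    pairs: list[PairSample], probs: np.ndarray, labels: np.ndarray, path,
    header: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("idA\tidB\tprobability_interaction\tlabel\n")
        for p, prob, lab in zip(pairs, probs, labels):
            fh.write(f"{p.idA}\t{p.idB}\t{repr(float(prob))}\t{int(lab)}\n")


def ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
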