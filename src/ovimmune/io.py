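"""Readers and writers for the pipeline's plain-text formats.

All adapters are round-trip faithful (write(read(x)) == x for conformant
files) and report malformed lines with their line numbers.  Formats:
gene x sample expression TSV plus a sample-metadata TSV, 6-column BED
(0-based half-open), GMT gene sets, survival CSV and JSON manifests.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genomic import validate_annotation
from .gsea import GeneSet
from .harmonize import METADATA_COLUMNS, ExpressionMatrix


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# -- expression matrix + metadata ------------------------------------------

def write_expression(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    meta = matrix.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


def read_expression(matrix_path, metadata_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index.name = None
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    meta.index.name = None
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{metadata_path}: metadata lacks columns {missing}")
    return ExpressionMatrix(values, meta)


# -- BED -------------------------------------------------------------------

def write_bed(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation)
    with open(path, "w") as fh:
        for gene, row in annotation.iterrows():
            strand = row.get("strand", "+")
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                f"\t{gene}\t0\t{strand}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """6-column BED (chrom, start, end, name, score, strand), 0-based half-open."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields, "
                                 f"got {len(fields)}")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer interval") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start ({start}, {end})")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            records.append((name, chrom, start, end, strand))
    frame = pd.DataFrame(
        records, columns=["gene", "chrom", "start", "end", "strand"]
    ).set_index("gene")
    frame.index.name = None
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups[:5]}")
    return validate_annotation(frame)


# -- GMT -------------------------------------------------------------------

def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\tna\t{genes}\n")


def read_gmt(path) -> list[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            name = fields[0]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
            seen.add(name)
            sets.append(GeneSet.from_iterable(name, fields[2:]))
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return sets


# -- survival CSV ----------------------------------------------------------

SURVIVAL_COLUMNS = ("study", "time", "event", "expression", "debulking", "stage")


def write_survival(survival: pd.DataFrame, path) -> None:
    survival.loc[:, list(SURVIVAL_COLUMNS)].to_csv(path, index=False)


def read_survival(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: survival table lacks columns {missing}")
    if (frame["time"] <= 0).any():
        bad = int((frame["time"] <= 0).sum())
        raise ParseError(f"{path}: {bad} non-positive survival times")
    return frame


# -- structure map / ground truth / manifest -------------------------------

def write_structure_map(structure_map: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for structure in sorted(structure_map):
            for gene in sorted(structure_map[structure]):
                fh.write(f"{structure}\t{gene}\n")


def read_structure_map(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
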