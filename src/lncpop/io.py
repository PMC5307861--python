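"""Readers and writers for the pipeline's on-disk formats.

One tabular dialect everywhere: TSV with a header row, UTF-8, ``.`` as
the decimal separator, missing values as empty strings.  Sequences are
FASTA wrapped at 60 columns (read case-insensitively via Biopython).
Configs, truths and run reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .matrix import ExpressionMatrix

__all__ = [
    "read_expression", "write_expression",
    "read_trait", "write_trait",
    "read_fasta", "write_fasta",
    "read_tsv", "write_tsv", "write_json", "read_json",
]

_FLOAT_FMT = "%.10g"


def _read_table(path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{name} file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype=None)
    except Exception as exc:
        raise FormatError(f"cannot parse {name} TSV {path}: {exc}") from exc


def read_expression(matrix_path, samples_path, features_path) -> ExpressionMatrix:
    """Load and validate the matrix + sample + feature TSV triple."""
    mat = _read_table(matrix_path, "matrix")
    if mat.columns[0] != "feature_id":
        raise FormatError(
            f"matrix {matrix_path}: first column must be 'feature_id', "
            f"got {mat.columns[0]!r}")
    mat = mat.set_index("feature_id")
    if mat.isna().any().any():
        row = mat.index[mat.isna().any(axis=1)][0]
        raise FormatError(
            f"matrix {matrix_path}: missing/ragged value in row {row!r}")
    samples = _read_table(samples_path, "samples")
    for col in ("individual_id", "environment"):
        if col not in samples.columns:
            raise FormatError(
                f"samples {samples_path}: missing column {col!r}")
    features = _read_table(features_path, "features")
    for col in ("feature_id", "class"):
        if col not in features.columns:
            raise FormatError(
                f"features {features_path}: missing column {col!r}")
    env = samples.set_index("individual_id")["environment"]
    cls = features.set_index("feature_id")["class"]
    unmapped = mat.columns.difference(env.index)
    if len(unmapped):
        raise FormatError(
            f"matrix {matrix_path}: individual {unmapped[0]!r} absent "
            f"from samples {samples_path} (field 'individual_id')")
    from .errors import InputError
    try:
        return ExpressionMatrix(values=mat.astype(float),
                                feature_class=cls, environment=env)
    except (InputError, ValueError) as exc:
        raise FormatError(f"matrix {matrix_path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, out_dir,
                     prefix: str = "expression") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}_matrix.tsv",
        "samples": out_dir / f"{prefix}_samples.tsv",
        "features": out_dir / f"{prefix}_features.tsv",
    }
    matrix.values.to_csv(paths["matrix"], sep="\t", float_format=_FLOAT_FMT,
                         index_label="feature_id")
    matrix.environment.rename_axis("individual_id").rename("environment") \
        .to_frame().to_csv(paths["samples"], sep="\t")
    matrix.feature_class.rename_axis("feature_id").rename("class") \
        .to_frame().to_csv(paths["features"], sep="\t")
    return paths


def read_trait(path) -> pd.Series:
    t = _read_table(path, "trait")
    for col in ("individual_id", "trait_value"):
        if col not in t.columns:
            raise FormatError(f"trait {path}: missing column {col!r}")
    s = t.set_index("individual_id")["trait_value"].astype(float)
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise FormatError(f"trait {path}: duplicate individual {dup!r}")
    return s.rename("trait_value")


def write_trait(trait: pd.Series, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trait.rename_axis("individual_id").rename("trait_value").to_frame() \
        .to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return path


def read_fasta(path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"FASTA {path}: no records")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)
    return path


def read_tsv(path) -> pd.DataFrame:
    return _read_table(path, "table")


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
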