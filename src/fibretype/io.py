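"""Readers and writers for the package's plain-text formats.

Beta/M matrices travel as TSV with probes as rows (first column the probe
id) alongside an annotation TSV; reference matrices as CSV with columns
``cpg_id, TI, TII`` (the shape consumed by EpiDISH-style deconvolution);
regions additionally as BED. Internal coordinates are 1-based inclusive
(array-manifest convention); exported BED is 0-based half-open. Run
manifests are JSON without timestamps so identical configurations reproduce
byte-identical output trees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ANNOTATION_COLUMNS,
    BetaMatrix,
    ReferenceMatrix,
    ValidationError,
    validate_sample_sheet,
)

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_reference_csv",
    "write_reference_csv",
    "write_bed",
    "write_manifest",
    "read_config",
]

_FLOAT_FMT = "%.10g"


def write_beta_tsv(beta: BetaMatrix, values_path, annotations_path=None) -> None:
    """Write a beta matrix (and optionally its annotations) as TSV."""
    out = beta.values.copy()
    out.index.name = "probe_id"
    out.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT)
    if annotations_path is not None:
        if beta.annotations is None:
            raise ValidationError("beta matrix has no annotations to write")
        ann = beta.annotations.copy()
        ann.index.name = "probe_id"
        ann.to_csv(annotations_path, sep="\t")


def read_beta_tsv(values_path, annotations_path=None) -> BetaMatrix:
    """Read a beta matrix TSV (probe rows), with optional annotation TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    bad = values.apply(lambda c: ~c.between(0, 1)).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value outside [0, 1] at probe {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col="probe_id")
        for col in ("non_cpg", "snp_related", "cross_reactive", "underperforming"):
            if col in ann:
                ann[col] = ann[col].astype(bool)
        missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
        if missing:
            raise ValidationError(f"annotation TSV missing columns: {sorted(missing)}")
    return BetaMatrix(values, ann)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))


def write_reference_csv(ref: ReferenceMatrix, path) -> None:
    """Write reference profiles as CSV: cpg_id, TI, TII."""
    out = ref.profiles.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_reference_csv(path) -> ReferenceMatrix:
    prof = pd.read_csv(path, index_col="cpg_id")
    if list(prof.columns) != ["TI", "TII"]:
        raise ValidationError("reference CSV must have columns cpg_id, TI, TII")
    arr = prof.to_numpy(dtype=float)
    if not np.isfinite(arr).all() or (arr < 0).any() or (arr > 1).any():
        bad = np.argwhere(~((arr >= 0) & (arr <= 1)))[0]
        raise ValidationError(
            f"reference value outside [0, 1] at cpg {prof.index[bad[0]]!r}, "
            f"column {prof.columns[bad[1]]!r}"
        )
    return ReferenceMatrix(prof)


def write_bed(regions: pd.DataFrame, path, score_col: str = "fisher_p") -> None:
    """Write regions as BED (0-based half-open).

    Internal 1-based inclusive ``[start, end]`` becomes BED
    ``start-1, end``. Scores are -log10 of ``score_col`` capped at 1000.
    """
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            p = float(row[score_col])
            score = 1000.0 if p <= 0 else min(1000.0, -np.log10(p))
            name = (row.get("genes") or ".") if "genes" in row else "."
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{name}\t{score:.4g}\t.\n"
            )


def write_protein_tsv(table, values_path) -> None:
    """Write a protein table as TSV; missing cells become empty fields.

    Contaminant/decoy flags travel as two leading boolean columns.
    """
    out = table.values.copy()
    if table.flags is not None:
        out = pd.concat([table.flags[["contaminant", "decoy"]], out], axis=1)
    out.index.name = "protein_id"
    out.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT, na_rep="")


def read_protein_tsv(values_path, samples: pd.DataFrame | None = None):
    from .containers import ProteinTable

    raw = pd.read_csv(values_path, sep="\t", index_col="protein_id")
    flags = None
    if {"contaminant", "decoy"}.issubset(raw.columns):
        flags = raw[["contaminant", "decoy"]].astype(bool)
        raw = raw.drop(columns=["contaminant", "decoy"])
    return ProteinTable(raw, flags=flags, samples=samples)


def write_peptide_tsv(peptides, path) -> None:
    peptides.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_peptide_tsv(path):
    from .containers import PeptideTable

    data = pd.read_csv(path, sep="\t")
    data["unique"] = data["unique"].astype(bool)
    return PeptideTable(data)


def write_manifest(path, stage: str, params: dict, outputs: dict[str, int]) -> None:
    """Append a stage record to a JSON-lines run manifest.

    ``outputs`` maps output file names to row counts. Deliberately carries
    no timestamps so repeated runs are byte-identical.
    """
    import fibretype

    record = {
        "stage": stage,
        "version": fibretype.__version__,
        "params": params,
        "outputs": outputs,
    }
    with open(path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")


def read_config(path) -> dict:
    """Load a YAML key-value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return cfg
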