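"""Shared data containers for methylation and proteomics matrices.

The central objects are thin wrappers around pandas DataFrames that enforce
the invariants the analysis relies on: beta values live in [0, 1], probe ids
are unique, sample sheets describe one row per array/MS run. Wrapping rather
than subclassing keeps pandas semantics untouched while giving each container
a place for its metadata (probe annotations, missingness masks, construction
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Probe annotation columns expected by filtering / DMR calling.
ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "gene",
    "context",
    "design_type",
    "non_cpg",
    "snp_related",
    "cross_reactive",
    "underperforming",
)

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

CPG_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation fractions with probe annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample; entries are
        beta values (methylation fractions) in [0, 1].
    annotations
        DataFrame indexed by probe id with columns ``chrom``, ``pos``
        (1-based), ``gene`` (possibly ``;``-separated), ``context``
        (Island/Shore/Shelf/OpenSea), ``design_type`` (Infinium I or II) and
        boolean flag columns ``non_cpg``, ``snp_related``, ``cross_reactive``,
        ``underperforming``. May be ``None`` for operations that do not need
        annotation (e.g. pure matrix math in tests).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _require(self.values.index.is_unique, "probe ids must be unique")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        _require(
            finite.size == arr.size and (finite >= 0).all() and (finite <= 1).all(),
            "beta values must be finite and in [0, 1]",
        )
        if self.annotations is not None:
            missing = set(self.values.index) - set(self.annotations.index)
            _require(not missing, f"{len(missing)} probes lack annotation")
            if "pos" in self.annotations:
                pos = self.annotations["pos"].dropna()
                _require((pos > 0).all(), "positions must be positive (1-based)")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[probe_ids]
        return BetaMatrix(self.values.loc[probe_ids], ann)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)], self.annotations)


@dataclass
class MValueMatrix:
    """CpG x sample matrix of M-values, ``log2(beta / (1 - beta))``.

    ``clip_eps`` records the clipping applied before the logit transform, so
    the inverse transform is exact on the clipped domain.
    """

    values: pd.DataFrame
    clip_eps: float = 1e-3

    def __post_init__(self) -> None:
        _require(0 < self.clip_eps < 0.5, "clip_eps must be in (0, 0.5)")
        _require(
            np.isfinite(self.values.to_numpy(dtype=float)).all(),
            "M-values must be finite everywhere",
        )


@dataclass
class QCFlags:
    """Per-probe, per-sample array QC: detection p-values and bead counts."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.detection_p.to_numpy(dtype=float)
        _require(((p >= 0) & (p <= 1)).all(), "detection p-values must be in [0, 1]")
        _require(
            (self.bead_count.to_numpy(dtype=float) >= 0).all(),
            "bead counts must be non-negative",
        )
        _require(
            self.detection_p.shape == self.bead_count.shape,
            "detection_p and bead_count shapes differ",
        )

    @classmethod
    def all_passing(cls, values: pd.DataFrame) -> "QCFlags":
        """QC flags that pass every probe (detection p = 0, 20 beads)."""
        zeros = pd.DataFrame(0.0, index=values.index, columns=values.columns)
        beads = pd.DataFrame(20, index=values.index, columns=values.columns)
        return cls(zeros, beads)


SAMPLE_SHEET_COLUMNS = ("sample_id", "subject_id", "group", "sex")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet: unique sample ids, known groups and sexes.

    Returns the sheet indexed by ``sample_id``; ``measured_prop_TI`` is
    optional and, when present, must lie in [0, 1].
    """
    sheet = sheet.copy()
    for col in SAMPLE_SHEET_COLUMNS:
        _require(col in sheet.columns or sheet.index.name == col, f"sample sheet missing column {col!r}")
    if sheet.index.name != "sample_id":
        sheet = sheet.set_index("sample_id")
    _require(sheet.index.is_unique, "sample ids must be unique")
    _require(sheet["group"].isin(["TI", "TII", "WM"]).all(), "group must be TI/TII/WM")
    _require(sheet["sex"].isin(["F", "M"]).all(), "sex must be F/M")
    if "measured_prop_TI" in sheet:
        prop = sheet["measured_prop_TI"].dropna()
        _require(((prop >= 0) & (prop <= 1)).all(), "measured_prop_TI must be in [0, 1]")
    return sheet


@dataclass
class ReferenceMatrix:
    """Selected CpGs x {TI, TII} mean-beta profiles for deconvolution.

    ``profiles`` has columns TI and TII; ``meta`` records per-CpG rank score
    and direction (hyper = higher beta in TI). Construction guarantees a
    balanced design: exactly k/2 CpGs hypermethylated and k/2 hypomethylated
    in TI relative to TII.
    """

    profiles: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _require(
            list(self.profiles.columns) == ["TI", "TII"],
            "reference profiles must have columns TI, TII",
        )
        _require(self.profiles.index.is_unique, "reference CpG ids must be unique")
        vals = self.profiles.to_numpy(dtype=float)
        _require(
            np.isfinite(vals).all() and (vals >= 0).all() and (vals <= 1).all(),
            "reference profiles must be beta fractions in [0, 1]",
        )

    @property
    def k(self) -> int:
        return self.profiles.shape[0]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.profiles.index


@dataclass
class TruthTable:
    """Ground truth bundled with synthetic data.

    ``sample_props``: per-WM-sample true fractions (w_TI, w_TII, w_other,
    summing to 1). ``cpg_truth``: per-CpG baseline beta, true TI-TII delta,
    differential flag and sex effect. ``protein_truth``: per-protein true
    log2 fold change and differential flag.
    """

    sample_props: pd.DataFrame | None = None
    cpg_truth: pd.DataFrame | None = None
    protein_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.sample_props is not None:
            w = self.sample_props[["w_TI", "w_TII", "w_other"]].to_numpy(dtype=float)
            _require(((w >= 0) & (w <= 1)).all(), "true proportions must be in [0, 1]")
            _require(
                np.allclose(w.sum(axis=1), 1.0, atol=1e-12),
                "true proportions must sum to 1 per sample",
            )


@dataclass
class ProteinTable:
    """Protein x sample log2-intensity matrix with missingness structure.

    ``values`` holds log2 intensities with NaN for missing cells; ``flags``
    carries boolean ``contaminant`` / ``decoy`` columns; ``samples`` is the
    sample sheet for the MS runs; ``imputed`` (same shape as ``values``)
    marks cells filled by imputation.
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _require(self.values.index.is_unique, "protein ids must be unique")
        arr = self.values.to_numpy(dtype=float)
        _require(
            np.isfinite(arr[~np.isnan(arr)]).all(),
            "protein intensities must be finite where observed",
        )
        if self.flags is not None:
            for col in ("contaminant", "decoy"):
                _require(col in self.flags.columns, f"flags missing column {col!r}")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


MYH_ISOFORMS = ("MYH1", "MYH2", "MYH4", "MYH7")


@dataclass
class PeptideTable:
    """Peptide-level intensities for myosin heavy-chain isoform analysis.

    ``data`` columns: ``peptide`` (sequence), ``isoform`` (parent MYH gene),
    ``unique`` (bool; only unique peptides enter the isoform percentages),
    plus one linear-scale intensity column per sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("peptide", "isoform", "unique"):
            _require(col in self.data.columns, f"peptide table missing column {col!r}")
        inten = self.data[self.sample_columns].to_numpy(dtype=float)
        _require((inten >= 0).all(), "peptide intensities must be non-negative")

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("peptide", "isoform", "unique")]
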