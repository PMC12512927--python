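"""Label-free proteomics: filtering, normalization, MNAR imputation,
differential expression and myosin heavy-chain isoform quantification.

Protein tables arrive as log2 LFQ intensities with missing cells. Missing
values in label-free data are predominantly low-abundance drop-outs
(missing-not-at-random), so imputation draws from a Gaussian left-shifted
relative to the observed intensity distribution: mean mu_obs - 1.8 sigma_obs
and SD 0.3 sigma_obs by default, the standard downshift-and-width convention.

Myosin isoform composition is computed exclusively from peptides unique to a
single isoform: per sample, unique intensities are summed within each of
MYH1/MYH2/MYH4/MYH7, the four sums are totalled, and each isoform is
expressed as a percentage of that grand total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    MYH_ISOFORMS,
    PeptideTable,
    ProteinTable,
    ValidationError,
)
from .diffmeth import DesignSpec, ModeratedTModel, ModeratedTResults

__all__ = [
    "filter_proteins",
    "median_center",
    "impute_mnar",
    "myosin_isoform_percentages",
    "call_deps",
]


def filter_proteins(
    table: ProteinTable,
    min_replicates: int = 3,
    per_group: bool = False,
) -> tuple[ProteinTable, dict[str, int]]:
    """Drop contaminants, decoys and sparsely observed proteins.

    A protein must be observed (non-missing) in at least ``min_replicates``
    samples overall; with ``per_group=True`` the requirement applies within
    at least one group instead. Returns the filtered table and a per-rule
    removal report (a protein failing several rules counts once, attributed
    to the first rule: contaminant, then decoy, then low observation).
    """
    values = table.values
    n = len(values)
    if table.flags is not None:
        contaminant = table.flags["contaminant"].to_numpy(dtype=bool)
        decoy = table.flags["decoy"].to_numpy(dtype=bool)
    else:
        contaminant = np.zeros(n, dtype=bool)
        decoy = np.zeros(n, dtype=bool)
    observed = values.notna()
    if per_group:
        if table.samples is None:
            raise ValidationError("per_group filtering requires sample annotations")
        groups = table.samples.loc[values.columns, "group"]
        counts = observed.T.groupby(groups.to_numpy()).sum().max(axis=0)
    else:
        counts = observed.sum(axis=1)
    low_obs = (counts < min_replicates).to_numpy()

    report: dict[str, int] = {}
    attributed = np.zeros(n, dtype=bool)
    for rule, mask in (
        ("contaminant", contaminant),
        ("decoy", decoy),
        ("low_observation", low_obs),
    ):
        report[rule] = int((mask & ~attributed).sum())
        attributed |= mask
    keep = ~attributed
    report["removed"] = int(attributed.sum())
    report["retained"] = int(keep.sum())

    out = ProteinTable(
        values[keep],
        flags=None if table.flags is None else table.flags[keep],
        samples=table.samples,
        imputed=None if table.imputed is None else table.imputed[keep],
    )
    return out, report


def median_center(table: ProteinTable) -> ProteinTable:
    """Subtract each sample's median observed log2 intensity.

    After centering every sample's observed median is zero; missing cells
    stay missing. A sample with no observed values is an error.
    """
    values = table.values
    if values.notna().sum(axis=0).eq(0).any():
        raise ValidationError("cannot median-center a sample with no observed values")
    centered = values - values.median(axis=0, skipna=True)
    return ProteinTable(
        centered, flags=table.flags, samples=table.samples, imputed=table.imputed
    )


def impute_mnar(
    table: ProteinTable,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
    seed: int = 0,
) -> ProteinTable:
    """Impute missing cells from a left-shifted Gaussian (global).

    Missing values are replaced by draws from
    ``Normal(mu_obs - shift_sd * sigma_obs, (width_sd * sigma_obs)^2)``
    where ``mu_obs`` / ``sigma_obs`` are the mean and SD of all observed
    values in the matrix. Observed cells are never altered; the imputed-cell
    mask is carried on the returned table.
    """
    values = table.values
    obs = values.to_numpy().ravel()
    obs = obs[~np.isnan(obs)]
    if obs.size < 2:
        raise ValidationError("need at least 2 observed values to impute")
    sigma = float(obs.std(ddof=0))
    if sigma == 0:
        raise ValidationError("observed intensities are constant; cannot impute")
    mu = float(obs.mean())
    rng = np.random.default_rng(seed)
    mask = values.isna()
    n_missing = int(mask.to_numpy().sum())
    draws = rng.normal(mu - shift_sd * sigma, width_sd * sigma, size=n_missing)
    filled = values.to_numpy().copy()
    filled[mask.to_numpy()] = draws
    out_values = pd.DataFrame(filled, index=values.index, columns=values.columns)
    imputed = mask.copy()
    if table.imputed is not None:
        imputed |= table.imputed
    return ProteinTable(
        out_values, flags=table.flags, samples=table.samples, imputed=imputed
    )


def myosin_isoform_percentages(peptides: PeptideTable) -> pd.DataFrame:
    """Per-sample myosin isoform composition from isoform-unique peptides.

    For each sample, unique-peptide intensities are summed within each of
    MYH1/MYH2/MYH4/MYH7 and expressed as percentages of the four-isoform
    grand total. Samples with a zero grand total get NaN percentages and a
    ``flagged`` mark. Rows sum to 100 whenever the grand total is positive.
    """
    data = peptides.data
    unknown = set(data["isoform"]) - set(MYH_ISOFORMS)
    if unknown:
        raise ValidationError(f"unknown isoforms in peptide table: {sorted(unknown)}")
    uniq = data[data["unique"].astype(bool)]
    sums = uniq.groupby("isoform")[peptides.sample_columns].sum()
    sums = sums.reindex(MYH_ISOFORMS, fill_value=0.0)
    grand = sums.sum(axis=0)
    pct = sums.T * 100.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = pct.div(grand, axis=0)
    pct.columns = [f"%{iso}" for iso in pct.columns]
    pct["flagged"] = grand.to_numpy() <= 0
    pct.loc[pct["flagged"], [f"%{iso}" for iso in MYH_ISOFORMS]] = np.nan
    pct.index.name = "sample_id"
    return pct


def call_deps(
    table: ProteinTable,
    design: DesignSpec,
    fdr_max: float = 0.001,
    min_abs_log2fc: float = 1.0,
) -> tuple[ModeratedTResults, pd.DataFrame]:
    """Moderated differential expression on a complete (imputed) table.

    Fits the shared moderated-t machinery on log2 intensities (paired via
    within-subject differencing when ``design.paired``), flags proteins
    robust when ``p_adj < fdr_max`` and ``|log2FC| > min_abs_log2fc``, and
    returns the full results object plus the robust subset.
    """
    if table.samples is None:
        raise ValidationError("call_deps requires sample annotations")
    if table.values.isna().any().any():
        raise ValidationError("call_deps expects a complete (imputed) table")
    model = ModeratedTModel(table.values, table.samples, design)
    res = model.fit()
    res.table.rename(columns={"logFC": "log2FC"}, inplace=True)
    res.table["robust"] = (res.table["p_adj"] < fdr_max) & (
        res.table["log2FC"].abs() > min_abs_log2fc
    )
    if table.imputed is not None:
        res.table["n_imputed"] = table.imputed.sum(axis=1)
    robust = res.table[res.table["robust"].fillna(False)].copy()
    return res, robust
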