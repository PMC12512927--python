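"""Synthetic fibre-type methylomes, whole-muscle mixtures and protein tables.

The generator reproduces the statistical structure the analysis pipeline
assumes, with known ground truth:

* two fibre-type methylation profiles (slow-twitch TI, fast-twitch TII)
  differing at a controllable set of CpGs by at least 10% beta, placed in
  short genomic blocks so region-level calling has something to find;
* whole-muscle (WM) samples as convex mixtures of the two fibre profiles
  (plus an optional non-fibre background profile) with per-sample mixing
  weights recorded in the truth table;
* paired subjects (one TI, one TII, one WM sample each) of both sexes, with
  a per-subject random intercept on the logit-beta scale;
* array noise as beta-distributed observations around the true means, so
  values stay in [0, 1] without clipping;
* label-free protein tables with group effects and intensity-dependent
  (missing-not-at-random) missingness, plus isoform-unique myosin peptides
  whose composition encodes each sample's designated fibre identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import (
    MYH_ISOFORMS,
    BetaMatrix,
    PeptideTable,
    ProteinTable,
    TruthTable,
    ValidationError,
    validate_sample_sheet,
)

__all__ = ["SimConfig", "simulate_fibre_methylomes", "simulate_protein_tables"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic fibre-type study.

    Methylation
    -----------
    n_cpgs, n_subjects
        Array size and number of paired subjects (each contributes one TI,
        one TII and one WM sample). 12 subjects matches a typical pooled
        fibre cohort.
    n_dmp_true
        Number of truly differential CpGs; placed in blocks of 4-8 adjacent
        CpGs sharing a direction, so true regions exist.
    delta_beta_range
        Range of the true TI - TII beta differences at differential CpGs.
    frac_hyper_in_TI
        Fraction of differential blocks hypermethylated in TI.
    noise_precision
        Concentration of the beta-distributed array noise; the observed
        variance at mean m is m(1-m)/(precision+1). The default 624 gives a
        per-CpG SD of about 0.02 at beta 0.5. ``numpy.inf`` switches noise
        off entirely (observations equal their means).
    wm_other_fraction
        Fraction of the WM signal contributed by a non-fibre background
        profile (uniform per-CpG on [0.2, 0.8]); 0 keeps WM an exact
        two-component mixture.
    sex_effect_cpgs
        CpGs shifted by ``sex_effect_delta`` in females only (all tissues).
    subject_sd_logit
        SD of the per-subject random intercept on logit-beta.
    n_wm_only
        Extra subjects contributing only a WM sample.

    Proteomics
    ----------
    n_proteins, n_dep_true, protein_log2fc, protein_sd
        Table size, number of truly differential proteins, their |log2 fold
        change| and the residual SD of log2 intensities.
    missing_intercept, missing_slope
        MNAR missingness: a cell at log2 intensity x is missing with
        probability expit(logit(intercept) - slope * (x - mean)); slope 0
        degenerates to missing-completely-at-random at the intercept rate.
    """

    n_cpgs: int = 20_000
    n_subjects: int = 12
    n_dmp_true: int = 2_000
    delta_beta_range: tuple[float, float] = (0.10, 0.40)
    frac_hyper_in_TI: float = 0.5
    noise_precision: float = 624.0
    wm_other_fraction: float = 0.0
    sex_effect_cpgs: int = 100
    sex_effect_delta: float = 0.10
    subject_sd_logit: float = 0.1
    n_wm_only: int = 0
    wm_w_ti: float | None = None
    seed: int = 0
    # proteomics
    n_proteins: int = 1_000
    n_dep_true: int = 100
    protein_log2fc: float = 2.0
    protein_sd: float = 0.3
    protein_mean: float = 20.0
    protein_between_sd: float = 2.0
    missing_intercept: float = 0.10
    missing_slope: float = 0.6
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_cpgs", "n_subjects", "n_proteins"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_dmp_true < 0 or self.n_dmp_true > self.n_cpgs:
            raise ValidationError("n_dmp_true must be in [0, n_cpgs]")
        lo, hi = self.delta_beta_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("delta_beta_range must satisfy 0 < lo <= hi < 1")
        if self.noise_precision <= 0:
            raise ValidationError("noise_precision must be positive (inf = no noise)")
        if not 0 <= self.wm_other_fraction < 1:
            raise ValidationError("wm_other_fraction must be in [0, 1)")
        if not 0 <= self.frac_hyper_in_TI <= 1:
            raise ValidationError("frac_hyper_in_TI must be in [0, 1]")
        if self.intensity_scale <= 0:
            raise ValidationError("intensity_scale must be positive")
        if self.wm_w_ti is not None and not 0 <= self.wm_w_ti <= 1:
            raise ValidationError("wm_w_ti must be in [0, 1] when fixed")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_beta_noise(rng: np.random.Generator, mean: np.ndarray, precision: float) -> np.ndarray:
    """Beta-distributed observation around ``mean`` with given concentration."""
    if np.isinf(precision):
        return mean.copy()
    m = np.clip(mean, 1e-6, 1 - 1e-6)
    return rng.beta(m * precision, (1.0 - m) * precision)


def _assign_dmp_blocks(rng: np.random.Generator, config: SimConfig) -> list[np.ndarray]:
    """Choose index blocks of 4-8 adjacent CpGs totalling n_dmp_true."""
    blocks: list[np.ndarray] = []
    remaining = config.n_dmp_true
    # Blocks are spaced out over the array so chains never merge.
    cursor = 0
    spacing = max(10, config.n_cpgs // max(1, config.n_dmp_true // 4))
    while remaining > 0 and cursor < config.n_cpgs:
        size = int(min(remaining, rng.integers(4, 9)))
        start = cursor + int(rng.integers(2, max(3, spacing - size)))
        if start + size > config.n_cpgs:
            break
        blocks.append(np.arange(start, start + size))
        cursor = start + size
        remaining -= size
    if sum(len(b) for b in blocks) < config.n_dmp_true:
        raise ValidationError(
            "n_dmp_true too large for n_cpgs given block placement; increase n_cpgs"
        )
    return blocks


def _genomic_annotations(
    rng: np.random.Generator, config: SimConfig, block_member: np.ndarray
) -> pd.DataFrame:
    """Synthetic probe annotations: 22 autosomes, clustered positions, genes."""
    n = config.n_cpgs
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    chrom_breaks = np.linspace(0, n, 23).astype(int)
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    for c in range(22):
        lo, hi = chrom_breaks[c], chrom_breaks[c + 1]
        chrom[lo:hi] = f"chr{c + 1}"
        gaps = np.where(
            block_member[lo:hi],
            rng.integers(50, 401, size=hi - lo),
            rng.integers(1200, 5001, size=hi - lo),
        )
        pos[lo:hi] = 10_000 + np.cumsum(gaps)
    # Genes: runs of ~10 CpGs; ~3% of probes annotated to two genes.
    gene_idx = np.arange(n) // 10
    gene = np.array([f"GENE{g:05d}" for g in gene_idx], dtype=object)
    multi = rng.random(n) < 0.03
    gene[multi] = [f"{g};GENE{int(g[4:]) + 1:05d}" for g in gene[multi]]
    context = rng.choice(CONTEXT_LEVELS, size=n, p=[0.15, 0.15, 0.08, 0.62])
    design_type = rng.choice(["I", "II"], size=n, p=[0.2, 0.8])
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "gene": gene,
            "context": context,
            "design_type": design_type,
            "non_cpg": False,
            "snp_related": False,
            "cross_reactive": False,
            "underperforming": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ann


CONTEXT_LEVELS = ["Island", "Shore", "Shelf", "OpenSea"]


def simulate_fibre_methylomes(
    config: SimConfig,
) -> tuple[BetaMatrix, pd.DataFrame, TruthTable]:
    """Generate TI/TII/WM beta values with known truth.

    Returns
    -------
    beta : BetaMatrix
        One TI, one TII and one WM sample per subject (plus any WM-only
        subjects), with synthetic probe annotations.
    sheet : DataFrame
        Sample sheet indexed by sample id (subject, group, sex,
        measured_prop_TI filled with the true w_TI for WM samples).
    truth : TruthTable
        True WM mixing weights, per-CpG baseline/delta/differential flag.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cpgs

    blocks = _assign_dmp_blocks(rng, config)
    block_member = np.zeros(n, dtype=bool)
    for b in blocks:
        block_member[b] = True

    ann = _genomic_annotations(rng, config, block_member)
    probe_ids = ann.index

    # True fibre profiles: bimodal baseline typical of methylation arrays.
    low = rng.beta(2, 8, size=n) * 0.4          # mostly-unmethylated mode
    high = 0.6 + rng.beta(8, 2, size=n) * 0.4   # mostly-methylated mode
    baseline = np.where(rng.random(n) < 0.5, low, high)

    delta = np.zeros(n)
    lo, hi = config.delta_beta_range
    for b in blocks:
        sign = 1.0 if rng.random() < config.frac_hyper_in_TI else -1.0
        d = rng.uniform(lo, hi, size=len(b))
        delta[b] = sign * d
        # re-centre baseline so both profiles stay inside [0.02, 0.98]
        baseline[b] = rng.uniform(0.02 + d / 2, 0.98 - d / 2)

    beta_ti = np.clip(baseline + delta / 2, 0.0, 1.0)
    beta_tii = np.clip(baseline - delta / 2, 0.0, 1.0)
    background = rng.uniform(0.2, 0.8, size=n)

    # Sex-effect CpGs: shifted in females only, chosen outside DMP blocks.
    sex_delta = np.zeros(n)
    eligible = np.flatnonzero(~block_member)
    n_sex = min(config.sex_effect_cpgs, eligible.size)
    if n_sex > 0:
        sex_sites = rng.choice(eligible, size=n_sex, replace=False)
        sex_delta[sex_sites] = config.sex_effect_delta * np.where(
            rng.random(n_sex) < 0.5, 1.0, -1.0
        )

    n_total_subj = config.n_subjects + config.n_wm_only
    subjects = [f"S{i + 1:02d}" for i in range(n_total_subj)]
    sexes = ["F" if i % 2 == 0 else "M" for i in range(n_total_subj)]
    subject_u = rng.normal(0.0, config.subject_sd_logit, size=n_total_subj)
    if config.wm_w_ti is None:
        # physiological spread of human vastus lateralis TI proportions
        w_ti_raw = rng.uniform(0.2, 0.8, size=n_total_subj)
    else:
        w_ti_raw = np.full(n_total_subj, float(config.wm_w_ti))

    rows = []
    sample_means: dict[str, np.ndarray] = {}
    props_rows = []
    for i, subj in enumerate(subjects):
        is_paired = i < config.n_subjects
        female = sexes[i] == "F"
        shift = sex_delta if female else 0.0
        w_other = config.wm_other_fraction
        w_ti = w_ti_raw[i] * (1.0 - w_other)
        w_tii = (1.0 - w_ti_raw[i]) * (1.0 - w_other)
        wm_mean = w_ti * beta_ti + w_tii * beta_tii + w_other * background

        groups = ("TI", "TII", "WM") if is_paired else ("WM",)
        for grp in groups:
            base = {"TI": beta_ti, "TII": beta_tii, "WM": wm_mean}[grp]
            mean = np.clip(base + shift, 1e-4, 1 - 1e-4)
            if config.subject_sd_logit > 0:
                mean = _expit(_logit(mean) + subject_u[i])
            sid = f"{subj}_{grp}"
            sample_means[sid] = mean
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subj,
                    "group": grp,
                    "sex": sexes[i],
                    "measured_prop_TI": w_ti_raw[i] if grp == "WM" else np.nan,
                }
            )
            if grp == "WM":
                props_rows.append(
                    {"sample_id": sid, "w_TI": w_ti, "w_TII": w_tii, "w_other": w_other}
                )

    sheet = validate_sample_sheet(pd.DataFrame(rows))
    values = pd.DataFrame(index=probe_ids)
    for sid in sheet.index:
        values[sid] = _draw_beta_noise(rng, sample_means[sid], config.noise_precision)

    truth = TruthTable(
        sample_props=pd.DataFrame(props_rows).set_index("sample_id"),
        cpg_truth=pd.DataFrame(
            {
                "base_beta": baseline,
                "beta_TI": beta_ti,
                "beta_TII": beta_tii,
                "delta": delta,
                "is_dmp": block_member,
                "sex_delta": sex_delta,
            },
            index=probe_ids,
        ),
    )
    return BetaMatrix(values, ann), sheet, truth


# Mean myosin isoform composition by designated fibre identity; TI pools are
# nearly pure MYH7, TII pools are MYH2-dominated with MYH1/MYH4 admixture.
_ISOFORM_COMPOSITION = {
    "TI": {"MYH1": 0.007, "MYH2": 0.02, "MYH4": 0.003, "MYH7": 0.97},
    "TII": {"MYH1": 0.12, "MYH2": 0.77, "MYH4": 0.05, "MYH7": 0.06},
}


def simulate_protein_tables(
    config: SimConfig,
    cpg_truth: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
) -> tuple[ProteinTable, PeptideTable, TruthTable]:
    """Generate a log2 protein table with MNAR missingness and MYH peptides.

    One TI and one TII sample per subject. Truly differential proteins get a
    TI - TII log2 fold change of +-``protein_log2fc``; missingness
    probability rises as intensity falls (logistic in log2 intensity).

    Proteins are named by gene symbol (matching the synthetic probe
    annotation scheme). When ``cpg_truth`` and ``annotations`` from
    :func:`simulate_fibre_methylomes` are supplied, the truly differential
    proteins are the genes with the strongest true methylation differences,
    signed opposite to the methylation delta — emulating the canonical
    hypermethylated/down-regulated coupling so integration analyses have a
    known negative relationship to recover. Otherwise DEPs are drawn at
    random.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    n_prot = config.n_proteins
    protein_ids = [f"GENE{i:05d}" for i in range(n_prot)]

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    sexes = ["F" if i % 2 == 0 else "M" for i in range(config.n_subjects)]
    rows = []
    for subj, sex in zip(subjects, sexes):
        for grp in ("TI", "TII"):
            rows.append(
                {"sample_id": f"{subj}_{grp}", "subject_id": subj, "group": grp, "sex": sex}
            )
    samples = validate_sample_sheet(pd.DataFrame(rows))

    base = rng.normal(config.protein_mean, config.protein_between_sd, size=n_prot)
    logfc = np.zeros(n_prot)
    n_dep = min(config.n_dep_true, n_prot)
    if cpg_truth is not None and annotations is not None:
        gene_delta = (
            annotations.assign(delta=cpg_truth["delta"], gene=annotations["gene"].str.split(";"))
            .explode("gene")
            .groupby("gene")["delta"]
            .mean()
            .reindex(protein_ids)
            .fillna(0.0)
        )
        order = gene_delta.abs().sort_values(ascending=False, kind="mergesort").index[:n_dep]
        idx = pd.Index(protein_ids).get_indexer(order)
        logfc[idx] = -np.sign(gene_delta[order].to_numpy()) * config.protein_log2fc
    else:
        dep_idx = rng.choice(n_prot, size=n_dep, replace=False)
        logfc[dep_idx] = config.protein_log2fc * np.where(
            rng.random(n_dep) < 0.5, 1.0, -1.0
        )

    subj_u = rng.normal(0.0, 0.1, size=config.n_subjects)
    cols = {}
    for i, subj in enumerate(subjects):
        for grp in ("TI", "TII"):
            eff = logfc / 2.0 if grp == "TI" else -logfc / 2.0
            cols[f"{subj}_{grp}"] = (
                base + eff + subj_u[i] + rng.normal(0.0, config.protein_sd, size=n_prot)
            )
    values = pd.DataFrame(cols, index=pd.Index(protein_ids, name="protein_id"))
    values *= config.intensity_scale

    # MNAR mask: lower-intensity cells are more likely to be missing.
    x = values.to_numpy()
    centred = x - x.mean()
    logit_rate = np.log(config.missing_intercept / (1.0 - config.missing_intercept))
    p_miss = _expit(logit_rate - config.missing_slope * centred)
    mask = rng.random(x.shape) < p_miss
    observed = values.where(~mask)

    flags = pd.DataFrame(
        {"contaminant": False, "decoy": False}, index=values.index
    )
    # a handful of contaminant/decoy rows, as real FragPipe output carries
    n_flag = max(2, n_prot // 100)
    flag_idx = rng.choice(n_prot, size=2 * n_flag, replace=False)
    flags.iloc[flag_idx[:n_flag], flags.columns.get_loc("contaminant")] = True
    flags.iloc[flag_idx[n_flag:], flags.columns.get_loc("decoy")] = True

    # Isoform-unique MYH peptides (3 per isoform) plus one shared peptide.
    pep_rows = []
    for iso in MYH_ISOFORMS:
        for j in range(3):
            pep_rows.append({"peptide": f"{iso}_pep{j}", "isoform": iso, "unique": True})
    pep_rows.append({"peptide": "MYH_shared", "isoform": "MYH1", "unique": False})
    peptides = pd.DataFrame(pep_rows)
    for sid, row in samples.iterrows():
        comp = _ISOFORM_COMPOSITION[row["group"]]
        total = rng.uniform(0.8e6, 1.2e6)
        inten = []
        for _, prow in peptides.iterrows():
            share = comp[prow["isoform"]] / 3.0
            noise = rng.lognormal(0.0, 0.1)
            inten.append(total * share * noise)
        peptides[sid] = inten

    truth = TruthTable(
        protein_truth=pd.DataFrame(
            {"log2fc": logfc, "is_dep": logfc != 0.0},
            index=values.index,
        )
    )
    return (
        ProteinTable(observed, flags=flags, samples=samples),
        PeptideTable(peptides),
        truth,
    )
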