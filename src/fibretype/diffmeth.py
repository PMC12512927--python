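"""Moderated differential testing and region calling.

The workhorse is :class:`ModeratedTModel`, an empirical-Bayes moderated
t-test in the statsmodels mould: construct from data matrices plus a
:class:`DesignSpec`, call :meth:`~ModeratedTModel.fit`, and get a
:class:`ModeratedTResults` carrying per-feature effects, moderated
t-statistics, BH-adjusted p-values and a ``summary()``. The same machinery
serves CpG M-value matrices (differentially methylated positions, DMPs) and
log2 protein tables (differentially expressed proteins, DEPs).

Moderation follows the scaled-inverse-chi-square hierarchy: per-feature
residual variances s_g^2 on df degrees of freedom are shrunk toward a prior
s0^2 with prior weight d0,

    s_tilde^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df),

and t = effect / (s_tilde * SE-scale) is referred to a t distribution on
d0 + df degrees of freedom. (d0, s0^2) are estimated by moment-matching the
mean and variance of log sample variances through digamma/trigamma relations
of the scaled-F marginal.

Paired designs are resolved by within-subject differencing (exact for
complete, balanced pairs) rather than a REML consensus correlation; the
approximation is recorded in the results metadata.

Region calling (DMRs) chains individually significant, sign-consistent CpGs
with inter-CpG gaps up to ``max_gap`` and scores each chain by Fisher's
combination of the member p-values. Fisher's independence assumption is
violated by local methylation correlation, so the combined p is a ranking
statistic rather than a calibrated error rate; the robust-region rule
(>= 4 CpGs and Fisher P < 0.001) is exposed as thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, MValueMatrix, ValidationError

__all__ = [
    "DesignSpec",
    "ModeratedFitParams",
    "ModeratedTModel",
    "ModeratedTResults",
    "fit_moderated_t",
    "pair_resolve",
    "benjamini_hochberg",
    "call_robust_dmps",
    "fisher_combine",
    "call_dmrs",
]

#: Sentinel cap for an effectively infinite prior df.
D0_INF = 1e6


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a two-group contrast with optional pairing.

    ``grouping`` names the sample-sheet column holding the factor;
    ``contrast`` is the ordered pair of levels, oriented first minus second
    (so "hyper"/"up" means higher in the first level). ``covariates`` are
    additional sample-sheet columns entering unpaired models as dummy-coded
    adjustments. ``paired`` resolves subject blocks to within-subject
    differences. ``interaction`` names a second binary factor whose
    interaction with the grouping factor becomes the tested effect.
    """

    grouping: str = "group"
    contrast: tuple[str, str] = ("TI", "TII")
    covariates: tuple[str, ...] = ()
    paired: bool = True
    interaction: str | None = None

    def __post_init__(self) -> None:
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise ValidationError("contrast must be two distinct levels")
        if self.interaction is not None and self.paired:
            raise ValidationError("interaction models are fitted unpaired")


@dataclass(frozen=True)
class ModeratedFitParams:
    """Empirical-Bayes hyperparameters of a moderated fit."""

    d0: float
    s0_sq: float
    df_residual: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValidationError("s0_sq must be positive")


def trigamma_inverse(x: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0_sq) from per-feature sample variances.

    Uses the distribution of log variances: under the hierarchy,
    log s_g^2 - log s0^2 follows a log scaled-F whose mean and variance are
    digamma/trigamma expressions in df and d0. Returns ``d0`` capped at
    :data:`D0_INF` when the excess variance of log s^2 is non-positive
    (i.e. the variances look homoscedastic).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return D0_INF, float(np.median(s2)) if s2.size else 1.0
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return D0_INF, float(np.exp(e_bar))
    d0 = 2.0 * trigamma_inverse(evar)
    if d0 >= D0_INF:
        return D0_INF, float(np.exp(e_bar))
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def pair_resolve(
    design: DesignSpec, samples: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Resolve subject blocks for a paired contrast.

    Returns a frame with one row per complete block (columns ``subject_id``,
    ``sample_first``, ``sample_second``) and the list of dropped incomplete
    blocks. A block is complete when it holds exactly one sample of each
    contrast level.
    """
    lev_a, lev_b = design.contrast
    sub = samples[samples[design.grouping].isin([lev_a, lev_b])]
    rows, dropped = [], []
    for subj, grp in sub.groupby("subject_id", sort=True):
        a = grp.index[grp[design.grouping] == lev_a]
        b = grp.index[grp[design.grouping] == lev_b]
        if len(a) == 1 and len(b) == 1:
            rows.append(
                {"subject_id": subj, "sample_first": a[0], "sample_second": b[0]}
            )
        else:
            dropped.append(subj)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} incomplete block(s): {dropped}", stacklevel=2
        )
    if not rows:
        raise ValidationError("no complete subject blocks for paired contrast")
    return pd.DataFrame(rows), dropped


def _dummy(series: pd.Series) -> np.ndarray:
    levels = sorted(series.unique())
    if len(levels) < 2:
        return np.zeros((len(series), 0))
    return np.column_stack(
        [(series == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )


class ModeratedTModel:
    """Empirical-Bayes moderated t-test for a two-group contrast.

    Parameters
    ----------
    endog
        Feature x sample matrix analysed on its own scale (M-values for
        methylation, log2 intensities for proteins).
    samples
        Sample sheet indexed by sample id with the design columns.
    design
        Contrast specification.
    effect_endog
        Optional second feature x sample matrix on which the same contrast
        is evaluated purely for effect-size reporting (beta values, giving
        the group beta difference alongside the M-scale test).
    """

    def __init__(
        self,
        endog: pd.DataFrame,
        samples: pd.DataFrame,
        design: DesignSpec,
        effect_endog: pd.DataFrame | None = None,
    ) -> None:
        self.endog = endog
        self.samples = samples
        self.design = design
        self.effect_endog = effect_endog
        lev_a, lev_b = design.contrast
        present = set(samples[design.grouping])
        if lev_a not in present or lev_b not in present:
            raise ValidationError(
                f"contrast levels {design.contrast} not both present in samples"
            )

    # -- design resolution ------------------------------------------------
    def _paired_effects(
        self, matrix: pd.DataFrame, blocks: pd.DataFrame
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        diffs = (
            matrix[blocks["sample_first"]].to_numpy()
            - matrix[blocks["sample_second"]].to_numpy()
        )
        n = diffs.shape[1]
        if n < 2:
            raise ValidationError("paired contrast needs >= 2 complete blocks")
        effect = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        return effect, s2, float(n - 1), 1.0 / np.sqrt(n)

    def _unpaired_design(self) -> tuple[np.ndarray, pd.Index, int]:
        d = self.design
        sheet = self.samples
        keep = sheet[d.grouping].isin(d.contrast)
        if d.interaction is not None:
            keep = keep  # interaction factor levels are used as found
        sheet = sheet[keep]
        g = (sheet[d.grouping] == d.contrast[0]).to_numpy(dtype=float)
        cols = [np.ones(len(sheet)), g]
        for cov in d.covariates:
            cols.append(_dummy(sheet[cov]))
        if d.interaction is not None:
            z = _dummy(sheet[d.interaction])
            if z.shape[1] != 1:
                raise ValidationError("interaction factor must be binary")
            cols.append(z)
            cols.append(g[:, None] * z)
        X = np.column_stack([np.atleast_2d(c).reshape(len(sheet), -1) for c in cols])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError("rank-deficient design matrix")
        # tested coefficient: interaction term if present, else group term
        test_col = X.shape[1] - 1 if d.interaction is not None else 1
        return X, sheet.index, test_col

    def _unpaired_effects(
        self, matrix: pd.DataFrame
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        X, sample_ids, j = self._unpaired_design()
        Y = matrix[sample_ids].to_numpy().T  # samples x features
        n, p = X.shape
        if n - p < 1:
            raise ValidationError("no residual degrees of freedom")
        xtx_inv = np.linalg.inv(X.T @ X)
        coefs = xtx_inv @ X.T @ Y
        resid = Y - X @ coefs
        s2 = (resid**2).sum(axis=0) / (n - p)
        return coefs[j], s2, float(n - p), float(np.sqrt(xtx_inv[j, j]))

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        prior_df: float | None = None,
        prior_var: float | None = None,
    ) -> "ModeratedTResults":
        """Fit per-feature models and moderate the variances.

        ``prior_df`` / ``prior_var`` override the moment-matched
        hyperparameters (``prior_df=0`` reproduces the classical t-test;
        ``numpy.inf`` applies total shrinkage to the prior variance).
        """
        d = self.design
        notes: dict[str, object] = {}
        if d.paired:
            blocks, dropped = pair_resolve(d, self.samples)
            effect, s2, df, se_scale = self._paired_effects(self.endog, blocks)
            notes["pairing"] = "within-subject differencing (duplicate-correlation approximation)"
            notes["n_blocks"] = int(len(blocks))
            notes["dropped_blocks"] = dropped
            if self.effect_endog is not None:
                delta, _, _, _ = self._paired_effects(self.effect_endog, blocks)
            else:
                delta = np.full_like(effect, np.nan)
        else:
            effect, s2, df, se_scale = self._unpaired_effects(self.endog)
            notes["pairing"] = "unpaired group-means model"
            if self.effect_endog is not None:
                delta, _, _, _ = self._unpaired_effects(self.effect_endog)
            else:
                delta = np.full_like(effect, np.nan)

        const = self.endog.max(axis=1).to_numpy() == self.endog.min(axis=1).to_numpy()

        d0, s0_sq = estimate_prior_variance(s2[~const], df)
        if prior_df is not None:
            d0 = float(prior_df)
        if prior_var is not None:
            s0_sq = float(prior_var)
        d0_eff = min(d0, D0_INF)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df_total = np.inf
        elif d0_eff == 0:
            s2_tilde = s2.copy()
            df_total = df
        else:
            s2_tilde = (d0_eff * s0_sq + df * s2) / (d0_eff + df)
            df_total = d0_eff + df

        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / (np.sqrt(s2_tilde) * se_scale)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)

        t = np.where(const, np.nan, t)
        p = np.where(const, np.nan, p)
        eff_out = np.where(const, np.nan, effect)

        table = pd.DataFrame(
            {
                "logFC": eff_out,
                "delta_beta": delta,
                "t": t,
                "p": p,
                "p_adj": benjamini_hochberg(p),
            },
            index=self.endog.index,
        )
        direction_source = table["delta_beta"].where(
            table["delta_beta"].notna(), table["logFC"]
        )
        table["direction"] = np.where(direction_source > 0, "hyper", "hypo")
        table.loc[direction_source.isna(), "direction"] = "na"

        params = ModeratedFitParams(
            d0=float(d0 if not np.isinf(d0) else D0_INF),
            s0_sq=float(s0_sq),
            df_residual=float(df),
        )
        return ModeratedTResults(table, params, design=d, notes=notes)


class ModeratedTResults:
    """Results of a moderated fit: per-feature table plus hyperparameters."""

    def __init__(
        self,
        table: pd.DataFrame,
        params: ModeratedFitParams,
        design: DesignSpec,
        notes: dict | None = None,
    ) -> None:
        self.table = table
        self.params = params
        self.design = design
        self.notes = notes or {}

    @property
    def n_features(self) -> int:
        return len(self.table)

    def robust(
        self, fdr_max: float = 0.001, min_delta: float = 0.10
    ) -> pd.DataFrame:
        """Stringent calls: ``p_adj < fdr_max`` and ``|delta| > min_delta``.

        The effect-size filter uses ``delta_beta`` when available (CpG
        analyses) and falls back to ``logFC`` (protein analyses).
        """
        return call_robust_dmps(self.table, fdr_max=fdr_max, min_delta=min_delta)

    def summary(self, fdr_levels: tuple[float, ...] = (0.05, 0.005, 0.001)) -> str:
        lines = [
            "Moderated t-test results",
            "=" * 38,
            f"contrast:        {self.design.contrast[0]} - {self.design.contrast[1]}",
            f"features:        {self.n_features}",
            f"residual df:     {self.params.df_residual:g}",
            f"prior df (d0):   {self.params.d0:g}",
            f"prior var (s0²): {self.params.s0_sq:.4g}",
            f"model:           {self.notes.get('pairing', 'unspecified')}",
        ]
        valid = self.table["p_adj"].dropna()
        for a in fdr_levels:
            lines.append(f"FDR < {a:<6g}: {(valid < a).sum()} features")
        return "\n".join(lines)


def fit_moderated_t(
    m: MValueMatrix,
    beta: BetaMatrix | None,
    design: DesignSpec,
    samples: pd.DataFrame,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple[pd.DataFrame, ModeratedFitParams]:
    """Functional facade over :class:`ModeratedTModel` for CpG matrices."""
    model = ModeratedTModel(
        m.values,
        samples,
        design,
        effect_endog=None if beta is None else beta.values,
    )
    res = model.fit(prior_df=prior_df, prior_var=prior_var)
    return res.table, res.params


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment with NA propagation.

    NAs are excluded from the number of tests and returned as NA; finite
    entries get the standard monotone step-up adjustment capped at 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_robust_dmps(
    dmps: pd.DataFrame, fdr_max: float = 0.001, min_delta: float = 0.10
) -> pd.DataFrame:
    """Subset differential calls to the stringent ("robust") criteria.

    Keeps rows with ``p_adj < fdr_max`` and effect size strictly above
    ``min_delta`` in absolute value; the effect column is ``delta_beta``
    where finite, else ``logFC``.
    """
    if dmps.empty:
        return dmps.copy()
    effect = dmps["delta_beta"].where(dmps["delta_beta"].notna(), dmps["logFC"])
    keep = (dmps["p_adj"] < fdr_max) & (effect.abs() > min_delta)
    return dmps[keep.fillna(False)].copy()


def fisher_combine(p) -> float:
    """Fisher's combination: X² = -2 Σ ln p against chi-square(2k).

    A zero input p-value forces the combined p to zero (with a warning,
    since -2 ln 0 is infinite).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("fisher_combine requires at least one p-value")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-value in Fisher combination; combined p = 0", stacklevel=2)
        return 0.0
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def call_dmrs(
    dmps: pd.DataFrame,
    annotations: pd.DataFrame,
    max_gap: int = 1000,
    min_cpgs_robust: int = 4,
    fisher_max: float = 0.001,
    seed_fdr: float = 0.05,
) -> pd.DataFrame:
    """Call differentially methylated regions by sign-consistent gap chaining.

    CpGs individually significant at BH FDR ``seed_fdr`` and sharing an
    effect sign are chained while consecutive genomic gaps stay within
    ``max_gap`` bp; chains of >= 2 CpGs become regions. Each region is scored
    by Fisher's combination of the member raw p-values and flagged robust
    when it has at least ``min_cpgs_robust`` CpGs and Fisher P below
    ``fisher_max``. Probes sharing a position (replicate-averaged loci) are
    collapsed to one CpG before chaining.

    Returns a frame sorted by Fisher p with 1-based inclusive ``start`` /
    ``end`` coordinates.
    """
    need = {"chrom", "pos"}
    if not need.issubset(annotations.columns):
        raise ValidationError("annotations must provide chrom and pos")
    sig = dmps[dmps["p_adj"] < seed_fdr].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_cpgs", "fisher_p",
                "mean_delta_beta", "direction", "genes", "robust", "probes",
            ]
        )
    missing = sig.index.difference(annotations.index)
    if len(missing):
        raise ValidationError(f"{len(missing)} significant probes lack positions")
    ann_cols = ["chrom", "pos"] + (["gene"] if "gene" in annotations else [])
    sig = sig.join(annotations.loc[sig.index, ann_cols])
    effect = sig["delta_beta"].where(sig["delta_beta"].notna(), sig["logFC"])
    sig["_sign"] = np.sign(effect)
    sig = sig[sig["_sign"] != 0]
    sig = sig.sort_values(["chrom", "pos"])
    sig = sig[~sig.duplicated(subset=["chrom", "pos"], keep="first")]

    regions = []
    for _, chrom_df in sig.groupby("chrom", sort=True):
        pos = chrom_df["pos"].to_numpy()
        sign = chrom_df["_sign"].to_numpy()
        breaks = np.flatnonzero(
            (np.diff(pos) > max_gap) | (np.diff(sign) != 0)
        )
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            if e - s + 1 < 2:
                continue
            members = chrom_df.iloc[s : e + 1]
            delta = members["delta_beta"].where(
                members["delta_beta"].notna(), members["logFC"]
            )
            genes: set[str] = set()
            if "gene" in members:
                for g in members["gene"].dropna():
                    genes.update(g.split(";"))
            n = len(members)
            fp = fisher_combine(members["p"].to_numpy())
            regions.append(
                {
                    "chrom": members["chrom"].iloc[0],
                    "start": int(members["pos"].min()),
                    "end": int(members["pos"].max()),
                    "n_cpgs": n,
                    "fisher_p": fp,
                    "mean_delta_beta": float(delta.mean()),
                    "direction": "hyper" if members["_sign"].iloc[0] > 0 else "hypo",
                    "genes": ";".join(sorted(genes)),
                    "robust": bool(n >= min_cpgs_robust and fp < fisher_max),
                    "probes": ",".join(members.index.astype(str)),
                }
            )
    out = pd.DataFrame(regions)
    if out.empty:
        out = pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_cpgs", "fisher_p",
                "mean_delta_beta", "direction", "genes", "robust", "probes",
            ]
        )
        return out
    return out.sort_values("fisher_p", kind="mergesort").reset_index(drop=True)
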