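"""Methylome-proteome integration at the gene level.

Proteins are matched to CpG probes via gene-symbol annotation (probes
annotated to several genes contribute to each). For every matched gene the
link table carries the protein log2 fold change alongside four methylation
effect summaries:

* ``top_dmp``  — delta beta of the gene's best CpG (smallest adjusted p,
  ties broken toward the larger |delta beta|);
* ``gene_mean`` — mean delta beta across all the gene's CpGs;
* ``top_dmr``  — mean delta of the gene's most significant robust region;
* ``dmr_mean`` — mean of the gene's robust-region mean deltas.

Averaging across a gene's CpGs cancels independent per-CpG noise, which is
why the gene-mean correlation with protein expression is typically stronger
than the top-CpG one. Quadrant classification labels genes significant in
both layers by sign combination (e.g. HyperDown = hypermethylated and
protein down-regulated in the first contrast level), producing the gene sets
that downstream enrichment tools consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

__all__ = [
    "map_proteins_to_cpgs",
    "build_gene_links",
    "correlate_methylation_protein",
    "quadrant_classify",
]

CORRELATION_MODES = ("top_dmp", "gene_mean", "top_dmr", "dmr_mean")

QUADRANTS = ("HyperDown", "HypoUp", "HyperUp", "HypoDown")


def _explode_genes(annotations: pd.DataFrame) -> pd.DataFrame:
    """One row per (probe, gene), splitting multi-gene annotations."""
    genes = annotations["gene"].dropna().astype(str).str.upper().str.split(";")
    frame = genes.explode().to_frame("gene")
    frame = frame[frame["gene"] != ""]
    frame.index.name = "probe_id"
    return frame.reset_index()


def map_proteins_to_cpgs(
    annotations: pd.DataFrame, proteins: pd.DataFrame
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Map protein gene symbols to annotated CpG sets.

    ``proteins`` is indexed by gene symbol (one row per protein). Returns
    the mapping restricted to proteins with at least one annotated CpG, and
    a count report (``mapped`` / ``unmapped``).
    """
    probe_gene = _explode_genes(annotations)
    by_gene = probe_gene.groupby("gene")["probe_id"].apply(list)
    symbols = proteins.index.astype(str).str.upper()
    mapping = {
        sym: sorted(by_gene[sym]) for sym in symbols if sym in by_gene.index
    }
    report = {"mapped": len(mapping), "unmapped": len(symbols) - len(mapping)}
    return mapping, report


def build_gene_links(
    dmps: pd.DataFrame,
    deps: pd.DataFrame,
    annotations: pd.DataFrame,
    dmrs: pd.DataFrame | None = None,
    dmp_fdr: float = 0.001,
    dep_fdr: float = 0.001,
) -> pd.DataFrame:
    """Assemble the per-gene link table joining both omic layers.

    ``dmps`` is a per-CpG differential table (delta_beta, p_adj), ``deps``
    a per-protein table indexed by gene symbol (log2FC, p_adj), ``dmrs`` an
    optional region table with ``genes`` and ``mean_delta_beta`` columns
    (robust regions only are used). Only proteins with >= 1 annotated CpG
    appear in the output.
    """
    probe_gene = _explode_genes(annotations)
    merged = probe_gene.merge(
        dmps[["delta_beta", "p_adj"]], left_on="probe_id", right_index=True
    )
    rows = []
    dep_idx = deps.index.astype(str).str.upper()
    deps = deps.set_axis(dep_idx)
    per_gene = dict(tuple(merged.groupby("gene")))
    dmr_by_gene: dict[str, pd.DataFrame] = {}
    if dmrs is not None and not dmrs.empty:
        robust = dmrs[dmrs["robust"]].copy()
        robust = robust.assign(gene=robust["genes"].str.upper().str.split(";")).explode(
            "gene"
        )
        dmr_by_gene = dict(tuple(robust.groupby("gene")))
    for gene in dep_idx:
        sub = per_gene.get(gene)
        if sub is None or sub.empty:
            continue
        # top DMP: smallest adjusted p, tie toward larger |delta beta|
        best = sub.sort_values(
            ["p_adj", "delta_beta"],
            ascending=[True, False],
            key=lambda s: s.abs() if s.name == "delta_beta" else s,
            kind="mergesort",
        ).iloc[0]
        gene_dmrs = dmr_by_gene.get(gene)
        if gene_dmrs is not None and len(gene_dmrs):
            top_dmr = float(
                gene_dmrs.sort_values("fisher_p", kind="mergesort")[
                    "mean_delta_beta"
                ].iloc[0]
            )
            dmr_mean = float(gene_dmrs["mean_delta_beta"].mean())
        else:
            top_dmr = np.nan
            dmr_mean = np.nan
        prot = deps.loc[gene]
        rows.append(
            {
                "gene": gene,
                "protein_log2FC": float(prot["log2FC"]),
                "protein_p_adj": float(prot["p_adj"]),
                "top_dmp": float(best["delta_beta"]),
                "top_dmp_p_adj": float(best["p_adj"]),
                "gene_mean": float(sub["delta_beta"].mean()),
                "top_dmr": top_dmr,
                "dmr_mean": dmr_mean,
                "n_cpgs": int(len(sub)),
                "meth_significant": bool(best["p_adj"] < dmp_fdr),
                "prot_significant": bool(prot["p_adj"] < dep_fdr),
            }
        )
    if not rows:
        cols = [
            "protein_log2FC", "protein_p_adj", "top_dmp", "top_dmp_p_adj",
            "gene_mean", "top_dmr", "dmr_mean", "n_cpgs",
            "meth_significant", "prot_significant",
        ]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="gene"))
    return pd.DataFrame(rows).set_index("gene")


def correlate_methylation_protein(
    links: pd.DataFrame, mode: str = "top_dmp"
) -> tuple[float, int, float]:
    """Pearson correlation of a methylation effect mode with protein log2FC.

    Returns ``(r, df, p)`` with ``df = n - 2`` complete gene links.
    """
    if mode not in CORRELATION_MODES:
        raise ValidationError(f"mode must be one of {CORRELATION_MODES}")
    sub = links[[mode, "protein_log2FC"]].dropna()
    if len(sub) < 3:
        raise ValidationError("need at least 3 complete gene links")
    x = sub[mode].to_numpy()
    y = sub["protein_log2FC"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in one of the correlated vectors")
    res = stats.pearsonr(x, y)
    return float(res.statistic), len(sub) - 2, float(res.pvalue)


def quadrant_classify(
    links: pd.DataFrame,
    meth_col: str = "top_dmp",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label genes significant in both layers by sign combination.

    Hyper/Hypo refers to the methylation effect sign, Up/Down to the protein
    log2FC sign, both oriented first contrast level minus second. Genes not
    significant in both layers are labelled ``none``. Returns the labelled
    table and quadrant counts (counts sum to the number of links).
    """
    links = links.copy()
    both = links["meth_significant"] & links["prot_significant"]
    meth_up = links[meth_col] > 0
    prot_up = links["protein_log2FC"] > 0
    quadrant = np.select(
        [
            both & meth_up & ~prot_up,
            both & ~meth_up & prot_up,
            both & meth_up & prot_up,
            both & ~meth_up & ~prot_up,
        ],
        QUADRANTS,
        default="none",
    )
    links["quadrant"] = quadrant
    counts = {q: int((quadrant == q).sum()) for q in QUADRANTS}
    counts["none"] = int((quadrant == "none").sum())
    return links, counts
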