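import numpy as np
import pandas as pd
import pytest

import fibretype as ft


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic study shared across read-only tests."""
    cfg = ft.SimConfig(seed=11)
    beta, sheet, truth = ft.simulate_fibre_methylomes(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def default_dmps(default_sim):
    """Moderated TI-vs-TII fit on the shared synthetic study."""
    _, beta, sheet, _ = default_sim
    m = ft.beta_to_m(beta)
    design = ft.DesignSpec(contrast=("TI", "TII"), paired=True)
    res = ft.ModeratedTModel(m.values, sheet, design, effect_endog=beta.values).fit()
    return res


def toy_beta(values: np.ndarray, ann: pd.DataFrame | None = None,
             samples=None) -> ft.BetaMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, s = values.shape
    idx = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")
    cols = samples if samples is not None else [f"smp{j}" for j in range(s)]
    if ann is None:
        ann = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1) * 100,
                "gene": "GENEA",
                "context": "OpenSea",
                "design_type": "II",
                "non_cpg": False,
                "snp_related": False,
                "cross_reactive": False,
                "underperforming": False,
            },
            index=idx,
        )
    else:
        ann = ann.set_axis(idx)
    return ft.BetaMatrix(pd.DataFrame(values, index=idx, columns=cols), ann)
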