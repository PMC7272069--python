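import numpy as np
import pandas as pd
import pytest

from msdart.simulator import SimParams


@pytest.fixture
def tissue_columns():
    """One-tissue 3v3 column index: (tissue, replicate, library)."""
    return pd.MultiIndex.from_tuples(
        [("t1", f"rep{r}", lib) for lib in ("MspI", "HpaII") for r in (1, 2, 3)],
        names=["tissue", "replicate", "library"],
    )


@pytest.fixture
def small_sim_params():
    """Desk-scale simulation: one 80-kb chromosome."""
    return SimParams(
        chrom_length=80_000,
        n_chromosomes=1,
        n_ccgg_per_chrom=80,
        n_psti_per_chrom=50,
        n_genes_per_chrom=10,
        n_tes_per_chrom=6,
    )


@pytest.fixture
def clean_sim_params(small_sim_params):
    """No methylation, no blocking, deterministic counts."""
    p = small_sim_params
    p.frac_fully_methylated = 0.0
    p.frac_hemi_methylated = 0.0
    p.p_external_chg = 0.0
    p.p_external_chg_solo = 0.0
    p.p_psti_blocked = 0.0
    p.tissue_state_flip_prob = 0.0
    p.dispersion = 0.0
    p.read_depth = 5.0
    return p


def draw_nb(rng: np.random.Generator, mean, dispersion, size):
    """Gamma-Poisson NB draws used to build synthetic count matrices."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)
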