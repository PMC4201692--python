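import numpy as np
import pytest

from embryoqc.cohort import CohortConfig, simulate_founders, simulate_trios
from embryoqc.matrix import GenotypeMatrix, make_locus_table


def small_config(**kw) -> CohortConfig:
    """Desk-scale-but-fast cohort: 10 autosomes + X, 40 founders, 10 trios."""
    defaults = dict(
        n_loci=1650,
        n_autosomes=10,
        x_fraction=0.09,  # ~150 X loci so sexing has power
        n_founders=40,
        n_trios=10,
        maf_low=0.1,
        maf_high=0.5,
        ld_rho=0.9,
        seed=1,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    trios = simulate_trios(founders, cfg, rng)
    return cfg, founders, trios


def toy_matrix(calls, chromosomes=None, quality=None) -> GenotypeMatrix:
    """Build a matrix from a (n_samples, n_loci) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    loci = make_locus_table(
        [f"snp{j}" for j in range(L)],
        ["1"] * L if chromosomes is None else chromosomes,
        np.arange(1, L + 1) * 100,
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], loci, calls, quality)
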