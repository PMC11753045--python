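import numpy as np
import pandas as pd
import pytest

from methcanyon.io import MethylationMatrix, records_from_arrays
from methcanyon.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with planted canyons, shared across tests."""
    cfg = SimulationConfig(
        seed=42,
        n_chroms=1,
        chrom_length_bp=2_000_000,
        island_count=16,
        gene_count=30,
        n_canyons=6,
        group_sizes={"NAT": 3, "EOCRC": 3},
    )
    wgbs, array_matrix, truth, annotation = simulate_cohorts(cfg)
    return cfg, wgbs, truth, annotation


def beta_matrix(rng, mu, n_samples, kappa=30.0):
    """Beta-noise sample columns around per-feature means mu."""
    mu = np.clip(np.asarray(mu, dtype=float), 1e-6, 1 - 1e-6)
    return np.column_stack(
        [rng.beta(mu * kappa, (1 - mu) * kappa) for _ in range(n_samples)]
    )


def site_matrix(pos, A, B, chrom="chr1", name_a="A", name_b="B"):
    """Assemble a site-level MethylationMatrix from two group blocks."""
    na, nb = A.shape[1], B.shape[1]
    cols = [f"{name_a.lower()}{i}" for i in range(na)] + [
        f"{name_b.lower()}{i}" for i in range(nb)
    ]
    values = pd.DataFrame(np.hstack([A, B]), columns=cols)
    features = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64)})
    groups = pd.Series(
        {c: (name_a if i < na else name_b) for i, c in enumerate(cols)}
    )
    return MethylationMatrix(values, features, groups)


def random_records(rng, n=200, chrom="chr1", max_pos=100_000):
    pos = np.sort(rng.choice(max_pos, size=n, replace=False))
    cov = rng.integers(4, 40, size=n)
    meth = rng.binomial(cov, rng.uniform(0, 1, size=n))
    return records_from_arrays(chrom, pos, cov, meth)
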