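import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

from pangenpop.io_filters import GenomeLayout, GroupDesign
from pangenpop.pav import PavMatrix
from pangenpop.synthetic_data import SimConfig, simulate_study


def small_config(seed: int, **overrides) -> SimConfig:
    """Desk-small study: same structure as the default, shrunk for speed."""
    params = dict(
        n_genes=600, n_snps=4000, n_dels=400, n_dups=115, n_ins=5,
        n_chromosomes=4, n_sweep_peaks=4, n_hotspot_clusters=4,
        n_subgroup_marker_genes=40, n_differential_genes=15,
    )
    params.update(overrides)
    return SimConfig(seed=seed, **params)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One small simulated study bundle shared across the session."""
    out = tmp_path_factory.mktemp("study")
    return simulate_study(small_config(seed=11), out)


@pytest.fixture(scope="session")
def toy_layout():
    return GenomeLayout(("chr1", "chr2"), (2_000_000, 1_000_000))


def random_pav(n_genes: int, n_samples: int, seed: int,
               p: float = 0.5) -> PavMatrix:
    rng = np.random.default_rng(seed)
    mat = (rng.random((n_genes, n_samples)) < p).astype(np.int8)
    return PavMatrix(pd.DataFrame(
        mat, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)]))


def two_group_design(n_a: int, n_b: int) -> tuple[GroupDesign, list]:
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    design = GroupDesign({c: ("A" if c.startswith("a") else "B") for c in cols})
    return design, cols
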