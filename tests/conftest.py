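import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import syllogist as sy

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_raw():
    """Hand-sized replicate matrix: 5 genes, 2 lineages x {2, 1} replicates."""
    return pd.DataFrame(
        {
            "A_r1": [2.0, 0.0, 1.0, 4.0, 0.0],
            "A_r2": [4.0, 0.0, 1.0, 2.0, 0.0],
            "B_r1": [0.0, 6.0, 1.0, 3.0, 0.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
    )


@pytest.fixture
def tiny_map():
    return {"A_r1": "A", "A_r2": "A", "B_r1": "B"}


@pytest.fixture(scope="session")
def small_atlas():
    """Fast synthetic atlas for engine tests: 4 lineages, 600 genes, 30 markers."""
    spec = sy.SyntheticAtlasSpec(
        n_lineages=4, n_genes=600, markers_per_lineage=30,
        replicates_per_lineage=2, seed=7,
    )
    raw, rep_map, markers = sy.generate_atlas(spec)
    ref = sy.average_replicates(raw, rep_map)
    sig = sy.build_signatures(ref, 20)
    return ref, sig, markers


@pytest.fixture(scope="session")
def default_atlas():
    """The default synthetic atlas (6 lineages, 5000 genes, 120 planted markers)."""
    spec = sy.SyntheticAtlasSpec()
    raw, rep_map, markers = sy.generate_atlas(spec)
    ref = sy.average_replicates(raw, rep_map)
    sig = sy.build_signatures(ref, 80)
    return ref, sig, markers


@pytest.fixture(scope="session")
def intensity_config():
    """Scoring configuration for intensity-like synthetic data (median cut)."""
    return sy.RunConfig(threshold=0.5, threshold_mode="quantile", seed=42)


def background_cohort(ref, n_samples, seed, exclude="L1"):
    """Equal-weight mixture of every lineage except ``exclude``."""
    lineages = [l for l in ref.lineage_ids if l != exclude]
    w = {l: 1.0 / len(lineages) for l in lineages}
    spec = sy.SyntheticMixtureSpec(weights=w, n_samples=n_samples, seed=seed)
    return sy.generate_mixture(ref.expression, spec)
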