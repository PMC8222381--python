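"""Seeded synthetic reference atlases and query mixtures with known ground truth.

The generator exists to exercise the estimator end-to-end without any
external atlas: each synthetic lineage gets a disjoint block of planted
marker genes whose expected expression is fold-change x baseline in that
lineage only, with multiplicative log-normal replicate noise.  Query
mixtures are convex combinations of the noiseless lineage mean profiles
(normalized to a sequencing-depth total), with mean-one log-normal noise
applied once at the sample level so the ground-truth weights are exact in
expectation.  No attempt is made to model sequencing counts, gene length
or GC bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticAtlasSpec",
    "SyntheticMixtureSpec",
    "generate_atlas",
    "generate_mixture",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Parameters of a synthetic reference atlas.

    Baseline expression is log-normal (meanlog 3, sdlog 1), emulating
    right-skewed microarray-intensity data; markers are planted at
    ``marker_fold`` times baseline in their lineage only, and each
    replicate applies independent multiplicative log-normal noise of
    spread ``noise_sigma``.
    """

    n_lineages: int = 6
    n_genes: int = 5000
    markers_per_lineage: int = 120
    replicates_per_lineage: int = 3
    marker_fold: float = 20.0
    noise_sigma: float = 0.3
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise ValueError("need at least 2 lineages")
        if self.markers_per_lineage * self.n_lineages > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.marker_fold <= 1.0:
            raise ValueError("marker fold-change must exceed 1")
        if self.noise_sigma < 0 or self.replicates_per_lineage < 1:
            raise ValueError("invalid noise or replicate specification")


@dataclass(frozen=True)
class SyntheticMixtureSpec:
    """Parameters of a synthetic bulk query cohort.

    ``weights`` maps lineage id -> mixing weight (non-negative, summing to
    1); samples have expected total ``total`` and mean-one multiplicative
    log-normal noise of spread ``noise_sigma``.
    """

    weights: Mapping[str, float]
    n_samples: int = 10
    total: float = 1e6
    noise_sigma: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(list(self.weights.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()!r}")
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_atlas(
    spec: SyntheticAtlasSpec,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[str]]]:
    """Generate a raw replicate-level atlas.

    Returns ``(raw_matrix, replicate_map, marker_sets)``: the gene x sample
    matrix of all replicates, the sample -> lineage map, and the planted
    marker genes per lineage (the ground truth signatures should recover).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    lineages = [f"L{i}" for i in range(1, spec.n_lineages + 1)]
    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, spec.n_genes)

    # disjoint marker blocks, one per lineage
    marker_sets: dict[str, list[str]] = {}
    means = np.tile(baseline[:, None], (1, spec.n_lineages))
    for li, lin in enumerate(lineages):
        block = slice(li * spec.markers_per_lineage, (li + 1) * spec.markers_per_lineage)
        means[block, li] *= spec.marker_fold
        marker_sets[lin] = genes[block]

    columns = {}
    replicate_map: dict[str, str] = {}
    for li, lin in enumerate(lineages):
        for r in range(1, spec.replicates_per_lineage + 1):
            sample = f"{lin}_r{r}"
            noise = (
                rng.lognormal(0.0, spec.noise_sigma, spec.n_genes)
                if spec.noise_sigma > 0
                else np.ones(spec.n_genes)
            )
            columns[sample] = means[:, li] * noise
            replicate_map[sample] = lin
    raw = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return raw, replicate_map, marker_sets


def generate_mixture(
    lineage_profiles: pd.DataFrame,
    spec: SyntheticMixtureSpec,
) -> pd.DataFrame:
    """Generate a query cohort as noisy convex mixtures of lineage profiles.

    ``lineage_profiles`` is the gene x lineage matrix of (noiseless or
    replicate-averaged) reference profiles; every lineage named in
    ``spec.weights`` must be present.  Each sample's expectation is
    ``total * sum_l w_l * profile_l / sum(profile_l)``.
    """
    missing = [lin for lin in spec.weights if lin not in lineage_profiles.columns]
    if missing:
        raise ValueError(f"weights reference unknown lineages: {missing}")
    profiles = lineage_profiles[list(spec.weights)].astype(float)
    col_sums = profiles.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError("lineage profile with non-positive total")
    normalized = profiles / col_sums
    w = np.asarray(list(spec.weights.values()), dtype=float)
    expected = spec.total * (normalized.to_numpy() @ w)

    rng = np.random.default_rng(spec.seed)
    sigma = spec.noise_sigma
    data = {}
    for s in range(1, spec.n_samples + 1):
        if sigma > 0:
            # mean-one log-normal keeps the expectation at the target mix
            noise = rng.lognormal(-0.5 * sigma**2, sigma, len(expected))
        else:
            noise = np.ones(len(expected))
        data[f"S{s:03d}"] = expected * noise
    return pd.DataFrame(data, index=lineage_profiles.index)
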