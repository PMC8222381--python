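"""In-silico spike-in limit-of-detection experiment.

A reference cell-type profile is linearly mixed into each sample of a
background cohort at fraction f (an RNA-mass fraction; both profiles are
first renormalized to a common total T so f is scale-free):

    mixed = (1 - f) * background + f * spike,   sum(mixed) = T.

The background cohort and each spiked cohort are scored with identical
settings and seeds, and for every fraction a two-tailed paired Student's
t-test compares the target lineage's odds ratios with and without
spike-in.  The limit of detection is the smallest grid fraction whose
paired p-value falls below alpha.  At f = 0 all paired differences are
zero and p is defined as 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .config import RunConfig
from .enrichment import CohortResult, score_cohort
from .signatures import SignatureMap

__all__ = [
    "SpikeInDesign",
    "DetectionCurve",
    "normalize_to_total",
    "spike_transcriptome",
    "detection_limit_curve",
]

DEFAULT_TOTAL = 1e6


def normalize_to_total(values: pd.Series | pd.DataFrame, total: float = DEFAULT_TOTAL):
    """Rescale each sample (column) to sum to ``total``."""
    sums = values.sum(axis=0) if isinstance(values, pd.DataFrame) else values.sum()
    if np.any(np.asarray(sums) <= 0):
        raise ValueError("cannot normalize a sample with non-positive total")
    return values / sums * total


def spike_transcriptome(
    background: pd.Series,
    spike: pd.Series,
    fraction: float,
    total: float = DEFAULT_TOTAL,
) -> pd.Series:
    """Linear mix of a background transcriptome with a spike profile.

    Both profiles are aligned on the union of their genes (absent genes
    count as 0) and normalized to ``total`` before mixing, so the mixed
    sample's total equals ``total`` for every fraction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("spike fraction must lie in [0, 1]")
    genes = background.index.union(spike.index, sort=False)
    bg = normalize_to_total(background.reindex(genes, fill_value=0.0).astype(float), total)
    sp = normalize_to_total(spike.reindex(genes, fill_value=0.0).astype(float), total)
    mixed = (1.0 - fraction) * bg + fraction * sp
    if (mixed < 0).any():
        raise ValueError("negative expression after mixing")
    return mixed


@dataclass(frozen=True)
class SpikeInDesign:
    """Background cohort, spike profile and fraction grid for one experiment."""

    background: pd.DataFrame
    spike_profile: pd.Series
    target_lineage: str
    fractions: tuple[float, ...] = (0.0, 0.001, 0.005, 0.01, 0.05)
    total: float = DEFAULT_TOTAL
    alpha: float = 0.05

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if list(fr) != sorted(fr):
            raise ValueError("fractions must be sorted ascending")
        if self.background.shape[1] < 2:
            raise ValueError("background cohort needs at least 2 samples")
        object.__setattr__(self, "fractions", fr)


@dataclass(frozen=True)
class DetectionCurve:
    """Per-fraction paired-test p-values and the limit of detection."""

    target_lineage: str
    table: pd.DataFrame  # columns: fraction, p_value, neglog10_p, significant
    alpha: float
    limit_of_detection: float | None = field(default=None)

    @property
    def lod_reached(self) -> bool:
        return self.limit_of_detection is not None


def detection_limit_curve(
    design: SpikeInDesign,
    signatures: SignatureMap,
    config: RunConfig,
    *,
    universe: Sequence[str] | None = None,
    baseline: CohortResult | None = None,
) -> DetectionCurve:
    """Run the spike-in experiment for one target lineage.

    The baseline cohort is the normalized background (equivalently a spike
    at f = 0); each spiked cohort shares its sample ids, settings and
    per-sample null seeds, so at f = 0 every paired difference is exactly 0
    and p = 1 by the degenerate convention.  Re-pass ``baseline`` to sweep
    several lineages without rescoring the background.
    """
    if design.target_lineage not in signatures.lineage_ids:
        raise KeyError(f"target lineage not in signatures: {design.target_lineage!r}")
    background = normalize_to_total(design.background.astype(float), design.total)
    if baseline is None:
        baseline = score_cohort(background, signatures, config, universe=universe)
    base_or = _lineage_ors(baseline, design.target_lineage, background.columns)

    rows = []
    lod = None
    for f in design.fractions:
        if f == 0.0:
            p = 1.0
        else:
            spiked = pd.DataFrame(
                {
                    s: spike_transcriptome(
                        background[s], design.spike_profile, f, design.total
                    )
                    for s in background.columns
                }
            )
            result = score_cohort(spiked, signatures, config, universe=universe)
            spike_or = _lineage_ors(result, design.target_lineage, background.columns)
            _, _, p = stats.t_test(spike_or, base_or, paired=True)
        neglog = -math.log10(p) + 0.0 if p > 0 else math.inf  # +0.0 avoids -0.0
        significant = p < design.alpha
        if significant and lod is None:
            lod = f
        rows.append((f, p, neglog, significant))
    table = pd.DataFrame(
        rows, columns=["fraction", "p_value", "neglog10_p", "significant"]
    )
    return DetectionCurve(
        target_lineage=design.target_lineage,
        table=table,
        alpha=design.alpha,
        limit_of_detection=lod,
    )


def _lineage_ors(result: CohortResult, lineage: str, order) -> np.ndarray:
    sub = result.table[result.table["lineage_id"] == lineage].set_index("sample_id")
    return sub.loc[list(map(str, order)), "odds_ratio"].to_numpy()
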