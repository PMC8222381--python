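"""Per-cell-type enrichment scoring of query transcriptomes.

For each query sample the set of expressed genes is defined by a threshold,
the overlap of each lineage signature with that set is counted, and the
count is compared to a Monte-Carlo null: B random m-gene lists drawn
without replacement from the gene universe, whose mean overlap with the
expressed set is the chance-enrichment baseline.  A two-sided Fisher's
exact test on the 2x2 table

    [[k_obs, m - k_obs], [k_null, m - k_null]]

yields a p-value and an odds ratio; the odds ratio serves as a relative,
intersample abundance proxy (not a cell fraction).  Across a cohort, odds
ratios are min-max normalized per lineage to [0, 1] for heatmap-style
comparison, and group contrasts use Student's t with BH correction across
lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .config import RunConfig
from .signatures import SignatureMap

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "CohortResult",
    "expressed_genes",
    "count_signature_hits",
    "build_null_model",
    "fisher_enrichment",
    "score_sample",
    "score_cohort",
    "normalize_odds_ratios",
    "compare_groups",
]

RESULT_COLUMNS = [
    "sample_id",
    "lineage_id",
    "k_obs",
    "k_null_mean",
    "k_null",
    "p_value",
    "odds_ratio",
]


def expressed_genes(
    values: pd.Series, threshold: float, mode: str = "absolute"
) -> set[str]:
    """Genes of one sample passing the expression threshold.

    ``absolute`` mode keeps genes with value strictly above ``threshold``
    (which must be >= 0); ``quantile`` mode keeps genes strictly above the
    per-sample ``threshold``-quantile, threshold in (0, 1).
    """
    if mode == "absolute":
        if threshold < 0:
            raise ValueError("absolute threshold must be >= 0")
        cut = threshold
    elif mode == "quantile":
        if not 0.0 < threshold < 1.0:
            raise ValueError("quantile threshold must lie in (0, 1)")
        cut = float(values.quantile(threshold))
    else:
        raise ValueError(f"unknown threshold mode: {mode!r}")
    return set(values.index[values > cut])


def count_signature_hits(signature_genes: Iterable[str], expressed: set[str]) -> int:
    """|signature ∩ expressed set|."""
    return len(set(signature_genes) & expressed)


@dataclass(frozen=True)
class NullModel:
    """Monte-Carlo random-gene-list null for one query sample.

    ``k_null_mean`` is the mean overlap of ``n_lists`` random ``list_size``-
    gene lists (drawn uniformly without replacement from the universe) with
    the sample's expressed set; ``k_null`` is its half-up rounding, the
    integer count entering the Fisher table.  The analytic mean
    m * |E ∩ U| / |U| of the equivalent hypergeometric distribution is kept
    for validation.
    """

    universe_size: int
    n_expressed_in_universe: int
    n_lists: int
    list_size: int
    seed: int
    k_null_mean: float
    hit_counts: np.ndarray

    @property
    def k_null(self) -> int:
        return int(np.floor(self.k_null_mean + 0.5))

    @property
    def analytic_mean(self) -> float:
        return self.list_size * self.n_expressed_in_universe / self.universe_size


def build_null_model(
    universe: Sequence[str],
    expressed: set[str],
    n_lists: int = 1000,
    list_size: int = 80,
    seed: int = 42,
) -> NullModel:
    """Draw ``n_lists`` random gene lists and record their expressed-set overlap."""
    universe = pd.Index(universe)
    if universe.has_duplicates:
        raise ValueError("gene universe contains duplicates")
    n_u = len(universe)
    if n_u < list_size:
        raise ValueError(f"universe size {n_u} smaller than list size {list_size}")
    mask = universe.isin(expressed)
    rng = np.random.default_rng(seed)
    hits = np.empty(n_lists, dtype=np.int64)
    for j in range(n_lists):
        idx = rng.choice(n_u, size=list_size, replace=False)
        hits[j] = int(mask[idx].sum())
    return NullModel(
        universe_size=n_u,
        n_expressed_in_universe=int(mask.sum()),
        n_lists=n_lists,
        list_size=list_size,
        seed=seed,
        k_null_mean=float(hits.mean()),
        hit_counts=hits,
    )


def fisher_enrichment(k_obs: int, k_null: int, m: int) -> tuple[float, float]:
    """Fisher's exact test of observed vs chance signature hits.

    Both rows of the 2x2 table sum to the signature size m.  Returns
    ``(p_value, odds_ratio)`` with the sample odds ratio (Haldane–Anscombe
    corrected when any cell is zero).
    """
    for name, k in (("k_obs", k_obs), ("k_null", k_null)):
        if not 0 <= k <= m:
            raise ValueError(f"{name}={k} outside [0, {m}]")
    table = [[k_obs, m - k_obs], [k_null, m - k_null]]
    return stats.fisher_exact_two_sided(table)


def score_sample(
    sample_id: str,
    values: pd.Series,
    signatures: SignatureMap,
    null: NullModel,
    *,
    threshold: float,
    threshold_mode: str = "absolute",
    expressed: set[str] | None = None,
) -> pd.DataFrame:
    """Score one sample against every lineage signature.

    One null model (one expressed set) per sample, shared across lineages.
    Returns a long-format frame with one row per lineage.
    """
    if expressed is None:
        expressed = expressed_genes(values, threshold, threshold_mode)
    m = signatures.signature_size
    if m != null.list_size:
        raise ValueError("signature size and null list size differ")
    rows = []
    for lineage in signatures.lineage_ids:
        genes = signatures.genes(lineage)
        k_obs = count_signature_hits(genes, expressed)
        p, or_ = fisher_enrichment(k_obs, null.k_null, m)
        rows.append((sample_id, lineage, k_obs, null.k_null_mean, null.k_null, p, or_))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass(frozen=True)
class CohortResult:
    """Scored cohort: long-format table plus the configuration that produced it."""

    table: pd.DataFrame
    config: RunConfig

    def wide_normalized(self) -> pd.DataFrame:
        """Samples x lineages matrix of normalized odds ratios (heatmap-ready)."""
        if "normalized_odds_ratio" not in self.table.columns:
            raise ValueError("cohort not normalized yet")
        return self.table.pivot(
            index="sample_id", columns="lineage_id", values="normalized_odds_ratio"
        )


def score_cohort(
    query: pd.DataFrame,
    signatures: SignatureMap,
    config: RunConfig,
    *,
    universe: Sequence[str] | None = None,
) -> CohortResult:
    """Score every sample of a query gene x sample matrix.

    The gene universe for the null defaults to the genes of the query's
    reference atlas recorded in ``universe``; ``config.universe = "query"``
    restricts it to genes measured in the query.  Each sample gets an
    independent, deterministically derived null-model seed so a rerun with
    the same seed is byte-identical.
    """
    if query.shape[1] == 0:
        raise ValueError("query cohort is empty")
    if universe is None or config.universe == "query":
        universe = list(query.index)
    sig_genes = set(signatures.table["gene_id"])
    missing = sig_genes - set(universe)
    if missing:
        logger.warning(
            "%d signature genes absent from the gene universe", len(missing)
        )
    sample_seeds = _sample_seeds(config.seed, query.shape[1])
    frames = []
    for pos, sample in enumerate(query.columns):
        values = query[sample]
        expressed = expressed_genes(values, config.threshold, config.threshold_mode)
        # the signatures actually supplied define m, even if config differs
        null = build_null_model(
            universe,
            expressed,
            n_lists=config.null_lists,
            list_size=signatures.signature_size,
            seed=sample_seeds[pos],
        )
        frames.append(
            score_sample(
                str(sample),
                values,
                signatures,
                null,
                threshold=config.threshold,
                threshold_mode=config.threshold_mode,
                expressed=expressed,
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table = normalize_odds_ratios(table)
    return CohortResult(table=table, config=config)


def _sample_seeds(seed: int, n: int) -> list[int]:
    """Per-sample null seeds derived from the run seed, independent of cohort
    content so the same sample position always gets the same stream."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def normalize_odds_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize odds ratios per lineage across the cohort to [0, 1].

    A lineage whose odds ratio is constant across the cohort maps to 0 for
    every sample (the degenerate max = min case).
    """
    out = table.copy()

    def _norm(col: pd.Series) -> pd.Series:
        lo, hi = col.min(), col.max()
        if hi == lo:
            return pd.Series(0.0, index=col.index)
        return (col - lo) / (hi - lo)

    out["normalized_odds_ratio"] = (
        out.groupby("lineage_id", sort=False)["odds_ratio"].transform(_norm)
    )
    return out


def compare_groups(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    *,
    paired: bool = False,
    welch: bool = False,
    value: str = "odds_ratio",
) -> pd.DataFrame:
    """Two-group comparison of per-lineage odds ratios across a cohort.

    ``groups`` maps sample_id -> group label (exactly two labels).  Unpaired
    uses the pooled-variance Student's t; paired pairs samples by their
    within-group order as listed in ``groups`` and requires equal sizes.
    p-values are BH-adjusted across lineages within the comparison.
    Returns a frame (lineage_id, t, df, p_value, p_adj).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1 = [s for s, g in groups.items() if g == labels[0]]
    g2 = [s for s, g in groups.items() if g == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    if paired and len(g1) != len(g2):
        raise ValueError("paired comparison requires equal group sizes")
    known = set(table["sample_id"])
    unknown = [s for s in (*g1, *g2) if s not in known]
    if unknown:
        raise ValueError(f"samples not present in results: {unknown}")
    wide = table.pivot(index="sample_id", columns="lineage_id", values=value)
    rows = []
    for lineage in wide.columns:
        x = wide.loc[g1, lineage].to_numpy()
        y = wide.loc[g2, lineage].to_numpy()
        t, df, p = stats.t_test(x, y, paired=paired, welch=welch)
        rows.append((lineage, t, df, p))
    out = pd.DataFrame(rows, columns=["lineage_id", "t", "df", "p_value"])
    out["p_adj"] = stats.bh_adjust(out["p_value"].to_numpy())
    return out
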