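"""Marker-signature construction from a reference expression atlas.

A reference atlas is a gene x lineage expression matrix obtained by
averaging technical replicates of purified cell populations.  For every
gene g the relative expression across the N lineages,

    p_(l|g) = x_(g,l) / sum_l' x_(g,l'),

defines an entropy-based specificity index

    S_(l|g) = H_g - log2 p_(l|g),    H_g = -sum_l' p_(l'|g) log2 p_(l'|g),

the Q statistic of Schug et al.  S is 0 exactly when gene g is expressed in
lineage l only, log2 N + log2 N = 2 log2 N when expression is uniform, and
+inf when the gene is silent in l.  The m most specific genes per lineage
(smallest S) form that lineage's signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceAtlas",
    "SignatureMap",
    "average_replicates",
    "relative_expression",
    "specificity_index",
    "build_signatures",
]

#: Default number of marker genes retained per lineage.
DEFAULT_SIGNATURE_SIZE = 80

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class ReferenceAtlas:
    """Replicate-averaged gene x lineage expression matrix.

    ``expression`` has one column per lineage, each the arithmetic mean of
    that lineage's technical replicates; ``replicate_map`` records the
    original sample -> lineage grouping.
    """

    expression: pd.DataFrame
    replicate_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expression.shape[1] < 2:
            raise ValueError("a reference atlas needs at least 2 lineages")
        if self.expression.index.has_duplicates:
            raise ValueError("duplicate gene ids in atlas")
        if self.expression.columns.has_duplicates:
            raise ValueError("duplicate lineage ids in atlas")
        vals = self.expression.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("atlas expression contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("atlas expression contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def lineage_ids(self) -> pd.Index:
        return self.expression.columns


@dataclass(frozen=True)
class SignatureMap:
    """Per-lineage ordered marker lists with their specificity indices.

    ``table`` is long-format with columns
    (lineage_id, rank, gene_id, specificity_index, relative_expression);
    rank is 1-based, most specific first.
    """

    table: pd.DataFrame
    signature_size: int

    _COLUMNS = ("lineage_id", "rank", "gene_id", "specificity_index", "relative_expression")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"signature table missing columns: {sorted(missing)}")
        counts = self.table.groupby("lineage_id", sort=False)["gene_id"].agg(["size", "nunique"])
        if not (counts["size"] == self.signature_size).all():
            raise ValueError("each lineage must have exactly signature_size entries")
        if not (counts["nunique"] == counts["size"]).all():
            raise ValueError("duplicate genes within a lineage signature")

    @property
    def lineage_ids(self) -> list[str]:
        return list(self.table["lineage_id"].unique())

    def genes(self, lineage: str) -> list[str]:
        sub = self.table.loc[self.table["lineage_id"] == lineage]
        if sub.empty:
            raise KeyError(f"unknown lineage: {lineage!r}")
        return sub.sort_values("rank")["gene_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMap":
        table = pd.read_csv(path, sep="\t")
        m = int(table.groupby("lineage_id", sort=False).size().iloc[0])
        return cls(table=table, signature_size=m)


def average_replicates(raw: pd.DataFrame, replicate_map: Mapping[str, str]) -> ReferenceAtlas:
    """Collapse technical replicates to one column per lineage by arithmetic mean.

    Every sample column of ``raw`` must appear in ``replicate_map``; lineage
    column order follows first appearance among the raw samples.  Gene order
    is preserved.
    """
    unmapped = [s for s in raw.columns if s not in replicate_map]
    if unmapped:
        raise ValueError(f"samples missing from replicate map: {unmapped}")
    groups: dict[str, list[str]] = {}
    for sample in raw.columns:
        groups.setdefault(replicate_map[sample], []).append(sample)
    empty = [lin for lin, cols in groups.items() if not cols]
    if empty:
        raise ValueError(f"lineages with no replicates: {empty}")
    averaged = pd.DataFrame(
        {lin: raw[cols].mean(axis=1) for lin, cols in groups.items()},
        index=raw.index,
    )
    used_map = {s: replicate_map[s] for s in raw.columns}
    return ReferenceAtlas(expression=averaged, replicate_map=used_map)


def relative_expression(atlas: ReferenceAtlas, gene: str) -> pd.Series:
    """Relative expression p_(l|g) of one gene across lineages.

    Returns a Series over lineages summing to 1.  A gene with zero total
    expression has undefined relative expression and is returned as all-NaN
    (such genes are excluded from signature candidacy).
    """
    if gene not in atlas.expression.index:
        raise KeyError(f"gene not in atlas: {gene!r}")
    row = atlas.expression.loc[gene].astype(float)
    total = row.sum()
    if total == 0:
        return pd.Series(np.nan, index=row.index, name=gene)
    return row / total


def specificity_index(p: Iterable[float], lineage: int) -> float:
    """Specificity index S = H - log2 p_l for a relative-expression vector.

    ``lineage`` is the 0-based position in ``p``.  Uses the convention
    0*log2(0) = 0 in the entropy sum; S = +inf when p_l = 0 and 0 when
    p_l = 1.  Raises if ``p`` is not a probability vector (tolerance 1e-9).
    """
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if np.any(p < -_PROB_TOL) or abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError("p is not a probability vector")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    pl = p[lineage]
    if pl == 0:
        return float("inf")
    return entropy - float(np.log2(pl)) + 0.0  # +0.0 normalizes -0.0


def _specificity_matrix(atlas: ReferenceAtlas) -> tuple[pd.DataFrame, pd.DataFrame]:
    """S and p matrices (genes x lineages) for all genes with non-zero row sum."""
    x = atlas.expression.to_numpy(dtype=float)
    row_sums = x.sum(axis=1)
    defined = row_sums > 0
    xd = x[defined]
    p = xd / row_sums[defined, None]
    log2p = np.full_like(p, -np.inf)
    np.log2(p, out=log2p, where=p > 0)
    with np.errstate(invalid="ignore"):
        plogp = np.where(p > 0, p * log2p, 0.0)
    entropy = -plogp.sum(axis=1)
    s = entropy[:, None] - log2p
    genes = atlas.expression.index[defined]
    return (
        pd.DataFrame(s, index=genes, columns=atlas.lineage_ids),
        pd.DataFrame(p, index=genes, columns=atlas.lineage_ids),
    )


def build_signatures(
    atlas: ReferenceAtlas,
    m: int = DEFAULT_SIGNATURE_SIZE,
    *,
    rank_direction: str = "ascending",
) -> SignatureMap:
    """Select the m most specific genes per lineage.

    Genes are ranked by ascending specificity index (a lineage-exclusive
    gene has S = 0, the most specific possible); ties are broken by higher
    expression in the lineage, then lexicographic gene id, so the result is
    deterministic across platforms.  ``rank_direction="descending"``
    reverses the S ordering.
    """
    if m < 1:
        raise ValueError("signature size m must be positive")
    if rank_direction not in ("ascending", "descending"):
        raise ValueError(f"rank_direction must be 'ascending' or 'descending', got {rank_direction!r}")
    s_mat, p_mat = _specificity_matrix(atlas)
    if len(s_mat) < m:
        raise ValueError(
            f"atlas has only {len(s_mat)} genes with defined relative expression; "
            f"{m} required"
        )
    s_ascending = rank_direction == "ascending"
    rows = []
    for lineage in atlas.lineage_ids:
        frame = pd.DataFrame(
            {
                "S": s_mat[lineage],
                "x": atlas.expression.loc[s_mat.index, lineage],
                "p": p_mat[lineage],
            }
        )
        frame["gene"] = frame.index
        frame = frame.sort_values(
            ["S", "x", "gene"], ascending=[s_ascending, False, True], kind="stable"
        )
        top = frame.head(m)
        rows.append(
            pd.DataFrame(
                {
                    "lineage_id": lineage,
                    "rank": np.arange(1, m + 1),
                    "gene_id": top["gene"].to_numpy(),
                    "specificity_index": top["S"].to_numpy(),
                    "relative_expression": top["p"].to_numpy(),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    logger.info("built %d-gene signatures for %d lineages", m, len(atlas.lineage_ids))
    return SignatureMap(table=table, signature_size=m)
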