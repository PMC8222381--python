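"""Readers and writers for expression matrices, replicate maps and results.

The canonical dialect is TSV (tab-separated, UTF-8, '.' decimal) with the
gene identifier in the first column and sample identifiers in the header
row; CSV is accepted on input.  Gzip-compressed files are read
transparently.  Ingest is defensive: duplicate gene rows are collapsed by
mean with a warning, negative values (microarray artifacts) are floored at
0 with a warning, and empty or non-numeric cells are hard errors.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .enrichment import CohortResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "read_replicate_map",
    "write_expression_matrix",
    "write_results",
]

_FLOAT_FORMAT = "%.10g"


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    name = path.name.removesuffix(".gz")
    return "," if name.endswith(".csv") else "\t"


def read_expression_matrix(path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene x sample matrix (genes as rows, samples as columns).

    Returns a DataFrame with unique gene index and sample columns, all
    values finite and non-negative.
    """
    path = Path(path)
    sep_ = _infer_sep(path, sep)
    try:
        # read the raw header separately: pandas silently renames duplicate
        # column names, which would mask duplicate sample ids
        header = pd.read_csv(path, sep=sep_, header=None, nrows=1).iloc[0].astype(str)
        samples = header.iloc[1:]
        if samples.duplicated().any():
            dupes = samples[samples.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate sample ids: {dupes}")
        df = pd.read_csv(path, sep=sep_, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"{path}: malformed expression matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if not bad.empty:
                # +2: header line and 1-based counting
                line = df.index.get_loc(bad.index[0]) + 2
                raise ValueError(
                    f"{path}: non-numeric value {bad[col].iloc[0]!r} in column "
                    f"{col!r} near line {line}"
                )
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: empty or missing cell at gene {gene!r}")
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        warnings.warn(
            f"{path}: {n_dup} duplicate gene rows collapsed by mean", stacklevel=2
        )
        df = df.groupby(level=0, sort=False).mean()
    if (df.to_numpy() < 0).any():
        n_neg = int((df.to_numpy() < 0).sum())
        warnings.warn(f"{path}: {n_neg} negative values floored at 0", stacklevel=2)
        df = df.clip(lower=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str)
    return df


def read_replicate_map(path, sep: str | None = None) -> dict[str, str]:
    """Read a 2-column (sample_id, lineage_id) table into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep))
    if df.shape[1] != 2:
        raise ValueError(f"{path}: replicate map must have exactly 2 columns")
    samples = df.iloc[:, 0].astype(str)
    if samples.duplicated().any():
        dupes = samples[samples.duplicated()].tolist()
        raise ValueError(f"{path}: samples mapped more than once: {dupes}")
    return dict(zip(samples, df.iloc[:, 1].astype(str)))


def write_expression_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, float_format=_FLOAT_FORMAT)


def write_results(result: CohortResult, out_dir) -> dict[str, Path]:
    """Write a scored cohort to ``out_dir``.

    Emits the long-format result table, the wide normalized-odds-ratio
    matrix, the run configuration with its digest, and a short log file.
    Column order is stable and floats use a fixed format, so identical
    runs produce byte-identical files.
    """
    if result.table.empty:
        raise ValueError("refusing to write an empty cohort result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "long": out_dir / "results_long.tsv",
        "wide": out_dir / "normalized_odds_ratios.tsv",
        "config": out_dir / "run_config.yaml",
        "digest": out_dir / "config_digest.txt",
        "log": out_dir / "run_log.txt",
    }
    result.table.to_csv(paths["long"], sep="\t", index=False, float_format=_FLOAT_FORMAT)
    result.wide_normalized().to_csv(paths["wide"], sep="\t", float_format=_FLOAT_FORMAT)
    result.config.to_yaml(paths["config"])
    digest = result.config.digest()
    paths["digest"].write_text(digest + "\n", encoding="utf-8")
    n_samples = result.table["sample_id"].nunique()
    n_lineages = result.table["lineage_id"].nunique()
    paths["log"].write_text(
        f"samples\t{n_samples}\nlineages\t{n_lineages}\nconfig_digest\t{digest}\n"
        f"seed\t{result.config.seed}\n",
        encoding="utf-8",
    )
    logger.info("wrote results for %d samples x %d lineages to %s", n_samples, n_lineages, out_dir)
    return paths
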