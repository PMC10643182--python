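"""Expression and clinical containers, TSV I/O, and expression normalization.

The pipeline works on two tabular objects: a gene-by-sample
:class:`ExpressionMatrix` whose ``mode`` records where it sits in the
counts -> normalized -> log -> zscore chain, and a per-sample
:class:`ClinicalTable` holding overall-survival time, an event indicator and
optional covariates.  Normalization follows the median-of-ratios recipe
(per-sample size factors are medians, over genes positive in every sample,
of the count divided by the gene's geometric mean), and standardization is
a per-gene z-score with the n-1 standard-deviation divisor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("counts", "normalized", "log", "zscore")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus a processing-mode tag.

    Parameters
    ----------
    values
        DataFrame with unique gene ids as index and unique sample ids as
        columns.  No missing values are allowed.
    mode
        One of ``counts``, ``normalized``, ``log``, ``zscore``.
    constant_genes
        Gene ids whose row was constant when z-scoring (their z-rows are 0).
    """

    values: pd.DataFrame
    mode: str = "counts"
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.mode == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("counts mode requires non-negative values")
        self.values.index.name = "gene_id"
        self.values.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Subset to ``gene_ids``; raises listing any genes that are absent."""
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[gene_ids].copy(), mode=self.mode,
                                constant_genes=list(self.constant_genes))


@dataclass
class ClinicalTable:
    """Per-sample survival time, event indicator and covariates.

    ``data`` is indexed by sample id with a positive ``time`` column and a
    binary ``event`` column (1 = death, 0 = censored); any further columns
    are covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing {col!r} column")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if (self.data["time"].to_numpy() <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.data["event"])) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def aligned_to(self, m: ExpressionMatrix) -> "ClinicalTable":
        """Reorder to the matrix's samples; raises if any sample lacks clinical data."""
        missing = [s for s in m.sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples without clinical data: {missing}")
        return ClinicalTable(self.data.loc[m.sample_ids].copy())


# ---------------------------------------------------------------------------
# TSV / JSON I/O (gzip-transparent through pandas' compression inference)
# ---------------------------------------------------------------------------

def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path, mode: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, mode=mode)


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    out = c.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Normalization and standardization
# ---------------------------------------------------------------------------

def median_of_ratios_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios normalization of a counts matrix.

    The reference set is the genes with strictly positive counts in every
    sample; each such gene's cross-sample geometric mean is the denominator
    of its per-sample ratio, and a sample's size factor is the median of its
    ratios over the reference set.  Every gene (including genes with zeros,
    which are excluded from the reference set only) is then divided by the
    sample's size factor.

    Returns the normalized matrix and the per-sample size factors.
    """
    if m.mode != "counts":
        raise ValueError(f"expected counts mode, got {m.mode!r}")
    counts = m.values.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "median-of-ratios normalization requires at least one gene with "
            "positive counts in every sample; none found"
        )
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geomean)
    size_factors = np.median(ratios, axis=0)
    normalized = counts / size_factors[np.newaxis, :]
    sf = pd.Series(size_factors, index=m.values.columns, name="size_factor")
    out = pd.DataFrame(normalized, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, mode="normalized"), sf


def log_transform(m: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log(pseudocount + x); default log2(1 + x)."""
    if m.mode not in ("counts", "normalized"):
        raise ValueError(f"log transform expects counts/normalized input, got {m.mode!r}")
    vals = np.log(pseudocount + m.values.to_numpy(dtype=float)) / np.log(base)
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, mode="log")


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores with the sample (n-1) standard-deviation divisor.

    Constant genes cannot be standardized; their rows are set to zero and
    their ids recorded in ``constant_genes`` so downstream gene indexing
    stays aligned.
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd_safe = np.where(constant[:, np.newaxis], 1.0, sd)
    z = (vals - mean) / sd_safe
    z[constant] = 0.0
    constant_ids = [g for g, c in zip(m.values.index, constant) if c]
    if constant_ids:
        logger.info("z-score: %d constant gene(s) set to zero: %s",
                    len(constant_ids), constant_ids[:10])
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, mode="zscore", constant_genes=constant_ids)
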