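"""Bulk-level DE/DV testing and per-sample mixture decomposition.

The analysis pipeline mirrors how multi-donor scRNA-seq data are reduced to a
bulk-style comparison:

1. log(1 + count) transform, then rescale each cell so its gene sum is 10^6;
2. pseudobulk: per-sample mean of the (normalised) single-cell values;
3. keep genes whose grand-mean pseudobulk expression exceeds a floor
   (default > 20) — the mean-proportionality assumption is unreliable for
   lowly expressed genes;
4. per gene, Welch's unequal-variance t-test (differential expression of the
   bulk mean) and a two-sided variance-ratio F-test (differential
   variability), each followed by Benjamini-Hochberg correction at 5% FDR;
5. for genes of interest (by default the top DE and top DV gene), decompose
   each sample's single-cell value vector into the two-subset parameters
   (mu_plus_hat, mu_minus_hat, r_hat) by 2-means clustering in 1-D.

The 1-D 2-means decomposition is solved exactly: optimal clusters in one
dimension are intervals, so the global optimum is the best of the n-1
threshold partitions of the sorted values, found in O(n log n) with prefix
sums.  This makes the decomposition deterministic with no restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .model import InvalidParameterError

__all__ = [
    "SingleCellDataset",
    "DecompositionEstimate",
    "TestResult",
    "PipelineConfig",
    "PipelineResult",
    "normalize_cells",
    "pseudobulk",
    "filter_genes",
    "de_dv_test",
    "decompose_sample",
    "run_pipeline",
]

CELL_SUM_TARGET = 1e6


@dataclass
class SingleCellDataset:
    """Cells x genes expression values with per-cell sample and group labels.

    Parameters
    ----------
    matrix
        Nonnegative cells x genes array (dense or scipy sparse; sparse input
        is densified).
    gene_ids, cell_ids
        Unique identifiers for columns and rows.
    cell_sample
        Sample label per cell (length = number of cells).
    sample_group
        Mapping sample label -> group label; every sample referenced by a
        cell must appear here, with exactly one group.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_sample: np.ndarray
    sample_group: dict[str, str]

    def __post_init__(self) -> None:
        if sp.issparse(self.matrix):
            self.matrix = np.asarray(self.matrix.todense(), dtype=float)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InvalidParameterError("matrix must be 2-D (cells x genes)")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_sample = np.asarray(self.cell_sample, dtype=object)
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise InvalidParameterError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise InvalidParameterError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise InvalidParameterError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise InvalidParameterError("duplicate gene ids")
        if self.cell_sample.shape[0] != n_cells:
            raise InvalidParameterError("cell_sample length does not match cell count")
        missing = sorted({str(s) for s in self.cell_sample} - set(self.sample_group))
        if missing:
            raise InvalidParameterError(
                f"samples without a group label: {', '.join(missing)}"
            )

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.cell_sample:
            seen.setdefault(str(s), None)
        return list(seen)

    def group_of(self, sample: str) -> str:
        return self.sample_group[sample]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene}") from None

    def cells_of_sample(self, sample: str) -> np.ndarray:
        return np.flatnonzero(self.cell_sample == sample)

    def to_anndata(self):
        """View as an :class:`anndata.AnnData` (obs carries sample and group)."""
        import anndata as ad

        obs = pd.DataFrame(
            {
                "sample_id": [str(s) for s in self.cell_sample],
                "group": [self.sample_group[str(s)] for s in self.cell_sample],
            },
            index=self.cell_ids,
        )
        return ad.AnnData(X=self.matrix.copy(), obs=obs, var=pd.DataFrame(index=self.gene_ids))

    @classmethod
    def from_anndata(cls, adata, sample_key: str = "sample_id", group_key: str = "group"):
        X = adata.X
        cell_sample = adata.obs[sample_key].astype(str).to_numpy()
        pairs = set(zip(cell_sample, adata.obs[group_key].astype(str)))
        sample_group: dict[str, str] = {}
        for s, g in pairs:
            if s in sample_group and sample_group[s] != g:
                raise InvalidParameterError(f"sample {s} maps to multiple groups")
            sample_group[s] = g
        return cls(
            matrix=X,
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            cell_sample=cell_sample,
            sample_group=sample_group,
        )


class DecompositionEstimate(NamedTuple):
    """Two-subset decomposition of one sample's cell values for one gene."""

    mu_plus_hat: float
    mu_minus_hat: float
    r_hat: float
    degenerate: bool = False


@dataclass
class TestResult:
    """Per-gene DE/DV test outputs.

    ``table`` is indexed by gene with columns ``mean_<g>``/``var_<g>`` for
    each group, the Welch t and variance-ratio F statistics and raw /
    BH-adjusted p-values, the DE/DV flags (adjusted p < alpha) and a
    degeneracy marker for zero-variance edge cases.
    """

    table: pd.DataFrame
    groups: tuple[str, str]
    alpha: float = 0.05

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["de"]])

    @property
    def dv_genes(self) -> list[str]:
        return list(self.table.index[self.table["dv"]])

    def top_de_gene(self) -> str:
        return str(self.table["t_pvalue"].idxmin())

    def top_dv_gene(self) -> str:
        return str(self.table["f_pvalue"].idxmin())


def normalize_cells(raw_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log(1 + count) per entry, then rescale each cell row to sum to 10^6.

    Returns the normalised matrix and a boolean mask of all-zero cells, which
    are left all-zero (no scale exists for them).
    """
    if sp.issparse(raw_counts):
        raw_counts = np.asarray(raw_counts.todense())
    raw = np.asarray(raw_counts, dtype=float)
    if (raw < 0).any():
        raise InvalidParameterError("raw counts must be nonnegative")
    logged = np.log1p(raw)
    row_sums = logged.sum(axis=1)
    zero_cells = row_sums == 0.0
    scale = np.where(zero_cells, 1.0, CELL_SUM_TARGET / np.where(zero_cells, 1.0, row_sums))
    return logged * scale[:, None], zero_cells


def pseudobulk(sc: SingleCellDataset, matrix: np.ndarray | None = None) -> pd.DataFrame:
    """Per-sample mean of single-cell values: a samples x genes table.

    ``matrix`` overrides the dataset's values (e.g. a normalised copy) while
    the cell-to-sample assignment comes from the dataset.
    """
    X = sc.matrix if matrix is None else np.asarray(matrix, dtype=float)
    if X.shape != sc.matrix.shape:
        raise InvalidParameterError("override matrix shape does not match dataset")
    rows = {}
    for sample in sc.samples:
        idx = sc.cells_of_sample(sample)
        if idx.size == 0:
            raise InvalidParameterError(f"sample {sample} has no cells")
        rows[sample] = X[idx].mean(axis=0)
    missing = sorted(set(sc.sample_group) - set(rows))
    if missing:
        raise InvalidParameterError(f"samples with no cells: {', '.join(missing)}")
    return pd.DataFrame.from_dict(rows, orient="index", columns=sc.gene_ids)


def filter_genes(bulk: pd.DataFrame, threshold: float = 20.0) -> list[str]:
    """Genes whose grand-mean bulk expression is strictly greater than ``threshold``."""
    grand_mean = bulk.mean(axis=0)
    return list(bulk.columns[grand_mean > threshold])


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Welch t statistic and two-sided p, with the zero-variance convention.

    If both groups have zero variance the test is degenerate: p = 1 for equal
    means, p = 0 for unequal means.
    """
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0, True
    stat, p = st.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p), False


def _variance_ratio_f(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided variance-ratio F-test: p = 2 * min(P(F<=f), P(F>=f)), capped at 1.

    Two-sided because differential variability is of interest in both
    directions.  Zero variance in both groups -> p = 1 (degenerate); zero
    variance in exactly one group -> p = 0 (degenerate).
    """
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return np.nan, 1.0, True
    if vb == 0.0 or va == 0.0:
        return np.inf if vb == 0.0 else 0.0, 0.0, True
    f = va / vb
    dist = st.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0)), False


def de_dv_test(
    bulk: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    group_order: tuple[str, str] | None = None,
) -> TestResult:
    """Welch t (DE) and two-sided F (DV) per gene, each BH-corrected.

    ``groups`` maps each sample (row of ``bulk``) to one of exactly two group
    labels; each group needs at least two samples or the tests are refused.
    BH correction is applied separately to the t p-value vector and the F
    p-value vector across the genes present in ``bulk`` (filter first, then
    test).  The F statistic is var(first group) / var(second group) in
    ``group_order`` (default: sorted labels).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = groups.loc[list(bulk.index)]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise InvalidParameterError(f"exactly two groups required, got {uniq}")
    g1, g2 = group_order if group_order is not None else (uniq[0], uniq[1])
    a_idx = labels[labels == g1].index
    b_idx = labels[labels == g2].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise InvalidParameterError(
            "testing refused: need >= 2 samples per group "
            f"(got {len(a_idx)} in {g1!r}, {len(b_idx)} in {g2!r})"
        )
    if bulk.shape[1] == 0:
        raise InvalidParameterError("no genes to test")

    records = []
    for gene in bulk.columns:
        a = bulk.loc[a_idx, gene].to_numpy(dtype=float)
        b = bulk.loc[b_idx, gene].to_numpy(dtype=float)
        t_stat, t_p, t_deg = _welch_t(a, b)
        f_stat, f_p, f_deg = _variance_ratio_f(a, b)
        records.append(
            {
                "gene": gene,
                f"mean_{g1}": a.mean(),
                f"mean_{g2}": b.mean(),
                f"var_{g1}": a.var(ddof=1),
                f"var_{g2}": b.var(ddof=1),
                "t_stat": t_stat,
                "t_pvalue": t_p,
                "f_stat": f_stat,
                "f_pvalue": f_p,
                "degenerate": t_deg or f_deg,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("gene")
    table["t_padj"] = multipletests(table["t_pvalue"], method="fdr_bh")[1]
    table["f_padj"] = multipletests(table["f_pvalue"], method="fdr_bh")[1]
    table["de"] = table["t_padj"] < alpha
    table["dv"] = table["f_padj"] < alpha
    return TestResult(table=table, groups=(g1, g2), alpha=alpha)


def decompose_sample(
    values: Sequence[float] | np.ndarray, seed: int | None = None
) -> DecompositionEstimate:
    """Exact 1-D 2-means decomposition of one sample's cell values for one gene.

    The cluster with the larger centroid is subset +; ``r_hat`` is its cell
    fraction and ``mu_plus_hat``/``mu_minus_hat`` are the cluster means.  In
    one dimension the optimal 2-means clusters are intervals, so the global
    optimum is found by scanning the n-1 threshold splits of the sorted
    values (ties broken toward the larger subset-+ cluster).  The result is
    deterministic; ``seed`` is accepted for interface uniformity and unused.

    With fewer than two distinct values no second cluster exists: the
    estimate degenerates to r_hat = 0 with both means at the common value,
    matching the reading that the zero/low-expression population is
    subset -.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidParameterError("values must be a nonempty 1-D vector")
    if np.unique(x).size < 2:
        v = float(x[0])
        return DecompositionEstimate(v, v, 0.0, degenerate=True)

    xs = np.sort(x)
    n = xs.size
    csum = np.cumsum(xs)
    csum2 = np.cumsum(xs * xs)
    # split t: left cluster xs[:t], right cluster xs[t:], t = 1..n-1
    t = np.arange(1, n)
    left_sum, left_sq = csum[t - 1], csum2[t - 1]
    right_sum, right_sq = csum[-1] - left_sum, csum2[-1] - left_sq
    wss = (left_sq - left_sum**2 / t) + (right_sq - right_sum**2 / (n - t))
    # ties (e.g. splits between identical values) resolve to the smallest
    # split index, i.e. the largest subset-+ cluster
    best = int(np.argmin(wss))
    t_best = best + 1
    mu_minus = float(left_sum[best] / t_best)
    mu_plus = float(right_sum[best] / (n - t_best))
    r_hat = float((n - t_best) / n)
    return DecompositionEstimate(mu_plus, mu_minus, r_hat, degenerate=False)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    ``normalize`` applies the log1p + per-cell-sum-to-10^6 step; disable it
    for data already on a continuous expression scale (e.g. simulated
    mixtures, which may contain negative values).  ``decompose_genes`` forces
    decomposition of specific genes instead of the top DE/DV pair.
    """

    alpha: float = 0.05
    min_mean: float = 20.0
    normalize: bool = True
    decompose_genes: tuple[str, ...] | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    test: TestResult | None
    decomposition: pd.DataFrame
    log: dict


def _decompose_genes(
    sc: SingleCellDataset, X: np.ndarray, genes: Iterable[str], seed: int
) -> pd.DataFrame:
    rows = []
    for gene in genes:
        j = sc.gene_index(gene)
        for sample in sc.samples:
            est = decompose_sample(X[sc.cells_of_sample(sample), j], seed=seed)
            rows.append(
                {
                    "gene": gene,
                    "sample_id": sample,
                    "group": sc.group_of(sample),
                    "mu_plus_hat": est.mu_plus_hat,
                    "mu_minus_hat": est.mu_minus_hat,
                    "r_hat": est.r_hat,
                    "degenerate": est.degenerate,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(sc: SingleCellDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """normalize -> pseudobulk -> filter -> DE/DV test -> decompose.

    Decomposes the top DE and top DV genes (smallest raw p-values) unless
    ``config.decompose_genes`` is given, and records per-group means of the
    estimated (mu_plus_hat, mu_minus_hat, r_hat) in the run log.
    """
    if config is None:
        config = PipelineConfig()
    log: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "min_mean": config.min_mean,
        "normalize": config.normalize,
        "n_cells": sc.n_cells,
        "n_genes_input": sc.n_genes,
    }
    if config.normalize:
        X, zero_cells = normalize_cells(sc.matrix)
        log["n_all_zero_cells"] = int(zero_cells.sum())
    else:
        X = sc.matrix
        log["n_all_zero_cells"] = None

    bulk = pseudobulk(sc, matrix=X)
    kept = filter_genes(bulk, config.min_mean)
    log["n_genes_filtered"] = len(kept)
    if not kept:
        warnings.warn("no genes pass the expression filter; empty result", stacklevel=2)
        return PipelineResult(test=None, decomposition=pd.DataFrame(), log=log)

    groups = pd.Series(sc.sample_group)
    result = de_dv_test(bulk[kept], groups, alpha=config.alpha)
    log["n_de"] = int(result.table["de"].sum())
    log["n_dv"] = int(result.table["dv"].sum())

    if config.decompose_genes is not None:
        targets = list(dict.fromkeys(config.decompose_genes))
    else:
        targets = list(dict.fromkeys([result.top_de_gene(), result.top_dv_gene()]))
    log["decomposed_genes"] = targets
    decomposition = _decompose_genes(sc, X, targets, config.seed)
    summary = (
        decomposition.groupby(["gene", "group"])[["mu_plus_hat", "mu_minus_hat", "r_hat"]]
        .mean()
        .reset_index()
        .to_dict(orient="records")
    )
    log["decomposition_group_means"] = summary
    return PipelineResult(test=result, decomposition=decomposition, log=log)
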