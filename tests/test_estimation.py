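"""Normalisation, pseudobulk, DE/DV testing and the 2-means decomposition."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scbulk import (
    GroupParams,
    InvalidParameterError,
    PipelineConfig,
    ShiftParams,
    SingleCellDataset,
    SimulationConfig,
    DonorParams,
    de_dv_test,
    decompose_sample,
    filter_genes,
    GeneArchetype,
    generate_dataset,
    normalize_cells,
    pseudobulk,
    run_pipeline,
    simulate_cells,
)
from scbulk.estimation import _variance_ratio_f


# ---------------------------------------------------------------- normalisation


def test_normalize_cells_examples():
    m, zero = normalize_cells(np.array([[0.0, 7.0, 0.0]]))
    assert m[0].tolist() == [0.0, 1e6, 0.0]  # single nonzero gene carries everything
    m, _ = normalize_cells(np.array([[1.0, 1.0]]))
    assert m[0] == pytest.approx([5e5, 5e5])
    # log1p maps (e-1, e^2-1) to (1, 2), so the row splits 1:2
    m, _ = normalize_cells(np.array([[math.e - 1.0, math.e**2 - 1.0]]))
    assert m[0] == pytest.approx([1e6 / 3, 2e6 / 3])


def test_normalize_cells_zero_rows_and_errors():
    m, zero = normalize_cells(np.array([[0.0, 0.0], [1.0, 0.0]]))
    assert zero.tolist() == [True, False]
    assert m[0].tolist() == [0.0, 0.0]
    with pytest.raises(InvalidParameterError):
        normalize_cells(np.array([[-1.0, 2.0]]))


# ------------------------------------------------------------------ pseudobulk


def _toy_dataset(matrix, cell_sample, sample_group):
    n_cells, n_genes = np.asarray(matrix).shape
    return SingleCellDataset(
        matrix=np.asarray(matrix, dtype=float),
        gene_ids=[f"g{j}" for j in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        cell_sample=np.asarray(cell_sample, dtype=object),
        sample_group=sample_group,
    )


def test_pseudobulk_is_per_sample_mean():
    sc = _toy_dataset(
        [[0.0], [0.0], [10.0], [10.0], [10.0], [7.0]],
        ["s1"] * 5 + ["s2"],
        {"s1": "C", "s2": "D"},
    )
    bulk = pseudobulk(sc)
    assert bulk.loc["s1", "g0"] == pytest.approx(6.0)
    assert bulk.loc["s2", "g0"] == pytest.approx(7.0)  # one cell: pseudobulk equals the cell


def test_pseudobulk_rejects_empty_sample():
    sc = _toy_dataset([[1.0]], ["s1"], {"s1": "C", "s2": "C"})
    with pytest.raises(InvalidParameterError, match="s2"):
        pseudobulk(sc)


def test_filter_genes_strict_threshold():
    bulk = pd.DataFrame({"a": [5.0, 5.0], "b": [20.0, 20.0], "c": [25.0, 25.0]})
    assert filter_genes(bulk, 20.0) == ["c"]  # grand mean exactly 20 is dropped
    assert filter_genes(pd.DataFrame({"z": [0.0, 0.0]})) == []


# ---------------------------------------------------------------- DE/DV tests


def _bulk_frame(a: np.ndarray, b: np.ndarray, gene="g") -> tuple[pd.DataFrame, dict]:
    samples = [f"C{i}" for i in range(len(a))] + [f"D{i}" for i in range(len(b))]
    bulk = pd.DataFrame({gene: np.concatenate([a, b])}, index=samples)
    groups = {s: s[0] for s in samples}
    return bulk, groups


def test_f_test_matches_r_var_test():
    # frozen from R: var.test(c(1,2,3,4), c(2,4,6,8)) and
    # var.test(c(0.5,1.9,3.2,4.4,5.1), c(2.2,2.4,2.6,2.9))
    f, p, deg = _variance_ratio_f(np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8]))
    assert not deg
    assert f == pytest.approx(0.25)
    assert p == pytest.approx(0.284756979865, rel=1e-9)
    f, p, _ = _variance_ratio_f(
        np.array([0.5, 1.9, 3.2, 4.4, 5.1]), np.array([2.2, 2.4, 2.6, 2.9])
    )
    assert f == pytest.approx(38.8822429907, rel=1e-9)
    assert p == pytest.approx(0.0128685484824, rel=1e-9)


def test_de_dv_test_identical_groups_are_degenerate_nulls():
    bulk, groups = _bulk_frame(np.array([5.0, 5.0, 5.0]), np.array([5.0, 5.0]))
    res = de_dv_test(bulk, groups)
    row = res.table.iloc[0]
    assert row["t_pvalue"] == 1.0 and row["f_pvalue"] == 1.0
    assert bool(row["degenerate"])
    assert not row["de"] and not row["dv"]


def test_de_dv_test_zero_variance_unequal_means():
    bulk, groups = _bulk_frame(np.array([5.0, 5.0]), np.array([9.0, 9.0]))
    res = de_dv_test(bulk, groups)
    row = res.table.iloc[0]
    assert row["t_pvalue"] == 0.0 and bool(row["degenerate"])


def test_de_dv_test_flags_and_bh():
    rng = np.random.default_rng(4)
    genes = {}
    # one strongly shifted gene among nulls
    genes["shifted"] = (rng.normal(0, 1, 20), rng.normal(3, 1, 20))
    for i in range(9):
        genes[f"null{i}"] = (rng.normal(0, 1, 20), rng.normal(0, 1, 20))
    samples = [f"C{i}" for i in range(20)] + [f"D{i}" for i in range(20)]
    bulk = pd.DataFrame(
        {g: np.concatenate(v) for g, v in genes.items()}, index=samples
    )
    res = de_dv_test(bulk, {s: s[0] for s in samples})
    assert res.top_de_gene() == "shifted"
    assert res.table.loc["shifted", "de"]
    # BH invariants: adjusted >= raw, monotone in the raw p-values
    for col in ("t", "f"):
        raw = res.table[f"{col}_pvalue"]
        adj = res.table[f"{col}_padj"]
        assert (adj >= raw - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(raw.to_numpy())
        assert (np.diff(adj.to_numpy()[order]) >= -1e-12).all()


def test_bh_worked_example_convention():
    # the step-up rule we rely on: (0.01, 0.02, 0.03) -> (0.03, 0.03, 0.03)
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
    assert adj == pytest.approx([0.03, 0.03, 0.03])


def test_de_dv_test_refuses_underpowered_designs():
    bulk, groups = _bulk_frame(np.array([1.0]), np.array([2.0, 3.0]))
    with pytest.raises(InvalidParameterError, match="testing refused"):
        de_dv_test(bulk, groups)
    bulk3 = pd.DataFrame({"g": [1.0, 2, 3, 4]}, index=["a", "b", "c", "d"])
    with pytest.raises(InvalidParameterError, match="two groups"):
        de_dv_test(bulk3, {"a": "C", "b": "D", "c": "E", "d": "C"})


# -------------------------------------------------------------- decomposition


def _exhaustive_best_wss(values: np.ndarray) -> float:
    """Independent oracle: minimum within-cluster sum of squares over ALL
    2-partitions (not just threshold splits)."""
    best = math.inf
    n = len(values)
    for mask in itertools.product([0, 1], repeat=n):
        mask = np.array(mask, dtype=bool)
        if mask.all() or (~mask).all():
            continue
        a, b = values[mask], values[~mask]
        wss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        best = min(best, wss)
    return best


def _wss_of_estimate(values: np.ndarray, est) -> float:
    centers = np.array([est.mu_minus_hat, est.mu_plus_hat])
    assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    return float(sum(((values[assign == c] - centers[c]) ** 2).sum() for c in (0, 1)))


def test_decompose_worked_case_and_degenerate():
    est = decompose_sample([0.0, 0.0, 0.0, 10.0, 10.0])
    assert (est.mu_plus_hat, est.mu_minus_hat, est.r_hat) == (10.0, 0.0, 0.4)
    assert not est.degenerate
    deg = decompose_sample([4.0, 4.0, 4.0])
    assert (deg.mu_plus_hat, deg.mu_minus_hat, deg.r_hat) == (4.0, 4.0, 0.0)
    assert deg.degenerate
    with pytest.raises(InvalidParameterError):
        decompose_sample([])


def test_decompose_matches_exhaustive_partition_oracle():
    rng = np.random.default_rng(123)
    vectors = []
    for n in range(2, 13):
        vectors.append(rng.normal(0, 1, n))
        vectors.append(np.concatenate([np.zeros(n // 2), rng.normal(8, 1, n - n // 2)]))
        vectors.append(rng.integers(0, 4, n).astype(float))
    for v in vectors:
        if np.unique(v).size < 2:
            continue
        est = decompose_sample(v)
        assert est.mu_plus_hat >= est.mu_minus_hat
        assert 0.0 <= est.r_hat <= 1.0
        assert _wss_of_estimate(v, est) == pytest.approx(_exhaustive_best_wss(v), abs=1e-9)


def test_decompose_matches_sklearn_kmeans():
    pytest.importorskip("sklearn")
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(7)
    for _ in range(10):
        v = np.concatenate([rng.normal(0, 1, 40), rng.normal(5, 1, 25)])
        est = decompose_sample(v)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(v[:, None])
        assert _wss_of_estimate(v, est) <= km.inertia_ + 1e-8


def test_recovery_improves_with_component_separation():
    cfg = SimulationConfig(n_samples=2, n_cells=5000, v_y_plus=1.0, v_y_minus=1.0)
    true_r = 0.3
    biases = []
    for gap in (1.0, 3.0, 10.0):
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(5):
            cells = simulate_cells(DonorParams(gap, 0.0, true_r), cfg, rng)
            errs.append(abs(decompose_sample(cells).r_hat - true_r))
        biases.append(np.mean(errs))
    assert biases[0] > biases[1] > biases[2]
    assert biases[2] < 0.02


# ------------------------------------------------------------------- pipeline


def test_pipeline_engineered_de_gene_is_top_hit():
    gp = GroupParams(30.0, 22.0, 0.5, 0.3, 0.1, 0.01)
    null = ShiftParams(0.0, 0.0, 1.0)
    panel = [GeneArchetype(f"null_{i}", gp, null, label="null") for i in range(5)]
    panel.append(GeneArchetype("hot", gp, ShiftParams(0.5, 0.5, 1.0), label="de"))
    sc, _ = generate_dataset(panel, samples_per_group=20, cells_per_sample=100, seed=3)
    res = run_pipeline(sc, PipelineConfig(normalize=False))
    assert res.test.top_de_gene() == "hot"
    assert "hot" in res.log["decomposed_genes"]
    assert set(res.decomposition["gene"]) == set(res.log["decomposed_genes"])


def test_pipeline_refuses_single_sample_per_group():
    sc = _toy_dataset(
        [[30.0], [31.0], [29.0], [32.0]],
        ["s1", "s1", "s2", "s2"],
        {"s1": "C", "s2": "D"},
    )
    with pytest.raises(InvalidParameterError, match="testing refused"):
        run_pipeline(sc, PipelineConfig(normalize=False))


def test_pipeline_empty_filter_warns():
    gp = GroupParams(3.0, 1.0, 0.5)  # expression far below the filter floor
    panel = [GeneArchetype("low", gp, ShiftParams(0.0, 0.0, 1.0), label="null")]
    sc, _ = generate_dataset(panel, samples_per_group=3, cells_per_sample=10, seed=0)
    with pytest.warns(UserWarning, match="filter"):
        res = run_pipeline(sc, PipelineConfig(normalize=False, min_mean=20.0))
    assert res.test is None and res.decomposition.empty


def test_pipeline_normalized_path_runs():
    gp = GroupParams(30.0, 22.0, 0.5, 0.3, 0.1, 0.01)
    panel = [
        GeneArchetype(f"g{i}", gp, ShiftParams(0.0, 0.0, 1.0), label="null") for i in range(3)
    ]
    sc, _ = generate_dataset(panel, samples_per_group=4, cells_per_sample=50, seed=1, mode="counts")
    res = run_pipeline(sc, PipelineConfig(normalize=True, min_mean=20.0))
    assert res.test is not None
    # 3 genes share each cell's 1e6 budget, so every gene passes min_mean=20
    assert res.log["n_genes_filtered"] == 3
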