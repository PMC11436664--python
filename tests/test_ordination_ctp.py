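"""Grouped ordination, retention rule, clustering and target-point selection."""

import numpy as np
import pandas as pd
import pytest

from reefmetrics import fixture_table1, hcpc, ksp_retention, mfa, select_ctp
from reefmetrics.complexity_table import METRIC_COLUMNS, MetricTable
from reefmetrics.errors import DegenerateInputError, ParameterError
from reefmetrics.ordination_ctp import describe_clusters, dim1_ci_correlation


@pytest.fixture(scope="module")
def fixture_mfa(table1):
    return mfa(table1)


def _random_table(rng, n=12, prefix="M"):
    data = {c: rng.random(n) for c in METRIC_COLUMNS}
    df = pd.DataFrame(data)
    df.insert(0, "model_id", [f"{prefix}{i:02d}" for i in range(n)])
    return MetricTable(df)


# ---------------------------------------------------------------------------
# MFA
# ---------------------------------------------------------------------------


def test_mfa_inertia_structure_on_reference_table(fixture_mfa):
    pct = fixture_mfa.inertia_pct
    assert pct.sum() == pytest.approx(100.0, abs=1e-6)
    # frozen from this decomposition of the printed (3-decimal) table
    assert pct[0] == pytest.approx(43.33, abs=0.02)
    assert pct[1] == pytest.approx(25.64, abs=0.02)
    for dim in fixture_mfa.contributions.columns:
        assert fixture_mfa.contributions[dim].sum() == pytest.approx(100.0, abs=1e-6)


def test_mfa_scores_are_orthogonal_across_dimensions(fixture_mfa):
    s = fixture_mfa.scores.to_numpy()
    s = s - s.mean(axis=0)
    gram = s.T @ s
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-8


def test_supplementary_variable_never_perturbs_the_decomposition(table1):
    with_supp = mfa(table1, supplementary="CI")
    without = mfa(table1, supplementary=None)
    assert np.allclose(with_supp.eigenvalues, without.eigenvalues, atol=0, rtol=0)
    # scores agree up to the per-dimension sign convention
    a = with_supp.scores.to_numpy()
    b = without.scores.to_numpy()
    assert np.allclose(np.abs(a), np.abs(b), atol=1e-12)


def test_supplementary_ci_correlates_with_first_dimension(fixture_mfa, table1):
    r, p = dim1_ci_correlation(fixture_mfa, table1)
    assert round(r, 2) == 0.92
    assert p < 1e-6
    assert fixture_mfa.supplementary_cor["Dim.1"] == pytest.approx(r)
    # sign convention: complexity increases along Dim.1
    assert r > 0


def test_dominant_contributions_split_between_dimensions(fixture_mfa):
    c = fixture_mfa.contributions
    # P_t, D_t, R, H_t build Dim.1; J and C dominate Dim.2
    assert c.loc[["P_t", "D_t", "R", "H_t"], "Dim.1"].min() > 20.0
    assert c.loc["J", "Dim.2"] > 30.0
    assert c.loc["C", "Dim.2"] > 20.0


def test_perfectly_correlated_single_variable_groups_concentrate_inertia():
    rng = np.random.default_rng(3)
    x = rng.random(15)
    df = pd.DataFrame({"model_id": [f"S{i}" for i in range(15)]})
    for c in METRIC_COLUMNS:
        df[c] = x  # every variable identical
    table = MetricTable(df)
    res = mfa(table, groups={"a": ["C"], "b": ["R"]}, supplementary=None)
    assert res.inertia_pct[0] == pytest.approx(100.0, abs=1e-9)


def test_zero_variance_variable_is_reported_by_name():
    rng = np.random.default_rng(4)
    table = _random_table(rng)
    table.df["D_t"] = 0.5
    with pytest.raises(DegenerateInputError, match="D_t"):
        mfa(table)


def test_row_permutation_only_permutes_the_outputs(table1, fixture_mfa):
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(table1))
    shuffled = MetricTable(table1.df.iloc[perm].reset_index(drop=True))
    res = mfa(shuffled)
    assert np.allclose(res.eigenvalues, fixture_mfa.eigenvalues, atol=1e-10)
    for model in table1.model_ids:
        assert res.scores.loc[model, "Dim.1"] == pytest.approx(
            fixture_mfa.scores.loc[model, "Dim.1"], abs=1e-9
        )
    # clustering and selection are equally order-free
    a = hcpc(fixture_mfa, k=3).assignments
    b = hcpc(res, k=3).assignments
    assert all(a[m] == b[m] for m in table1.model_ids)
    sel_a = select_ctp(table1, scores=fixture_mfa.scores)
    sel_b = select_ctp(shuffled, scores=res.scores)
    assert set(sel_a.selected) == set(sel_b.selected)
    assert sel_a.threshold == pytest.approx(sel_b.threshold, abs=1e-12)


def test_planted_two_factor_model_is_recovered():
    from scipy.linalg import subspace_angles

    loadings = np.array(
        [
            [0.9, 0.1], [0.8, -0.2], [0.7, 0.3],  # group 1
            [0.1, 0.9], [-0.2, 0.8], [0.3, 0.7],  # group 2
        ]
    )
    hits = 0
    n = 50
    for seed in range(100):
        rng = np.random.default_rng(seed)
        factors = rng.standard_normal((n, 2))
        X = factors @ loadings.T + 0.1 * rng.standard_normal((n, 6))
        df = pd.DataFrame(X, columns=METRIC_COLUMNS)
        df.insert(0, "model_id", [f"R{i:02d}" for i in range(n)])
        res = mfa(MetricTable(df), supplementary=None)
        angle = subspace_angles(
            factors - factors.mean(axis=0), res.scores.iloc[:, :2].to_numpy()
        ).max()
        hits += np.degrees(angle) < 10.0
    assert hits >= 95


# ---------------------------------------------------------------------------
# retention rule
# ---------------------------------------------------------------------------


def test_retention_threshold_values():
    thr, _ = ksp_retention(20, 6)
    assert round(thr, 2) == 2.03
    thr, _ = ksp_retention(5, 2)
    assert thr == pytest.approx(2.0)
    thr, _ = ksp_retention(10**9, 6)
    assert thr == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ParameterError):
        ksp_retention(1, 6)


def test_retention_keeps_at_least_two_dimensions(fixture_mfa):
    # all eigenvalues sit below the threshold here, so the rule alone keeps
    # none; the planar ordination still needs two dimensions
    assert fixture_mfa.retained_by_rule == 0
    assert fixture_mfa.n_retained == 2


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_reference_clustering_recovers_design_purposes(table1, fixture_mfa):
    clusters = hcpc(fixture_mfa, k=3)
    a = clusters.assignments
    biom = {a[m] for m in table1.model_ids if m.startswith("BIOM")}
    assert len(biom) == 1
    prod = {a[m] for m in table1.model_ids if m.startswith("PROD")}
    assert len(prod) == 1
    assert a["PROT4"] in prod
    others = {a[m] for m in ("PROT1", "PROT2", "PROT3", "PROT5", "PROT6")}
    assert len(others) == 1 and others != prod != biom


def test_well_separated_groups_form_their_own_clusters():
    rng = np.random.default_rng(9)
    centers = np.array([0.0, 10.0, 20.0])
    rows = []
    for g, c in enumerate(centers):
        for i in range(3):
            vals = c + 0.01 * rng.standard_normal(6)
            rows.append([f"G{g}{i}", *vals])
    table = MetricTable(pd.DataFrame(rows, columns=["model_id", *METRIC_COLUMNS]))
    res = mfa(table, supplementary=None)
    a = hcpc(res, k=3).assignments
    for g in range(3):
        assert len({a[f"G{g}{i}"] for i in range(3)}) == 1


def test_cluster_description_matches_hand_computed_v_tests():
    # six models, one variable shifted for the second half
    base = {c: [0.0] * 6 for c in METRIC_COLUMNS}
    base["C"] = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
    base["P_t"] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    df = pd.DataFrame({"model_id": list("ABCDEF"), **base})
    table = MetricTable(df)
    assignments = pd.Series([1, 1, 1, 2, 2, 2], index=list("ABCDEF"), name="cluster")

    class Stub:
        pass

    stub = Stub()
    stub.assignments = assignments
    desc = describe_clusters(table, stub, variables=["C", "P_t"])
    x = np.array(base["C"])
    expect = (1.0 - 0.5) / np.sqrt((x.var() / 3) * (6 - 3) / (6 - 1))
    got = desc.query("cluster == 2 and variable == 'C'")["v_test"].item()
    assert got == pytest.approx(expect, abs=1e-9)
    assert desc.query("cluster == 2 and variable == 'C'")["characterizing"].item()


def test_biomimicry_cluster_is_characterized_by_informational_metrics(table1, fixture_mfa):
    clusters = hcpc(fixture_mfa, k=3)
    desc = describe_clusters(table1, clusters)
    biom_cluster = clusters.assignments["BIOM6"]
    sub = desc.query("cluster == @biom_cluster").set_index("variable")
    for var in ("R", "H_t", "J", "CI"):
        assert sub.loc[var, "v_test"] >= 1.96


# ---------------------------------------------------------------------------
# target points
# ---------------------------------------------------------------------------


def test_ctp_selection_from_printed_distances(table1):
    res = select_ctp(table1, use_printed_distances=True)
    assert set(res.selected) == {"BIOM5", "BIOM6", "BIOM7", "PROD3", "PROD4"}
    assert res.threshold == pytest.approx(1.112, abs=0.0005)
    assert res.threshold_sd == pytest.approx(0.689, abs=0.001)
    assert res.ctp_mean["C"] == pytest.approx(0.550, abs=0.0005)
    assert res.ctp_sd["C"] == pytest.approx(0.232, abs=0.0005)


def test_distance_is_euclidean_in_the_plane(table1):
    scores = pd.DataFrame(
        {"Dim.1": [3.0] + [0.1] * 19, "Dim.2": [4.0] + [0.0] * 19},
        index=table1.model_ids,
    )
    res = select_ctp(table1, scores=scores)
    assert res.distances.iloc[0] == pytest.approx(5.0)


def test_empty_selection_is_an_error(table1):
    scores = pd.DataFrame(
        {"Dim.1": [-1.0] * 20, "Dim.2": [0.0] * 20}, index=table1.model_ids
    )
    with pytest.raises(DegenerateInputError):
        select_ctp(table1, scores=scores)
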