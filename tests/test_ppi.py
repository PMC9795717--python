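"""Fold changes, DEG calling, profile clustering and interaction screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from angiocross.phantom import (
    ExpressionPhantomSpec,
    make_expression_phantom,
    make_ppi_candidates,
)
from angiocross.ppi import (
    FoldChangeMatrix,
    call_degs,
    cluster_degs,
    filter_ppis,
    fold_changes,
    network_from_edges,
)


def _toy_experiment():
    genes = ["g1", "g2", "g3"]
    expr = pd.DataFrame(
        {
            "EC_mono_12h": [10.0, 8.0, 100.0],
            "EC_co_12h": [10.0, 32.0, 25.0],
            "EC_mono_24h": [10.0, 8.0, 100.0],
            "EC_co_24h": [40.0, 8.0, 100.0],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    sheet = pd.DataFrame(
        {
            "sample": expr.columns,
            "cell_type": "EC",
            "condition": ["mono", "co", "mono", "co"],
            "time_h": [12, 12, 24, 24],
        }
    )
    return expr, sheet


# ---------------------------------------------------------------------------
# fold changes


def test_fold_change_identity_when_co_equals_mono():
    expr, sheet = _toy_experiment()
    expr["EC_co_12h"] = expr["EC_mono_12h"]
    expr["EC_co_24h"] = expr["EC_mono_24h"]
    fc = fold_changes(expr, sheet, pseudocount=0.0)["EC"]
    assert np.allclose(fc.log2fc.to_numpy(), 0.0)


def test_fold_change_quadrupling_gives_two():
    expr, sheet = _toy_experiment()
    expr["EC_co_12h"] = 4.0 * expr["EC_mono_12h"]
    expr["EC_co_24h"] = 4.0 * expr["EC_mono_24h"]
    fc = fold_changes(expr, sheet, pseudocount=0.0)["EC"]
    assert np.allclose(fc.log2fc.to_numpy(), 2.0)


def test_fold_change_matches_hand_computed_table():
    expr, sheet = _toy_experiment()
    fc = fold_changes(expr, sheet, pseudocount=0.0)["EC"]
    hand = np.array(
        [
            [0.0, 2.0],  # g1: 10→10 then 10→40
            [2.0, 0.0],  # g2: 8→32 then 8→8
            [-2.0, 0.0],  # g3: 100→25 then unchanged
        ]
    )
    assert np.allclose(fc.log2fc.to_numpy(), hand)
    # z-profiles standardized per gene
    z = fc.zprofile.to_numpy()
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=1), 1.0, atol=1e-12)


def test_missing_control_raises_with_context():
    expr, sheet = _toy_experiment()
    sheet = sheet[sheet["sample"] != "EC_mono_24h"]
    with pytest.raises(ValueError, match="24"):
        fold_changes(expr[sheet["sample"]], sheet)


# ---------------------------------------------------------------------------
# DEG calling


def test_deg_threshold_is_strict():
    fc = FoldChangeMatrix(
        cell_type="EC",
        log2fc=pd.DataFrame(
            {"12h": [1.0, 1.0001, -1.0, -1.01], "24h": [0.0, 0.0, 0.0, 0.0]},
            index=["exact_up", "up", "exact_down", "down"],
        ),
        zprofile=None,
    )
    degs = call_degs(fc)
    assert "exact_up" not in degs.index
    assert "exact_down" not in degs.index
    assert degs.loc["up", "direction"] == "up"
    assert degs.loc["down", "direction"] == "down"


def test_deg_any_timepoint_rule():
    fc = FoldChangeMatrix(
        cell_type="EC",
        log2fc=pd.DataFrame({"12h": [0.2], "24h": [1.7]}, index=["g"]),
        zprofile=None,
    )
    degs = call_degs(fc)
    assert degs.loc["g", "direction"] == "up"


def test_planted_matrix_exact_deg_counts():
    spec = ExpressionPhantomSpec(
        n_background=200,
        up_clusters={"early": 25, "late": 25},
        down_clusters={"early": 30},
        seed=3,
    )
    expr, sheet, _ = make_expression_phantom(spec, "EC")
    degs = call_degs(fold_changes(expr, sheet)["EC"])
    assert (degs.direction == "up").sum() == 50
    assert (degs.direction == "down").sum() == 30


def test_up_down_sets_disjoint():
    spec = ExpressionPhantomSpec(seed=5)
    expr, sheet, _ = make_expression_phantom(spec, "MSC")
    degs = call_degs(fold_changes(expr, sheet)["MSC"])
    up = set(degs[degs.direction == "up"].index)
    down = set(degs[degs.direction == "down"].index)
    assert not (up & down)


# ---------------------------------------------------------------------------
# clustering


def test_identical_profiles_single_cluster():
    profiles = pd.DataFrame(
        np.tile([1.0, -1.0], (6, 1)), index=[f"g{i}" for i in range(6)]
    )
    cs = cluster_degs(profiles, "EC", "up")
    assert cs.k == 1
    assert cs.assignments.nunique() == 1


def test_orthogonal_groups_recovered_exactly():
    """Two planted temporal patterns: k = 2 and ARI = 1."""
    spec = ExpressionPhantomSpec(
        n_background=100,
        up_clusters={"early": 20, "late": 20},
        down_clusters={},
        timepoints=(6, 12, 24, 48),
        seed=7,
    )
    expr, sheet, truth = make_expression_phantom(spec, "EC")
    fc = fold_changes(expr, sheet)["EC"]
    degs = call_degs(fc)
    up = degs[degs.direction == "up"].index
    cs = cluster_degs(fc.zprofile.loc[up], "EC", "up")
    ari = adjusted_rand_score(
        [truth.cluster[g] for g in up], list(cs.assignments)
    )
    assert cs.k == 2
    assert ari == 1.0
    assert all(np.isnan(v) or v > 0.6 for v in cs.within_corr.values())


def test_cluster_labels_follow_direction_and_peak_order():
    profiles = pd.DataFrame(
        [[2.0, 0.1], [2.1, 0.2], [0.1, 2.0], [0.2, 2.2]],
        index=["a", "b", "c", "d"],
    )
    cs = cluster_degs(profiles, "MSC", "up")
    assert set(cs.assignments.unique()) == {"MSC-U1", "MSC-U2"}
    assert cs.assignments["a"] == "MSC-U1"  # early peak ranks first
    assert cs.assignments["c"] == "MSC-U2"


def _ward_oracle_merge_sizes(X):
    """Greedy Ward merges via the Lance–Williams recurrence on cosine distances.

    Returns the sorted cluster sizes after each merge, an order-free
    signature of the merge sequence.
    """
    from scipy.spatial.distance import cosine

    clusters = [[i] for i in range(len(X))]
    d = {
        (i, j): cosine(X[i], X[j])
        for i in range(len(X))
        for j in range(i + 1, len(X))
    }
    d = {k: v**2 for k, v in d.items()}  # work in squared distances
    sizes = {i: 1 for i in range(len(X))}
    active = set(range(len(X)))
    signature = []
    next_id = len(X)
    members = {i: [i] for i in range(len(X))}
    while len(active) > 1:
        (i, j), _ = min(
            ((k, v) for k, v in d.items() if k[0] in active and k[1] in active),
            key=lambda kv: kv[1],
        )
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        members[new] = members[i] + members[j]
        sizes[new] = ni + nj
        for k in active - {i, j}:
            nk = sizes[k]
            dik = d.get((min(i, k), max(i, k)))
            djk = d.get((min(j, k), max(j, k)))
            dij = d[(i, j)]
            d[(k, new)] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        active -= {i, j}
        active.add(new)
        signature.append(sorted(len(members[a]) for a in active))
    return signature


def test_merge_order_matches_ward_oracle_on_toy_set():
    X = np.array(
        [[1.0, 0.1, 0.0], [0.9, 0.2, 0.0], [0.0, 1.0, 0.8], [0.1, 0.9, 1.0]]
    )
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    Z = linkage(pdist(X, metric="cosine"), method="ward")
    # reconstruct scipy's cluster-size signature after each merge
    sizes = {i: 1 for i in range(len(X))}
    active = set(range(len(X)))
    sig = []
    for m, row in enumerate(Z):
        i, j = int(row[0]), int(row[1])
        new = len(X) + m
        sizes[new] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(new)
        sig.append(sorted(sizes[a] for a in active))
    assert sig == _ward_oracle_merge_sizes(X)


def test_unreachable_criterion_returns_singletons():
    rng = np.random.default_rng(0)
    profiles = pd.DataFrame(rng.normal(size=(6, 5)), index=[f"g{i}" for i in range(6)])
    with pytest.warns(UserWarning, match="singleton"):
        cs = cluster_degs(profiles, "EC", "up", min_within_corr=0.999999)
    assert cs.all_singletons
    assert cs.assignments.nunique() == len(profiles)


# ---------------------------------------------------------------------------
# PPI screening


def _toy_candidates():
    rows = [
        # gene_a, ct_a, gene_b, ct_b, db, exp, text, keep?
        ("E1", "EC", "M1", "MSC", 0.95, 0.95, 0.95, True),
        ("E2", "EC", "M2", "MSC", 0.95, 0.89, 0.95, False),  # low exp score
        ("E3", "EC", "M3", "MSC", 0.90, 0.95, 0.95, False),  # 0.90 not > 0.9
        ("E1", "EC", "E2", "EC", 0.99, 0.99, 0.99, False),  # same cell type
        ("S1", "EC", "M1", "MSC", 0.99, 0.99, 0.99, False),  # shared DEG
        ("E4", "EC", "M4", "MSC", 0.91, 0.92, 0.93, True),
        ("E5", "EC", "M9", "MSC", 0.95, 0.95, 0.95, False),  # M9 not an MSC DEG
        ("E1", "EC", "M2", "MSC", 0.999, 0.999, 0.999, True),
        ("E2", "EC", "M3", "MSC", 0.95, 0.95, 0.901, True),
        ("E3", "EC", "M1", "MSC", 0.95, 0.95, 0.2, False),  # low text score
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "cell_type_a",
            "gene_b",
            "cell_type_b",
            "db_score",
            "exp_score",
            "text_score",
            "keep",
        ],
    )
    ec = {"E1", "E2", "E3", "E4", "E5", "S1"}
    msc = {"M1", "M2", "M3", "M4", "S1"}
    return df, ec, msc


def test_filter_matches_bruteforce_on_toy_table():
    df, ec, msc = _toy_candidates()
    kept = filter_ppis(df.drop(columns="keep"), ec, msc)
    expected = df[df.keep].drop(columns="keep").reset_index(drop=True)
    pd.testing.assert_frame_equal(kept, expected)


def test_filter_strict_all_three_scores():
    df, ec, msc = _toy_candidates()
    row = df.iloc[[1]].drop(columns="keep")  # (0.95, 0.89, 0.95)
    assert len(filter_ppis(row, ec, msc)) == 0


def test_filter_monotone_in_threshold():
    df, ec, msc = _toy_candidates()
    cand = df.drop(columns="keep")
    n_low = len(filter_ppis(cand, ec, msc, threshold=0.85))
    n_mid = len(filter_ppis(cand, ec, msc, threshold=0.9))
    n_high = len(filter_ppis(cand, ec, msc, threshold=0.95))
    assert n_low >= n_mid >= n_high


@settings(derandomize=True, max_examples=20, deadline=None)
@given(threshold=st.floats(0.5, 0.99))
def test_filter_never_keeps_subthreshold_scores(threshold):
    df, ec, msc = _toy_candidates()
    kept = filter_ppis(df.drop(columns="keep"), ec, msc, threshold=threshold)
    for col in ("db_score", "exp_score", "text_score"):
        assert (kept[col] > threshold).all()


def test_malformed_score_reports_row():
    df, ec, msc = _toy_candidates()
    bad = df.drop(columns="keep").copy()
    bad.loc[4, "db_score"] = 1.7
    with pytest.raises(ValueError, match="4"):
        filter_ppis(bad, ec, msc)


def test_planted_candidate_table_recovered():
    ec = [f"E{i}" for i in range(12)] + ["SH"]
    msc = [f"M{i}" for i in range(12)] + ["SH"]
    cand, truth = make_ppi_candidates(
        ec, msc, n_true=4, n_decoy=15, shared_degs=["SH"], seed=2
    )
    kept = filter_ppis(cand, set(ec), set(msc))
    expected = truth[truth.keep].drop(columns="keep").reset_index(drop=True)
    pd.testing.assert_frame_equal(kept, expected)


def test_network_export_shapes():
    df, ec, msc = _toy_candidates()
    kept = filter_ppis(df.drop(columns="keep"), ec, msc)
    G = network_from_edges(kept)
    assert G.number_of_edges() == len(kept)
    assert all("cell_type" in G.nodes[n] for n in G.nodes)
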