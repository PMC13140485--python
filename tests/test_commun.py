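"""Distance-constrained ligand-receptor communication scoring."""

import numpy as np
import pandas as pd
import pytest

from norn import commun
from norn.commun import CommResult, Interaction


def _expr(rng, n=40, genes=("L1", "L2", "R1", "R2")):
    return pd.DataFrame(rng.gamma(2.0, 1.0, size=(n, len(genes))), columns=list(genes))


# ---------------------------------------------------------------------------
# sender definition


def test_sender_radius_is_inclusive_threshold():
    positions = np.array([[0.0, 0.0], [249.0, 0.0], [251.0, 0.0]])
    receivers = np.array([True, False, False])
    dominant = pd.Series(["x", "PT", "PT"])
    groups = commun.define_senders(dominant, positions, receivers, 250.0, min_group_size=1)
    assert list(groups) == ["PT"]
    assert groups["PT"].tolist() == [1]  # 249 µm in, 251 µm out


def test_receivers_never_senders():
    positions = np.array([[0.0, 0.0], [10.0, 0.0]])
    receivers = np.array([True, True])
    groups = commun.define_senders(pd.Series(["a", "b"]), positions, receivers, 250.0, 1)
    assert groups == {}


def test_no_receivers_rejected():
    with pytest.raises(ValueError, match="no receiver"):
        commun.define_senders(pd.Series(["a"]), np.zeros((1, 2)), np.array([False]), 250.0)


def test_toy_lattice_matches_manual_enumeration(rng):
    """Exhaustive oracle on a small grid: brute-force distances."""
    xx, yy = np.meshgrid(np.arange(7) * 50.0, np.arange(7) * 50.0)
    positions = np.column_stack([xx.ravel(), yy.ravel()])
    receivers = np.zeros(49, bool)
    receivers[[0, 24, 30]] = True
    dominant = pd.Series(rng.choice(["A", "B"], size=49))
    groups = commun.define_senders(dominant, positions, receivers, 120.0, min_group_size=1)
    # oracle
    d = np.hypot(
        positions[:, None, 0] - positions[None, receivers, 0],
        positions[:, None, 1] - positions[None, receivers, 1],
    ).min(axis=1)
    expected_members = set(np.flatnonzero((d <= 120.0) & ~receivers))
    got_members = set(np.concatenate(list(groups.values())))
    assert got_members == expected_members
    for ctype, members in groups.items():
        assert all(dominant.iloc[m] == ctype for m in members)


def test_small_groups_dropped():
    positions = np.array([[0.0, 0.0]] + [[10.0 * i, 0.0] for i in range(1, 6)])
    receivers = np.array([True] + [False] * 5)
    dominant = pd.Series(["x", "A", "A", "A", "B", "B"])
    groups = commun.define_senders(dominant, positions, receivers, 500.0, min_group_size=3)
    assert set(groups) == {"A"}


def test_infinite_radius_recovers_all_non_receivers(rng):
    positions = rng.uniform(0, 1000, size=(30, 2))
    receivers = np.zeros(30, bool)
    receivers[:3] = True
    dominant = pd.Series(["T"] * 30)
    groups = commun.define_senders(dominant, positions, receivers, np.inf, min_group_size=1)
    assert len(groups["T"]) == 27


# ---------------------------------------------------------------------------
# communication probability


def test_zero_ligand_gives_zero_probability(rng):
    expr = _expr(rng)
    expr["L1"] = 0.0
    inter = Interaction(("L1",), ("R1",))
    p = commun.communication_probability(expr, np.arange(5), np.arange(5, 10), inter)
    assert p == 0.0


def test_half_saturation_gives_quarter_probability():
    expr = pd.DataFrame({"L": [0.5, 0.5], "R": [0.5, 0.5]})
    inter = Interaction(("L",), ("R",))
    p = commun.communication_probability(
        expr, np.array([0]), np.array([1]), inter, K=0.5, n=1.0
    )
    assert p == pytest.approx(0.25)


def test_probability_monotone_in_ligand_and_receptor():
    inter = Interaction(("L",), ("R",))
    grid = np.linspace(0, 5, 11)
    probs = np.array([
        [
            commun.communication_probability(
                pd.DataFrame({"L": [l], "R": [r]}), np.array([0]), np.array([0]), inter
            )
            for r in grid
        ]
        for l in grid
    ])
    assert np.all(np.diff(probs, axis=0) >= -1e-12)
    assert np.all(np.diff(probs, axis=1) >= -1e-12)
    assert ((probs >= 0) & (probs <= 1)).all()


def test_missing_subunit_scores_zero(rng):
    expr = _expr(rng)
    inter = Interaction(("L1", "Lmissing"), ("R1",))
    assert commun.communication_probability(expr, np.arange(5), np.arange(5, 10), inter) == 0.0


def test_multisubunit_uses_geometric_mean():
    expr = pd.DataFrame({"L1": [4.0], "L2": [1.0], "R": [1e9]})
    inter = Interaction(("L1", "L2"), ("R",))
    p = commun.communication_probability(expr, np.array([0]), np.array([0]), inter, K=2.0)
    # geometric mean of (4, 1) is 2 = K -> Hill 0.5; receptor saturated
    assert p == pytest.approx(0.5, abs=1e-6)


def test_empty_sender_group_rejected(rng):
    with pytest.raises(ValueError, match="empty sender"):
        commun.communication_probability(
            _expr(rng), np.array([]), np.array([1]), Interaction(("L1",), ("R1",))
        )


def test_duplicating_the_sender_group_leaves_probability_unchanged(rng):
    expr = _expr(rng)
    inter = Interaction(("L1",), ("R1",))
    senders = np.arange(5)
    p1 = commun.communication_probability(expr, senders, np.arange(5, 10), inter)
    p2 = commun.communication_probability(
        expr, np.concatenate([senders, senders]), np.arange(5, 10), inter
    )
    assert p1 == pytest.approx(p2)


def test_mass_action_mode_bounded(rng):
    expr = _expr(rng)
    inter = Interaction(("L1",), ("R1",))
    p = commun.communication_probability(
        expr, np.arange(5), np.arange(5, 10), inter, mode="mass_action"
    )
    assert 0 <= p <= 1


# ---------------------------------------------------------------------------
# permutation test


def test_same_seed_gives_identical_p(rng):
    expr = _expr(rng)
    inter = Interaction(("L1",), ("R1", "R2"))
    out1 = commun.permutation_test(expr, np.arange(20), np.arange(20, 40), inter, B=300, seed=5)
    out2 = commun.permutation_test(expr, np.arange(20), np.arange(20, 40), inter, B=300, seed=5)
    assert out1 == out2


def test_strong_sender_effect_reaches_minimal_p(rng):
    expr = _expr(rng, n=40)
    expr["L1"] = 0.0
    expr.iloc[:20, expr.columns.get_loc("L1")] = 10.0  # ligand only in senders
    expr["R1"] = 1.0  # receptor uniform: the ligand asymmetry drives the test
    inter = Interaction(("L1",), ("R1",))
    _, p = commun.permutation_test(expr, np.arange(20), np.arange(20, 40), inter,
                                   B=400, seed=1, K=5.0)
    assert p <= 1 / (1 + 400) + 0.01


def test_degenerate_all_zero_expression_gives_p_one(rng):
    expr = pd.DataFrame(np.zeros((20, 2)), columns=["L1", "R1"])
    inter = Interaction(("L1",), ("R1",))
    _, p = commun.permutation_test(expr, np.arange(10), np.arange(10, 20), inter, B=200, seed=0)
    assert p == 1.0


def test_too_few_permutations_rejected(rng):
    with pytest.raises(ValueError, match="100"):
        commun.permutation_test(
            _expr(rng), np.arange(5), np.arange(5, 10), Interaction(("L1",), ("R1",)), B=50
        )


def test_null_pvalues_super_uniform(rng):
    """Label-independent expression: rejection calibrated, CDF below uniform."""
    inter = Interaction(("L1",), ("R1",))
    ps = []
    for rep in range(200):
        expr = _expr(rng, n=30, genes=("L1", "R1"))
        _, p = commun.permutation_test(expr, np.arange(20), np.arange(20, 30), inter, B=200, seed=rep)
        ps.append(p)
    ps = np.asarray(ps)
    rate = (ps < 0.05).mean()
    assert rate <= 0.09
    grid = np.linspace(0.01, 0.99, 50)
    emp = (ps[:, None] <= grid[None, :]).mean(axis=0)
    assert (emp - grid).max() <= 0.08


# ---------------------------------------------------------------------------
# condition comparison


def _result(rows, condition):
    return CommResult(table=pd.DataFrame(rows), condition=condition)


def test_condition_compare_flags_single_condition_significance():
    rows_a = [{"sender": "PT", "interaction": "L->R", "pathway": "p",
               "probability": 0.8, "p": 0.01, "n_senders": 10}]
    rows_b = [{"sender": "PT", "interaction": "L->R", "pathway": "p",
               "probability": 0.2, "p": 0.8, "n_senders": 10}]
    out = commun.condition_compare(_result(rows_a, "c.l."), _result(rows_b, "lig."), alpha=0.05)
    assert out["flag"].tolist() == ["A_only"]


def test_identical_results_never_single_condition():
    rows = [{"sender": "PT", "interaction": "L->R", "pathway": "p",
             "probability": 0.5, "p": 0.03, "n_senders": 5},
            {"sender": "PT", "interaction": "L2->R2", "pathway": "p",
             "probability": 0.5, "p": 0.5, "n_senders": 5}]
    out = commun.condition_compare(_result(rows, "a"), _result(rows, "b"))
    assert set(out["flag"]) <= {"both", "neither"}


def test_mismatched_interaction_sets_rejected():
    rows_a = [{"sender": "PT", "interaction": "L->R", "pathway": "p",
               "probability": 0.5, "p": 0.5, "n_senders": 5}]
    rows_b = [{"sender": "PT", "interaction": "X->Y", "pathway": "p",
               "probability": 0.5, "p": 0.5, "n_senders": 5}]
    with pytest.raises(ValueError, match="differ"):
        commun.condition_compare(_result(rows_a, "a"), _result(rows_b, "b"))


def test_spp1_cd44_flagged_in_injured_condition_only(rng):
    """Spp1 elevated specifically in injured-PT senders makes Spp1->Cd44
    significant in the injured condition and only there."""
    n_send, n_recv = 12, 10
    receivers = np.zeros(n_send + n_recv, bool)
    receivers[n_send:] = True
    groups = {"injured_PT": np.arange(n_send)}

    def expr_for(spp1_sender_level):
        e = pd.DataFrame(
            {
                "Spp1": rng.gamma(2.0, 0.25, n_send + n_recv),
                "Cd44": rng.gamma(2.0, 1.0, n_send + n_recv),
                "Itgav": rng.gamma(2.0, 1.0, n_send + n_recv),
                "Itgb3": rng.gamma(2.0, 1.0, n_send + n_recv),
                "Tgfb1": rng.gamma(2.0, 0.5, n_send + n_recv),
                "Tgfbr1": rng.gamma(2.0, 1.0, n_send + n_recv),
                "Tgfbr2": rng.gamma(2.0, 1.0, n_send + n_recv),
            }
        )
        e.iloc[:n_send, e.columns.get_loc("Spp1")] += spp1_sender_level
        return e

    res_h = commun.score_communication(
        expr_for(0.0), groups, receivers, commun.demo_lr_database(),
        B=300, seed=0, condition="contralateral", K=1.0,
    )
    res_i = commun.score_communication(
        expr_for(8.0), groups, receivers, commun.demo_lr_database(),
        B=300, seed=0, condition="ligated", K=1.0,
    )
    flags = commun.condition_compare(res_h, res_i, alpha=0.05).set_index("interaction")
    assert flags.loc["Spp1->Cd44", "flag"] == "B_only"  # ligated only
    assert flags.loc["Tgfb1->Tgfbr1+Tgfbr2", "flag"] in ("neither", "both")
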