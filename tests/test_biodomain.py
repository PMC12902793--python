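"""Gene-level ORA, biodomain assignment heuristic, enrichment mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adtargets import biodomain as bd


# ---------------------------------------------------------------------------
# TermSystem
# ---------------------------------------------------------------------------

def test_term_system_round_trips_through_frames(toy_term_system):
    ann, dom = toy_term_system.to_frames()
    rebuilt = bd.TermSystem.from_frames(ann, dom)
    assert rebuilt.annotations == toy_term_system.annotations
    assert rebuilt.domain_of == toy_term_system.domain_of


def test_term_graph_shared_gene_edges(toy_term_system):
    G = toy_term_system.term_graph()
    assert G.has_edge("t1", "t2") and G["t1"]["t2"]["weight"] == 1  # share g2
    assert not G.has_edge("t1", "t3")
    assert all(not G.has_edge(t, t) for t in G)  # no self-edges


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def test_ora_exact_tail_probability():
    universe = [f"u{i}" for i in range(10)]
    term = frozenset(universe[:5])
    res = bd.gene_set_ora(set(term), {"t": term}, universe,
                          min_size=1, max_size=10)
    assert res.loc[0, "p"] == pytest.approx(1 / 252)


def test_ora_disjoint_term_p_is_one():
    universe = [f"u{i}" for i in range(20)]
    res = bd.gene_set_ora(set(universe[:5]), {"t": frozenset(universe[10:])},
                          universe, min_size=1, max_size=20)
    assert res.loc[0, "k"] == 0 and res.loc[0, "p"] == 1.0


def test_ora_size_filter_and_empty_warning():
    universe = [f"u{i}" for i in range(30)]
    terms = {"tiny": frozenset(universe[:2]), "ok": frozenset(universe[:15])}
    res = bd.gene_set_ora(set(universe[:5]), terms, universe,
                          min_size=10, max_size=500)
    assert list(res["term_id"]) == ["ok"]
    with pytest.warns(UserWarning):
        empty = bd.gene_set_ora(set(universe[:5]), terms, universe,
                                min_size=29, max_size=500)
    assert empty.empty


def test_ora_rejects_genes_outside_universe():
    with pytest.raises(ValueError):
        bd.gene_set_ora({"x"}, {"t": frozenset({"a"})}, {"a"},
                        min_size=1, max_size=5)


def test_ora_null_p_is_superuniform_and_calibrated(rng):
    """Random gene sets: P(p <= t) never exceeds t, and is close at coarse t."""
    universe = [f"u{i}" for i in range(800)]
    terms = {f"t{j}": frozenset(rng.choice(universe, 250, replace=False))
             for j in range(5)}
    pvals = []
    for _ in range(120):
        genes = set(rng.choice(universe, 120, replace=False))
        res = bd.gene_set_ora(genes, terms, universe, min_size=1, max_size=800)
        pvals.extend(res["p"])
    pvals = np.array(pvals)
    for t in (0.05, 0.2, 0.5):
        frac = (pvals <= t).mean()
        se = np.sqrt(t * (1 - t) / len(pvals))
        assert frac <= t + 3 * se          # validity
        assert frac >= t - 3 * se - 0.06   # calibration, discreteness slack


# ---------------------------------------------------------------------------
# assignment heuristic
# ---------------------------------------------------------------------------

@pytest.fixture
def four_term_system():
    """Hand-checkable: domain A has 3 terms (gene covers 2), domain B has 1.

    gene = g1. Terms: a1 {g1,g2} (size 2), a2 {g1,g2,g3,g4} (size 4),
    a3 {g5,g6} (no g1), b1 {g1,g3,g4} (size 3).
    """
    return bd.TermSystem(
        {
            "a1": frozenset({"g1", "g2"}),
            "a2": frozenset({"g1", "g2", "g3", "g4"}),
            "a3": frozenset({"g5", "g6"}),
            "b1": frozenset({"g1", "g3", "g4"}),
        },
        domain_of={"a1": "A", "a2": "A", "a3": "A", "b1": "B"},
    )


def test_domain_scores_hand_computed(four_term_system):
    scores = bd.domain_scores("g1", four_term_system).set_index("term_id")
    # q1: g1 covers 2 of A's 3 terms, 1 of B's 1 term
    assert scores.loc["a1", "q1"] == pytest.approx(2 / 3)
    assert scores.loc["a2", "q1"] == pytest.approx(2 / 3)
    assert scores.loc["b1", "q1"] == pytest.approx(1.0)
    # sizes: a2=4, b1=3, a1=2 -> descending ranks 1,2,3 -> q2 = rank/3
    assert scores.loc["a2", "q2"] == pytest.approx(1 / 3)
    assert scores.loc["b1", "q2"] == pytest.approx(2 / 3)
    assert scores.loc["a1", "q2"] == pytest.approx(1.0)
    # weighted degrees in g1's term graph: shared counts a1-a2=2 (g1,g2),
    # a1-b1=1 (g1), a2-b1=3 (g1,g3,g4) -> strengths a1=3, b1=4, a2=5
    # ascending ranks a1=1, b1=2, a2=3 -> q3 = rank/3
    assert scores.loc["a1", "q3"] == pytest.approx(1 / 3)
    assert scores.loc["b1", "q3"] == pytest.approx(2 / 3)
    assert scores.loc["a2", "q3"] == pytest.approx(1.0)
    # totals: a1 = 2/3+1+1/3 = 2; a2 = 2/3+1/3+1 = 2; b1 = 1+2/3+2/3 = 7/3
    assert scores.loc["a1", "total"] == pytest.approx(2.0)
    assert scores.loc["a2", "total"] == pytest.approx(2.0)
    assert scores.loc["b1", "total"] == pytest.approx(7 / 3)
    assert bd.assign_top_biodomain("g1", four_term_system) == "B"


def test_assignment_tie_breaks_alphabetically():
    # perfectly symmetric two-domain fixture: totals tie, "A" wins
    ts = bd.TermSystem(
        {"x1": frozenset({"g1", "g2"}), "x2": frozenset({"g1", "g3"})},
        domain_of={"x1": "B", "x2": "A"},
    )
    assert bd.assign_top_biodomain("g1", ts) == "A"


def test_single_domain_gene_and_unassigned(four_term_system):
    assert bd.assign_top_biodomain("g2", four_term_system) == "A"
    assert bd.assign_top_biodomain("g9", four_term_system) == "unassigned"


def test_assignment_invariant_to_annotation_order(four_term_system):
    reordered = bd.TermSystem(
        dict(reversed(list(four_term_system.annotations.items()))),
        domain_of=dict(four_term_system.domain_of))
    for g in ("g1", "g2", "g3", "g4"):
        assert bd.assign_top_biodomain(g, four_term_system) == \
            bd.assign_top_biodomain(g, reordered)


def test_raising_q1_never_flips_assignment_away(four_term_system):
    """With q2/q3 held fixed, raising a domain's coverage fraction can only
    keep or improve that domain's standing in the argmax."""
    scores = bd.domain_scores("g1", four_term_system)
    winner = scores.sort_values(["total", "domain", "term_id"],
                                ascending=[False, True, True]).iloc[0]["domain"]
    for delta in (0.05, 0.2, 1.0):
        bumped = scores.copy()
        mask = bumped["domain"] == winner
        bumped.loc[mask, "total"] = bumped.loc[mask, "total"] + delta
        new_winner = bumped.sort_values(
            ["total", "domain", "term_id"],
            ascending=[False, True, True]).iloc[0]["domain"]
        assert new_winner == winner


def test_rank_direction_flags_flip_q2_q3(four_term_system):
    flipped = bd.domain_scores("g1", four_term_system,
                               specific_high=False, hub_high=False)
    default = bd.domain_scores("g1", four_term_system)
    n = len(default)
    merged = default.merge(flipped, on="term_id", suffixes=("", "_f"))
    assert np.allclose(merged["q2"] + merged["q2_f"], (n + 1) / n)
    assert np.allclose(merged["q3"] + merged["q3_f"], (n + 1) / n)


# ---------------------------------------------------------------------------
# mapping enrichment rows to biodomains
# ---------------------------------------------------------------------------

def test_mapping_equals_hand_built_join(toy_term_system):
    rows = pd.DataFrame({
        "term_id": ["t1", "t2", "t3"],
        "fdr": [0.01, 0.2, 0.04],
        "or_rel": [2.0, 1.0, 4.0],
    })
    mapped, report = bd.map_enrichment_to_biodomains(rows, toy_term_system)
    assert list(mapped["term_id"]) == ["t1", "t3"]
    assert list(mapped["domain"]) == ["BD01", "BD02"]
    assert report == {"n_input": 3, "n_significant": 2,
                      "n_filtered": 1, "n_unmapped": 0}
    assert mapped["log2_or"].tolist() == pytest.approx([1.0, 2.0])


def test_mapping_reports_unmapped_and_all_filtered(toy_term_system):
    rows = pd.DataFrame({"term_id": ["t1", "zz"], "fdr": [0.01, 0.01]})
    mapped, report = bd.map_enrichment_to_biodomains(rows, toy_term_system)
    assert report["n_unmapped"] == 1 and len(mapped) == 2
    none_sig = pd.DataFrame({"term_id": ["t1"], "fdr": [0.9]})
    mapped2, report2 = bd.map_enrichment_to_biodomains(none_sig, toy_term_system)
    assert mapped2.empty and report2["n_filtered"] == 1


# ---------------------------------------------------------------------------
# cross-module oracle
# ---------------------------------------------------------------------------

def test_ora_p_equals_one_sided_fisher(rng):
    """Hypergeometric upper tail == one-sided Fisher on the same 2×2."""
    from adtargets.setcompare import overlap_fisher
    universe = [f"u{i}" for i in range(200)]
    for _ in range(20):
        term = frozenset(rng.choice(universe, int(rng.integers(10, 80)),
                                    replace=False))
        genes = set(rng.choice(universe, int(rng.integers(10, 80)),
                               replace=False))
        ora = bd.gene_set_ora(genes, {"t": term}, universe,
                              min_size=1, max_size=200)
        fisher = overlap_fisher(genes, set(term), universe)
        assert ora.loc[0, "p"] == pytest.approx(fisher.p, abs=1e-12)
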