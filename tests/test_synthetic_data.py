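"""Generators: determinism, planted effects, and shape invariants."""

import json

import numpy as np
import pandas as pd
import pytest

from adtargets import synthetic_data as sd
from adtargets.harmonize import harmonize_agent_name
from adtargets.setcompare import top_fraction


def test_identical_config_gives_identical_outputs(small_cfg):
    g1, g2 = sd.gen_bipartite(small_cfg), sd.gen_bipartite(small_cfg)
    assert g1.edges == g2.edges
    t1, t2 = sd.gen_term_system(small_cfg), sd.gen_term_system(small_cfg)
    assert t1.annotations == t2.annotations
    r1 = sd.gen_risk_table(small_cfg)
    r2 = sd.gen_risk_table(small_cfg)
    pd.testing.assert_frame_equal(r1, r2)
    tr1, _ = sd.gen_trial_records(small_cfg)
    tr2, _ = sd.gen_trial_records(small_cfg)
    pd.testing.assert_frame_equal(tr1, tr2)


def test_outputs_identical_across_processes_and_hash_seeds(tmp_path):
    """Byte-identical artifacts regardless of interpreter hash randomization."""
    import subprocess
    import sys

    prog = (
        "from adtargets import synthetic_data as sd\n"
        "cfg = sd.SimConfig(seed=3, n_drugs=20, n_genes=200,"
        " term_size_range=(10, 40), n_trials_per_source=10)\n"
        "g = sd.gen_bipartite(cfg); ts = sd.gen_term_system(cfg)\n"
        "r = sd.gen_risk_table(cfg)\n"
        "print(hash(tuple(g.edges)))\n"
        "print(sorted((t, tuple(sorted(v))) for t, v in ts.annotations.items()))\n"
        "print(r['total'].sum())\n"
    )
    outs = set()
    for hash_seed in ("1", "271828"):
        res = subprocess.run(
            [sys.executable, "-c", prog], capture_output=True, text=True,
            env={"PYTHONHASHSEED": hash_seed, "PATH": "/usr/bin:/bin"},
        )
        assert res.returncode == 0, res.stderr
        outs.add(res.stdout.split("\n", 1)[1])  # hash() itself is seeded
    assert len(outs) == 1


def test_generators_use_independent_substreams(small_cfg):
    """Regenerating one artifact never perturbs another (fixed offsets)."""
    before = sd.gen_bipartite(small_cfg).edges
    sd.gen_risk_table(small_cfg)
    sd.gen_term_system(small_cfg)
    assert sd.gen_bipartite(small_cfg).edges == before


# ---------------------------------------------------------------------------
# bipartite graph
# ---------------------------------------------------------------------------

def test_fixed_degree_law():
    cfg = sd.SimConfig(seed=1, n_drugs=10, n_genes=50,
                       term_size_range=(5, 20),
                       drug_degree_law=sd.DegreeLaw("fixed", {"degree": 1}))
    g = sd.gen_bipartite(cfg)
    assert len(g) == 10
    assert all(d == 1 for d in g.drug_degree().values())


def test_degenerate_zipf_rejected():
    with pytest.raises(ValueError):
        sd.DegreeLaw("zipf", {"a": 1.0})
    with pytest.raises(ValueError):
        sd.DegreeLaw("fixed", {"degree": 0})
    # bounded support makes a <= 1 legal
    sd.DegreeLaw("zipf", {"a": 0.9, "max_degree": 20})


def test_zipf_tail_mass_matches_law():
    """Frequency of degree >= 10 across replicates tracks the law's tail."""
    law = sd.DegreeLaw("zipf", {"a": 2.0, "max_degree": 60})
    ks, pmf = law.pmf()
    tail = pmf[ks >= 10].sum()
    n_rep, n_drugs = 200, 500
    count = total = 0
    max_degrees = []
    for s in range(n_rep):
        cfg = sd.SimConfig(seed=s, n_drugs=n_drugs, n_genes=2000,
                           drug_degree_law=law)
        deg = np.array(list(sd.gen_bipartite(cfg).drug_degree().values()))
        count += (deg >= 10).sum()
        total += n_drugs
        max_degrees.append(deg.max())
    frac = count / total
    se = np.sqrt(tail * (1 - tail) / total)
    assert abs(frac - tail) <= 4 * se
    assert np.mean(np.array(max_degrees) >= 10) > 0.99


def test_planted_term_receives_excess_hits():
    base = sd.SimConfig(seed=3, n_drugs=100, n_genes=500)
    planted = sd.SimConfig(seed=3, n_drugs=100, n_genes=500,
                           planted_terms=(("T0000", 0.8),))
    ts = sd.gen_term_system(base)
    from adtargets.perm_enrichment import observed_stat
    O_base = observed_stat(sd.gen_bipartite(base), ts.annotations["T0000"])
    O_planted = observed_stat(sd.gen_bipartite(planted), ts.annotations["T0000"])
    assert O_planted > O_base + 30  # ~80 extra hitting drugs


def test_unknown_planted_term_rejected():
    cfg = sd.SimConfig(seed=0, planted_terms=(("nope", 0.5),))
    with pytest.raises(ValueError):
        sd.gen_bipartite(cfg)


# ---------------------------------------------------------------------------
# term system
# ---------------------------------------------------------------------------

def test_term_sizes_within_range_and_single_domain_labels(small_cfg):
    ts = sd.gen_term_system(small_cfg)
    lo, hi = small_cfg.term_size_range
    sizes = [len(g) for g in ts.annotations.values()]
    assert min(sizes) >= lo and max(sizes) <= hi
    assert lo <= np.mean(sizes) <= hi
    assert set(ts.domain_of) == set(ts.annotations)
    assert len(ts.domains) == small_cfg.n_domains


def test_zero_overlap_gives_disjoint_terms_within_domain():
    cfg = sd.SimConfig(seed=9, n_genes=600, n_domains=2, terms_per_domain=5,
                       term_size_range=(10, 50), term_overlap_fraction=0.0)
    ts = sd.gen_term_system(cfg)
    for dom in ts.domains:
        terms = sorted(ts.domain_terms(dom))
        for i, t in enumerate(terms):
            for u in terms[i + 1:]:
                assert not (ts.annotations[t] & ts.annotations[u])


def test_single_term_covering_all_genes():
    cfg = sd.SimConfig(seed=2, n_genes=40, n_domains=1, terms_per_domain=1,
                       term_size_range=(40, 40))
    ts = sd.gen_term_system(cfg)
    (term,) = ts.annotations
    assert ts.annotations[term] == frozenset(cfg.genes())
    # every gene belongs to exactly one domain
    assert all(len({ts.domain_of[t] for t in ts.terms_of(g)}) == 1
               for g in cfg.genes())


def test_invalid_term_configs_rejected():
    with pytest.raises(ValueError):
        sd.SimConfig(terms_per_domain=0)
    with pytest.raises(ValueError):
        sd.SimConfig(n_genes=10, term_size_range=(5, 20))


# ---------------------------------------------------------------------------
# risk table
# ---------------------------------------------------------------------------

def test_no_planting_gives_chance_level_top_tail_overlap():
    """p = 0: expected overlap with the top 1% is ~1% of trial targets."""
    overlaps = []
    for s in range(500):
        cfg = sd.SimConfig(seed=s, n_genes=400, n_drugs=5,
                           planted_top_fraction_overlap=0.0)
        targets = [f"G{i:06d}" for i in range(1, 51)]
        risk = sd.gen_risk_table(cfg, targets)
        top = top_fraction(risk, 0.01)  # 4 genes
        overlaps.append(len(top & set(targets)))
    mean = np.mean(overlaps)
    expected = 50 * 4 / 400  # 0.5
    se = np.std(overlaps) / np.sqrt(len(overlaps))
    assert abs(mean - expected) <= 4 * se


def test_full_planting_puts_all_targets_in_top_tail():
    cfg = sd.SimConfig(seed=4, n_genes=1000,
                       planted_top_fraction_overlap=1.0)
    targets = [f"G{i:06d}" for i in range(1, 9)]
    risk = sd.gen_risk_table(cfg, targets)
    assert set(targets) <= top_fraction(risk, cfg.top_fraction)
    assert risk["boosted"].sum() == len(targets)


def test_scores_are_strictly_rankable(small_cfg):
    risk = sd.gen_risk_table(small_cfg)
    ordered = np.sort(risk["total"].to_numpy())[::-1]
    assert (np.diff(ordered) < 0).all()  # strictly decreasing


def test_risk_rejects_targets_outside_universe(small_cfg):
    with pytest.raises(ValueError):
        sd.gen_risk_table(small_cfg, ["NOT_A_GENE"])


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def test_alpha_limits_give_perfect_correlations():
    cfg = sd.SimConfig(seed=6, n_genes=300, signature_alphas=(1.0, -1.0),
                       noise_sd=1e-9)
    sig = sd.gen_signature(cfg)
    profiles, truth = sd.gen_perturbation_profiles(cfg, sig)
    from adtargets.reversal import signature_correlation
    r_pos, _, _ = signature_correlation(profiles[0], sig)
    r_neg, _, _ = signature_correlation(profiles[1], sig)
    assert r_pos == pytest.approx(1.0, abs=1e-6)
    assert r_neg == pytest.approx(-1.0, abs=1e-6)
    assert profiles[1].modality == "inhibition"


def test_zero_alpha_is_uncorrelated():
    rs = []
    from adtargets.reversal import signature_correlation
    for s in range(30):
        cfg = sd.SimConfig(seed=s, n_genes=900, signature_alphas=(0.0,))
        sig = sd.gen_signature(cfg)
        profiles, _ = sd.gen_perturbation_profiles(cfg, sig)
        r, _, _ = signature_correlation(profiles[0], sig)
        rs.append(r)
    assert np.mean(np.abs(rs) < 3 / np.sqrt(900)) > 0.9


# ---------------------------------------------------------------------------
# trial records
# ---------------------------------------------------------------------------

def test_zero_decoration_rate_emits_clean_names():
    cfg = sd.SimConfig(seed=8, n_drugs=20, n_genes=100, term_size_range=(10, 40),
                       n_trials_per_source=30, decoration_rate=0.0)
    trials, truth = sd.gen_trial_records(cfg)
    assert (trials["agent_name"] == truth["clean_name"]).all()


def test_decorated_names_harmonize_back_to_clean():
    cfg = sd.SimConfig(seed=8, n_drugs=20, n_genes=100, term_size_range=(10, 40),
                       n_trials_per_source=40, decoration_rate=1.0)
    _, truth = sd.gen_trial_records(cfg)
    recovered = truth["agent_name"].map(harmonize_agent_name)
    assert (recovered == truth["clean_name"]).all()


def test_source_overlap_fraction_controls_shared_ncts():
    cfg = sd.SimConfig(seed=8, n_drugs=20, n_genes=100, term_size_range=(10, 40),
                       n_trials_per_source=50, source_overlap_fraction=0.4)
    trials, _ = sd.gen_trial_records(cfg)
    a = set(trials.loc[trials["source"] == "pipeline_set", "nct_id"])
    b = set(trials.loc[trials["source"] == "known_drugs", "nct_id"])
    assert len(a) == len(b) == 50
    assert len(a & b) == round(0.4 * 50)
    assert all(len(x) == 11 and x.startswith("NCT") for x in a | b)


# ---------------------------------------------------------------------------
# TDL and the one-call writer
# ---------------------------------------------------------------------------

def test_tdl_levels_valid_and_boost_shifts_tclin(small_cfg):
    boosted = set(small_cfg.genes()[:100])
    tdl = sd.gen_tdl_table(small_cfg, boosted=boosted)
    assert set(tdl["level"]) <= {"Tclin", "Tchem", "Tbio", "Tdark"}
    in_boost = tdl["gene"].isin(boosted)
    frac_boost = (tdl.loc[in_boost, "level"] == "Tclin").mean()
    frac_rest = (tdl.loc[~in_boost, "level"] == "Tclin").mean()
    assert frac_boost > 0.6 > frac_rest


def test_simulate_all_writes_every_artifact(tmp_path, small_cfg):
    paths = sd.simulate_all(small_cfg, tmp_path)
    expected = {"edges", "annotations", "biodomains", "trials_pipeline_set",
                "trials_known_drugs", "agent_truth", "resolver", "risk",
                "tdl", "signature", "perturbations", "perturbation_truth",
                "manifest"}
    assert expected <= set(paths)
    assert all(p.exists() for p in paths.values())
    manifest = json.loads(paths["manifest"].read_text())
    assert manifest["seed"] == small_cfg.seed
    edges = pd.read_csv(paths["edges"], sep="\t")
    assert list(edges.columns) == ["agent", "gene"]
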