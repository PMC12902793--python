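"""Synthetic study inputs with planted, recoverable effects.

Every table the pipeline consumes can be generated here, so the full
analysis runs offline and deterministically: a sparse bipartite drug→target
graph with heavy-tailed drug degrees (a few agents with tens of targets,
most with one or two), a term system grouped into biodomains with nested
term sizes and controllable within-domain overlap, a genome-wide risk table
with a rankable continuum and a planted high-scoring tail, messy trial
records whose raw agent strings decorate known clean names, a target
development level table, and perturbation profiles that are noisy scalar
multiples of a disease signature.

The planted effects are the test surface: excess drug hits on chosen terms
must be flagged by the permutation enrichment test, trial targets planted
into the top risk tail must light up the Fisher overlap test, decorated
agent names must harmonize back to their clean forms, and negative-alpha
perturbations must be recovered by the reversal screen.

Determinism: a single integer master seed fans out to per-generator
substreams through fixed offsets, so adding a generator never perturbs the
draws of another. Gene identifiers are synthetic symbols ("G000001", ...),
never real gene symbols, to prevent accidental dependence on real
annotations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .biodomain import TermSystem
from .harmonize import DrugTargetGraph, Lexicon
from .reversal import DiseaseSignature, PerturbationProfile

__all__ = [
    "DegreeLaw", "SimConfig", "gen_bipartite", "gen_term_system",
    "gen_risk_table", "gen_signature", "gen_perturbation_profiles",
    "gen_trial_records", "gen_tdl_table", "ground_truth_resolver",
    "simulate_all",
]

# Fixed substream offsets: one per generator, never reused.
_STREAMS = {
    "bipartite": 11,
    "terms": 23,
    "risk": 37,
    "signature": 51,
    "perturb": 63,
    "trials": 77,
    "tdl": 91,
}


@dataclass(frozen=True)
class DegreeLaw:
    """Drug-degree distribution: ``zipf`` (truncated power law) or ``fixed``.

    zipf params: ``a`` (exponent, > 1 unless ``max_degree`` bounds the
    support) and ``max_degree``. fixed params: ``degree``.
    """

    kind: str
    params: tuple[tuple[str, float], ...]

    def __init__(self, kind: str, params: Mapping[str, float]):
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "params", tuple(sorted(params.items())))
        if kind == "zipf":
            p = dict(self.params)
            if "max_degree" not in p:
                if p.get("a", 0) <= 1:
                    raise ValueError("zipf exponent <= 1 needs bounded support")
            elif p["max_degree"] < 1:
                raise ValueError("max_degree must be >= 1")
        elif kind == "fixed":
            if dict(self.params).get("degree", 0) < 1:
                raise ValueError("fixed degree must be >= 1")
        else:
            raise ValueError(f"unknown degree law {kind!r}")

    def pmf(self, support_cap: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
        """(degrees, probabilities) over the law's support."""
        p = dict(self.params)
        if self.kind == "fixed":
            k = int(p["degree"])
            return np.array([k]), np.array([1.0])
        kmax = int(p.get("max_degree", support_cap))
        ks = np.arange(1, kmax + 1)
        w = ks ** (-float(p["a"]))
        return ks, w / w.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a scaled-down study: a few hundred trial agents with
    heavy-tailed polypharmacology over a universe of 2,000 genes, 50
    annotation terms across 5 biodomains, and perturbation profiles that
    are noisy unit-alpha copies of the disease signature.
    """

    seed: int = 0
    n_drugs: int = 200
    n_genes: int = 2000
    #: drugs draw their baseline targets from the first target_pool_size
    #: genes (None = whole universe), emulating how trial agents concentrate
    #: on a small druggable subset of the genome
    target_pool_size: int | None = None
    drug_degree_law: DegreeLaw = field(
        default_factory=lambda: DegreeLaw("zipf", {"a": 2.0, "max_degree": 60}))
    n_domains: int = 5
    terms_per_domain: int = 10
    term_size_range: tuple[int, int] = (20, 120)
    term_overlap_fraction: float = 0.3
    planted_terms: tuple[tuple[str, float], ...] = ()
    top_fraction: float = 0.01
    planted_top_fraction_overlap: float = 0.0
    signature_alphas: tuple[float, ...] = (1.0,)
    signature_sd: float = 1.0
    noise_sd: float = 1.0
    n_trials_per_source: int = 80
    source_overlap_fraction: float = 0.3
    decoration_rate: float = 0.8

    def __post_init__(self):
        for name in ("n_drugs", "n_genes", "n_domains", "terms_per_domain",
                     "n_trials_per_source"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("term_size_range must lie within [1, n_genes]")
        if self.noise_sd <= 0 or self.signature_sd <= 0:
            raise ValueError("noise_sd and signature_sd must be positive")
        for prob in ("term_overlap_fraction", "planted_top_fraction_overlap",
                     "source_overlap_fraction", "decoration_rate"):
            if not 0 <= getattr(self, prob) <= 1:
                raise ValueError(f"{prob} must lie in [0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.target_pool_size is not None and \
                not 1 <= self.target_pool_size <= self.n_genes:
            raise ValueError("target_pool_size must lie within [1, n_genes]")
        for _, excess in self.planted_terms:
            if not 0 <= excess <= 1:
                raise ValueError("planted excess probabilities must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def genes(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.n_genes + 1)]

    def drugs(self) -> list[str]:
        return [f"agent{i:04d}" for i in range(1, self.n_drugs + 1)]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["drug_degree_law"] = {"kind": self.drug_degree_law.kind,
                                "params": dict(self.drug_degree_law.params)}
        return json.dumps(d, indent=2, sort_keys=True, default=list)


# ---------------------------------------------------------------------------
# Term system
# ---------------------------------------------------------------------------

def gen_term_system(cfg: SimConfig) -> TermSystem:
    """Terms with nested sizes, one domain each, controllable overlap.

    With ``term_overlap_fraction`` f, each term after the first in a domain
    draws ~f of its genes from genes already annotated within that domain;
    the remainder come from genes unused in the domain, so f = 0 yields
    pairwise-disjoint term gene sets within each domain. Genes recur across
    domains freely, so a configurable share of the universe ends up
    multi-domain.
    """
    rng = cfg.rng("terms")
    genes = np.array(cfg.genes())
    lo, hi = cfg.term_size_range
    if cfg.term_overlap_fraction == 0 and cfg.terms_per_domain * hi > cfg.n_genes:
        raise ValueError("disjoint terms need terms_per_domain * max_size <= n_genes")
    annotations: dict[str, frozenset[str]] = {}
    domain_of: dict[str, str] = {}
    subdomain_of: dict[str, str] = {}
    k = 0
    for d in range(cfg.n_domains):
        domain = f"BD{d + 1:02d}"
        used: list[str] = []
        used_set: set[str] = set()
        for _ in range(cfg.terms_per_domain):
            term = f"T{k:04d}"
            k += 1
            size = int(rng.integers(lo, hi + 1))
            n_shared = min(int(round(cfg.term_overlap_fraction * size)), len(used))
            shared = rng.choice(used, size=n_shared, replace=False) if n_shared else []
            fresh_pool = np.array([g for g in genes if g not in used_set])
            n_fresh = min(size - n_shared, len(fresh_pool))
            fresh = rng.choice(fresh_pool, size=n_fresh, replace=False)
            members = frozenset(map(str, shared)) | frozenset(map(str, fresh))
            annotations[term] = members
            domain_of[term] = domain
            subdomain_of[term] = f"{domain}.s{(k - 1) % 2 + 1}"
            # sorted: set iteration order is hash-randomized, and the order
            # genes enter the reuse pool feeds later rng.choice draws
            for g in sorted(members):
                if g not in used_set:
                    used_set.add(g)
                    used.append(g)
    return TermSystem(annotations, domain_of, subdomain_of)


# ---------------------------------------------------------------------------
# Bipartite drug→target graph
# ---------------------------------------------------------------------------

def gen_bipartite(cfg: SimConfig) -> DrugTargetGraph:
    """Drug→target edges with law-drawn degrees and planted term hits.

    Each drug's baseline degree comes from ``drug_degree_law``; its targets
    are drawn without replacement from the gene universe. For every planted
    ``(term_id, excess_p)``, each drug additionally hits one uniformly
    chosen gene of that term with probability ``excess_p`` (the planted
    enrichment signal). Deterministic under the seed.
    """
    rng = cfg.rng("bipartite")
    drugs = cfg.drugs()
    genes = cfg.genes()
    pool = cfg.target_pool_size or cfg.n_genes
    ks, pmf = cfg.drug_degree_law.pmf()
    degrees = rng.choice(ks, size=cfg.n_drugs, p=pmf)
    edges: list[tuple[str, str]] = []
    for d, deg in zip(drugs, degrees):
        targets = rng.choice(pool, size=min(int(deg), pool), replace=False)
        edges.extend((d, genes[t]) for t in targets)
    if cfg.planted_terms:
        terms = gen_term_system(cfg)
        for term_id, excess in cfg.planted_terms:
            if term_id not in terms.annotations:
                raise ValueError(f"planted term {term_id!r} not in term system")
            members = sorted(terms.annotations[term_id])
            hits = rng.random(cfg.n_drugs) < excess
            picks = rng.integers(0, len(members), size=cfg.n_drugs)
            for d, hit, pick in zip(drugs, hits, picks):
                if hit:
                    edges.append((d, members[pick]))
    return DrugTargetGraph(edges)


# ---------------------------------------------------------------------------
# Risk table
# ---------------------------------------------------------------------------

def gen_risk_table(cfg: SimConfig,
                   trial_targets: Iterable[str] = ()) -> pd.DataFrame:
    """Continuous, rankable risk scores with a planted top-tail overlap.

    Baseline genetics and multi-omics scores are independent standard
    normals; the total is their sum. With planting probability
    ``planted_top_fraction_overlap`` p, each trial target's total score is
    lifted strictly above the pre-existing maximum, guaranteeing membership
    in the top ``top_fraction`` tail (requires the number of boosted genes
    not to exceed the tail size). Ties, should they occur, are broken by a
    deterministic jitter smaller than the smallest nonzero score gap; the
    jitter is recorded in the output.
    """
    rng = cfg.rng("risk")
    genes = cfg.genes()
    trial_targets = sorted(set(trial_targets))
    unknown = set(trial_targets) - set(genes)
    if unknown:
        raise ValueError(f"trial targets outside the gene universe: {sorted(unknown)[:5]}")
    n = cfg.n_genes
    genetics = rng.normal(0.0, 1.0, n)
    omics = rng.normal(0.0, 1.0, n)
    total = genetics + omics
    boosted = np.zeros(n, dtype=bool)
    if trial_targets and cfg.planted_top_fraction_overlap > 0:
        tail_size = int(np.ceil(cfg.top_fraction * n))
        idx = {g: i for i, g in enumerate(genes)}
        lift = rng.random(len(trial_targets)) < cfg.planted_top_fraction_overlap
        if lift.sum() > tail_size:
            raise ValueError("more boosted targets than the top tail can hold")
        top = total.max()
        offsets = rng.uniform(0.5, 1.5, len(trial_targets))
        for g, do, off in zip(trial_targets, lift, offsets):
            if do:
                total[idx[g]] = top + off
                boosted[idx[g]] = True
    jitter = np.zeros(n)
    order = np.sort(total)
    gaps = np.diff(order)
    pos = gaps[gaps > 0]
    if len(pos) < n - 1:  # ties present
        scale = (pos.min() if len(pos) else 1.0) / (10 * n)
        jitter = rng.uniform(0, scale, n)
        total = total + jitter
    return pd.DataFrame({"gene": genes, "total": total, "genetics": genetics,
                         "omics": omics, "jitter": jitter, "boosted": boosted})


# ---------------------------------------------------------------------------
# Disease signature and perturbation profiles
# ---------------------------------------------------------------------------

def gen_signature(cfg: SimConfig) -> DiseaseSignature:
    """Per-gene meta-analysis log fold changes ~ Normal(0, signature_sd)."""
    rng = cfg.rng("signature")
    vals = rng.normal(0.0, cfg.signature_sd, cfg.n_genes)
    return DiseaseSignature(pd.Series(vals, index=cfg.genes()))


def gen_perturbation_profiles(cfg: SimConfig, signature: DiseaseSignature,
                              modalities: Sequence[str] | None = None,
                              cell_type: str = "neuron",
                              ) -> tuple[list[PerturbationProfile], pd.DataFrame]:
    """One profile per alpha: ``alpha * signature + Normal(0, noise_sd)``.

    The scaling alphas are the ground truth, returned alongside the
    profiles. Targets are distinct genes drawn from the universe; the
    modality defaults to "activation" for alpha >= 0 and "inhibition"
    otherwise (override with ``modalities``).
    """
    if not set(signature.genes) >= set(cfg.genes()):
        raise ValueError("signature must cover the gene universe")
    rng = cfg.rng("perturb")
    alphas = list(cfg.signature_alphas)
    targets = rng.choice(cfg.n_genes, size=len(alphas), replace=False)
    sig = signature.values.loc[cfg.genes()]
    profiles, truth = [], []
    for i, alpha in enumerate(alphas):
        noise = rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        logfc = pd.Series(alpha * sig.to_numpy() + noise, index=cfg.genes())
        if modalities is not None:
            modality = modalities[i]
        else:
            modality = "activation" if alpha >= 0 else "inhibition"
        target = cfg.genes()[targets[i]]
        profiles.append(PerturbationProfile(target, modality, cell_type, logfc))
        truth.append({"target": target, "modality": modality,
                      "cell_type": cell_type, "alpha": alpha})
    return profiles, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Trial records
# ---------------------------------------------------------------------------

_PHASES = ("Phase 1", "Phase 2", "Phase 2/Phase 3", "Phase 3")
_STATUSES = ("Completed", "Recruiting", "Active", "Terminated")
_CASES = ("lower", "title", "upper")


def _decorate(clean: str, rng: np.random.Generator, lexicon: Lexicon) -> str:
    """Append salt / dosage / formulation decorations and randomize case."""
    parts = [clean]
    salts = sorted(lexicon.salts)
    units = sorted(u for u in lexicon.units if u.isalpha())
    forms = sorted(lexicon.formulations)
    if rng.random() < 0.6:
        parts.append(salts[rng.integers(len(salts))])
    if rng.random() < 0.5:
        amount = int(rng.choice([5, 10, 20, 25, 50, 100]))
        parts.append(f"{amount} {units[rng.integers(len(units))]}")
    if rng.random() < 0.5:
        parts.append(forms[rng.integers(len(forms))])
    raw = " ".join(parts)
    case = _CASES[rng.integers(len(_CASES))]
    if case == "title":
        return raw.title()
    if case == "upper":
        return raw.upper()
    return raw


def gen_trial_records(cfg: SimConfig, lexicon: Lexicon | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw two-source trial tables plus the ground-truth clean names.

    Each source holds ``n_trials_per_source`` trials; a
    ``source_overlap_fraction`` share of registry ids appears in both
    sources (shared trials may carry differently decorated names of the
    same clean agents). Raw agent strings are built from clean agent names
    (the drugs of :func:`gen_bipartite`) with salt / formulation / dosage
    decorations drawn from the harmonization lexicon's own token lists and
    randomized case, at probability ``decoration_rate``; with rate 0 the
    raw string is the clean (lowercase) name itself.

    Returns ``(trials, truth)``: trials has one row per (trial, source,
    agent) with columns nct_id, source, phase, status, start_date,
    completion_date, agent_name; truth adds the clean_name per row.
    """
    lexicon = lexicon or Lexicon.default()
    rng = cfg.rng("trials")
    drugs = cfg.drugs()
    n = cfg.n_trials_per_source
    n_shared = int(round(cfg.source_overlap_fraction * n))
    total = 2 * n - n_shared
    nct_nums = rng.choice(100_000_000, size=total, replace=False)
    ncts = [f"NCT{v:08d}" for v in nct_nums]
    shared = ncts[:n_shared]
    only_a = ncts[n_shared:n]
    only_b = ncts[n:]
    rows, truth_rows = [], []
    for source, ids in (("pipeline_set", shared + only_a),
                        ("known_drugs", shared + only_b)):
        for nct in ids:
            n_agents = int(rng.integers(1, 3))
            picks = rng.choice(len(drugs), size=n_agents, replace=False)
            start = pd.Timestamp("2005-01-01") + pd.Timedelta(
                days=int(rng.integers(0, 7000)))
            end = start + pd.Timedelta(days=int(rng.integers(180, 3000)))
            phase = _PHASES[rng.integers(len(_PHASES))]
            status = _STATUSES[rng.integers(len(_STATUSES))]
            for pick in picks:
                clean = drugs[pick]
                if rng.random() < cfg.decoration_rate:
                    raw = _decorate(clean, rng, lexicon)
                else:
                    raw = clean
                row = {"nct_id": nct, "source": source, "phase": phase,
                       "status": status,
                       "start_date": start.date().isoformat(),
                       "completion_date": end.date().isoformat(),
                       "agent_name": raw}
                rows.append(row)
                truth_rows.append({**row, "clean_name": clean})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def ground_truth_resolver(graph: DrugTargetGraph) -> pd.DataFrame:
    """Resolver fixture (canonical_name, identifier, gene_symbol) for a
    synthetic graph: each drug's identifier is synthetic and unambiguous."""
    rows = [{"canonical_name": d, "identifier": f"SYNCHEM{i:05d}", "gene_symbol": g}
            for i, d in enumerate(sorted(graph.drugs), start=1)
            for g in sorted({g for dd, g in graph.edges if dd == d})]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Target development levels
# ---------------------------------------------------------------------------

_TDL_BASE = {"Tclin": 0.04, "Tchem": 0.12, "Tbio": 0.62, "Tdark": 0.22}
_TDL_TRIAL = {"Tclin": 0.83, "Tchem": 0.12, "Tbio": 0.049, "Tdark": 0.001}


def gen_tdl_table(cfg: SimConfig, boosted: Iterable[str] = (),
                  base_probs: Mapping[str, float] | None = None,
                  boost_probs: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Assign one development level per gene.

    Background genes follow ``base_probs`` (defaults emulate a genome that
    is mostly Tbio/Tdark); genes in ``boosted`` — e.g., trial targets —
    follow ``boost_probs`` (defaults heavily Tclin, as expected when a
    therapeutic agent already exists).
    """
    rng = cfg.rng("tdl")
    base = base_probs or _TDL_BASE
    boost = boost_probs or _TDL_TRIAL
    boosted = set(boosted)
    levels = list(base)
    p_base = np.array([base[l] for l in levels], dtype=float)
    p_base /= p_base.sum()
    p_boost = np.array([boost[l] for l in levels], dtype=float)
    p_boost /= p_boost.sum()
    out = []
    for g in cfg.genes():
        p = p_boost if g in boosted else p_base
        out.append({"gene": g, "level": levels[rng.choice(len(levels), p=p)]})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# One-call artifact writer
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir`` as TSV + manifest JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path

    graph = gen_bipartite(cfg)
    terms = gen_term_system(cfg)
    ann, dom = terms.to_frames()
    trials, truth = gen_trial_records(cfg)
    trial_targets = sorted(graph.genes)
    risk = gen_risk_table(cfg, trial_targets)
    signature = gen_signature(cfg)
    profiles, perturb_truth = gen_perturbation_profiles(cfg, signature)
    tdl = gen_tdl_table(cfg, boosted=trial_targets)

    write("edges", graph.to_frame())
    write("annotations", ann)
    write("biodomains", dom)
    write("trials_pipeline_set", trials[trials["source"] == "pipeline_set"])
    write("trials_known_drugs", trials[trials["source"] == "known_drugs"])
    write("agent_truth", truth)
    write("resolver", ground_truth_resolver(graph))
    write("risk", risk)
    write("tdl", tdl)
    write("signature",
          signature.values.rename("logfc").rename_axis("gene").reset_index())
    long = pd.concat([
        prof.logfc.rename("logfc").rename_axis("gene").reset_index().assign(
            target=prof.target, modality=prof.modality, cell_type=prof.cell_type)
        for prof in profiles])
    write("perturbations",
          long[["target", "modality", "cell_type", "gene", "logfc"]])
    write("perturbation_truth", perturb_truth)

    manifest = out / "manifest.json"
    manifest.write_text(cfg.to_json())
    paths["manifest"] = manifest
    return paths
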