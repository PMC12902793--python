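"""Agent-name harmonization, trial-source merging, and drug→target graph assembly.

Clinical-trial registries record the same interventional agent under many raw
strings ("Donepezil hydrochloride", "Donepezil HCL", "donepezil 10 mg tablet").
This module collapses such variants onto one canonical lowercase agent name by
stripping salt, formulation, and unit/dosage tokens; merges trial records from
independent sources on their registry (NCT) identifier; and resolves the
harmonized agents to molecular targets through a pluggable lookup table,
yielding the bipartite drug–target graph that the enrichment statistics
consume.

Live registry or chemistry-database clients are out of scope: the resolver is
a pure lookup (a TSV fixture, or any mapping), so the whole pipeline runs
offline and deterministically.
"""

from __future__ import annotations

import json
import logging
import re
import string
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NCT_RE = re.compile(r"^NCT\d{8}$")

#: punctuation stripped from token boundaries ('%' is kept: it is a unit token)
_STRIP_CHARS = "".join(c for c in string.punctuation if c not in "%+-/")


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lexicon:
    """Token lists driving name harmonization.

    The default ships as an editable YAML resource; registries with unusual
    vocabularies can extend it and pass their own instance everywhere a
    ``lexicon`` argument appears.
    """

    salts: frozenset[str]
    formulations: frozenset[str]
    units: frozenset[str]

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            salts=frozenset(t.lower() for t in raw.get("salts", [])),
            formulations=frozenset(t.lower() for t in raw.get("formulations", [])),
            units=frozenset(t.lower() for t in raw.get("units", [])),
        )

    @classmethod
    def default(cls) -> "Lexicon":
        return _default_lexicon()

    @property
    def droppable(self) -> frozenset[str]:
        return self.salts | self.formulations | self.units


_DEFAULT: Lexicon | None = None


def _default_lexicon() -> Lexicon:
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("adtargets.data") / "default_lexicon.yaml"
        with resources.as_file(ref) as path:
            _DEFAULT = Lexicon.from_yaml(path)
    return _DEFAULT


# ---------------------------------------------------------------------------
# Name harmonization
# ---------------------------------------------------------------------------

_NUMERAL_RE = re.compile(r"^\d+(?:[.,]\d+)?$")


def _glued_unit_re(lexicon: Lexicon) -> re.Pattern:
    # "10mg", "2.5mcg": numeral glued to an alphabetic unit token
    alpha_units = sorted((u for u in lexicon.units if u.isalpha() or u == "%"),
                         key=len, reverse=True)
    if not alpha_units:
        return re.compile(r"$^")
    return re.compile(r"^\d+(?:[.,]\d+)?(?:%s)$" % "|".join(map(re.escape, alpha_units)))


def _tokenize(raw: str) -> list[str]:
    toks = []
    for tok in raw.lower().split():
        tok = tok.strip(_STRIP_CHARS)
        if tok and tok not in "+-/":
            toks.append(tok)
    return toks


def harmonize_agent_name(raw: str, lexicon: Lexicon | None = None) -> str:
    """Collapse a raw agent string to its canonical lowercase name.

    Removes salt tokens (hydrochloride, sulfate, ...), formulation tokens
    (tablet, transdermal, ...), unit tokens, and numerals attached to a unit
    ("10 mg", "2.5mcg"). Bare numerals and code-style names ("ac-3933")
    survive: a numeral is only dropped when the following token is a unit or
    it is glued to one. Idempotent by construction — the output contains no
    droppable token and no unit-adjacent numeral.

    If stripping would leave nothing (the raw string was decoration only),
    the whitespace-collapsed lowercase input is returned unchanged so the
    raw name is retained; :func:`is_unresolvable` flags this case.
    """
    if not raw or not raw.strip():
        raise ValueError("agent name is empty")
    lexicon = lexicon or Lexicon.default()
    glued = _glued_unit_re(lexicon)
    toks = _tokenize(raw)
    drop = lexicon.droppable
    kept: list[str] = []
    for i, tok in enumerate(toks):
        if tok in drop or glued.match(tok):
            continue
        if _NUMERAL_RE.match(tok) and i + 1 < len(toks) and toks[i + 1] in lexicon.units:
            continue
        kept.append(tok)
    if not kept:
        return " ".join(toks)
    return " ".join(kept)


def is_unresolvable(raw: str, lexicon: Lexicon | None = None) -> bool:
    """True when the name consists entirely of droppable decoration."""
    lexicon = lexicon or Lexicon.default()
    glued = _glued_unit_re(lexicon)
    toks = _tokenize(raw)
    if not toks:
        return True
    for i, tok in enumerate(toks):
        if tok in lexicon.droppable or glued.match(tok):
            continue
        if _NUMERAL_RE.match(tok) and i + 1 < len(toks) and toks[i + 1] in lexicon.units:
            continue
        return False
    return True


_COMBO_RE = re.compile(r"\s*\+\s*|\s+/\s+")


def split_combination(raw: str) -> list[str]:
    """Split combination agents ("insulin + empagliflozin", "a / b") into components.

    Applied before harmonization; each component is then resolved separately.
    Hyphenated code names ("axs-05") and glued unit fractions ("mg/ml") are
    not split.
    """
    parts = [p.strip() for p in _COMBO_RE.split(raw)]
    return [p for p in parts if p] or [raw.strip()]


def apply_rxnorm(names: Iterable[str], rxnorm: Mapping[str, str] | None) -> list[str]:
    """Best-effort exact-match normalization against a user-supplied lookup.

    ``rxnorm`` maps harmonized name → preferred name; names without an entry
    pass through unchanged. With ``rxnorm=None`` this is the identity.
    """
    if rxnorm is None:
        return list(names)
    lowered = {k.lower(): v.lower() for k, v in rxnorm.items()}
    return [lowered.get(n, n) for n in names]


# ---------------------------------------------------------------------------
# Trial records
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "nct_id", "source", "phase", "status",
    "start_date", "completion_date", "agent_name",
]


def merge_trial_sources(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Merge two trial tables keyed by NCT id; report list sizes and overlap.

    Rows with a malformed ``nct_id`` are quarantined (logged, excluded from
    all counts). The merged table carries one row per NCT id with the union
    of raw agent names and the provenance of both sources; when the sources
    disagree on phase/status/dates the first source's non-null value wins and
    both raw agent names are retained.

    The report gives ``|A|``, ``|B|``, ``|A ∩ B|`` (distinct valid NCT ids)
    and each intersection percentage rounded to a whole percent.
    """
    frames, quarantined = [], []
    for df in (a, b):
        valid = df["nct_id"].astype(str).str.match(NCT_RE)
        bad = df.loc[~valid]
        if len(bad):
            logger.warning("quarantined %d records with malformed NCT ids: %s",
                           len(bad), sorted(bad["nct_id"].astype(str).unique())[:5])
            quarantined.append(bad)
        frames.append(df.loc[valid])
    a_valid, b_valid = frames
    ids_a = set(a_valid["nct_id"])
    ids_b = set(b_valid["nct_id"])
    common = ids_a & ids_b

    both = pd.concat([a_valid, b_valid], ignore_index=True)
    rows = []
    for nct, grp in both.groupby("nct_id", sort=True):
        row = {"nct_id": nct,
               "sources": "|".join(sorted(set(grp["source"].astype(str)))),
               "agent_names": ";".join(sorted(set(grp["agent_name"].astype(str))))}
        for col in ("phase", "status", "start_date", "completion_date"):
            vals = grp[col].dropna() if col in grp else pd.Series(dtype=object)
            row[col] = vals.iloc[0] if len(vals) else None
        rows.append(row)
    merged = pd.DataFrame(rows)

    def pct(n, d):
        return int(round(100.0 * n / d)) if d else 0

    report = {
        "n_a": len(ids_a),
        "n_b": len(ids_b),
        "n_common": len(common),
        "pct_of_a": pct(len(common), len(ids_a)),
        "pct_of_b": pct(len(common), len(ids_b)),
        "n_merged": len(merged),
        "n_quarantined": int(sum(len(q) for q in quarantined)),
    }
    assert report["n_merged"] == report["n_a"] + report["n_b"] - report["n_common"]
    return merged, report


# ---------------------------------------------------------------------------
# Harmonized agents and the drug–target graph
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedAgent:
    canonical_name: str
    raw_names: set[str] = field(default_factory=set)
    nct_ids: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)


def build_harmonized_agents(merged: pd.DataFrame,
                            lexicon: Lexicon | None = None,
                            rxnorm: Mapping[str, str] | None = None,
                            ) -> dict[str, HarmonizedAgent]:
    """Harmonize every raw agent name in a merged trial table.

    Combination agents are split into components first; each component
    becomes (or joins) its own harmonized agent, with provenance retained.
    """
    lexicon = lexicon or Lexicon.default()
    agents: dict[str, HarmonizedAgent] = {}
    for _, row in merged.iterrows():
        raw_field = row["agent_names"] if "agent_names" in row else row["agent_name"]
        for raw in str(raw_field).split(";"):
            if not raw.strip():
                continue
            for component in split_combination(raw):
                name = harmonize_agent_name(component, lexicon)
                (name,) = apply_rxnorm([name], rxnorm)
                ag = agents.setdefault(name, HarmonizedAgent(name))
                ag.raw_names.add(raw)
                ag.nct_ids.add(row["nct_id"])
    return agents


class DrugTargetGraph:
    """Bipartite edge multiset between harmonized agents and gene symbols."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        self.edges: list[tuple[str, str]] = [(str(d), str(g)) for d, g in edges]
        self.drugs: set[str] = {d for d, _ in self.edges}
        self.genes: set[str] = {g for _, g in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, DrugTargetGraph) and \
            Counter(self.edges) == Counter(other.edges)

    def drug_degree(self) -> dict[str, int]:
        return dict(Counter(d for d, _ in self.edges))

    def gene_multiplicity(self) -> dict[str, int]:
        return dict(Counter(g for _, g in self.edges))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["agent", "gene"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DrugTargetGraph":
        return cls(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_resolver(path) -> pd.DataFrame:
    """Read a resolver fixture TSV: canonical_name, identifier, gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"canonical_name", "identifier", "gene_symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"resolver fixture missing columns: {sorted(missing)}")
    return df


def resolve_targets(agents: Mapping[str, HarmonizedAgent] | Iterable[HarmonizedAgent],
                    resolver: pd.DataFrame,
                    ) -> tuple[DrugTargetGraph, dict]:
    """Map harmonized agents to mechanism-of-action targets via a lookup table.

    Agents whose name maps to two distinct identifiers are ambiguous: they
    are excluded from the graph and listed in the report, never silently
    dropped. Agents with no resolved targets (supplements, vaccines, cell
    and tissue therapies) are retained with an empty target set and listed
    under ``no_targets``.
    """
    if isinstance(agents, Mapping):
        agent_list = list(agents.values())
    else:
        agent_list = list(agents)
    by_name = {
        name: grp for name, grp in resolver.groupby("canonical_name", sort=False)
    }
    edges: list[tuple[str, str]] = []
    no_targets: list[str] = []
    ambiguous: dict[str, list[str]] = {}
    for ag in agent_list:
        grp = by_name.get(ag.canonical_name)
        if grp is None:
            no_targets.append(ag.canonical_name)
            continue
        idents = sorted(set(grp["identifier"].dropna()))
        if len(idents) > 1:
            ambiguous[ag.canonical_name] = idents
            continue
        genes = sorted(set(grp["gene_symbol"].dropna()))
        if not genes:
            no_targets.append(ag.canonical_name)
            continue
        ag.targets = set(genes)
        edges.extend((ag.canonical_name, g) for g in genes)
    graph = DrugTargetGraph(edges)
    report = {
        "n_agents": len(agent_list),
        "n_resolved": len(graph.drugs),
        "no_targets": sorted(no_targets),
        "ambiguous": ambiguous,
    }
    return graph, report


def write_harmonization(outdir, agents: Mapping[str, HarmonizedAgent],
                        graph: DrugTargetGraph, report: dict) -> None:
    """Write agents.tsv, edges.tsv and merge/resolution reports under outdir."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{"canonical_name": a.canonical_name,
             "raw_names": ";".join(sorted(a.raw_names)),
             "nct_ids": ";".join(sorted(a.nct_ids)),
             "targets": ";".join(sorted(a.targets))}
            for a in agents.values()]
    pd.DataFrame(rows).sort_values("canonical_name").to_csv(
        out / "agents.tsv", sep="\t", index=False)
    graph.to_frame().to_csv(out / "edges.tsv", sep="\t", index=False)
    with open(out / "resolution_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
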