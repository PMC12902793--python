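"""Gene-level ORA of the top-risk set and biodomain assignments.

Runs hypergeometric overrepresentation of the top-risk genes over the
term system, maps significant terms onto biodomains/subdomains, and assigns
a headline biodomain to every gene in the trial ∩ top-risk overlap with the
three-quantity heuristic.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS  # noqa: E402

from adtargets.biodomain import (  # noqa: E402
    TermSystem, assign_top_biodomain, gene_set_ora,
    map_enrichment_to_biodomains,
)
from adtargets.setcompare import top_fraction  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=RESULTS / "sim")
    ap.add_argument("--out", type=Path, default=RESULTS / "biodomains")
    args = ap.parse_args()

    risk = pd.read_csv(args.sim / "risk.tsv", sep="\t")
    edges = pd.read_csv(args.sim / "edges.tsv", sep="\t")
    terms = TermSystem.from_frames(
        pd.read_csv(args.sim / "annotations.tsv", sep="\t"),
        pd.read_csv(args.sim / "biodomains.tsv", sep="\t"))

    import json
    fraction = json.loads((args.sim / "manifest.json").read_text())["top_fraction"]
    top = top_fraction(risk, fraction)
    in_universe = top & set(terms.universe)
    print(f"{len(in_universe)} of {len(top)} top-risk genes are annotated")
    ora = gene_set_ora(in_universe, terms, min_size=10, max_size=500)
    n_sig = (ora["fdr"] <= 0.05).sum()
    print(f"ORA: {n_sig} of {len(ora)} terms at FDR <= 0.05")

    mapped, report = map_enrichment_to_biodomains(ora, terms, fdr_cut=0.05)
    overlap = sorted(top & set(edges["gene"]))
    assignments = pd.DataFrame(
        [{"gene": g, "top_biodomain": assign_top_biodomain(g, terms)}
         for g in overlap])
    counts = assignments["top_biodomain"].value_counts()
    print("headline biodomains of the trial ∩ top-risk genes:")
    print(counts.to_string())

    args.out.mkdir(parents=True, exist_ok=True)
    ora.to_csv(args.out / "ora.tsv", sep="\t", index=False)
    mapped.to_csv(args.out / "biodomain_enrichment.tsv", sep="\t", index=False)
    assignments.to_csv(args.out / "assignments.tsv", sep="\t", index=False)
    print(f"wrote ora/enrichment/assignments -> {args.out} "
          f"({report['n_unmapped']} unmapped terms)")


if __name__ == "__main__":
    main()
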