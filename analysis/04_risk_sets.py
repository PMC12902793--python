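"""Compare the trial-target set against the genome-wide risk ranking.

Selects the top risk tail (fraction from the simulation manifest, so the
tail is comparable in size to the trial-target set), tests the trial-target
overlap with
Fisher's exact test (the planted overlap probability is 0.3, so the test
should reject decisively), compares score distributions for trial targets
vs all other genes with K-S statistics, and summarizes target development
levels for both sets.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS  # noqa: E402

from adtargets import setcompare as sc  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=RESULTS / "sim")
    ap.add_argument("--out", type=Path, default=RESULTS / "risk_sets")
    args = ap.parse_args()

    risk = pd.read_csv(args.sim / "risk.tsv", sep="\t")
    edges = pd.read_csv(args.sim / "edges.tsv", sep="\t")
    tdl = pd.read_csv(args.sim / "tdl.tsv", sep="\t")
    trial = set(edges["gene"])
    universe = set(risk["gene"])

    fraction = json.loads((args.sim / "manifest.json").read_text())["top_fraction"]
    top = sc.top_fraction(risk, fraction)
    ov = sc.overlap_fisher(trial, top, universe)
    print(f"trial targets: {len(trial)}; top {fraction:.0%}: {len(top)} genes")
    print(f"overlap {ov.a}/{ov.a + ov.b} ({ov.percent_of_first}% of trial set), "
          f"Fisher p = {ov.p:.3g}, sample OR = {ov.odds_sample:.2f}, "
          f"conditional-MLE OR = {ov.odds_cmle:.2f}")

    ks = {score: sc.ks_gene_scores(risk, trial, score=score)
          for score in ("total", "genetics", "omics")}
    for score, res in ks.items():
        print(f"K-S {score:8s}: D = {res.D:.3f}, p = {res.p:.3g}, "
              f"trial targets {res.direction}")

    props_trial, _ = sc.tdl_proportions(trial, tdl)
    props_top, _ = sc.tdl_proportions(top, tdl)
    print(f"TDL proportions (trial | top {fraction:.0%}):")
    for level in sc.TDL_LEVELS:
        print(f"  {level}: {props_trial[level]:.3f} | {props_top[level]:.3f}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "top_targets.txt").write_text("\n".join(sorted(top)) + "\n")
    (args.out / "overlap.json").write_text(json.dumps({
        "a": ov.a, "b": ov.b, "c": ov.c, "d": ov.d, "p": ov.p,
        "odds_sample": ov.odds_sample, "odds_cmle": ov.odds_cmle,
        "percent_of_first": ov.percent_of_first}, indent=2))
    (args.out / "ks.json").write_text(json.dumps(
        {s: {"D": r.D, "p": r.p, "direction": r.direction}
         for s, r in ks.items()}, indent=2))
    pd.DataFrame([{"set": "trial", **props_trial},
                  {"set": "top1pct", **props_top}]).to_csv(
        args.out / "tdl_proportions.tsv", sep="\t", index=False)
    print(f"wrote overlap/ks/tdl tables -> {args.out}")


if __name__ == "__main__":
    main()
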