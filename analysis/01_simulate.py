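"""Generate the synthetic study inputs.

Writes every table the downstream drivers consume under results/sim/:
trial records from two overlapping sources with decorated agent names, the
planted drug–target graph, term annotations with biodomain labels, the
risk-score table with trial targets planted into the top tail, TDL
assignments, the disease signature, and 30 perturbation profiles.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, study_config  # noqa: E402

from adtargets.synthetic_data import simulate_all  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=RESULTS / "sim")
    args = ap.parse_args()

    cfg = study_config(args.seed)
    paths = simulate_all(cfg, args.out)
    print(f"study seed {cfg.seed}: {cfg.n_drugs} agents, {cfg.n_genes} genes, "
          f"{cfg.n_domains * cfg.terms_per_domain} terms")
    for name, path in sorted(paths.items()):
        print(f"  wrote {name:24s} -> {path}")


if __name__ == "__main__":
    main()
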