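"""Shared study conditions for the numbered analysis drivers.

One synthetic study powers the whole pipeline: 200 trial agents with
heavy-tailed polypharmacology over 2,000 genes, 50 annotation terms in 5
biodomains, one term ("T0000") with a planted excess drug-hit probability of
0.5, trial targets planted into the top-1% risk tail with probability 0.3,
and 30 perturbation profiles of which 5 reverse the disease signature
(alpha = -1) and 25 mimic it (alpha = +1).
"""

from pathlib import Path

from adtargets.synthetic_data import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(seed: int = 0) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_drugs=200,
        n_genes=2000,
        target_pool_size=80,
        planted_terms=(("T0000", 0.5),),
        top_fraction=0.05,
        planted_top_fraction_overlap=0.3,
        signature_alphas=(-1.0,) * 5 + (1.0,) * 25,
        n_trials_per_source=300,
    )
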