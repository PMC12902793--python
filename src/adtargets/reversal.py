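"""Transcriptomic reversal screening of perturbation profiles.

Given per-gene log fold changes measured after perturbing a target
(e.g., CRISPRa activation or CRISPRi interference in iPSC-derived neurons,
astrocytes, or microglia) and a disease meta-analysis signature of per-gene
log fold changes, this module correlates each perturbation response with the
disease signature within biodomain-restricted gene sets. Cells with a
significant positive correlation move the transcriptome *toward* the disease
state; significant negative correlations mark candidate *reversal*
perturbations that shift expression away from it.

The screen is descriptive: a reversal flag ranks candidates for functional
follow-up and is not a prediction of clinical efficacy — receptor dynamics,
dosage, and tissue-level feedback are outside this paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .perm_enrichment import bh_adjust

__all__ = [
    "PerturbationProfile", "DiseaseSignature",
    "signature_correlation", "reversal_screen", "reversal_candidates",
]

MIN_SHARED_GENES = 3


@dataclass
class PerturbationProfile:
    """One (target, modality, cell type) perturbation's per-gene responses."""

    target: str
    modality: str  # e.g. "activation" (CRISPRa) or "inhibition" (CRISPRi)
    cell_type: str
    logfc: pd.Series = field(repr=False)  # gene -> log fold change

    def __post_init__(self):
        self.logfc = pd.Series(self.logfc, dtype=float)

    @property
    def label(self) -> str:
        return f"{self.target}|{self.modality}|{self.cell_type}"


@dataclass
class DiseaseSignature:
    """Meta-analysis per-gene log fold changes defining the disease state."""

    values: pd.Series = field(repr=False)

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)
        finite = np.isfinite(self.values.dropna())
        if not bool(finite.all()):
            raise ValueError("signature contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def signature_correlation(profile: PerturbationProfile,
                          signature: DiseaseSignature,
                          genes: Iterable[str] | None = None,
                          method: str = "pearson",
                          ) -> tuple[float, float, int] | None:
    """Correlate a perturbation response with the disease signature.

    Restricted to ``genes`` (default: all shared genes), complete-case:
    genes missing or NaN in either map are dropped. Returns ``(r, p, n)``
    with a two-sided p from the t-transform, or ``None`` when fewer than
    three genes are shared — an untestable cell, not an error.
    """
    x = profile.logfc.dropna()
    y = signature.values.dropna()
    shared = x.index.intersection(y.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(set(genes)))
    n = len(shared)
    if n < MIN_SHARED_GENES:
        return None
    if method == "pearson":
        r, p = stats.pearsonr(x.loc[shared], y.loc[shared])
    elif method == "spearman":
        r, p = stats.spearmanr(x.loc[shared], y.loc[shared])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n


def _direction(r: float) -> str:
    if r > 0:
        return "toward_disease"
    if r < 0:
        return "away_from_disease"
    return "none"


def reversal_screen(profiles: Sequence[PerturbationProfile],
                    signature: DiseaseSignature,
                    domain_gene_sets: Mapping[str, Iterable[str]],
                    alpha_fdr: float = 0.05,
                    method: str = "pearson") -> pd.DataFrame:
    """Correlate every (perturbation, biodomain) cell; BH across the matrix.

    Returns one row per cell: target, modality, cell_type, biodomain, n, r,
    p, p_adj, significant, direction. Untestable cells (< 3 shared genes)
    are kept with ``testable=False`` and excluded from the BH family; the
    multiple-testing family is all testable cells of the run.
    """
    rows = []
    for prof in profiles:
        for domain, genes in sorted(domain_gene_sets.items()):
            res = signature_correlation(prof, signature, genes, method=method)
            row = {"target": prof.target, "modality": prof.modality,
                   "cell_type": prof.cell_type, "biodomain": domain}
            if res is None:
                row.update({"n": 0, "r": np.nan, "p": np.nan, "testable": False})
            else:
                r, p, n = res
                row.update({"n": n, "r": r, "p": p, "testable": True})
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty or not out["testable"].any():
        raise ValueError("no testable (profile, biodomain) cells")
    out["p_adj"] = np.nan
    testable = out["testable"]
    out.loc[testable, "p_adj"] = bh_adjust(out.loc[testable, "p"])
    out["significant"] = testable & (out["p_adj"] <= alpha_fdr)
    out["direction"] = [_direction(r) if t else "none"
                        for r, t in zip(out["r"], out["testable"])]
    return out


def reversal_candidates(screen: pd.DataFrame) -> list[str]:
    """Targets significantly anti-correlated with disease in >= 1 biodomain."""
    mask = screen["significant"] & (screen["direction"] == "away_from_disease")
    return sorted(screen.loc[mask, "target"].unique())
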