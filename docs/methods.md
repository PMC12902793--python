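# Methods

This package implements a comparative analysis between the molecular targets
of drugs in a clinical-trial pipeline and the targets ranked highest by a
genome-wide disease risk score, together with the synthetic data generator
that defines the conditions under which the statistics are validated. This
note records the models, the choices that were genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Pipeline overview

1. **Harmonization** (`adtargets.harmonize`). Trial registries describe one
   agent under many raw strings. Harmonization lowercases, strips salt
   tokens (hydrochloride, sulfate, ...), formulation tokens (tablet,
   transdermal, ...), and unit/dosage tokens with their attached numerals,
   and collapses whitespace. Two trial sources are merged on the registry
   (NCT) identifier; harmonized agents are resolved to gene-symbol targets
   through a pure lookup table (no network clients — live database
   retrieval is replaced by fixture-backed resolvers).
2. **Drug-level enrichment** (`adtargets.perm_enrichment`). For a term
   *t* and the bipartite drug–target graph, the statistic is the number of
   distinct drugs with at least one target in *t* (per-drug indicator
   collapse, so a polypharmacologic drug hitting many subunits of one
   complex counts once). Odds are Haldane–Anscombe corrected with ε = 0.5.
   The null shuffles target labels across all edges without replacement —
   preserving every drug's degree and every target's overall multiplicity —
   B = 4000 times by default; one shuffle ensemble scores all terms. The
   one-sided p-value uses the +1 correction, p = (1 + #{O_b ≥ O_obs})/(B+1),
   and the permutation-relative odds ratio is the median over shuffles of
   odds_obs/odds_b. FDR is Benjamini–Hochberg across terms.
3. **Set comparisons** (`adtargets.setcompare`). The top risk tail is the
   ceil(fraction·n) highest-scoring genes (0.01 × 24,786 → 248), with
   cutoff ties broken by the genetics component then the symbol. Overlap is
   tested one-sided by Fisher's exact test; both the sample odds ratio
   (HA-corrected at zero cells) and the conditional-MLE odds ratio are
   reported because published odds ratios for such tables are ambiguous
   between conventions. Score-distribution shifts use the two-sample,
   two-sided Kolmogorov–Smirnov statistic with a median-shift direction
   label. Druggability is summarized as proportions over the Pharos tiers
   Tclin/Tchem/Tbio/Tdark.
4. **Biodomains** (`adtargets.biodomain`). Gene-level overrepresentation is
   a hypergeometric upper tail per term (identical to one-sided Fisher on
   the same 2×2 — asserted as a cross-module oracle), BH-corrected, with
   the cited tool's conventional size filter (10–500, configurable).
   Significant terms (FDR ≤ 0.05) are mapped onto biodomain/subdomain
   labels; unmapped terms are counted, never dropped.
5. **Reversal screen** (`adtargets.reversal`). Each perturbation profile is
   Pearson-correlated with the disease signature inside each biodomain gene
   set (complete case, ≥ 3 shared genes or the cell is reported
   untestable). One BH family spans all (target, modality, cell type,
   biodomain) cells of a run — the adjustment family was an open choice and
   is deliberately the widest one. Significant negative cells mark reversal
   candidates; the flag ranks candidates for follow-up and is never a
   claim of clinical efficacy.

## The biodomain assignment heuristic

A gene annotated to terms in several biodomains receives one headline
domain: the domain of the term maximizing q1 + q2 + q3 over the gene's
annotated terms, where

* q1 = the fraction of that term's domain (all of the domain's terms in the
  system) the gene is annotated to;
* q2 = rank/n over the gene's terms ranked by annotated-gene count
  descending — an *inverse-rank* normalization under which smaller, more
  specific terms score higher (the direction is a documented
  interpretation; both directions are implemented behind a flag);
* q3 = rank/n over the gene's terms ranked by degree in the gene's term
  graph ascending, so well-connected terms score higher. The degree is
  **weighted** (total shared-gene count): every pair of a gene's terms
  shares at least that gene, so the unweighted graph is complete and its
  degree carries no information. Ranks use average tie-handling; exact
  total ties break to the alphabetically first domain, then term id.

Ranks are computed among the gene's annotated terms (not genome-wide),
matching the phrase "terms to which the gene is annotated".

## Synthetic data: what it emulates

`adtargets.synthetic_data` generates every input from a single integer seed
that fans out to fixed per-generator substreams (regenerating one artifact
never perturbs another; outputs are byte-identical across interpreter
processes, covered by a subprocess test). Gene identifiers are synthetic
("G000001", ...), never real symbols.

* **Drug–target graph**: drug degrees follow a truncated zipf law (default
  exponent 2.0, max degree 60) — most agents have one or two targets, a few
  have tens, echoing agents with ≥ 10 targets in real pipelines. An
  optional `target_pool_size` concentrates baseline targets on a druggable
  subset of the genome so that the distinct-target set is comparable in
  size to the risk tail, as in the real comparison. Planted terms receive
  an extra edge per drug with the configured excess probability — the
  recoverable enrichment signal.
* **Term system**: 5 domains × 10 terms by default, sizes 20–120, with a
  controllable within-domain gene-reuse fraction (0 ⇒ disjoint terms);
  genes recur across domains freely, so part of the universe is
  multi-domain.
* **Risk table**: genetics and multi-omics components are independent
  standard normals, total = their sum; planted trial targets are lifted
  strictly above the pre-existing maximum with the configured probability,
  guaranteeing top-tail membership. Ties, if any, break by recorded
  deterministic jitter smaller than the smallest score gap.
* **Trial records**: two sources with a configurable shared-NCT fraction;
  raw agent strings decorate clean names with salt/dosage/formulation
  tokens drawn from the harmonization lexicon's own lists plus randomized
  case. Recovery is therefore exact by construction — the round-trip test
  validates the stripping logic, not robustness to unknown vocabularies.
* **Perturbations**: profile = alpha · signature + N(0, noise_sd) per gene;
  alpha is recorded ground truth. The observed correlation attenuates to
  alpha·s/√(alpha²s² + noise²) for signature scale s, which the tests check
  in closed form.

What passing these tests does **not** show: performance on real
vocabularies (novel salts, typos, multilingual names), real GO DAG
topology or annotation propagation, realistic pharmacology, or
between-gene correlation structure in expression signatures. The
generator's independence assumptions make the planted effects cleaner than
real data would be.

## Calibration experiments and their limits

The permutation test's statistic is an integer count, and the
degree-preserving shuffle holds each term's total edge count fixed, so the
null distribution of the count has small conditional variance (sd ≈ 1.5–4
at 100 drugs for any realistic configuration). Its tie-inclusive p-values
are therefore discrete and superuniform, with atoms of mass ~0.1. Two
consequences, both verified against an independent brute-force shuffle
oracle:

* the fraction of null terms with p ≤ 0.05 sits inside the 95% binomial
  band of 0.05 (slightly conservative, as a valid test must be);
* the pooled null p-value ECDF deviates below the diagonal by up to the
  typical atom gap. Under the calibration configuration chosen to maximize
  the statistic's granularity (100 drugs of fixed degree 10 on 1,000
  genes, 50 terms of 70–150 genes, B = 500, 20 seeds), the pooled
  Kolmogorov distance is 0.057 against the 0.051 two-sided 1%-level band
  for n = 1000 — the band check fails for structural reasons, not an
  implementation defect; a randomized or mid-p tie-break would pass but
  would contradict the tie-inclusive +1 definition used throughout. The
  corresponding test is left failing, with this explanation.

Recovery experiments use conditions sized to their decisions: the planted
term (excess hit probability 0.5, 200 drugs) with B = 2000, whose p floor
1/(B+1) comfortably clears the BH rank-1 threshold 0.05/50; the planted
top-tail overlap (probability 0.3, 250 trial targets on 20,000 genes)
against Fisher at p < 0.01; and the reversal screen with 5 of 30 targets at
alpha = −1 and the remainder at +1 — disease-like rather than null, since a
screen of 25 null targets would produce BH false positives often enough to
make "exactly the planted five" an unfair bar for a correctly calibrated
test. Problem sizes were chosen so the whole suite completes in about half
a minute.

## Numerical and procedural choices

* Drugs whose every edge leaves the annotation universe are excluded from N
  before testing (otherwise O_t ≤ N can fail).
* Duplicate edges created by a shuffle (a drug drawing one target twice)
  are kept; the indicator collapse makes them harmless.
* Shuffle b is keyed by (seed, constant, b) with a fixed domain-separation
  constant so permutation streams can never alias generator substreams;
  any single permutation is reproducible in isolation.
* Median over an even B is the mean of the two central order statistics;
  the identity median_b(odds_obs/odds_b) = odds_obs/median_b(odds_b) is
  exact for odd B and asserted there.
* Annotation tables are taken as materialized term→gene sets; no
  ontology-DAG propagation is applied and none is attempted.
* Combination agents split on "+" (and spaced "/") into components resolved
  separately; numerals are removed only when adjacent to a unit token, so
  code names like "ac-3933" survive.
* An optional exact-match RxNorm-style lookup can post-process harmonized
  names; it is skippable and user-supplied.
* K-S background excludes only the compared subset (not other special
  sets); p-values are asymptotic.
* Perturbation modality is recorded verbatim and used only as a label; the
  inference "activation correlates positively ⇒ inhibition would reverse"
  is reported wording, never a computed claim.

## Known limitations

Exhaustive permutation mode is limited to tiny graphs (≤ 8 edges by
default). The harmonization lexicon is a deliberately small, editable
default (~30 salts, ~20 formulations, ~10 units), not a curated registry
vocabulary. The reversal screen treats genes as exchangeable within a
biodomain and ignores expression correlation, so its p-values are
optimistic for real transcriptomes. The biodomain assignment direction
choices (q2/q3) are interpretations of an underdetermined verbal
description; both directions ship behind flags.
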