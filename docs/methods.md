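# Methods

This note defines the model and procedures implemented by `hrdscar`, the
default parameters, and the numerical/design decisions that are not
obvious from the code.

## Mutation contexts (142 categories)

**SNVs (96).** Each substitution is read off the pyrimidine strand
(purine references are reverse-complemented together with their flanks)
and keyed as `5'[REF>ALT]3'`, e.g. `A[C>T]G`.

**Indels (30).** After VCF-padding removal and left-alignment against the
reference, each pure insertion/deletion of sequence `S` (length `L`) is
classified by the flanking sequence, searching a window of `L` bp on each
side:

1. *Repeat* — the `L` bp immediately downstream are a full copy of `S`
   and `L` < 50 bp. This rule takes precedence.
2. *Microhomology* — any of: a full copy of `S` on either side when
   `L` ≥ 50 bp; ≥ 2 bp of flanking identity; or ≥ 1 bp of identity when
   `L` ≥ 3 bp. The homology length `bimh` is the larger of the downstream
   prefix match and the upstream suffix match of `S`.
3. *None* — otherwise.

Keys are `del.rep.len.N` / `ins.rep.len.N` / `del.mh.bimh.N` /
`ins.mh.bimh.N` / `del.none.len.N` / `ins.none.len.N` with `N` capped at
5 (1, 2, 3, 4, ≥5), giving 30 categories.

**SVs (16).** DEL/DUP/INV binned by length (1–10 kb, 10–100 kb,
100 kb–1 Mb, 1–10 Mb, > 10 Mb; lower bound inclusive) plus translocations
(`TRA`, no length). SVs shorter than 1 kb are excluded
(`sv_min_length=1000`): below typical short-read SV-caller resolution and
overlapping the indel regime.

**MSI.** A sample with **more than 14,000** repeat-bin indels is flagged
microsatellite-instable; its repeat-driven indel load obscures the HRD
scar, so such samples are excluded from training and flagged at
prediction time.

## Features (29)

Counts are collapsed to relative contributions **within each mutation
class** (SNV, indel, SV blocks each sum to 1, or are all zero when the
class is empty):

* 6 substitution types (`C>A` … `T>G`),
* 7 indel features: `del.mh.bimh.1`, `del.mh.bimh.2.5` (bimh 2–≥5
  pooled), `ins.mh`, `del.rep`, `ins.rep`, `del.none`, `ins.none`,
* the 16 SV bins unchanged.

The split of microhomology deletions at bimh 1 vs ≥ 2 matters: only the
≥ 2 bp fraction is the MMEJ footprint. A 28-feature variant with the two
deletion-microhomology features merged is provided for comparison, as is
an alternative front-end that replaces raw SNV/SV fractions with NNLS
signature contributions (`scipy.optimize.nnls`) against user-supplied
signature matrices. No signature matrices are shipped: the standard
catalogs are external, versioned data and the raw-context features are
the package default.

## Classifier

A three-class random forest (`BRCA1`, `BRCA2`, `none`; scikit-learn,
500 trees, `max_features="sqrt"`) on the 29 features.

* `p_hrd = p(BRCA1) + p(BRCA2)`; `p_hrd ≥ 0.5` → HRD, subtype is the
  larger of the two (ties → BRCA2-type, the more common deficiency).
* **Feature pre-selection**: one-sided Wilcoxon rank-sum (feature higher
  in deficient samples), p < 0.01; exact enumeration for group sizes
  ≤ 10 without ties, normal approximation otherwise.
* **Class resampling**: "none" down-sampled without replacement by factor
  d ∈ {1, 2, 4}; BRCA1 up-sampled with replacement by u ∈ {1, 1.5, 2}
  (originals always kept). The pair is chosen once by 10-fold
  cross-validated pooled out-of-fold AUPRC of `p_hrd`; ties go to the
  first cell in row-major order (least resampling).
* **Blacklisting** (`train_full`): the core training runs inside a
  10-fold CV loop repeated 100 times (feature selection per fold);
  deficient-labelled samples called HRD in < 60% of repeats and
  "none" samples called HRD in > 40% are dropped, then the core training
  runs once on the filtered set. The resampling grid search runs once up
  front rather than inside every repeat — at 100 repeats the nested
  search would dominate runtime while the selected cell is stable.
* **QC flags**: `MSI` (repeat indels > 14,000), `LOW_INDEL` (< 50
  indels), and `LOW_SV` (< 30 SVs, applied only to HRD calls since the
  subtype rests on SV features).

## Biallelic gene status

Per gene and sample, events are scored 0–5 (P-scores):

* Clinical significance takes precedence: pathogenic 5, likely
  pathogenic 4, VUS 3, likely benign 2, benign 1.
* Otherwise by predicted effect: out-of-frame frameshift 5,
  nonsense/canonical splice 4, missense/inframe/essential-splice 3,
  other 2.
* Germline variants seen in more than 1% of cohort germlines are marked
  benign (P = 0); the threshold is configurable.
* LOH (minimum minor-allele CN **< 0.2** over segments overlapping the
  gene) scores 5. Deep deletion (minimum total CN **< 0.3**) is complete
  loss: BP = 10 outright.

The biallelic pathogenicity score **BP = P(a) + P(b)** of the best
allele-pair (two variants — never two germline; or LOH plus a variant);
BP = 10 → deficient. Greedy tie-break among equal scores: deep deletion
> LOH+frameshift > LOH+other variant, matching the clustering display
order. Training labels: both-gene proficiency (no deep deletion, no LOH,
no variant above VUS) → `none`; BP = 10 in one gene (and not MSI) → that
gene's class; everything else unlabeled. HRD-cause calling uses looser
thresholds (deep deletion; LOH + germline P ≥ 4; LOH + somatic P ≥ 3;
two P = 5 variants) — a strict superset of the training rule.

## Cohort analyses

* **Enrichment**: per-gene one-tailed Fisher's exact test on the 2×2
  deficient × HRD table; Hochberg step-up correction (statsmodels
  `simes-hochberg`, equal to R's `p.adjust(method="hochberg")`). The gene
  universe is pluggable; `default_gene_universe()` provides a 781-symbol
  placeholder list guaranteed to contain the HRD priority genes.
* **CNA co-occurrence**: the same test between each gene's CNA state and
  an anchor gene's, flagging passengers linked by chromosomal proximity.
* **Clustering**: HRD samples split 4 ways by subtype (BRCA2-type first)
  and by presence of an *impactful* biallelic event (P-score pair of 5
  and ≥ 3) in any priority gene (`BRCA2 > BRCA1 > RAD51C > PALB2`).
  Impactful samples are greedily assigned the max-BP gene (ties by
  priority); consecutive same-gene samples form clusters, internally
  ordered deep deletion > LOH+frameshift > LOH+other. Each non-impactful
  group is one "unknown cause" cluster. The result is independent of
  input order.

## Synthetic data generator

The generator serves the tests; it emulates the *feature-level* contrasts
the classifier exploits, not genome biology:

* Per sample, SNV/indel/SV counts are drawn Poisson (loads 5,000 / 300 vs
  600 / 100–250) and split over contexts by a Dirichlet-multinomial
  around class means (concentration 150 — tight enough for learnable
  classes, loose enough for overlap).
* HRD samples put 45% of indels in deletion-microhomology (vs 8%), with
  85% of that mass at bimh ≥ 2 (vs 40%); BRCA1 samples put 40% of SVs in
  the two small-duplication bins (vs 5%).
* `CohortEffects.null()` removes **all** class differences, giving the
  negative control (feature AUROC ≈ 0.5).
* `plant_variants` places individual variants so that profile extraction
  returns an exact requested context spectrum: candidate positions are
  drawn and verified through the classifier itself (rejection sampling).
  This is sound as ground truth because the classifier's correctness is
  established independently, against a brute-force literal-rule oracle.

Not emulated: chromatin/replication-timing covariates, signature
etiologies beyond the HRD-relevant contrasts, subclonal structure, purity.

## Problem sizes and runtimes

Defaults target a few hundred samples × 29 features — seconds to train.
The test suite uses cohorts of 30–300 samples, 60–100 trees, reduced
grids, and blacklisting at repeats = 25 (a scaled stand-in for the
default 100), keeping the full suite within minutes on one CPU.

## Numerical conventions

* Internal coordinates are 0-based half-open; VCF (1-based) conversion
  happens only in the I/O layer. Breakend (BND) mate pairs are typed from
  the lower mate's orientation: `t[p[` → DEL-like, `]p]t` → DUP-like,
  mixed → INV; inter-chromosomal → TRA.
* All thresholds use strict inequalities exactly as stated above
  (e.g. total CN 0.3 is *not* a deep deletion).
* All randomness flows through `numpy.random.default_rng` seeds; derived
  seeds stay below 2³¹. Pipeline reruns with the same manifest are
  byte-identical.
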