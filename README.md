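# hrdscar

Mutational-scar classification of homologous recombination deficiency
(HRD) in tumor genomes, with BRCA1-type / BRCA2-type subtyping, biallelic
gene-inactivation scoring, and cohort-level enrichment analysis.

## The problem

Tumors that have lost homologous recombination repair (most often through
biallelic inactivation of *BRCA1* or *BRCA2*) are sensitive to PARP
inhibitors and platinum chemotherapy, but the causal mutation is not
always found. The repair defect, however, leaves characteristic **scars**
throughout the genome:

* deletions flanked by short stretches of **microhomology**, the footprint
  of microhomology-mediated end joining taking over double-strand-break
  repair — enriched in all HRD tumors;
* small (1–100 kb) **tandem duplications**, specifically marking
  BRCA1-type HRD;
* characteristic shifts in structural-variant and base-substitution
  spectra.

`hrdscar` reads a tumor's somatic variants, counts them into 142 mutation
contexts (96 trinucleotide substitution types, 30 indel types
distinguished by flanking repeat/microhomology sequence, 16 structural
variant type×length bins), collapses those to 29 within-class relative
contributions, and classifies the sample with a three-class random forest
(`BRCA1` / `BRCA2` / `none`). The predicted HRD probability is
`p(BRCA1) + p(BRCA2)`; samples at or above 0.5 are called HRD and
subtyped by the larger of the two class probabilities.

Around the classifier, the package implements the full supporting
machinery:

* **Genotype side** — per-gene biallelic-status scoring from copy-number
  segments plus annotated variants (deep deletion, LOH, pathogenicity
  scores), HRD-cause calling, and training-label derivation (including
  exclusion of microsatellite-instable samples, whose repeat-indel load
  masks the scar).
* **Training machinery** — one-sided rank-sum feature pre-selection,
  class-resampling grid search, and blacklisting of samples whose
  out-of-fold predictions repeatedly contradict their genetic label.
* **Cohort analysis** — one-tailed Fisher enrichment of gene deficiency
  in HRD vs HRP samples (Hochberg-adjusted), a copy-number co-occurrence
  test that exposes passenger genes linked to an anchor gene, and the
  ordered clustering of HRD samples by subtype and causal gene.
* **Synthetic fixtures** — deterministic fixture genomes, exact planting
  of variants per context, and a parametric cohort generator used
  throughout the test suite.

## Worked example

Classify individual variants into contexts and build features:

```python
from hrdscar import (InMemoryGenome, SmallVariant, StructuralVariant,
                     classify_indel_context, classify_sv_context,
                     extract_profile, build_scar_features)

genome = InMemoryGenome({"chr1": "TTAGCAGTTCCGGTATAGCAATT"})
v = SmallVariant("chr1", 2, "TAGC", "T")     # deletes AGC after position 2
print(classify_indel_context(v, genome))

sv = StructuralVariant("DUP", 50_000)
print(classify_sv_context(sv))

profile = extract_profile([v], [sv], genome)
f = build_scar_features(profile)
print(f[f > 0].round(3).to_string())
```

Output:

```
del.mh.bimh.2
DUP_1e04_1e05_bp
del.mh.bimh.2.5     1.0
DUP_1e04_1e05_bp    1.0
```

The deleted `AGC` is followed by `AGT` — 2 bp of flanking identity, so
the deletion lands in the microhomology bin with `bimh=2`, which the
feature collapse pools into `del.mh.bimh.2.5` (the strongest single HRD
marker).

Train on a synthetic cohort and predict held-out samples:

```python
from hrdscar import simulate_cohort, core_train
from hrdscar.classifier import predictions_to_frame
from hrdscar.config import ForestParams

X, y = simulate_cohort(30, 30, 120, seed=7)         # BRCA1 / BRCA2 / none
model = core_train(X, y, seed=7, forest=ForestParams(n_trees=100))
print(model.feature_importances().sort_values(ascending=False).head(3).round(3))

Xt, yt = simulate_cohort(10, 10, 40, seed=8)
frame = predictions_to_frame(model.predict(Xt))
print(frame.loc[["BRCA1_003", "BRCA2_004", "none_011", "none_032"]].round(3).to_string())
```

Output:

```
del.mh.bimh.2.5     0.568
DUP_1e03_1e04_bp    0.208
DUP_1e04_1e05_bp    0.200
dtype: float64
           p_BRCA1  p_BRCA2  p_none  p_hrd hr_status    hrd_type    qc
sample
BRCA1_003      1.0     0.00    0.00   1.00       HRD  BRCA1-type  PASS
BRCA2_004      0.0     0.99    0.01   0.99       HRD  BRCA2-type  PASS
none_011       0.0     0.00    1.00   0.00       HRP        none  PASS
none_032       0.0     0.00    1.00   0.00       HRP        none  PASS
```

The importance ranking recovers the designed biology: microhomology
deletions dominate the HRD/HRP split and the two small-duplication bins
separate the subtypes.

### Command line

The same pipeline is exposed as `hrdscar` subcommands:

```bash
hrdscar simulate --n-b1 30 --n-b2 30 --n-none 120 --seed 7 --out-prefix cohort
hrdscar train --features cohort.features.tsv --labels cohort.labels.tsv \
              --core --seed 7 --out model.joblib
hrdscar predict --model model.joblib --features cohort.features.tsv --out preds.tsv
hrdscar extract --vcf sample.vcf --sv-vcf sample.sv.vcf --ref ref.fa \
                --sample s1 --out profile.tsv
hrdscar biallelic --genes genes.tsv --copynumber cn.tsv --sample s1 --out calls.tsv
hrdscar enrich  --deficiency defic.tsv --hrd-calls preds.tsv --out enrich.tsv
hrdscar cluster --predictions preds.tsv --gene-calls calls.tsv --out clusters.tsv
```

## Testing and reproduction

```bash
pytest -q                                   # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recovers the toolkit's structural thresholds by
sweeping synthetic inputs through the public API (MSI boundary, QC
minimum indel count, deep-deletion and LOH copy-number boundaries, LOH
P-score, deep-deletion BP-score) and writes them as JSON. All sweeps are
deterministic; the `--seed` argument is accepted for interface uniformity.

See `docs/methods.md` for the model definition, default parameters, and
the design decisions behind the synthetic data generator.
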