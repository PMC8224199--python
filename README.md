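# cohortsig

Cross-cohort concordance analysis of longitudinal microbiome signatures.

## What it does

After an intervention such as Roux-en-Y gastric bypass, gut microbiome
composition shifts. Individual studies report long lists of differentially
abundant taxa, but the interesting scientific question is *replication*: do
independent cohorts, sequenced and processed separately, recover the same
signature of change? `cohortsig` implements a complete desk-scale workflow for
that question:

1. **Per-study differential abundance.** Each study's count table is
   depth-normalized (`log10(count / depth × mean-depth + 1)`), features present
   in fewer than 10 % of samples are removed, and every feature is fit with a
   random-intercept linear mixed model `abundance ~ timepoint, random = ~1 |
   subject` with the pre-intervention baseline as reference. Each
   (study, post-timepoint) contrast yields a per-feature *signed log10 p-value*
   — `sign(effect) × (−log10 p)` — the signature statistic.
2. **Concordance.** Signatures are compared across every between-study pair of
   contrasts and every within-study pair of timepoints with Spearman rank
   correlation over shared features, with Benjamini–Hochberg FDR control over
   the whole comparison family and a Wilcoxon rank-sum contrast of
   within-study versus between-study correlations.
3. **Community-level structure.** Bray–Curtis dissimilarities, principal
   coordinates analysis, Shannon diversity, and a sequential two-factor
   PERMANOVA (`distance ~ study + timepoint`) quantifying how much community
   variance is batch (study) versus intervention (pre/post).
4. **Classifier transfer.** An L1-regularized logistic regression (or random
   forest) is trained per study under subject-grouped 8-fold × 10-repeat
   cross-validation on frozen z-scored `log10(relative abundance + 1e-5)`
   features, then evaluated on external studies and in leave-one-study-out
   (LOSO) pooling, with per-sample scores averaged across the model ensemble.

Because multi-cohort sequencing data cannot ship with a package, `cohortsig`
includes a synthetic multi-study generator with a *planted, partially shared*
intervention signature: the parameter `rho_between` tunes how much of each
study's signature is common across cohorts, so every stage of the analysis is
testable against ground truth.

## Worked example

Simulate four cohorts mimicking published 16S gastric-bypass studies
(30/25/19/9 subjects, unequal follow-up schedules, 60 % post-baseline
retention, `rho_between = 0.8`), scan them, and measure concordance:

```python
import pandas as pd
import cohortsig as cs

cfg = cs.SyntheticConfig(seed=7)          # default four-study design
studies = cs.simulate_multistudy(cfg)

sigs = []
for table, meta in studies:
    norm = cs.normalize_depth(cs.prevalence_filter(table))
    sigs.append(cs.signature_scan(norm, meta))
signatures = pd.concat(sigs, ignore_index=True)

results, tidy, summary = cs.concordance_analysis(signatures)
print("n signature rows:", len(signatures))
for kind in ("between", "within"):
    s = summary[kind]
    print(f"{kind} pairs: {s['n_pairs']}  mean rho = {s['rho_mean']:.3f} "
          f"(sd {s['rho_sd']:.3f})")
print(f"within vs between Wilcoxon p = {summary['within_vs_between_p']:.4f}")
print("pairs significant at q<0.05:", summary["n_significant_q05"])
```

With seed 7 this prints:

```
n signature rows: 799
between pairs: 23  mean rho = 0.150 (sd 0.147)
within pairs:  5  mean rho = 0.552 (sd 0.058)
within vs between Wilcoxon p = 0.0006
pairs significant at q<0.05: 11
```

The four-study follow-up design yields exactly 23 between-study and 5
within-study comparison pairs, and within-study concordance clearly exceeds
between-study concordance — the qualitative ordering the analysis is designed
to detect when half-shared signatures (`rho_between = 0.8` with study-specific
noise) drive the data.

## Command line

Every stage is also exposed as a CLI over a YAML config:

```yaml
# run.yaml
seed: 7
synthetic:
  n_studies: 4
n_perm: 999
model: lasso
```

```bash
cohortsig all --config run.yaml --out results/
# or stage by stage:
cohortsig simulate  --config run.yaml --out results/
cohortsig scan      --config run.yaml --out results/
cohortsig concord   --config run.yaml --out results/
cohortsig community --config run.yaml --out results/
cohortsig transfer  --config run.yaml --out results/
```

Outputs are plain TSV/JSON (`signatures.tsv`, `concordance.tsv`,
`permanova.tsv`, `ordination.tsv`, `shannon.tsv`, `transfer.tsv`,
`manifest.json`). Re-running an identical config reproduces every file
bit-identically; the manifest records the config hash and row counts and no
timestamps.

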