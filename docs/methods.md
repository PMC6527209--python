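# Methods

## Scope and data model

`aerodx` analyses OTU-by-sample abundance tables from multi-body-site 16S
studies of the aerodigestive tract. The unit of inference is the
*patient*: each patient contributes up to one sample per body site
(lung/BAL, oropharynx, gastric fluid, stool), annotated with a sequencing
batch and an aspiration status (`aspirator`, merging aspiration and
penetration on videofluoroscopic swallow study; `non_aspirator`;
`untested`). Body-site labels are normalised at parse time through an
alias map (e.g. "BAL" → lung, "oropharyngeal swab" → oropharynx) because
specimen and site names are used interchangeably in practice. Tables are
dense; at cohort scale (hundreds of samples, a few thousand OTUs) sparse
storage buys nothing. Counts are not rarefied or depth-filtered: alpha
diversity is computed on raw counts and everything else on per-sample
relative abundances, and all downstream statistics are rank- or
proportion-based, so library-size differences enter only through
detection (presence/absence) sensitivity.

## Beta diversity

The primary metric is the Jensen-Shannon distance: the square root of the
Jensen-Shannon divergence with **base-2 logarithms**, giving a true
metric bounded in [0, 1] (the base is a convention choice; base 2 makes
"1 = disjoint communities" exact). `0·log 0` is taken as 0, and the
mixture `m = (p+q)/2` is strictly positive wherever either input is, so
no pseudocounts are needed. Bray-Curtis is provided as a check that
conclusions are not metric-specific.

Cross-patient comparisons use only pairs of samples sequenced in the same
batch, because batch effects inflate between-sample distances;
within-patient comparisons need no restriction since a patient's samples
share a batch. Group summaries report medians. PERMANOVA (through
scikit-bio) uses the add-one permutation convention,
p = (1 + #{F* ≥ F}) / (1 + n_permutations).

The within- vs. across-patient comparison computes, per patient with both
sites of a pair, the within-patient cross-site distance and the mean
distance from each of the patient's two samples to all other patients'
same-site, same-batch samples, then applies Wilcoxon signed-rank tests
paired over patients. With fewer than 6 complete patients the signed-rank
test is meaningless and the operation refuses to run; when every paired
difference is zero the test is degenerate and NaN is reported.

## Exchanged-OTU detection

Detection uses patients with all three aerodigestive sites sampled. For
an OTU and a site pair (x, y) with third site z:

1. the patient set is those with relative abundance > 0 in *both* x and
   y; OTUs with fewer than `min_patients = 10` such patients are excluded
   from testing and from the multiple-testing family;
2. the statistic is the first-order partial Spearman correlation of x and
   y given z (average ranks on ties), with the third-site vector taken
   over the same patients, zeros retained;
3. the null distribution permutes y across patients (2,000 draws),
   keeping x and z paired — this breaks the x–y and z–y associations
   simultaneously, which is exactly the null of "no exchange beyond what
   the third site explains";
4. p = #{ρ*_null > ρ_obs} / n_permutations — a **one-sided, signed,
   strict-inequality** tail, since exchange is a positive-association
   hypothesis; p = 0 is attainable and the raw proportions go directly
   into Benjamini-Hochberg correction, applied **within one site pair**;
   q < 0.1 flags exchange.

Degenerate cases: a constant conditioning vector z carries no information
and its correlations are set to 0, reducing the statistic to the plain
Spearman correlation; a constant x or y, or a vanishing denominator
(|r_xz| = 1 or |r_zy| = 1), makes the statistic not-computable and the
OTU is excluded (NaN sentinel at the scalar level). Permutation draws
with vanishing denominators are NaN and never count as exceedances.

The permutation loop is vectorised (all 2,000 permutations ranked and
correlated as one matrix operation), which keeps full-cohort detection at
2,000 permutations to roughly a second per site pair.

**Null calibration.** To ask "how many exchanged OTUs would this pipeline
find if no exchange existed?", patient IDs are shuffled independently for
every OTU within every site and the entire detection (filter, permutation
test, BH) is re-run; the per-round counts and their maximum are reported.
The default is 10 rounds — enough to bound the typical null count, cheap
enough to run routinely — and the round count is configurable.

**Co-occurrence prevalence.** For a patient group, an OTU's prevalence is
the percentage of the group's patients (those with both sites sampled)
carrying it in both sites. The aspirator/non-aspirator contrast uses a
paired t-test over OTUs on log₁₀ prevalences; a zero prevalence is
replaced by the half-patient pseudo-prevalence 100·0.5/n_group before
taking logs (the paired test needs finite values, and half a patient is
the natural resolution limit). Identical prevalence vectors make the test
degenerate and are reported as p = 1.

## Group statistics

Aspiration contrasts exclude `untested` patients; they are never imputed.
Within-patient JSD contrasts and alpha-diversity contrasts use the
Wilcoxon rank-sum test. Differential abundance uses Kruskal-Wallis with
tie correction on relative abundances — retained even for two groups, for
fidelity to the rank-sum-equivalent analysis it generalises — with BH
correction per (site, taxonomic level) family and a q < 0.1 screen.
Taxa absent (or constant) across a site's samples are dropped before
testing to avoid zero-variance degeneracy. Reflux analyses report the
Spearman correlation between a per-patient covariate and the
within-patient lung-gastric distance, requiring at least 5 patients.

## Classifiers

Random forests with `n_estimators = 1000`; all other hyperparameters at
scikit-learn defaults, with seeds threaded through for bit-reproducible
reports. Site classifiers use 5-fold cross-validation whose folds
partition *patients*, so both of a patient's samples always share a
split (audited in tests); out-of-fold probabilities are pooled into one
ROC/AUC. Aspiration classifiers use leave-one-out evaluation; AUC comes
from the pooled held-out probabilities and a two-sided Fisher exact
p-value from the 2×2 confusion matrix of hard labels at probability 0.5
(a confusion matrix needs a threshold; 0.5 is the symmetric choice).
Feature encodings: site-tagged relative abundances (multi-site features
keep identically named OTUs distinct), per-site 0/1 presence of exchanged
OTUs (presence means relative abundance > 0, consistent with the
detection filter), or the concordance code — 1 when an OTU is present in
both sites or absent in both, 0 otherwise.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analyses assume,
not biological realism: no real taxonomies, phylogenies or read
sequences, only abundance structure.

- **Oropharynx**: one shared sparse core composition (Dirichlet, shape
  `base_sparsity = 0.5` over `n_otus = 200`); each patient's oropharynx
  is a Dirichlet draw around it at `core_concentration = 100` — high, so
  oropharyngeal communities are conserved across people.
- **Lung and gastric**: each patient gets an independent sparse personal
  base per site (total concentration `person_concentration = 15` spread
  over all OTUs) and the sample is a Dirichlet draw around it
  (`within_person_concentration = 50`). Low person-level concentration
  makes these communities person-specific. Because the bases are
  independent *per site*, all cross-site coupling in a generated cohort
  comes from the planted exchange and the aspiration effect — the
  property the detector's null calibration relies on. The cost is that a
  patient's lung and stomach are no more similar than two strangers'
  lungs, a person effect real cohorts do show; tests that need that
  structure build a dedicated shared-community cohort.
- **Planted exchange**: for each designated OTU and pair, the source
  site's latent abundance across patients is lognormal (sigma
  `exchange_spread = 1.2`, median `exchange_abundance = 1e-3`) and the
  recipient site's log-abundance is the source's plus Gaussian noise,
  with the noise variance set from the bivariate-normal identity
  ρ_s = (6/π)·arcsin(r/2) so the within-patient Spearman correlation
  targets `exchange_strength = 0.8`. The recipient (lung for
  lung-oropharynx and lung-gastric, gastric for gastric-oropharynx —
  the aspiration, reflux and swallowing directions) carries only
  `exchange_carryover = 0.15` of the source's abundance, so its presence
  after read sampling is partial; that partial presence is what makes
  co-occurrence prevalence informative.
- **Aspiration effect**: each aspirator's lung latent composition is a
  convex mixture of their own oropharynx (weight
  `aspiration_mixing = 0.6`) and their lung latent; non-aspirators get
  weight 0. Mixing both pulls the within-patient lung-oropharynx JSD
  down and raises the lung presence of oropharyngeal taxa — the two
  observable signatures of aspiration.
- **Read sampling**: multinomial at `sequencing_depth = 10,000` per
  sample, then an independent per-entry dropout (probability 0.05)
  emulating detection loss in low-biomass specimens; batches assigned
  round-robin over patients (a patient's samples share a batch);
  aspiration statuses (25 aspirators, 23 non-aspirators, 18 untested of
  66 patients — the labelled-cohort proportions of the study design this
  emulates) are randomly permuted over patients.

Defaults were fixed once against the descriptive shape of real
aerodigestive cohorts — across-patient median JSD ≈ 0.6 for the
oropharynx vs ≈ 0.9 for the lung, within-patient lung-oropharynx ≈ 0.9 —
and against the planted-correlation target; they are calibration
constants of the simulator, not estimates of any real quantity.

**What passing tests do and do not show.** The generator's cohorts have
clean Dirichlet-multinomial noise, independent patients, no contamination,
no compositional artefacts beyond the simplex constraint, and an exchange
signal that is monotone by construction (matching the rank-based
detector's assumption without being identical to it — the link is on
latent log-abundances, the detector sees noisy counts). Recovery results
on these cohorts validate the machinery — filters, statistics,
permutation nulls, error control — not the biological effect sizes of any
real cohort.

## Numerical and reproducibility notes

- All randomness flows from explicit seeds; per-OTU permutation streams
  are spawned from a single seed sequence, so detection is bit-for-bit
  reproducible and independent of OTU evaluation order.
- Relative-abundance columns must sum to 1 within 1e-9; probability
  vectors within 1e-6; JS divergences are clipped at 0 before the square
  root to absorb rounding.
- Chao1 uses S_obs + F₁²/(2F₂), with the F₁(F₁−1)/2 correction when no
  doubletons exist.
- Taxonomy collapsing conserves per-sample totals exactly and groups
  OTUs unannotated at the target rank under an "unclassified at <rank>"
  sentinel per parent lineage.

## Known limitations

- No phylogeny-aware metrics (UniFrac) and no ordination inference; no
  source-tracking models — exchange here is association, not direction.
- The generator does not reproduce the shared person effect between lung
  and gastric communities, nor oropharyngeal seeding of the stomach
  outside planted exchange (see above).
- Real cohorts have incomplete site coverage per patient; the generator
  emits complete triple-site patients only (analyses tolerate
  missingness, and tests exercise it by pruning samples).
- The null-calibration round count (10) bounds typical null detections
  but is too few to estimate tail quantiles of the null count.
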