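# Methods

Models, parameter defaults, numerical conventions, and limitations of
`amfdiv`. Section order follows the pipeline: read preprocessing, OTU
construction, taxonomic identification, diversity estimation, community
statistics, the synthetic study generator, and the bundled survey tables.

## 1. Read preprocessing (`readprep`)

**Pair merging.** Mate 2 is reverse-complemented and slid along mate 1; among
overlap lengths ≥ `min_overlap` (default 16) the alignment minimizing the
mismatch fraction wins, ties going to the longest overlap. Overlaps whose
mismatch fraction exceeds `max_mismatch_frac` (default 0.25) are rejected as
`no_overlap`. In the overlapped stretch the higher-quality base is taken; on
agreement the consensus quality is Q1 + Q2 capped at 45, on disagreement
|Q1 − Q2| — the standard posterior-quality approximation used by read
mergers.

**Length filter.** Merged reads shorter than `min_len` = 120 are dropped
(the boundary is kept). This removes primer dimers and fragments too short
to span a spacer.

**Primer stripping.** A read is assigned to ITS1 or ITS2 only when it starts
with that region's forward primer *and* ends with the reverse complement of
its reverse primer, each with at most one mismatch; both primers are then
removed. Requiring both ends (the analogue of `--discard-untrimmed` in
cutadapt-style workflows) keeps partially stripped artifacts out of the
clustering pools — a lone forward match would leave a ~20 bp reverse-primer
tail that depresses identity to every true centroid and seeds artifact OTUs.
Reads failing the rule keep `region_tag = "unknown"` and take no further
part in the analysis. Default primers: ITS5/ITS-2RK for ITS1, ITS3/ITS4 for
ITS2.

**Expected-error filter.** E = Σᵢ 10^(−Qᵢ/10); reads with E > `max_ee` = 1.0
are discarded. The filter is applied after primer stripping so E is computed
on the bases that actually enter clustering.

## 2. OTU construction (`otucluster`)

**Identity convention.** Global (end-to-end) pairwise alignment with match
+1, mismatch −1, gap open −2, gap extend −1, computed with
`Bio.Align.PairwiseAligner`; identity = matches / (matches + mismatches +
gap columns), terminal gaps included. The test suite re-derives every
identity with an independent numpy Gotoh aligner.

**Two-step clustering** at `identity_radius` = 0.97:

1. *Closed-reference step.* Each dereplicated sequence is mapped to its
   best-scoring database centroid; ties break to the lexicographically
   smallest accession. Hits at ≥ 97% identity join that reference OTU
   (named `REF_<accession>`); singletons are eligible here — a read
   matching a known species is trusted even if seen once.
2. *De novo step.* The remainder is processed in decreasing abundance
   (UPARSE-style greedy order). Each sequence joins the first existing
   de novo centroid within the radius, otherwise founds a new OTU
   (`DN0001`, `DN0002`, …) — unless it is flagged as a chimera. After
   clustering, de novo OTUs whose total abundance is 1 are removed: a
   sequence seen once that matches nothing known is indistinguishable
   from a PCR/sequencing artifact. This asymmetric singleton policy
   (rescued on references, removed de novo) is deliberate.

**Chimera detection.** For each candidate and every ordered pair of
more-abundant potential parents, a per-position match profile against each
parent is combined over all single crossover points via prefix/suffix
cumulative sums. A candidate is discarded as a chimera when some two-parent
model explains it at ≥ 0.99 identity while the best single parent is below
the 0.97 radius — i.e. the chimeric model must be decisively better than
any biological explanation.

**Read conservation.** The pipeline asserts that input reads = reads
assigned to OTUs + reads discarded (chimeras, de novo singletons), and
raises otherwise.

## 3. Taxonomic identification (`taxonid`)

**Annotation.** Each de novo centroid is annotated with its best-hit
reference (global identity); hits below 0.80 are `unclassified`, and ties
spanning more than one genus are `ambiguous`. Reference OTUs inherit their
centroid's lineage exactly.

**Trimming.** Conserved rRNA anchors flanking each spacer are located
(one mismatch tolerated) and removed, so distances and trees are computed
on the variable spacer only; a missing anchor is flagged.

**Distances and trees.** p-distances use pairwise deletion (gap or N
columns excluded per pair). Trees are built with an own implementation of
Saitou–Nei neighbor joining: lexicographic tie-breaking for determinism,
negative branch lengths clamped to zero with the difference shifted to the
sister edge, trifurcating root. On additive matrices NJ is exact (verified
to 1e−8 in tests). Bootstrap supports come from resampling alignment
columns (`n_boot` = 50 in the pipeline) and counting clade recovery.

**Clade rules.** Within each genus bin (OTUs sharing a best-hit genus), with
thresholds `s_min` = 70 (bootstrap support), `t_species` = 0.03 (species
radius), `t_genus` = 0.15 (genus radius), applied in order:

1. An OTU inside a supported clade whose references belong to exactly one
   species, at p-distance ≤ `t_species` and with no contradicted diagnostic
   site, is called that **species**.
2. Two or more OTUs forming a supported reference-free clade become a
   **virtual taxon** with a stable `VT_<genus>_<k>` label.
3. An OTU in no supported clade and farther than `t_genus` from every
   reference is **excluded** (higher-rank or artifact).
4. Remaining OTUs pair into VTs only when their mutual distance is ≤
   `t_species`; otherwise they are excluded.

A consequence worth noting: a *single* reference-free OTU is legitimately
excluded — virtual taxa require corroboration by at least two OTUs. Bins
with fewer than three sequences (or without references) fall back to
nearest-reference distances without a tree.

## 4. Diversity estimation (`hilldiv`)

Hill numbers ^qD for q ∈ {0, 1, 2}: observed values are richness,
exp(Shannon), and 1/Simpson. Asymptotic estimators:

- q = 0: Chao1, S + ((n−1)/n)·f₁²/(2f₂); when f₂ = 0 the bias-corrected
  form S + ((n−1)/n)·f₁(f₁−1)/2.
- q = 1: Chao–Jost entropy estimator (sum of reciprocal-index series plus
  the f₁-based correction), exponentiated.
- q = 2: unbiased Simpson, 1 / Σ xᵢ(xᵢ−1)/(n(n−1)); undefined when all
  taxa are singletons (raises).

Sample coverage: Ĉ = 1 − (f₁/n)·((n−1)f₁ / ((n−1)f₁ + 2f₂)). Closed-form
checks in the tests include Chao1({1,1,2,3}) = 40/7 and
coverage({1,1,2,6}) = 0.82 exactly, both verified to 1e−9.

Confidence intervals use a coverage-adjusted multinomial bootstrap (200
replicates by default; 100 in the pipeline): taxon probabilities are scaled
to the estimated coverage with the remainder assigned to an unseen pool,
resampled counts are re-estimated, and the percentile interval is expanded
if needed to contain the point estimate.

## 5. Community statistics (`ecostats`)

- **Normalization**: total-sum scaling per sample; all-zero samples dropped.
- **Correlation screen**: Pearson r with a two-sided t-test on df = n − 2;
  a star marks p < 0.05 (for n = 9 the critical |r| is ≈ 0.666).
- **Distance**: 1 − Spearman ρ between sample profiles.
- **ANOSIM**: own rank-based implementation, R = (r̄_between − r̄_within) /
  (M/2) with M = n(n−1)/2, permutation p-value with the +1 correction
  (p = (1 + #{R_perm ≥ R}) / (1 + n_perm)); cross-checked against
  scikit-bio to 1e−10. Pipeline default `n_perm` = 999. Type-I error is
  calibrated in the acceptance tests (empirical rate within [0.02, 0.09]
  at α = 0.05).
- **Ordination**: classical MDS (double-centering + eigendecomposition,
  deterministic sign convention) and PCA via SVD.
- **Clustering**: Ward linkage via scipy, exported as a Newick dendrogram.
- **Group tests**: two-group t-test / k-group one-way ANOVA per taxon with
  Benjamini–Hochberg adjustment.

## 6. Synthetic study generator (`simcomm`)

The generator is the package's source of ground truth; its defaults *are*
the study conditions exercised everywhere else.

**Reference database.** `n_genera` = 4 genera × `species_per_genus` = 3
species radiate from a genus ancestor on a star tree; the per-lineage
substitution rate m solves 2m(1−m) + (2/3)m² = `inter_species_divergence`
(default 0.10) so the *expected pairwise* distance between congeners hits
the target. Each reference amplicon is conserved-anchor + spacer
(`spacer_length` = 170) + anchor, flanked by the primer sites.
`n_background_taxa` = 8 unrelated non-Glomeromycota taxa are added; the
construction guarantees distinct species stay below the 0.97 OTU radius.

**Ribotypes.** Each species carries `ribotypes_per_species` = 3 amplicon
variants per region. Every variant differs from the reference by *exactly*
round(`intra_species_divergence` × spacer length) substitutions (minimum 1),
confined to the spacer. Two modelling decisions are intentional: the count
is exact rather than binomial, so intra-species divergence is a hard bound
and ribotypes can never leak outside the 97% radius by sampling noise; and
mutations never touch primer or anchor sites, because a template with a
broken primer site would not amplify in the first place.

**Reads.** Depth `depth_per_sample` = 400 pairs per sample, `n_samples` = 9,
biotopes assigned round-robin from `biotope_labels`. Community structure is
hierarchical: per-biotope lognormal(0, 1) base weights over species,
multiplied by per-sample lognormal(0, 0.4) jitter — so samples within a
biotope share structure that ANOSIM can detect. Per read: background taxon
with probability `background_fraction` = 0.3, region ITS1 with probability
`its1_fraction` = 0.5, a uniformly chosen ribotype, chimera with probability
`chimera_rate` = 0.02 (single crossover with a same-pool partner), singleton
tagging with probability `singleton_rate` = 0.05 (unique erroneous variant).
Qualities are two-state: `q_good` = 38 with per-base error applied at the
corresponding rate, or a `bad_quality_fraction` = 0.03 chance of a
`q_bad` = 12 read. Every read is logged in a truth table (sample, species,
ribotype, region, chimera/singleton/background flags).

**Metadata.** `percent_annual_plants` is a linear Gaussian blend
r·z + √(1−r²)·ε with the standardized AMF abundance vector, so its sample
Pearson correlation is centred on `r_target` = 0.8. Altitude is drawn from
disjoint biotope bands ordered valley < forest < meadow; soil variables are
uninformative uniforms.

**Seed streams.** Database, reads, and metadata use independent
`numpy.random.default_rng` streams at seed, seed+1, seed+2; all derived
seeds stay below 2³¹. Identical seeds give byte-identical run directories
(asserted via the SHA-256 manifest).

## 7. Bundled survey tables (`amfdiv.data`)

Three small TSVs describe a nine-plot field survey across three North
Caucasus biotopes (subalpine meadow, forest, river valley): plot altitudes,
per-plot sequencing/AMF read and OTU counts for both spacers, and
biotope-pooled OTU counts. `ecostats.summary_tables` and the
`amfdiv golden-check` command reproduce the headline numbers (means 1774 and
722 AMF reads per plot for ITS1/ITS2, totals 15 969 and 6 500, marker read
ratio 2.5, biotope OTU ratios, and the Pearson screen r = 0.88*, −0.68*,
0.64 n.s.).

## 8. Numerical choices and problem sizes

- All stochastic procedures take explicit seeds; nothing reads global RNG
  state.
- Alignment-score ties and NJ ties break lexicographically for
  determinism across platforms.
- Bootstrap CIs are percentile intervals expanded to contain the point
  estimate, avoiding empty intervals at small replicate counts.
- Test problem sizes are chosen for exhaustive verifiability on one CPU:
  clustering-oracle equivalence uses 100 random problems of ≤ 14
  dereplicated sequences of length 50 (~40 s total); NJ exactness uses
  trees of ≤ 8 taxa; ANOSIM calibration uses 200 null simulations × 199
  permutations.

## 9. Limitations

- The simulator plants point substitutions only; indel variation, variable
  spacer lengths, and degenerate primers are not modelled, so the merger
  and aligner are never stressed by length heterogeneity from the
  generator (the unit tests cover indels directly).
- Chimeras are single-crossover with two parents; multi-parent or
  multi-breakpoint chimeras are out of scope.
- The quality model is two-state (good/bad read), not a learned per-cycle
  error profile.
- Clade rules operate within genus bins defined by best-hit annotation; an
  OTU whose best hit lands in the wrong genus is classified in that bin.
- ANOSIM uses a Spearman-based distance on TSS-normalized counts;
  compositional alternatives (CLR, Aitchison) are not provided.
- The asymptotic Hill estimators assume multinomial sampling within a
  pooled biotope; spatial structure below the biotope level is ignored.
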