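# Methods

## Scope and model

The package turns raw glycan-microarray fluorescence into per-lectin
specificity annotations. Its processing chain is fixed:

1. trimmed spot average (drop exactly one minimum and one maximum of the
   ≥ 4 replicate spots; ties trimmed once each);
2. per-array Z-score over glycans on raw RFU with the sample (n−1)
   standard deviation;
3. array exclusion (max signal < 1000 RFU) and lectin exclusion (no glycan
   ≥ 4000 RFU at any concentration, or fewer than two surviving arrays);
4. Stouffer combination, *Z*ₛ = ΣZ_c/√(n_conc), per lectin;
5. non-varying/nonspecific flagging (below);
6. per-glycan background subtraction of the mean *Z*ₛ across lectins;
7. binder call at processed *Z*ₛ ≥ 1.645, nonspecific cells forced unbound;
8. removal of glycans bound by no lectin.

The 1.645 cutoff is the one-tailed normal quantile at p = 0.05, computed by
`binding_threshold()`; the comparison is inclusive (≥), reading the cutoff
as attainment. Z-scores are computed on raw, untransformed RFU. The
Z-score model assumes the large majority of glycans on each array are not
bound; lectins that bind a third or more of the library sit near the edge
of that assumption and their combined scores compress accordingly.

### The non-varying (σ²) rule

Glycans above threshold whose signal does not change across the
concentration series earn no independent support from the titration; their
*Z*ₛ is replaced by the plain across-concentration Z average and they are
flagged. The variance in this rule is computed on the **averaged raw RFU**
across concentrations, with the reference maximum taken per lectin over
glycans, and the comparison is strict (< 10 % of the maximum). Computing it
on Z values instead is structurally wrong: a per-array Z-score is invariant
to the overall array scale, so a genuine saturating binder — whose RFU
rises tenfold over the series while the whole array scales with it — has a
near-constant Z profile and would be spuriously deflated. Flagged glycans
whose top-concentration signal is also below 10 % of that array's maximum
are nonspecific binders and are labeled unbound regardless of score.

## Glycan model and featurization

Condensed strings are parsed into rooted trees (root = reducing end).
Both ASCII (`b1-4`) and Greek/comma (`β1,4`) linkage spellings normalize to
ASCII; `(3S)`/`(3OSO3)` prefixes normalize to a (position, S) substituent on
the node; the spacer suffix (`-Sp8`, `-Thr`) is stored but excluded from all
sugar-level features and exposed as a one-hot categorical instead.
Canonical serialization orders siblings by (parent carbon ascending, then
canonical subtree string), making the string a pure function of structure;
round-tripping is checked over entire generated libraries.

Motif matching counts injective subtree embeddings honoring sugar,
substituent-superset, anomer and carbon constraints; `?` in a pattern is a
wildcard, while `?` in data is an unknown that never equals a specified
carbon. Embeddings are counted by image (the matched residue set), so
template automorphisms are not double-counted. Anchors: `terminal` maps
every template leaf onto a glycan leaf, `root` pins the template root to
the reducing end, `internal` requires template-leaf images to be non-leaves.
Curated features are binary presence; systematic mono/disaccharide features
are counts and include substituents in the token (an interpretive choice —
sulfated and plain residues are distinct monosaccharide features).

The curated catalog ships ~50 motifs named for the epitopes the field uses
(Lewis a/x/y/b; blood groups A, B, H; Forssman; LacNAc types; LacdiNAc;
polyLacNAc; chitin; bisecting GlcNAc; core fucose; high-mannose Man3–Man9;
terminal residues; α2-3/6/8 sialylation; Neu5Gc; KDN; 3-O/6-O-sulfation;
O-glycan cores 1–4, Tn, T, sialyl-Tn). It is a YAML-editable config, not a
closed list; high-mannose classes use terminal anchoring so the classes
stay disjoint.

## Rule mining

Ensembles are 50 bagged depth-one `DecisionTreeClassifier`s (Gini, bootstrap
resampling); every root-to-leaf path predicting "bound" is a candidate
conjunction, deduplicated by canonical form, with estimator support = the
fraction of trees proposing it. Thresholds snap to half-integers for
readable count rules. Validity requires precision ≥ 0.3, recall ≥ 0.1 and
support ≥ 0.15 (all inclusive); if no depth-one rule qualifies, depth-two
trees are tried. Mining uses a stratified, seeded 80/20 split; rules are
scored on the held-out 20 % (`min_split_size` configures a full-set
fallback, used by default only below 25 glycans, and deliberately engaged
in the structural validation experiments below). Levels restrict to the
previous level's satisfiers and must strictly improve precision; mining
stops at precision 1.0, five levels, or exhaustion. Ranking among valid
rules is precision, then recall, then support, then canonical name; two
qualifying rules at a level are reported as alternatives (a/b) — identical
binary/count feature pairs (e.g. a curated motif and its defining
disaccharide) commonly tie this way.

## Annotation reports

The enhancer/inhibitor contrast automates a comparison that is otherwise
done by eye: within glycans satisfying the level-1 rule, each feature's
presence is tested against binding with a two-sided Fisher exact test and
BH adjustment across features (q ≤ 0.05); the output labels this as an
automated statistical contrast, not expert annotation. "Tolerates" lists
features present in ≥ 20 % of binders without significant association.
Bound glycans failing all rule levels are grouped by curated features shared
by ≥ 50 % of the group. Matched-pair reasoning (single glycan pairs
differing in one feature) is not implemented.

## Clustering

Lectins (and optionally glycans) are clustered on processed *Z*ₛ profiles
with distance 1 − Pearson r and average linkage (UPGMA, scipy). Columns are
sorted lexicographically before linkage so tied merges resolve
deterministically; the dendrogram exports to Newick and the matrix reorders
by leaf order with a binary bound layer at 1.645 for external heatmap
plotting.

## Synthetic data generator

The generator emulates a CFG-style printed array: 22.3 % N-glycans
(bi- to tetra-antennary with optional bisecting GlcNAc at 25 %, core fucose
at 35 %, sialylated/fucosylated/polyLacNAc antenna caps; high-mannose
Man3–Man9 at 30 % of the class), 18.5 % O-glycans (cores 1–4, Tn,
sialyl-Tn, capped and extended arms, Ser/Thr linkers), and the remainder
free terminal epitopes on aliphatic spacers. Category counts follow exact
largest-remainder allocation; duplicates are rejected up to canonical form.

A synthetic lectin binds when its predominant motif embeds at least once;
enhancers multiply and inhibitors suppress the bound-state affinity
(fold 0 = hard knockout; ground-truth bound = relative affinity ≥ 0.5, so
enhancers never change labels). Mean RFU follows one-site saturation,
baseline + max_rfu · a · c/(c + K), with Hill coefficient 1 over the
default 0.1/1/10/100 µg/mL series (K = 1 µg/mL, max 30 000 RFU over a
100-RFU baseline). Spots get i.i.d. mean-preserving multiplicative
lognormal noise (default CV 0.15). Label noise is an independent per-array
bound-state flip (default probability 0 unless requested): it models
scan-level artifacts — spot dropout, spurious capture on one slide — and is
exactly the failure mode that combining concentrations by Stouffer's method
is designed to absorb. A whole-experiment flip would instead manufacture
glycans that genuinely bind at every concentration, which no scoring scheme
could reclassify.

What the generator does **not** emulate: spatial slide artifacts,
avidity/multivalency, printing-density and linker-presentation effects,
glycan-specific affinity spreads, or cross-reactive weak binding. Passing
recovery tests therefore shows the pipeline is correct and self-consistent
under a clean saturation model, not that real arrays are this easy.

## Validation experiments (study designs)

The self-validation module plants known answers and measures recovery:

- **Planted rule** (200 glycans, 4 concentrations, CV 0.15, 5 % per-array
  label noise): a chitobiose-directed lectin among 13 decoys that bind only
  epitope/O-glycan motifs. Decoy orthogonality to N-glycans means target
  binders that fail the Z-call drop out of the analysis (as they would in a
  large panel), and the polyLacNAc decoy keeps multi-GlcNAc non-carriers in
  the pool so GlcNAc counts cannot proxy for the motif. The mined level-1
  rule must name the planted feature (either alias) with held-out precision
  and recall ≥ 0.9.
- **Planted inhibitor / two-level stop** (300 glycans): binding =
  chitobiose present AND bisecting GlcNAc absent, in a 15-lectin panel that
  includes a bisect-directed binder (keeping inhibited glycans in the
  analysis) and enough N-/O-directed decoys that the target's binders are a
  minority of the analyzed pool — the regime a many-lectin experiment
  operates in, and the regime where precision-first ranking favors the true
  motif over negated proxies. These two experiments score rules on the
  full analyzed set (`min_split_size` override): they test rule structure
  and contrast direction, for which a 20 %-split estimate at this problem
  size is too noisy to be the quantity of interest.
- **Cluster separation** (two five-lectin families, varied K and dynamic
  range, CV 0.15): a k = 2 cut must separate the families exactly.
- **Oracle equivalences**: vectorized Stouffer vs a scalar loop (< 1e-12
  over 1,000 random profiles), rule precision/recall vs exhaustive counting
  (exact over 100 fixtures), and parse→canonicalize→parse round-trips over
  1,000 generated structures.
- **Exclusion accounting**: the packaged synthetic metadata fixture encodes
  a 116-preparation commercial panel with 42 duplicate preparations, 15
  low-activity and 2 literature-incongruent exclusions; the QC log must
  report 57 unique annotated lectins.

Problem sizes (200–300 glycans, 10 seeds) keep each experiment under two
minutes on one CPU while leaving the statistical margins of the planted
designs wide.

## Numerical choices and degenerate inputs

Sample (n−1) SD everywhere a spread is estimated from data; zero-variance
arrays and profiles raise errors naming the offender; background
subtraction requires ≥ 2 lectins; mining requires ≥ 5 glycans per class and
reports the reason when a level cannot continue; rules satisfied by no
glycan are discarded with a logged reason; q-values are floored at their
p-values. All randomness flows through explicit integer seeds; identical
inputs and seeds give byte-identical outputs (manifest hashes verify this).

## Known limitations

Rule mining inherits SkopeRules-style behavior: precision-first ranking can
surface a high-precision sub-rule (e.g. a count ≥ 2 variant) when the
analyzed pool is dominated by binders, and collinear curated/systematic
features tie arbitrarily. The exact supplementary 68-feature catalog of any
particular study is not reproduced; the shipped catalog covers the motifs
the field names and is user-replaceable. Binder calls inherit the Z-score
assumption that binders are a minority per array. Real-array phenomena
listed above as un-emulated are untested by construction.
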