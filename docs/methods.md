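# Methods

## The scientific question and the measurement

Marine surface waters differ systematically in nitrogen availability:
open-ocean gyres are chronically nitrogen-poor compared with coastal
waters. If nitrogen scarcity acts as a selective force on protein
composition, open-ocean microbial communities should encode proteins
that spend fewer nitrogen atoms per residue — and the saving should
concentrate where selection is least opposed: in weakly constrained,
fast-evolving positions, and in proteins that are up-regulated
precisely when nitrogen is scarce (the NtcA regulon), not in pathways
down-regulated under scarcity (arginine biosynthesis, which *stores*
nitrogen).

The package measures protein nitrogen content as

```
Nc = (Σ_i n_i) / L
```

where `n_i` is the number of side-chain nitrogen atoms of residue *i*
(1 for N, Q, K, W; 2 for H; 3 for R; 0 otherwise) and `L` the number
of residues scored. `Nc` is dimensionless, bounded in [0, 3], and
reaches 3 only for polyarginine. Backbone nitrogen is deliberately
ignored — every residue costs one backbone N regardless of identity,
so only side chains discriminate.

Ambiguity codes (X, B, Z, U, O, `*`) are excluded from numerator and
denominator alike, keeping `Nc` a mean over scorable residues. This is
our documented choice; source data pipelines rarely state how assembly
artifacts were handled.

## Filters

* Only proteins strictly longer than 100 amino acids are analysed
  ("longer than" read strictly; the threshold is a config key).
* Estuary samples are merged into the coastal group at load time
  (estuaries are a coastal subtype and too few to stand alone); the
  original label is kept in metadata for provenance.
* Membrane proteins (≥ 1 predicted transmembrane segment) are
  dissected into cytoplasmic / transmembrane / periplasmic-extracellular
  domains; a protein enters the per-domain analysis only if **each**
  of the three domains has ≥ 20 residues (inclusive). Signal-peptide
  residues are excluded from every domain. The > 100 aa filter is
  applied to the full peptide, before signal removal — the alternative
  (after removal) is not distinguishable from published descriptions,
  so we fixed one reading and documented it.

## Topology input

We parse the Phobius short output format rather than re-implement a
topology HMM: topology prediction is an external classification step,
and the synthetic generator emits the same format, so real predictions
drop in unchanged. Coordinates are 1-based inclusive. The signal
segment ends at the residue before the annotated cleavage site.
"Periplasmic" and "extracellular" are one compartment kind, as the
prediction cannot distinguish them.

## Functional annotation

HMMER3 per-sequence tabular hit files are filtered by model-specific
noise cutoffs (inclusive `score ≥ cutoff`, matching HMMER's own
threshold semantics) and each query is assigned to the gene of its
best surviving bitscore, ties broken by smallest model accession.
The two gene sets are the NtcA-induced cascade (NtcA, glnA, pII,
urtB, urtC, urtD, urtE, recD, amt1 — recD is carried verbatim from
the source gene list) and the arginine biosynthesis control (argC,
argJ, argH, argE, argG, argF). The gene→model-accession map ships as
an editable TSV with synthetic placeholder accessions; a deployment
against real TIGRFAM models only has to replace that file.
Per-sequence (not per-domain) scores are used.

## Per-site evolutionary rates

Rates are estimated per alignment column by empirical Bayes, the
standard construction behind ConSurf-style conservation scoring:

1. **Column masking.** Columns with fewer than 10% ungapped residues
   are excluded (strict `<`).
2. **Distances.** Pairwise Poisson-corrected amino-acid distances
   `d = −(19/20)·ln(1 − (20/19)·p)` with `p` the mismatch fraction
   over shared ungapped sites — the 20-state analogue of the
   Jukes–Cantor correction. At `p ≥ 0.95` the correction diverges;
   the distance saturates at 10 substitutions/site with a warning.
3. **Tree.** Saitou–Nei neighbor joining; negative branch lengths are
   clamped to zero; no branch-length optimization (NJ lengths are
   final).
4. **Substitution model.** JTT: the published exchangeability
   integers and equilibrium frequencies are embedded as constants;
   the rate matrix is scaled to one expected substitution per unit
   branch length and exponentiated through the symmetric
   eigendecomposition that time-reversibility permits.
5. **Rate prior.** Mean-one discrete gamma with K = 16
   equal-probability categories, each represented by its conditional
   mean (incomplete-gamma identity), renormalized to mean exactly 1.
   The shape α is estimated by grid maximum likelihood (25 log-spaced
   points in [0.1, 5]); a boundary maximum warns. α can be fixed via
   config instead. No published value prescribes the prior family or
   K; discrete gamma with 16 categories is the established default in
   this literature.
6. **Likelihoods.** Felsenstein pruning, vectorized over columns,
   with per-column rescaling against underflow; gaps and ambiguity
   codes are missing data (all-ones partial vectors). The root is the
   (arbitrary) NJ join point — reversibility makes the placement
   immaterial, which the tests verify indirectly through the
   enumeration oracle.
7. **Posterior mean.** `r̂_s = Σ_k r_k L_s(r_k) / Σ_k L_s(r_k)` with
   equal category priors, computed in log space.
8. **Normalization and classes.** z-scores over included columns
   (population sd; all-zero if the rates are constant). Slow sites:
   `z ≤ −0.75`; fast: `z ≥ +0.75`; boundaries inclusive ("as a
   cutoff" read inclusively); both cutoffs are config keys.

Column classes are mapped back to each sequence's ungapped positions;
residues in excluded columns stay unclassified and are omitted from
masked Nc.

For large gene families, rates are estimated on a habitat-stratified
subsample of at most 30 rows (config `max_inference_rows`) — rates
are column properties, so the classes transfer to every sequence —
and masked Nc is then computed for all rows. This mirrors how
conservation servers cap the number of homologs used for estimation.

## Statistics

The effect size is the relative difference of group means,
`100·(mean_open − mean_coastal)/mean_coastal` (negative = open ocean
nitrogen-poorer). Uncertainty is reported as the standard error of
the mean (sample sd / √n).

Significance uses the unpaired Wilcoxon–Mann–Whitney rank-sum test.
Three methods:

* `exact` — full enumeration of the C(n, n_x) rank assignments
  (combined n ≤ 20); midranks are enumerated as observed, so ties are
  exact too;
* `normal_approx` — normal approximation with tie and continuity
  corrections (scipy);
* `monte_carlo` — label permutation of the rank-sum statistic with
  the add-one estimate `p = (1 + #extreme)/(1 + B)`, default
  B = 10,000, seeded. This is the default, matching the
  "approximative" test naming convention in permutation-inference
  frameworks.

The test unit is the per-sequence Nc (sequences are closer to
independent sampling units than sites; a site-level mode is not
provided). The default alternative is one-sided "open < coastal" —
the thrifty-nitrogen hypothesis; pathway-scan contrasts can use the
two-sided variant. No multiple-testing correction is applied by
default, mirroring the analysis design this package reproduces.

## The synthetic-data generator

The generator produces the statistical structure the analysis
assumes, with every label known:

* **Habitat profiles.** Coastal baseline = JTT equilibrium
  frequencies. The open-ocean profile multiplies the frequencies of
  the six N-bearing residues by a common factor, renormalizes, and
  solves the factor by root finding so the relative difference in
  expected Nc hits the target exactly (default −5%).
* **Proteomes.** I.i.d. residues from the profiles, lengths uniform
  on [101, 300] (passing the length filter by construction), 2,000
  sequences per habitat group split over two samples — one coastal
  sample is labeled estuary to exercise the merge rule.
* **Membrane proteins.** Assembled segment-wise: hydrophobic-enriched
  transmembrane stretches of 15–30 residues, loops from the habitat
  profile, optional signal peptide; the emitted Phobius line
  re-parses to the true annotation. 300 per habitat group, 1–4 TMs.
* **Gene families.** A Yule topology (dendropy pure-birth) rescaled
  to a mean root-to-tip path of 1.0 substitutions/site; gap-free
  alignments evolved under JTT with mean-one gamma(α = 0.7) site
  rates. The habitat effect is injected *after* evolution: at
  designated sites (the top 25% of drawn rates), every N-bearing
  residue of an open-habitat leaf is swapped to a fixed nitrogen-free
  counterpart (N→D, Q→E, K→T, W→F, H→Y, R→S) with probability q.
  Because all swap targets carry zero side-chain N, the expected
  relative Nc drop at designated sites is exactly −100·q% (default
  q = 0.05 → −5%). The effect-carrying gene is labeled NtcA; argF is
  generated with no effect as the metabolic control.
* **Hit tables.** One above-cutoff hit per gene-family sequence plus
  sub-cutoff decoys the noise filter must remove.

One master seed feeds named substreams (CRC-hashed labels) per stage;
regeneration is byte-identical.

**What the generator does not emulate:** indels (alignments are
gap-free; gap handling is covered by hand-built fixtures),
composition heterogeneity across lineages, alignment error, chimeric
assemblies, and the amino-acid-specific rate differences present in
real proteins. Passing tests therefore demonstrate that the pipeline
recovers effects under its own model assumptions — not that the real
data satisfy those assumptions.

## Study sizes and power

The localization power study (can the pipeline detect a −5% Nc
deficit confined to fast sites, and *not* flag slow sites?) uses 250
sequences per habitat group and 2,000-column alignments. These sizes
come from an a-priori power calculation: with per-site Nc variance
≈ 0.59 under JTT equilibrium composition, a per-sequence masked Nc
over m fast sites has sd ≈ 0.77/√m, so detecting a 5% shift of the
mean (≈ 0.018) at one-sided α = 0.05 with ≥ 90% power needs roughly
n·m ≳ 4×10⁴ after allowing for imperfect overlap between inferred
and designated fast sites. They are also commensurate with the
per-gene homolog counts of the metagenome study this emulates
(thousands of homologs over 15 genes). Rate inference runs on a
30-row stratified subsample with α fixed at the generating value;
α-estimation quality is established separately by the
parameter-recovery test (40 taxa, 400 columns, grid ML).

## Numerical choices

* Transition matrices: spectral form of the reversible Q; rows
  clipped at 0 and renormalized to kill `exp` round-off.
* Pruning rescales partials by their per-column maximum; log scale
  factors accumulate, so category weights are formed in log space and
  underflow cannot corrupt posterior means.
* Gamma discretization uses the incomplete-gamma identity rather
  than quadrature; the category mean is renormalized to exactly 1.
* Distances: saturation cap 10.0 substitutions/site (configurable).
* NJ ties in the Q-criterion resolve by `argmin` scan order —
  deterministic for identical inputs.
* Degenerate inputs: constant rates normalize to all-zero z-scores
  (no site classified); a column set empty after masking raises; a
  stratum with < 2 sequences per group is skipped with a warning.

## Known limitations

* The NJ implementation is O(n³) in pure numpy — adequate for the
  ≤ ~500-taxon trees used here, not for thousands of taxa.
* The exact rank test is restricted to combined n ≤ 20 by design;
  larger samples use the permutation or normal methods.
* Homolog retrieval and alignment construction are out of scope:
  alignments are inputs (here, generated).
* `recD` sits in the NtcA gene set because the source gene list
  places it there; no functional claim is implied.
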