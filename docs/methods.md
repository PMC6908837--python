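# Methods

`prosip` implements a proteomic stable isotope probing (SIP) analysis:
identifying ¹³C-labeled peptides and proteins from shotgun-proteomics
spectra, and reconstructing metagenome-assembled genomes (MAGs) for the
organisms that produced them.  This note records the model, the numerical
choices, and what the synthetic test bed does and does not show.

## Isotopologue envelope model

The central quantity is the isotopologue envelope of a peptide under a
carbon enrichment hypothesis *p*: every carbon atom is ¹³C with probability
*p* independently; hydrogen, nitrogen, oxygen, and sulfur keep natural
isotope abundances (NIST values via pyteomics).  Isotopologues are
aggregated by nucleon-number offset from the all-light species — at the
0.03 Da parent / 0.01 Da fragment tolerances used here, isotopic fine
structure is unresolvable — and each offset class carries an
abundance-weighted centroid mass.

The envelope of a formula is the convolution of per-element envelopes: the
carbon marginal is a closed-form binomial (n carbons, probability *p*), the
other elements are iterated polynomial products of their per-atom
distributions.  Intermediate and final distributions are truncated at a
cumulative abundance of 0.999 and renormalized; tests that compare against
exhaustive enumeration disable truncation.  The enrichment element is
carbon throughout, but the machinery is element-generic so a ¹⁵N mode could
be added without touching the convolution.

Natural ¹³C abundance is fixed at 0.0107 atom fraction unless overridden.

## SIP database search

Spectra are searched against a concatenated target+decoy database (one
full-sequence-reversed decoy per target).  Digestion is fully specific
trypsin (cleave after K/R, not before P), up to three missed cleavages,
peptide length 6–50 residues — the length bounds are this package's choice
of standard identifiability limits.  Methionine oxidation (at most one per
peptide) is the only variable modification and is enabled in the regular
(unlabeled) search mode.

For each spectrum the engine evaluates candidate peptides over an
enrichment grid — the natural point plus 1 atom% steps from 2% to 99% in
SIP mode; the natural point only in regular mode.  A grid point is
admissible when the most abundant peak of the precursor envelope matches
the reported precursor within 0.03 Da after one allowed integer parent-mass
offset (−4..4 in SIP mode, −1..3 in regular mode).  Offsets are applied in
units of the ¹³C–¹²C mass spacing (1.00336 Da), since they model precursor
deisotoping errors.

The score is a cosine-normalized weighted dot product between theoretical
envelope abundances and observed intensities (nearest peak within
tolerance, zero where none), combined as

    score = 0.5 · precursor-envelope cosine
          + 0.5 · mean fragment-envelope cosine over the b/y series

with singly-charged b/y ions (b1/y1 omitted), each fragment's envelope
computed from its own composition at the hypothesized enrichment.  A
fragment with no matched peak contributes zero to the mean.  Averaging over
the *full* ion series rather than over matched ions only is deliberate:
with a matched-only mean, a decoy that matches a single chance fragment
ties a true match with a complete ion series, and peptide-level FDR control
degrades.  Ties across enrichment values break toward the lower enrichment
(the conservative labeling claim).

Two standard pruning steps keep the search at desk scale without changing
the ranking in practice: per candidate, fragment envelopes are evaluated
only for the seven grid points with the best precursor score; per spectrum,
full fragment scoring is applied to the five candidates with the best
precursor-only score.  Both shortlists are deterministic.

The best candidate per spectrum is retained.  PSMs are collapsed to the
best per peptide, sorted by score (decoys first at equal score,
conservatively), and the largest prefix with #decoy/#target ≤ 1% is kept;
decoys are excluded from the returned identifications.  The protein-level
FDR is the ratio of decoy to target protein groups inferred above the same
score threshold.

## Protein inference and labeling filters

Proteins are inferred by the parsimony rule, implemented as greedy minimal
set cover (ties broken by accession order); proteins with identical peptide
sets merge into one group, and groups without a unique peptide are
discarded.  A protein group is called ¹³C-labeled only if

* CO₂ (rhizosphere) mode: all supporting identifications exceed 10 atom%
  and at least one sample of the group's plant-species block holds two or
  more distinct labeled peptides;
* methanol (microcosm) mode: labeled identifications appear in at least
  two replicates of one incubation triplicate.

An identification counts once per (sample, peptide, charge).  The
two-peptide rule requires distinct peptide sequences, not merely two PSMs
of one peptide.  Labeled-peptide atom% values are clustered into protein
isotopologues by merging the closest cluster means until all pairwise mean
differences exceed 10 atom%.

Timepoint comparisons use a Mann–Whitney U test whose null is enumerated
exactly (ties handled by midranks) for n₁+n₂ ≤ 20 and approximated
normally with tie correction above; the default alternative is one-sided
(later timepoint more enriched), configurable.  Functional profiles are
flat sums of normalized protein peak areas over GO/EC terms; proteins
without annotation fall into an `unannotated` bucket.  Protein abundance is
a total-sum-scaled peak-area sum — deliberately simpler than profile-based
quantification tools.

## Binning

Scaffolds ≥ 5 kbp are embedded as log(coverage + pseudocount) per sample —
pseudocount 0.01 × the global mean coverage — concatenated with canonical
(reverse-complement-collapsed, 136-dimensional) tetranucleotide
frequencies, each block standardized.  Features are projected onto the
principal components explaining 90% of variance and clustered with a
seeded diagonal-covariance Gaussian mixture (k = 10 by default).  A seeded
mixture replaces the interactive refinement a human curator would do; the
whole stage is reproducible from the seed.

Targeted binning anchors on scaffolds carrying genes for labeled unique
proteins.  Anchors within one radius merge into a group; the candidate MAG
is the anchors plus cluster members within the radius of the anchor
centroid.  The radius is the 0.90 quantile (configurable) of the
dataset-wide distribution of scaffold-to-own-cluster-centroid distances —
a global scale, so that a cluster contaminated by a few distant scaffolds
does not inflate its own radius.

Quality comes from a user-supplied universal single-copy marker table:
completeness = % of markers present at least once, contamination = % of
excess copies.  This is a simplified, testable stand-in for lineage-specific
marker models; MAGs without markers are classed `no-marker` rather than
estimated.  Acceptance rules: untargeted MAGs need completeness > 70% and
contamination < 10%; targeted MAGs need contamination ≤ 5% and either two
labeled-protein identifications (CO₂ mode) or one labeled protein in ≥ 2
replicates of a triplicate (methanol mode).  The targeted contamination
bound is inclusive at 5 because reported quality values are rounded to
integer precision and the reference reports accept a MAG printed at exactly
5%.  Accepted MAGs are classed `medium` at ≥ 50% completeness and < 10%
contamination, else `low`.

Taxonomy is voted from per-marker labels: assigned at ≥ 75% concordance,
putative above 50%, unclassified otherwise.  When at least two of three
independent tool lineages agree at the phylum level (the first rank of a
lineage path), their lowest common ancestor overrides the voted taxon.
Taxonomy labels are opaque strings; no taxid resolution is attempted.

## Synthetic test bed

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* communities of 8 genomes (default) with per-genome dinucleotide Markov
  bias and iid lognormal per-sample abundance over a 14-sample design
  (three plant blocks × two timepoints × two replicates, plus two
  controls); scaffold coverage is Poisson around abundance × depth;
* random tryptic proteomes placed as non-overlapping genes (GFF3-linked to
  scaffolds), with a labeled subset at chosen atom% — defaults 20/50/95
  atom%, spanning the ranges the two reference experiments report;
* centroided spectra holding the precursor envelope (charge 2–3) and b/y
  fragment envelopes at the true enrichment, perturbed by multiplicative
  lognormal intensity noise (signal-to-noise ≈ 1/sd) and optional peak
  dropout; a configurable fraction of spectra comes from shuffled
  (unmatchable) peptides.

Everything is deterministic given the seed.  What the test bed does *not*
emulate: chromatography and co-elution, profile peaks, charge states above
3, real cleavage irregularities, read-level coverage noise, and shared
k-mer composition between related genomes.  Passing tests therefore show
that the algorithms are implemented correctly and behave as designed under
their own model assumptions — not that real soil metaproteomes would yield
the same error rates.

Default problem sizes (8 genomes × 25 kbp, ~100 proteins, ~36 spectra per
scene; 50 spectra per condition in recovery/detection experiments; 20
seeded entrapment searches) keep the full pipeline under a few seconds to
a couple of minutes per experiment on one CPU.

## Known limitations

* The scoring algebra is this package's explicit stand-in for the named
  weighted dot-product family; published SIP engines may weight precursor
  and fragment evidence differently.
* Protein quantification is a normalized peak-area sum, not a
  chromatographic profile fit.
* The entrapment FDR experiment measures peptide-level error under clean,
  model-generated spectra; real spectra carry correlated noise that can
  widen the gap between nominal and empirical FDR.
* Binning operates on a composite coverage table; it does not model
  strain-level microdiversity or differential assembly artifacts.
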