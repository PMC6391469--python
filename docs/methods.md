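# Methods

## Coordinate and cut-site conventions

Internally all genomic coordinates are 0-based, half-open on the forward
strand; the command line speaks 1-based positions (VCF convention). SpCas9
guides are 20-nt protospacers immediately 5′ of an NGG PAM on either
strand; the degenerate PAM position accepts any real base but not N, and
protospacers containing N are excluded. The double-strand break is modelled
as blunt, 3 bp 5′ of the PAM (between protospacer positions 17 and 18) —
the canonical SpCas9 cut.

The mutation-to-cut distance is signed in PAM-strand orientation: with `m`
the index of the edited base and `c` the cut boundary, `d = c − m`, so 0 is
the first base 3′ of the cut, positive values lie 5′ of the cut and
negative values run 3′ toward the PAM. This convention admits distances of
both signs "around zero" and is mirror-consistent: a guide and its image on
the reverse complement give the same distance to the mirrored site
(property-tested).

ssODN donors are homologous to the PAM strand: for a − strand guide the
donor is the reverse complement of the forward-reference window, and the
centre base carries the alt allele expressed in PAM-strand orientation.
Arm lengths are per-call parameters (defaults 70/70, a 141-mer); the
curation schema accepts an optional `arm5` column because real donors are
often asymmetric, and falls back to a centre-symmetric assumption without
it.

## Feature encodings

Composition features are counts: 4 mononucleotides plus 16 *overlapping*
dinucleotides (a length-L sequence yields L−1 dinucleotides). The guide
family is nested, with dimensions fixed at G1=20, G2=25, G3=29, G4=33:

* G2 adds 5 repeat features — the longest homopolymer run per base and the
  number of bases inside any run of length ≥ 3;
* G3 adds 4 weak/strong features — A+T count, C+G count, longest AT-only
  and CG-only runs;
* G4 adds 4 purine/pyrimidine features — counts and longest single-class
  runs.

The repeat/class features are defined here by these dimensions; alternative
definitions with the same dimensions would be admissible, and the encoders
are small pure functions that are easy to swap. G5 is a positional one-hot
(`N_<pos>_<base>`; 80 indicators for a bare protospacer, 4 more per context
base) — deliberately high-dimensional relative to small datasets, which is
the point of including it in comparisons.

Donor regions are anchored at the edited centre base and extend outward;
the 5′ region is *read* outward (centre → 5′ end) so both arms are encoded
in the same frame — a donor with mirror-symmetric arms then encodes
identically on both sides, which is used as a consistency test. O1 encodes
the whole donor, O2 the 3′ arm, O3 the 5′ arm (mono+di by default,
mono-only available), and M1 = G1 ⊕ O2 with `arm3_`-prefixed names to keep
the concatenation unambiguous.

## Dataset curation

Duplicate experiments per target are merged by summing counts (guide,
donor, distance and arm layout must agree within a target; conflicts are
errors, not warnings). Samples with no observed mutation at all are
discarded — they measure cutting failure, not repair-pathway choice. HDR
and NHEJ efficiencies both use total mice as denominator. Binarization
thresholds at the dataset median with *strict* greater-than for "high":
classes are balanced by construction up to ties, exact-median ties go to
"low" and are logged. Degenerate (all-equal) efficiency vectors are
rejected rather than silently labelled.

## Random-Forest evaluation protocol

Forests use 1,000 trees, √p feature subsampling, unlimited depth, bootstrap
sampling and a fixed seed (all configurable; recorded in the model
manifest). Two OOB conventions are computed:

* **ensemble-vote OOB** (headline): each sample is predicted by the
  majority vote of trees that did not draw it; error ≈ 0.5 is chance for
  balanced classes;
* **per-tree-average OOB**: the mean over trees of each tree's error on
  its own out-of-bag samples. This is systematically higher (single trees
  are weak) and is reported alongside for transparency.

Cross-validation is stratified 5-fold with shuffling under the evaluation
seed. Reported metrics are unweighted fold means; `correct` is the total
count of correctly classified held-out samples across folds. Fold
assignments are generated once per dataset and shared across feature
schemes so scheme comparisons are paired. Both the fold-averaged OOB of the
five training forests and the whole-data OOB are reported, since either
reading of "averaged over folds" is defensible for an OOB statistic.

The arm-region sweep trains one forest per region length k (default k from
5 to the shortest arm on that side, step 1) and records whole-data
ensemble-vote OOB; the Spearman ρ of OOB against k summarizes the trend.
The distance regression is OLS of HDR efficiency on |distance| (pooling
both sides of the cut; a signed fit is available), with R² from the
squared correlation. The improvement statistic compares the mean efficiency
of predicted-high targets against the mean over all targets, as a percent
gain.

No multiple-testing correction is applied anywhere; reports carry raw
metrics only.

## Base-editing rules

The rule table is: C→T ⇒ CBE on the edit's own strand; G→A ⇒ CBE on the
opposite strand; A→G ⇒ ABE same strand; T→C ⇒ ABE opposite strand; every
other substitution falls through to HDR. Protospacer positions are numbered
1–20 (PAM 21–23) and the default editing window is positions 4–8 — the
classical five-position window; published windows vary by editor
generation, so the window is a parameter rather than a constant. Bystanders
(same-letter bases in-window) never disqualify a plan; plans are sorted by
bystander count, then by how central the target sits in the window. The
engine is validated against exhaustive enumeration of guides and window
letters on random loci.

## Synthetic data generator

The generator emulates the statistical shape of a mouse-zygote knock-in
study: by default 30 targets, Poisson(25) mice each scattered over ~4
duplicate experiment rows (merged back during curation), 84-nt 5′ / 81-nt
3′ arms, and HDR/NHEJ efficiency medians near 0.2/0.6. The latent model is
logit-linear:

```
p = expit(b0 + w_g·(G1(guide) − E[G1]) + w3·z(GC of 3′-arm bases 20..60)
          + w_d·|d| + ε),   ε ~ N(0, σ²)
```

with `n_hdr ~ Binomial(n_mice, p)` and indels drawn from the remaining mice
at a fixed per-mouse rate. Defaults: `b0 = −1.28` and indel rate 0.7575,
derived analytically from the target medians (logit(0.199) plus the mean
distance-term offset; 0.606/(1−0.2)); guide weights 0.35 on the G and C
counts; 3′-arm weight 1.0 on the standardized GC content of bases 20–60
from the centre (beyond the typical 30–40-nt resection overhang, where
composition should matter most); distance weight −0.05 per base; noise SD
0.5. Setting any weight to zero provably removes that component from the
latent probability (ablation-tested).

What the generator does *not* emulate: locus and chromatin effects, guide
activity beyond composition, real codon/GC structure of genic sequence, or
correlated donor/guide sequence (guides and donors are independent random
sequences). Passing tests therefore demonstrate that the pipeline recovers
planted composition signal at realistic n and noise — not that real HDR
efficiency is governed by these features.

## Problem sizes and numerical choices

Statistical acceptance checks run at n = 100–150 targets, 100–300 trees and
sweep steps of 5–10 bases: orderings, trends and null bands are scale-free,
and these sizes give stable majorities over 20 seeded replicates while
keeping the suite fast. Null calibration accepts mean OOB/AUC in 0.5 ± 0.1
over 20 permutation seeds. Ties at the median label boundary go to "low";
ROC AUC with a single-class fold is recorded as NaN and excluded from the
fold mean; constant-response distance regressions return R² = 0 explicitly
(the closed-form correlation is undefined there).

## Known limitations

* Off-target enumeration and specificity scoring are out of scope (use
  dedicated tools); only NGG PAMs and single-base substitutions are
  supported.
* Per-tree OOB bookkeeping reaches into scikit-learn's private bootstrap
  helpers (`sklearn.ensemble._forest`); the headline ensemble-vote OOB uses
  only the public `oob_score_`.
* The G2–G4 repeat/class feature definitions are one reasonable choice
  among several with the printed dimensions.
* Base-editing plans carry no efficiency score; ranking within base-editing
  plans is purely rule-based (bystanders, centrality).
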