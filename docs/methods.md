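# Methods

This note records the model implemented by `lmrsvm`, the defaults and why
they were chosen, the numerical decisions, and what the simulated study can
and cannot demonstrate.

## Model and assumptions

The framework is positive–unlabeled learning over DNA sequence composition.
Its premises:

* LMRs called from WGBS methylation are enriched for distal regulatory
  elements but are individually unreliable labels, so they form an
  *unlabeled* candidate set rather than a positive set.
* Enhancer-like sequence composition is captured by normalized 5-mer count
  vectors; a linear decision function in that 1,024-dimensional space
  separates enhancer-like from background composition.
* A small anchor set of validated enhancers (VISTA-style) overlapping the
  LMRs identifies, through a kernel density estimate, which LMRs most
  resemble known enhancers.  The anchor *sequences used are the LMRs
  themselves*, not the validated fragments, because such fragments carry
  several hundred bp of primer-derived flanks that would contaminate the
  k-mer profile.

## Sequence encoding

`kmer.encode` counts every overlapping k-length window over {A,C,G,T} and
divides by the total count, making vectors length-independent.  Windows
containing N are skipped; a sequence with zero valid windows yields an
all-zero vector flagged invalid instead of an error so that observed regions
straddling assembly gaps degrade gracefully.  Counting is forward-strand
(plain occurrence counting); a `canonical=True` flag collapses reverse
complements for experimentation but is not the default.

## Density ranking

KDE in the raw 1,024-dimensional simplex is degenerate for ~10²-scale anchor
sets, so anchors are first projected by PCA onto the leading components
explaining ≥ 95% of anchor variance (configurable; `reduce_dim=0` disables
the projection).  The kernel is a product Gaussian with per-dimension
Silverman bandwidth

    h_j = sigma_j * (4 / ((q + 2) m))^(1/(q + 4))

over m anchors in q retained dimensions, floored at 1e-8 (with a warning)
so duplicate or constant anchors still give finite densities.  Densities
are evaluated in log space (log-sum-exp); ranking uses the log density, so
the stored linear-scale density may underflow for extreme outliers without
affecting ranks.  Ranks ascend with density — rank 1 is least anchor-like —
and ties are broken deterministically by (density, chromosome, start), so
identical inputs always give identical ranks.  Mode-based cluster *labels*
(the hill-climbing step of density clustering) are not computed: only the
density rank feeds the partition.

## Partition and the negative set

Quantile = rank / n.  Boundary semantics are: RP iff quantile ≥ δ ("top δ
quantiles" inclusive), LN iff quantile < the LN cutoff.  Defaults δ-grid
(0.90, 0.95, 0.98) and LN cutoff 0.15; δ = 0.95 is the value such protocols
typically learn, and the LN cutoff is a plain configuration value (0.11–0.15
being the reported working range for real cell types).

Reliable negatives are produced by per-chromosome rejection sampling: each
template (LMR) interval is re-placed uniformly on its own chromosome with
identical length, rejecting placements that overlap the exclusion set
(exons + LMRs), contain N, or (by default) overlap an already-placed
negative.  Rejecting and resampling N-containing placements — rather than
dropping them — preserves the per-chromosome count and length multiset
exactly.  Self-overlap avoidance is stricter than classic BED shuffling;
`allow_self_overlap=True` relaxes it.  GC-matched negatives are deliberately
not the default: matching GC trades sensitivity for precision and removes
the GC component of the signal the classifier is meant to learn.

## The four-weight SVM

Each training row's misclassification cost is the penalty of its set
(C_RP, C_LP, C_LN, C_RN), with C_RP ≥ C_LP and C_RN ≥ C_LN enforced.  The
dual is solved by SMO with maximal-violating-pair working-set selection, a
per-sample box [0, C_i], a precomputed kernel matrix, and gradient
maintenance; alphas within 1e-12 of a bound are snapped to it so bound-riding
values cannot stall pair selection.  Training stops when the maximal KKT
violation is ≤ `tol` (default 1e-6) and raises if the iteration cap is hit
first, so every returned model carries a KKT certificate (`kkt_gap`).  With
all four penalties equal the problem is a standard C-SVM, which the test
suite exploits as an independent cross-check (libsvm and a generic
QP-plus-KKT-polish oracle).

**Penalty scale.** Because the feature vectors are L1-normalized, their
squared L2 norms are of order 1/d_eff ≈ 1e-3 at k = 5.  Slack penalties must
be of order the inverse of that scale before margins become affordable; the
default grid is therefore C_RP = C_RN ∈ {10³, 10⁴, 10⁵} crossed with
C_LP = C_LN ∈ {10, 10², 10³}.  The grid is fully configurable.

## Model selection

For each (δ, weights) grid point: stratified 5-fold CV (folds preserve
RP/LP/LN/RN proportions; assignment seeded), pooling TP/FN/PP counts over
held-out folds (micro-averaging — stable when RP is small).  F, recall and
precision follow the unlabeled-positive definitions: TP/FN count RP∪LP
members predicted positive/negative, PP counts *all* predictions including
LN/RN false positives.  Each candidate is then retrained on all rows and its
genomic coverage measured by scanning a designated proxy chromosome (default:
the first) and dividing merged positive-window bp by chromosome length;
candidates above the coverage cap (default 5%, with 10%/15% as the usual
alternatives) are discarded — this is what stops degenerate "everything is
an enhancer" models that can dominate the unlabeled-positive F-score.
Survivors within 0.005 (absolute, configurable) of the best F form a tie
group; the highest-precision member wins, residual ties going to the
lexicographically smallest (δ, weights).  Coverage is evaluated on the full
retrained model, not per fold.

## Scanning and merging

Windows of 2,000 bp are tiled from position 0 of each chromosome every
500 bp; a trailing partial window is not emitted.  Window score is w·x + b;
windows with no N-free k-mer are flagged non-callable and scored −inf so
assembly-gap deserts are never treated as confident negatives.  Positive
windows are merged under overlap-or-adjacency.  "Separating at negative
windows" is under-specified when windows overlap; the implemented rule cuts
a merged run at the midpoint of an intervening callable negative window only
when no positive member spans that midpoint (both behaviours ship;
`split_at_negative=False` disables splitting).  Each reported enhancer's
representative is its highest-scoring member window, leftmost on ties —
evaluating representatives avoids the inflation that whole merged spans
would cause.

## Validation

Distances in the validation rules are edge distances (overlap = 0) with
inclusive thresholds; center-point distance is available by flag and is used
only for TSS-distance profiles.  TSSs are treated as 1 bp points (interval
inputs are collapsed to the start base).  True-positive markers are DHS,
p300 and enhancer-associated-TF peaks strictly more than 1 kb from the
nearest TSS.  Categories are assigned in order: validated (TPM ≤ 1 kb),
misclassified (TSS ≤ 2.5 kb), unknown.  Validated calls fall into six
mutually exclusive marker states; p300 without TF collapses "p300+DHS" and
"p300 only" into "p300+/−DHS".  A validated window with no marker in range
is an internal-consistency error, not a category.  The two-proportion z-test
uses the pooled-variance normal approximation (statsmodels backend).

## Simulated study

The generator emulates the pipeline's inputs at desk scale; all randomness
flows from one seed through a single generator, so outputs are
byte-identical across runs.  Defaults (the study conditions): three 400 kb
chromosomes of i.i.d. 40%-GC background with one 1 kb N island each; five
planted enhancers per chromosome, 1.2–2 kb long — commensurate with the 2 kb
scan window, which is the scale the window size is chosen for — covering
≈ 2% of bases; four hexamer motif words planted at rate 0.5 on a 20 bp slot
grid inside enhancers (≈ 15% motif bp), the sequence signal that makes
enhancers learnable from 5-mers; 240 LMRs, half covering enhancers (jitter
± 150 bp) and half background; VISTA-like fragments over 30% of the
enhancer-covering LMRs (real anchor sets are far sparser relative to the
LMR count, but a toy-scale KDE needs a populated anchor sample); 15 TSS
points per chromosome at ≥ 3 kb from enhancers; DHS/p300/TF peaks on true
enhancers at rates 0.9/0.6/0.5 plus 8 uniform background peaks per
chromosome and track; FANTOM-style fragments inside half the enhancers; and
conserved segments on 70% of enhancer midpoints plus dense background
segments.

What passing on this study shows: the chain of encoding, ranking,
partitioning, weighted training, selection and scanning is wired correctly
and recovers a planted compositional signal at realistic coverage.  What it
does not show: performance on real genomes — real enhancer sequence signal
is far weaker and more heterogeneous than planted motifs, real LMR sets are
two orders of magnitude larger, background sequence is not i.i.d., and
marker tracks carry correlated biases.  Published validation rates on real
cell types are therefore not reproduced here.

Problem sizes were scaled for a desk-scale study: a 1.2 Mb genome
(≈ 2,400 scan windows), 240 LMRs and a 27-point selection grid make the full
chain run in seconds to minutes.

## Known limitations

* The SMO solver materializes the n×n kernel matrix; fine for 10³–10⁴
  training rows, not for much larger sets.
* Scanning encodes each window independently (no sliding-count reuse);
  genome scale beyond tens of Mb would warrant the incremental encoder.
* The density model assumes anchors occupy a low-dimensional subspace;
  with fewer than ~10 anchors the PCA/bandwidth estimates are fragile
  (a hard floor of 5 anchors is enforced).
* Strand information is ignored throughout (LMRs and peaks are unstranded).
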