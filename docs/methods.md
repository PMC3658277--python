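# Methods

This note records the models implemented in `sh3map`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was genuinely
open.

## Specificity models (`sh3map.pwm`)

A PWM for one SH3 domain is estimated from *N* aligned phage-display
peptides of common length *L* over the 20 amino acids plus a gap character.

1. **Counts.**  Each residue adds one count to its column; a gap adds 1/20
   of a count to every residue of its column, treating gaps as fully
   non-specific.
2. **Entropy-proportional pseudocount.**  Column *j* receives a per-residue
   pseudocount `β_j = kappa · H_j / ln 20`, where `H_j` is the Shannon
   entropy (nats) of the raw column frequencies and `kappa` defaults to 1.
   The proportionality constant is not uniquely determined by the estimation
   problem, so it is exposed; at `kappa = 1` a maximally non-specific column
   gains one count per residue, which smooths noisy columns toward uniform
   while leaving near-deterministic columns (H ≈ 0) essentially untouched.
   Note the flattening is material at small *N* (≈ 40 peptides, 20
   pseudocounts): any pipeline that compares a PWM estimated from peptides
   with a reference PWM should apply the same estimator to both sides
   (see the generator notes below).
3. **Background-significance averaging.**  Residues whose integer count is
   not significantly above the 1/20 background (one-sided binomial test,
   `p > alpha = 0.05`; gap-derived fractional counts are rounded down for
   the test only) have their frequencies replaced by their joint mean,
   preserving column mass.  This removes small fluctuations among
   non-specific residues without touching the selected ones.
4. **Normalisation.**  Probabilities renormalise per column; the odds matrix
   is `20 · p`, so a uniform column contributes a factor 1 and a fully
   uniform PWM scores every peptide exactly 1.  Scores of different-width
   PWMs are therefore on a common scale.
5. **Flank trimming.**  Columns with normalised entropy `H/ln 20 ≥ 0.76`
   are removed iteratively from the two ends only; interior columns are
   never removed, and at least one column (minimum entropy, smallest index
   on ties) is always retained.  The threshold is interpreted on the
   normalised scale `[0, 1]` (0.76 on raw nats would exceed most columns'
   entropy at this alphabet size) and is configurable.

Scanning slides all full windows; ties on the best score go to the smallest
start.  Proteome ranks use the minimum-rank convention for ties so that a
protein's rank never depends on how its equals are ordered.  Residues
outside the 20-letter alphabet (X, *, U) score odds 1 — neutral — so real
proteomes scan without errors.  Coordinates are 1-based and inclusive.
Binding motifs are windows with score ≥ `T = 1000`; the threshold is the
point at which matches to the phage-derived specificity become unambiguous,
and downstream results are insensitive to its exact value because scores of
true sites sit orders of magnitude above it.

## PWM similarity and the specificity tree (`sh3map.tree`)

For two PWMs at a given ungapped offset, the union alignment substitutes
the uniform vector where a matrix has no column; the distance is
`sqrt((1/n) Σ_cols ||p1 − p2||²)` with *n* the union length.  The
normalisation by *n* is placed inside the square root (a per-column RMS);
the alternative (outside) is available behind a flag, as the choice is not
forced by the definition.  Because even non-specific columns of two PWMs
resemble each other, the zero-overlap distance `d_unaligned` (every column
faces uniform, `n = m_a + m_b`) serves as a baseline and

    sim = (d_unaligned − d_aligned) / d_unaligned, clamped to [0, 1].

Clamping matters: for anti-correlated PWMs the best alignment can be worse
than no alignment, and the clamp keeps `1 − sim` a valid dissimilarity.  A
fully informative PWM against a fully uniform one yields sim = 0 exactly
(no alignment beats the baseline); two uniform PWMs are defined to have
sim = 1.  The tree is average-linkage agglomeration on `1 − sim` with merge
ties broken by the lexicographically smallest member id, which makes the
Newick output invariant to input order.

## Network filtering (`sh3map.network`)

Raw candidates are deduplicated by (bait, prey) with colony counts summed
across screens.  The keep rule is a disjunction of independent evidence:
≥ 2 colonies (`multi_colony`); 1 colony plus any literature-type flag
(`literature`); 1 colony plus a PWM score ≥ T for SH3-domain baits only
(`motif` — full-length and fragment baits have no specificity profile to
match).  After the keep step, transcription-factor preys connected to more
than `tf_degree_max = 5` distinct baits are removed with all their edges:
activation-domain TF fusions are a known source of promiscuous
self-activation, and genuine TF preys in such screens bind at most a couple
of baits.  Class counts are reported both before and after TF removal, as
the two bookkeeping conventions differ.

The phage/Y2H agreement statistic takes all network edges whose bait has a
proteome rank table, excluding `motif`-class edges (they were admitted
*because* of the PWM and would bias the comparison).  The cumulative
fraction of edges with prey rank ≤ x, averaged over x, equals
`1 − mean(rank − 1)/P` and is 0.5 under uniform ranks; the null re-draws
each edge's rank uniformly, and the p-value uses the add-one estimator so
it is never exactly 0.  The randomisation count is configurable
(default 10⁴ at desk scale; the statistic itself is exact given the ranks,
only the p-value resolution depends on it).

## Conservation and rewiring (`sh3map.conservation`)

Edges are undirected across species (the bait/prey orientation is an assay
artifact), so projected and reference interactions are endpoint sets.  The
universe of possible interactions is `n_baits · n_preys − n_bp(n_bp−1)/2`,
subtracting the double-counted unordered pairs among proteins that occur on
both sides.  The overlap test is the one-sided hypergeometric upper tail
(equivalently Fisher's exact test of enrichment) with the reference set
restricted to pairs inside the conserved-protein universe.

Rewiring classification of an interaction seen in only one species:

* **Specificity conserved** — if both the source domain and its ortholog
  domain have specificity profiles, `pwm_similarity ≥ 0.5`; otherwise the
  ungapped sequence identity of the two domain sequences ≥ 0.5 (a full
  aligner is deliberately avoided: at domain length the ungapped sliding
  comparison is adequate and keeps the module dependency-free).  An
  ortholog without an SH3 domain is not conserved.
* **Motif conserved** — any binding motif on the target (score ≥ T under
  the source PWM) whose surrounding stretch has ≥ 50% ungapped identity
  somewhere in an ortholog of the target.  Identity is measured over a
  stretch of `context = 15` residues centred on the motif window (clipped
  at protein ends): binding sites are conventionally reported as 15-residue
  stretches, and the wider window is what makes a 50% cutoff selective — a
  50% match to a 6-mer occurs by chance in essentially every 400-residue
  sequence, while ≥ 8/15 has chance probability ~10⁻⁷ per offset.  When the
  subject is shorter than the query, overhanging offsets are allowed and
  overhang positions count as mismatches.
* Scenario (i) = motif ∧ ¬specificity; (ii) = specificity ∧ ¬motif;
  (iii) = neither; both conserved is reported as `conserved_both`; missing
  profile, missing sequence, or no motif reaching T is `unmappable`.

## Function prediction (`sh3map.kcore`)

The modified k-core differs from the classical k-core in conditioning on a
seed set: candidates are non-seed proteins adjacent to ≥ 1 seed, and
pruning removes (simultaneously each round — simultaneity makes the
fixpoint unique and order-independent) every candidate with fewer than k
neighbours among remaining candidates and seeds.  Scores: max k of
membership; 0 for in-network proteins that never qualify; −1 for proteins
absent from the network.  Cross-validation splits seeds into 10 folds,
conditions on 9/10, and scores held-out seeds against sampled negatives;
ROC curves are built over the integer score thresholds including −1 and 0
(both are informative: −1 separates absent from present-but-unconnected)
with trapezoidal AUC, so fully tied scores give exactly 0.5.  Predictions
use k = 3, ranked by score, then seed-degree, then id.

## Annotation similarity (`sh3map.gosim`)

`IC(t) = −ln(n_t/n_root)` with `n_t` the annotation events on t or its
descendants, per namespace.  The gene-pair score is the maximum over
same-namespace term pairs of the Lin form `2·IC(MICA)/(IC(a)+IC(b))`,
which is bounded in [0, 1]; a normalised-Resnik variant is available behind
`measure=`.  Cross-namespace pairs are skipped rather than scored 0 so that
multi-namespace annotation does not dilute the maximum.  Genes without
annotation receive no score.  The benchmark draws, for each bait, `per_bait`
random interactors from the genome, `n_networks` times, and reports four
metrics (percentage of scored pairs, score sum, mean over scored pairs,
mean over all pairs) with add-one empirical p-values.  Note the score sum
is not comparable when the random networks are larger than the real one;
the mean-based metrics are the interpretable ones.

## Competition analysis (`sh3map.competition`)

Motif sites on one protein are clustered greedily left-to-right with a
minimum start-to-start separation of 10 residues; a violating run forms one
cluster represented by its highest-scoring site (acceptance decisions use
the start of the site that opened the cluster, so the later choice of
representative cannot reshuffle clusters).  Per target, motifs are the
clustered union over the PWMs of its interacting domains (per-domain
clustering is available behind a flag).  Two domains on one target are
*competitive* if their accepted sites overlap in residue span, *coincident*
otherwise.  Spearman correlations use average ranks; p-values come from the
t-approximation, or exact enumeration of all n! orderings for n ≤ 9.

## The synthetic world (`sh3map.simulate`)

The generator emits every input the pipeline consumes, with ground truth.
Defaults (one `WorldConfig`): 12 domains (40% class I, 40% class II, 20%
atypical), 85% with phage data; PWM width 10 at sharpness 0.9; 40 peptides
per domain with 10% residue noise (comparable to real per-domain peptide
yields); 300 background proteins with log-normal lengths (median 400,
σ = 0.5) plus the SH3 proteins themselves; 8 true interactions per domain
with the domain's consensus planted at a non-overlapping random position;
zero-truncated Poisson(2) colony counts (P(≥ 2) ≈ 0.69); single-colony
false positives at 50% of the true-edge count; half of single-colony true
edges carry a literature flag; two sticky TF preys at 8 baits each; 80%
ortholog coverage with 5% dual orthologs; rewiring mixture
i/ii/iii/conserved = 0.10/0.29/0.56/0.05 (the relative frequencies seen in
cross-species SH3 comparisons: joint loss dominates, motif-only loss is
rare); a one-namespace ontology with four planted functional modules at 70%
annotation coverage; and a seed module of 40 proteins with internal edge
density 0.35 in a 280-node background at density 0.01.

Generator design notes:

* Non-anchor PWM columns carry a mild domain-specific residue preference
  (weight `0.55 · sharpness`).  Real SH3 profiles show secondary
  selectivity outside their anchors; without it, every same-class domain
  would share one consensus and planted motifs would cross-match between
  domains, which no threshold could untangle.
* Ortholog-domain PWMs are *rebuilt from sampled peptides* with the same
  estimator as species-A PWMs rather than taken verbatim from the
  generator.  Both species' profiles are phage-derived in the setting being
  emulated, and comparing a smoothed estimate with an unsmoothed reference
  would systematically understate similarity (see the pseudocount note).
* Scenario labels are assigned per interaction with exact
  largest-remainder counts; each rewired interaction carries its own
  ortholog-domain context, so a domain involved in several rewired edges
  can exercise different scenarios.
* A master seed fans out through independent child seeds per component
  (`numpy.random.SeedSequence.spawn`), so the same seed reproduces the
  world byte-identically and components can be regenerated independently.

What the generator does **not** emulate: phylogenetic sequence evolution
(ortholog sequences are fresh random backgrounds with motifs spliced in,
not diverged copies), realistic amino-acid composition (background residues
are uniform, which makes proline-rich motifs slightly easier to detect
than in real proteomes), correlated evidence (literature flags are
independent coin flips), assay mechanics (no mating design, autoactivation
gradients, or prey abundance effects), and multi-domain proteins on the
bait side (one SH3 domain per synthetic protein).  Passing recovery tests
therefore demonstrates the correctness and statistical calibration of the
pipeline's machinery under its own model assumptions — not the false
positive/negative rates to expect on real screens.

## Problem sizes and determinism

The test suite and the demo pipeline run at the default world scale
(hundreds of proteins, ~100 interactions), where every stage completes in
seconds; the randomisation counts default to 10⁴ (rank-enrichment null)
and 50–100 (random annotation networks), which already give p-value
resolution well below the decision thresholds used.  All stochastic steps
take explicit seeds; reruns with the same configuration are byte-identical,
and stage reruns from cached upstream files reproduce the same report
entries.

## Known limitations

* The pairwise PWM distance treats offsets exhaustively but ungapped;
  specificities related by an internal insertion would be under-matched.
* The similarity clamp discards information about anti-correlated PWMs
  (all map to 0).
* `universe_size` assumes every bait-prey pair is testable; screens with
  incomplete bait panels violate this and make the conservation p-values
  conservative.
* The k-core ROC treats scores as a complete ordering; graphs where most
  candidates tie at the same k give step-shaped curves whose AUC is
  dominated by the tie-handling convention (trapezoids, here).
* Lin similarity saturates at 1 for any shared leaf term regardless of how
  specific that term is relative to the rest of the annotation corpus.
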