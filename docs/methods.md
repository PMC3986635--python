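# Methods

This note documents the models implemented in `metaconsist`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions.

## Taxonomy and rank projection

A taxonomy is a single rooted tree of nodes with free-text rank labels.
Comparisons happen on the seven canonical ranks (domain, phylum, class,
order, family, genus, species); NCBI's "superkingdom" is identified with
domain, so Viruses, Bacteria and Archaea are all domain-level outcomes.
Projection of a taxon onto a rank climbs strictly upward to the nearest
ancestor-or-self carrying that rank; it never descends, so a taxon above
the requested rank — and any lineage that genuinely lacks the rank, such as
viruses at phylum — yields the `NO_RANK` sentinel.  `NO_RANK` is distinct
from `UNASSIGNED` throughout: the former is a property of a lineage, the
latter of a classifier's abstention.  Taxon identifiers are opaque strings
so generated fixture taxonomies work identically to NCBI dumps.  Merged or
deleted-node resolution and synonym handling are out of scope.

## Community design

Abundances follow a geometric rank-abundance series pᵢ ∝ θⁱ, chosen because
a single parameter spans the whole feasible entropy range (0, ln S] and is
monotone in H′, making inversion well posed.  θ is solved by bisection so
the realized Shannon entropy matches the target within 10⁻³ nats.  The
dominance cap is enforced by exact water-filling: entries above the cap are
pinned to it and the remaining mass is redistributed proportionally (with
the weights sorted, the pinned set is a prefix, so the fixed point has a
closed form); bisection runs against the *capped* entropy so the cap does
not pull the realized H′ off target.

Feasibility requires cap·S ≥ 1, H′ ≤ ln S, and — less obviously —
H′ ≥ −ln(cap): a distribution whose largest probability is at most `cap`
cannot have entropy below ln(1/cap).  Configurations violating any of
these raise a configuration error rather than silently missing the target.

Scenario presets use the two study caps (5% non-dominant, 80% dominant)
and 60,000 reads.  The H′ targets (3.4 for the 40-taxon non-dominant
scenarios, 1.0 for the dominant ones, 3.0 for the 25-taxon bacterial
scenario) are package defaults chosen as realistic for moderately diverse
communities; with the 5% cap, H′ must exceed ln 20 ≈ 3.0 in any case, and
H′ = 1.0 under an 80% cap yields a community dominated by one species at
roughly 65% abundance.

## Rarefaction curve

The expected species-accumulation curve is E[S(n)] = Σᵢ (1 − (1 − pᵢ)ⁿ).
Three anchors define the fit: the origin, the "maximum linear point", and
the maximum sampling point (n_reads, max_taxa).  The maximum linear point
is operationalized as the largest read count at which the discrete slope
E[S(n+1)] − E[S(n)] is still at least 1/e of the initial slope (the
fraction is a parameter); since the slope is strictly decreasing this is
found by bisection.  The fitted form is S(n) = a·ln(1 + b·n) — through the
origin, increasing and concave — with a, b obtained by least squares on the
two non-trivial anchors.  A single-taxon profile produces a degenerate
curve and a warning flag.

## Read sampling and error model

Fragment lengths are uniform on [350, 600] bp (a "range" with no stated
distribution is read as uniform), start positions uniform over valid
offsets, strands Bernoulli(1/2) with minus-strand reads
reverse-complemented.  Coordinates are 0-based half-open on the forward
strand, stated in the truth-table header.  Per-genome read counts are
multinomial on the community abundances, so the emitted total is exact.

The error model separates the two 454-style error modes: each base is
substituted with probability `substitution_rate` (uniform over the three
alternatives), and each maximal homopolymer run of length ≥ 2 is lengthened
or shortened by one base (equal odds) with probability
min(1, homopolymer_rate · run_length).  Defaults are 0.001 substitutions
per base and 0.01 per run-length unit — plausible magnitudes for
pyrosequencing, exposed as config keys since no authoritative per-platform
rates are bundled.  Quality scores, paired reads and chimeras are not
modeled.

The novel-taxon generator (`diverge_genome`) applies i.i.d. substitutions
and single-base indels at given rates.  It is a deliberately simple neutral
stand-in — no codon structure, no rate heterogeneity — sufficient to create
reference-free taxa for combination tests, not a realistic evolutionary
simulator.

## Naive Bayes classifier and ε cutoff

Per genome, all overlapping k-mers are counted with both strands collapsed
onto the canonical (lexicographically smaller of code and reverse
complement) code — reads come from both strands, so strand-collapsed
training is the correct symmetry — then add-one smoothed over the canonical
slot set and log-normalized.  A read's score for genome g is
Σ log p(kmer | g) over its k-mers; the argmax genome's taxon is assigned,
with ties broken lexicographically on genome id (logged) for deterministic
outputs.  k defaults to 8: 4⁸ canonical slots keep per-genome tables at
desk scale while separating genomes well; it is configurable in [4, 12].

The ε cutoff is defined as a posterior retention floor: the softmax
posterior over genomes is computed from the log-likelihood vector and the
assignment is retained iff the best genome's posterior is at least ε.
ε = 0 therefore retains everything, ε = 1 only posterior-1 reads, and the
retained set shrinks monotonically in ε.  This is an interpretation — the
original classifier's ε semantics are not published in a formula — and is
documented as such; the hit-selection rule for the similarity combination
(all surviving hits, not a top-score window) is likewise a configurable
interpretation.

In the similarity-restricted combination, the Bayes argmax runs only over
genomes having a similarity hit with e-value ≤ 10⁻⁵ for that read; a read
with no surviving hit is never assigned.  This reproduces the desired
contaminant behavior: reads with no counterpart in the reference set
cannot acquire a taxon under combination.

## Agreement classes

Per read and rank, calls are projected and classified with the precedence:
unassigned-majority (more than half the methods abstained) → all-same
(every method on one ranked taxon) → no-rank (every method on `NO_RANK`) →
confused (at genus, the disagreeing pair between the two designated
composition methods is in the configured confused-genera set; the set
ships empty because the published list lives in an external reference) →
two-same (≥ 2 but not all methods on one ranked taxon) → all-different.
Agreement on `UNASSIGNED` or `NO_RANK` never forms a consensus: consensus
on absence is not an assignment.  With K > 3 methods the same scheme
applies (m-of-K); K = 3 reproduces the standard three-program design.
Agreement tables always conserve reads — every read lands in exactly one
class per rank — and `UNASSIGNED_MAJORITY` is its own class, so tallies
with and without unassigned reads are both recoverable.

## Sensitivity and precision

sensitivity = 100·n_correct/n_total and precision = 100·n_correct/n_assigned,
per rank and method, with raw counts emitted alongside so every percentage
is recomputable.  Conventions:

* a call is correct at a rank when its projection equals the truth's
  projection, including the case where both are `NO_RANK` (the truth
  genuinely lacks the rank and the method said so);
* reads whose truth lacks a rank stay in n_total — denominators are whole
  datasets;
* zero assignments yield precision NA (0/0 is undefined; n_assigned = 0 is
  attached so a "0" convention can be recovered if preferred);
* the combined strategy's n_assigned counts reads with a ≥ 2-method
  consensus taxon; because consensus is always a ranked taxon, truth-NO_RANK
  reads can never score correct under it.

In the true/false-positive split of agreement classes, the consensus taxon
is judged for all-same/two-same records; for the remaining classes a record
counts as a true positive when at least one method's projected call matches
truth.

## Length curves and thresholds

Reads are binned by length (default 25 bp), the per-bin proportion with a
≥ 2-method consensus is computed, and a weighted least-squares polynomial
(default degree 3, configurable) is fitted to proportion vs. bin midpoint.
The threshold length for an agreement level is the smallest length on a
1 bp grid where the fitted polynomial reaches the level **and stays at or
above it** for the rest of the observed range — a single-crossing read-off
is ill-defined for degree ≥ 2, since polynomials can dip back.  Pooled
datasets are binned after pooling.

## Synthetic data: what passing tests show

Mock genomes are i.i.d. base sequences at controlled GC content attached to
a balanced seven-rank taxonomy (grouping factor 2 per rank step).  Distinct
GC values make genomes compositionally well separated, which is what makes
near-perfect Bayes self-recovery achievable; real genomes share core genes,
repeats and horizontally transferred material, so real-data accuracy is far
lower and the package's perfect-classifier results must be read as
identities (sanity checks of the evaluation machinery), not performance
claims.  Likewise the generated taxonomy has every rank present, so
`NO_RANK` behavior is exercised through hand-built viral fixtures rather
than the generator.

## Problem sizes and determinism

Test and demonstration runs use tens of genomes of 8–30 kb and 10²–6×10⁴
reads — sizes chosen so the full suite and the acceptance script complete
in minutes on one core while still exercising the 60,000-read scenario
configuration end to end.  All randomness flows from a single root seed
through named substreams (community / counts / fragments / errors /
assignment noise), so identical configurations replay with bit-identical
outputs; the pipeline manifest records SHA-256 checksums of every artifact
to make that verifiable.

## Known limitations

* The interpolated-Markov-model classifier is not re-implemented; its role
  enters only via ingested tables or the perturbed-Bayes stand-in.
* The shared-k-mer hit finder used when no external similarity table is
  supplied produces monotone heuristic scores, not calibrated e-values.
* ANOVA on score categories is not performed; only group means and 95%
  t-intervals are reported.
* Results that depend on a specific reference-database snapshot or
  taxonomy release are inherently non-reproducible here and are not
  attempted.
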