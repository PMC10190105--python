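# Methods

This note documents the models, numerical choices and limitations of
`sketchclust` in enough detail to interpret what a green test establishes.

## Sketching

**Canonical k-mers.** A sliding width-k window is taken over each contig
(never across contig junctions in pooled, multi-contig genomes); windows
containing any non-ACGT character are skipped. The canonical form is the
lexicographically smaller of the window and its reverse complement —
chosen over min-of-two-hashes canonicalization so that the k-mer stream
is independent of the hash seed. With the A<C<G<T ordering this equals
numeric comparison of the 2-bit packings, which is what the vectorized
kernel does.

**Hashing.** Canonical k-mers (k ≤ 32) are packed two bits per base into
a 64-bit word and finalized with the MurmurHash3 `fmix64` mixer; the hash
seed (default 42) enters through one splitmix64 round XORed into the
packing. The finalizer is a bijection on 64-bit words, so same-length
k-mers never collide; uniformity is verified by exhaustive enumeration of
all 4⁸ 8-mers in the test suite. Only determinism and uniformity are
contractual; the k ≤ 32 limit is irrelevant in practice because the
automatic k-mer rule yields k ≤ 21 for any genome below ~10¹² bases.

**Bottom-s sketches** hold the s smallest *distinct* hash values (set
semantics, matching Jaccard on k-mer sets). Fixed mode: s = S, default
1000. Variable mode: s = max(1, round(L·P)) — the rounding rule and the
floor of one hash are our pins, as is sampling proportion P defaulting to
1000/L̄ (mean sketch size 1000).

**Parameter rules.** k_o = ⌈log₄(L_l·(1−q)/q)⌉ at q = 10⁻⁴ on the largest
genome length L_l; warning size k_w at q = 10⁻³; a user k below k_w is
reset to k_o with a logged warning. The ceiling is computed with a 10⁻⁹
slack against floating-point grazing. The maximum resolvable threshold is
d_max = −(1/k)·ln(2J_m/(1+J_m)) with J_m = 1/S (resemblance) or
d_max = −(1/k)·ln C_m with C_m = 1/(L_m·P) (containment); pipelines warn
when the requested threshold exceeds it.

## Distances

The fixed-sketch Jaccard uses the **merged bottom-s estimator**: with
U the min(S, |union|) smallest values of the two sketches' union, the
estimate is |U ∩ A ∩ B| / |U|. The alternative reading (intersection over
full sketch union) is biased for partially overlapping genomes; merged
bottom-s is the standard MinHash convention and is what our estimator
noise analysis below assumes.

Containment always uses the shorter genome's sketch as denominator (ties
broken by id), making the operation argument-order invariant.

Zero similarity clamps the distance to 1 (the log diverges); distances
are also capped at 1 from above. Both transforms are strictly decreasing
in the similarity on (0, 1].

## Streaming MST and single linkage

Blocks of t = 8 matrix rows (upper triangle) are streamed; each logical
worker keeps the Kruskal forest of the edges it has seen. Edge-partition
safety (an edge not in the MST of some sub-graph containing it is not in
the global MST) guarantees the merged forest is the exact MST — property
tested against a brute-force oracle for arbitrary block sizes and worker
counts. Ties are broken by (weight, u, v) everywhere, so the MST and the
clustering are deterministic and worker-count invariant. Peak retained
edges are instrumented and bounded by workers·(t+1)·N.

Cutting edges with weight strictly above the threshold reproduces
single-linkage agglomeration stopped at that threshold (oracle-checked
against scipy's single linkage).

**Noise pruning.** Local density dens(x) = number of neighbours at
distance strictly below the threshold, accumulated during streaming (one
pass, no second scan). Within each cluster, members with
dens(x) < min(Q1, 2) are noise, where Q1 is the first quartile of the
cluster's own member densities with linear interpolation (type-7) — the
quartile scope and method are our pins. MST edges incident to noise
vertices are cut and components recomputed, so noise ends as singletons.

**Stored MSTs.** The MST file records format version, mode, k, S or P,
hash seed, N, a genome table (index, id, length, density) and edge lines
at 6 significant digits. Re-cutting a stored MST at the *same* threshold
reproduces the fresh run exactly. Re-cutting at a *different* threshold
is supported but reuses the stored densities for noise pruning: exact
densities at the new threshold would require all pairwise distances,
which the linear-memory design deliberately never retains. The cut itself
is exact for any threshold; only the pruning step inherits the
generation-time densities (a warning is logged).

## Greedy incremental clustering

Sketches are processed in stable descending length order. The minimum-
distance representative within the threshold wins; ties go to the
earliest-created cluster. Distances among redundant (non-representative)
genomes are never computed — the clustering records the distance-
computation count so tests can assert the work shrinks as the threshold
grows. Representatives are never re-elected: a later genome is never
longer than an existing representative.

## Evaluation

Purity, MI, entropy and NMI are implemented directly from their
definitions in natural logarithms (0·ln 0 := 0), with NMI normalized by
the arithmetic mean of the entropies; agreement with scikit-learn's
implementation to 10⁻¹² is a test oracle. Degenerate case (both
partitions single-cluster, zero entropy): NMI := 1, since the partitions
are identical. Coverage = fraction of genomes in clusters of size ≥ 2;
purity is reported alongside coverage because all-singleton clusterings
are trivially pure. Impurity reports break dominant-class ties by larger
total genome length, then label order.

## Simulators and what desk scale establishes

All generators are deterministic given a `numpy.random.Generator`.
Lengths are scaled down from the ~10 Mb genomes of full-scale experiments
so everything runs on one CPU in minutes: 100 kb for the seed-mutant
design, 1 Mb seeds for the containment design. The sequences are i.i.d.
uniform ACGT — no GC bias, repeats or compositional structure — so green
tests establish the estimators' statistical behaviour, not robustness to
real genomic composition.

**Mutation model.** Each base independently mutates with the given rate;
the event is substitution, single-base deletion or single-base insertion
(after the site) with equal probability, so the expected length change is
zero. Event counts are binomially distributed and property-tested.

**Seed-mutant design** (5 seeds + 30 mutants each at rate 0.045): the
generator *verifies* the intended distance structure with default
resemblance sketches — mutant-to-own-seed Mash distance < 0.05 (failing
draws are redrawn, bounded retries), same-seed mutant pairs > 0.05 — and
errors out otherwise; redrawing enforces the stated structure (a few
percent of draws fall on the wrong side of 0.05 through estimator noise).
One scaling effect: at 100 kb / k=15, a seed pair is expected to share
one or two sketch hashes by chance, bounding the inter-seed estimate near
−ln(2/S)/k ≈ 0.41 rather than the value 1.0 seen at 10 Mb scale (where
the expected shared count is ≈ 0.05 and the Jaccard estimate is 0). The
verification therefore requires inter-seed distance > 0.3 — still 6× the
clustering threshold, which is all the clustering result depends on.

**Containment design** (8 seeds × 50 prefix fragments, uniform proportion
in (0, 1]): prefixes guarantee exact k-mer containment. Here scaling has
a quantitative consequence: the containment estimator's noise depends on
the *absolute* sketch size m = L·P, not on length ratios. For a fragment
of proportion u, the expected estimate deficit is ≈ 0.4·√((1−u)/m), so at
1 Mb seeds and P = 1/1000 (mean sketch ≈ 500) fragments below roughly a
third of the seed length drift past an AAF threshold of 0.001 and found
their own clusters. Greedy AAF clustering on this world lands at
NMI ≈ 0.78–0.87 with ~25–40 clusters — matching the known behaviour of the
method at comparable sketch sizes at full scale, but not the NMI ≈ 0.98
achieved when the mean sketch holds several thousand hashes. The
corresponding acceptance test encodes the full-scale level (≥ 0.95) and
is expected to fail at desk scale; the qualitative claims (AAF NMI far
above fixed-sketch Mash NMI at every tested S; Mash producing several
times more clusters than real classes) hold robustly and are tested
separately.

**Mutation panel** (rates 1–10%, k ∈ {16,18,21}, S ∈ {1000,10000},
L = 100 kb): mean estimates track the rate within ±0.01 for rates ≤ 5% at
S = 10⁴, and RMSE against the identity model is non-increasing in S. The
downward small-k bias from chance k-mer collisions scales as L/4^k; at
L = 100 kb it is ~2·10⁻⁵ at k = 16 — below estimator noise — so the panel
additionally includes k = 12, the collision-pressure equivalent
(L/4¹² ≈ 6·10⁻³) of k = 16 at 10 Mb, where the bias is clearly measurable.

## Known limitations

* Sketch distances lose accuracy for highly divergent genomes (distance
  ≳ 0.1 at S = 1000) and for short sequences; the toolkit targets long
  assembled genomes with relatively high similarity.
* Re-cutting a stored MST at a new threshold reuses generation-time
  densities for noise pruning (see above).
* k is limited to 32 by the 64-bit packing; the automatic rule never
  approaches this.
* The greedy pipeline's quality degrades when a class's natural
  representative is not its longest member — this is inherent to the
  heuristic and is exactly what the seed-mutant benchmark demonstrates.
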