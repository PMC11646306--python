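# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `arachne` pipeline: profile-HMM annotation of spider
silk (spidroin) genes and hox clusters, rearrangement counting against an
ancestral gene order, Brownian-motion ancestral-state reconstruction, and
the synthetic-genome benchmark that exercises all of it.

## Nucleotide profile HMMs

**Model.** Each terminal-domain class (and each hox gene's homeobox) is
modelled as a linear profile of `M` match states with per-position
emission distributions over {A,C,G,T}, insert states emitting the
background distribution, and delete states. The model is trained from a
reference multiple alignment:

- *Conserved-core trimming.* Leading and trailing alignment columns are
  cropped until the first/last window of 10 columns reaches mean
  conservation ≥ 0.6, where a column's conservation is the excess majority
  fraction `(top count − 1)/(rows − 1)`. This statistic is 1 for an
  invariant column and ≈ 0.25 in expectation for unrelated random DNA
  *independently of row count*, so the 0.6 threshold behaves consistently
  for alignments of 2 rows and of 200 rows (the plain majority fraction
  would saturate at 0.625 for random 2-row alignments and never reject).
- *Match columns* are those with gap fraction < 0.5.
- *Emissions*: Laplace `+1` pseudocounts, `(count + 1)/(total + 4)`;
  *transitions* are counted from each row's implied state path with `+1`
  pseudocounts; the *background* is the training-set base composition.
  Pseudocounts keep the small per-class reference sets well-behaved.

**Scoring.** Local Viterbi alignment in log2-odds ("bit") units against
the background null. Alignment is local in both sequence and model: a path
may enter any match state from an unscored begin and leave any match state
(flanking sequence is free). Insert emissions equal the background, so
inserts cost only their transition probabilities. `N` bases emit with
log-odds 0 in every state — assembly gaps neither attract nor repel hits.
The inner loop is an `O(L·M)` dynamic programme JIT-compiled with numba.

**Multiple hits.** Scaffolds are scanned in overlapping windows (window
`max(5000, 40·M)` bp, overlap `4·M` capped at 2 kbp, far larger than any
plausible domain alignment); within a window the best hit is extracted by
traceback and its span masked to `N` until the best remaining score falls
below the reporting threshold. Duplicate candidates from window overlaps
are reduced to the best non-overlapping set per strand. Both strands are
scanned; minus-strand hits are reported in forward coordinates with a
strand flag, which makes scores reverse-complement symmetric by
construction (and tested).

**E-values.** Each profile is calibrated by scoring `n = 200` i.i.d.
background sequences of 1000 bp (seeded from the run configuration) and
fitting a Gumbel law to the maxima by maximum likelihood (location `mu`,
rate `lambda = 1/scale`). A hit of score `S` in a search of total length
`L` (both strands counted) has

    E = (L / 1000) · exp(−lambda · (S − mu)),

i.e. the search is treated as `L/1000` calibration-sized windows. On a
fresh random database of the calibration size the best hit has E ≈ 1
(verified by Monte Carlo); an exact planted 150-column consensus in
100 kbp of background scores E below 1e-70, which is what makes the strict
1e-10 reporting threshold workable.

**Bias score.** The aligned span is re-scored against a null re-estimated
from the span's own base frequencies; the loss relative to the background
null is `n · KL(span composition ‖ background)` bits — always ≥ 0 and
monotone in compositional skew. The `bit > bias` filter therefore rejects
hits whose score is attributable to low-complexity composition (e.g. the
glycine/alanine-rich spidroin repeat region) rather than positional match.
This definition is ours; external search engines compute a related but
differently derived bias correction.

An adapter for external `nhmmer --tblout` output (`parse_nhmmer_tblout`)
produces the same hit records for users who prefer the external engine; it
is not used by the pipeline or tests.

## Spidroin annotation

Filters (configurable; defaults are the published operating point):
E-value < 1e-10, bit score strictly greater than bias score, and model
coverage ≥ 90% of profile length. Overlapping filtered hits from all class
searches (same scaffold and strand, ≥ 1 bp shared, transitively) collapse
to a single call for the member with the lowest E-value; ties break by
higher bit score, smaller start, then class name, making outputs fully
deterministic.

Pairing walks NTD calls 5′→3′ in strand orientation and joins each to the
nearest downstream unused CTD on the same scaffold and strand; gene span is
the NTD-start-to-CTD-end genomic distance (introns included) and pairs
above 100 kbp are rejected — spidroin coding sequences are typically about
10 kbp, so the cap tolerates introns and long genes while excluding joins
of unrelated hits. Design choices where the procedure was genuinely open:

- pairing is strand-aware (head-to-head "genes" are biologically
  impossible);
- a CTD is consumed only by a successful pairing, so a CTD too far from
  one NTD stays available to a closer one;
- a rejected over-span pair leaves both domains reported as unpaired.

Classification: equal domain classes keep the class; *unclassified* acts
as a wildcard deferring to the partner; two wildcards give *unclassified*;
any other disagreement is *discordant*. The Mesothelae-specific CTD
(`MesCTD`) is an eleventh class treated as a CTD-side wildcard. For
candidate novel CTDs, `extract_candidate_ctd` walks codons in a given
frame/strand from a start position and returns the ≤ 500 bp immediately
upstream of the first stop codon.

## Hox clusters

Homeobox hits from all 10 gene profiles are filtered at E < 1e-20 and
merged into loci when overlapping or within 1 kbp; each locus takes the
gene of its lowest-E member. Partitioning along a scaffold is
duplicate-aware: a repeated gene is tolerated inside a cluster only as an
immediately adjacent (tandem) copy within the gap threshold; any other
repeat opens a new cluster. Large gaps alone never split a cluster,
because real B clusters stretch over tens of Mbp with Mbp-scale internal
gaps. A singleton cluster more than 5 Mbp (configurable; the conventional
"clearly separated" gap) from a neighbouring cluster that already contains
its gene is re-attached as a *separated extra copy*.

The multi-gene cluster retaining *ftz* is labelled A, its ftz-less partner
B; a genome with a single multi-gene cluster (mite-like outgroups) gets A;
ambiguous configurations stay unlabelled with a logged warning. A cluster
is *fragmented* — and excluded from rearrangement counting — iff it is
missing expected genes *and* its first or last member lies within 10 kbp
of a scaffold end.

**Rearrangement counting.** Against the ancestral order
(lab, pb, Hox3, Dfd, Scr, ftz, Antp, Ubx, AbdA, AbdB — the canonical
arthropod order, config-overridable):

- *losses* = ancestral genes absent from the cluster; *ftz* absence in a B
  cluster is definitional, not a loss;
- *tandem duplications* = adjacent same-gene copies beyond the first;
- *inversions* = after collapsing duplicates and dropping lost genes, the
  exact minimum number of signed reversals transforming the ancestral
  order into the observed signed order, found by bidirectional
  breadth-first search over reversal moves (exact at ≤ 10 genes; verified
  against a full-state-space enumeration for 5 genes);
- residual non-adjacent extra copies are tallied as *unexplained*.

Limitations: transpositions are not atomic events and surface as 2–3
inversions; whole-cluster orientation is taken as observed (the count is
zero *iff* the signed member list equals the ancestral list, so a cluster
assembled entirely on the minus strand scores one inversion — the
simulator plants clusters in forward orientation).

## Ancestral states

Continuous traits (copy numbers, event counts — treated as continuous
exactly as contMap-style mapping does) are reconstructed on a rooted,
branch-length-bearing tree under Brownian motion. The implementation is
two-pass message passing: each subtree is condensed to a
(value, effective branch length) message; the downward pass supplies the
complementary message, so every internal node's estimate is the
precision-weighted mean over all neighbouring regions — identical to
re-rooting the tree at each node, and verified against a dense GLS solve
of the phylogenetic covariance system to < 1e-8 on random trees. Branch
profiles are linear interpolations between parent and child estimates at
`n_points = 20` positions including both endpoints. Zero or missing branch
lengths and non-bifurcating roots are rejected up front.

## Synthetic benchmark

The generator stands in for real assemblies and reference databases so
every stage is testable offline:

- *Reference sets*: one random consensus per class/terminus
  (150 bp domains; 180 bp homeoboxes), rejection-sampled to pairwise
  identity ≤ 60% so cross-class near-misses occur but the best class is
  decidable; 20 aligned variants per set at 10% substitution divergence
  with geometric indels (event probability 0.02, mean length 2). At
  divergence 0 the rows are exact copies.
- *Genomes*: i.i.d. background at GC 0.35; spidroin genes planted as
  NTD variant + low-complexity repeat region (mutated tandem copies of a
  glycine/alanine-codon-like motif) + CTD variant on a random strand,
  spans drawn in [5, 50] kbp; solitary domains, discordant-class pairs and
  oversized (120 kbp) pairs planted on request; hox clusters planted on
  their own scaffolds in the specified signed order with configurable
  losses, tandem duplications, inversions, internal gaps and scaffold-edge
  truncation. Placement distributes random gaps over the slack, so planted
  features can never overlap. Identical seeds give byte-identical output.
- *Default benchmark* (`default_benchmark_spec`): ~2 Mbp over 4 scaffolds,
  24 spidroin genes in 6 classes at 10% divergence, one intact hox cluster
  and one B-type cluster with 1 loss + 1 tandem duplication + 1 inversion,
  seed 42. These are the study conditions used by the end-to-end tests and
  the acceptance script; on one CPU the full pipeline runs in ~3 minutes.

What the simulator does *not* emulate: the repeat landscape of real spider
genomes (~55–70% repetitive), sequencing/assembly error, fragmented
contigs (beyond the one planted truncation), pseudogenes, and within-class
sequence heterogeneity beyond i.i.d. substitution. Passing the benchmark
therefore demonstrates correctness of the procedure's logic and the
detectability arithmetic, not robustness to real assembly artefacts; a
`hard_mode` flag adds tandem-repeat background for stress testing
specificity but is excluded from the default conditions.

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.default_rng` seeded by the run
  configuration; calibration seeds derive from the run seed and the sorted
  profile order. Reruns with the same configuration are bit-identical and
  each stage writes a manifest of config and output hashes to prove it.
- Scores are float64 throughout; the Viterbi kernel is exact dynamic
  programming (no banding, no heuristics), so it agrees with brute-force
  path enumeration to 1e-9.
- Degenerate inputs fail loudly: uncalibrated profiles cannot scan,
  Gumbel fits with non-positive scale raise, fragmented clusters refuse
  rearrangement counting, and unknown class/gene labels are errors.
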