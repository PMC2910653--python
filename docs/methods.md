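# Methods

This note documents the models and algorithms implemented in `retromark`,
the defaults and why they were chosen, the numerical details, and what the
synthetic generator does and does not emulate.

## Coordinates and annotation parsing

RepeatMasker `.out` coordinates are kept in their native convention
throughout: 1-based, fully closed intervals on both the genomic sequence
and the family consensus. Complement rows (orientation `C`) print their
consensus interval as `(left) end begin`; these are normalised on parse so
`consensus_start < consensus_end` always holds and the strand field alone
records orientation. Downstream continuity checks rely on this single
convention. Rows flagged with the trailing `*` (a higher-scoring overlapping
hit exists) are retained and flagged rather than dropped: whether such rows
belong in nesting screens is unsettled, so exclusion is left to the caller.
Unknown or extra columns are ignored, since `.out` dialects differ across
RepeatMasker versions. RepeatMasker reuses its ID column to link fragments
of one interrupted element; parsed `hit_id`s are suffixed positionally when
duplicated so they remain unique within a file.

## Nested-insertion (TinT) detection

A transposition-in-transposition event is recognised from coordinates
alone: three mutually adjacent hits on one sequence in which the outer two
belong to the same family and strand, both are at least `min_fragment`
(default 30 bp) long, and their consensus coordinates are continuous across
the gap — for a plus-strand host the right fragment resumes where the left
fragment stopped, for a minus-strand host the roles reverse. Continuity is
accepted when the consensus gap deviates from zero by at most
`continuity_window` (default 30 bp), absorbing small alignment slop at the
breakpoint. Both defaults are conservative and configurable; they are the
package's own choices, as no standard values exist. Two candidate guests
between the same host fragments are ambiguous and produce no event
(precision over recall), and each hit can be the guest of at most one
event. Self-nesting (a family landing in its own older copies) is counted
like any other cell.

## Activity-period model

Family *f* is modelled as active at times distributed Normal(μ_f, σ_f) on a
latent relative axis where larger values are more recent. A guest inserting
at time *t* can only land in host copies already present; host family *j*
offers target mass w_j·Φ((t−μ_j)/σ_j), where w_j is its relative copy
abundance. Averaging the host-choice probability over the guest's insertion
time has a closed form, giving the cell probabilities

    P(host=j | guest=i) = w_j Φ(d_ij) / Σ_k w_k Φ(d_ik),
    d_ij = (μ_i − μ_j) / sqrt(σ_i² + σ_j²),

and the count matrix is multinomial per guest row. The closed form is exact
(the Gaussian convolution of a Gaussian CDF), so no quadrature is needed.
The model encodes the one essential asymmetry — young elements insert into
old ones, never the reverse — with two parameters per family.

Identifiability: nesting counts carry no absolute time scale, so the
likelihood is invariant to shifting all μ and jointly rescaling (μ, σ).
Fits are normalised to mean(μ) = 0 and mean(σ) = 1, a pure
reparameterisation. Copy weights w default to each family's share of event
participation (a proxy for copy number when annotation totals are not
supplied; the CLI passes true per-family hit counts).

Estimation is multi-start L-BFGS-B on (μ, log σ), 10 seeded restarts by
default, σ floored at 10⁻³, μ bounded at ±50 (the likelihood saturates well
before that). The spreads of the extreme families — the oldest (whose
hosts are only themselves) and the youngest (who see every family as an
almost-certain target) — are only weakly identified and can collapse to
the floor, which produces degenerate activity intervals. A mild ridge on
the dispersion of log σ (strength 2 by default) keeps fits away from that
boundary without materially constraining well-identified families; the
reported log-likelihood is the unpenalised data likelihood. Activity
intervals are central quantiles of the fitted activity density,
μ ± z(level)·σ with z(0.5) = 0.6745 and z(0.9) = 1.6449.

In simulation checks (6 families, several thousand events) the fitted
locations recover the true activity order essentially perfectly (Kendall
τ ≈ 1), and the 90% intervals cover the normalised true locations in well
over 90% of family×replicate combinations at 3,000 events per replicate.

## Marker matrices and clade support

States are `+` (present), `-` (absent), `?` (missing), `d` (deleted). A
deletion destroys the locus, so presence of the original insertion is
unknowable there: `d` is coded as missing in every downstream computation,
never as absence. Clade support counts a marker for a clade when it is
present in every *scored* member and absent in every *scored* taxon of the
frame outside the clade; missing/deleted entries are compatible with either
side, and a marker with no scored taxon on one side is ignored. For a local
trichotomy the two rival clades are counted the same way, yielding the
[k l m] pattern. Taxon identity in the packaged marsupial matrix is
positional with full species names, because the published table uses the
abbreviation "Pt" for two different taxa.

Orthology validation of a candidate locus checks six criteria per taxon:
(1) element at the reference alignment columns within a slop (default 2
columns), (2) same orientation, (3) same subtype, (4) matching target-site
duplication when recorded, (5) shared diagnostic indels (gap pattern within
the element span), (6) a consistent, interpretable site (adequate flank
alignment and element occupancy). Criteria whose inputs are unavailable are
skipped. "Present" requires every checkable criterion to pass; "absent"
requires a clean empty site (aligned flanks, fully gapped span); everything
else is "missing", with the failed criteria reported.

## Irreversible parsimony

Characters are binary and irreversible: a 0→1 gain costs one step on the
edge where it occurs, 1→0 is forbidden (infinite cost), and the root —
where the all-absent outgroup attaches — is fixed at state 0. Missing and
deleted leaf states cost nothing in either state. Scoring is a two-state
dynamic program over the rooted tree, vectorised across characters with a
large-integer infinity, so polytomies are handled natively. The consistency
index divides the minimum conceivable steps (one per character with any
scored presence) by the realised length; CI = 1 means every marker fits the
tree with a single gain.

The heuristic search replicates PAUP-style practice: each replicate builds
a starting tree by stepwise addition in a seeded random taxon order, every
insertion point chosen to minimise length (ties broken uniformly at
random), then branch-swaps to convergence. TBR is implemented on per-edge
cost vectors: removing an edge splits the tree into a context part R and a
detached part S; one down-pass and one context-pass over R and an
all-directions pass over S give, for every (reattachment edge in R,
rerooting edge of S) pair, the exact score of the reassembled tree by
combining three two-state vectors — no whole-tree rescoring. Sweeps accept
the first improving bisection; SPR restricts S to its original orientation,
and NNI additionally restricts reattachment to the neighbourhood of the
original position. After the replicates, the set of best trees is closed
under equal-score TBR moves (every stored tree is swapped, equal-score
rearrangements are added, until no new topology appears), so the returned
set is the full connected plateau of co-optimal binary topologies, not just
replicate endpoints. Topology identity is a canonical rooted form with the
outgroup at the root. Everything is reproducible from a single seed.

Branch support is summarised by per-branch gain bounds over all optimal
reconstructions: the minimum (gains forced onto the branch) and maximum
(gains that could sit there). `collapse_zero_length_branches` contracts
branches by either rule; the conservative `min` rule keeps only branches
that carry a forced gain in every optimal reconstruction. On the packaged
marsupial matrix the 405 co-optimal binary trees collapse under the `min`
rule to a single partially-resolved tree whose clades are exactly the
marker-forced ones; the published count of six equally parsimonious trees
is not recoverable from the printed matrix under any collapse convention
examined (none, min, max, ACCTRAN/DELTRAN reconstruction lengths give 405,
1, 4, 2 respectively) and presumably reflects settings or matrix details of
the original analysis not recorded in print. The scientifically meaningful
quantities — length 53, CI 1, the strict consensus topology, and every
per-clade support count — reproduce exactly.

The strict consensus is computed by intersecting clade sets and rebuilding
the tree from the surviving clades. Newick parsing and serialisation are
delegated to dendropy behind the package's own tree structure; polytomies
and branch lengths round-trip.

## Insertion significance test

Under a hard polytomy each marker independently supports one of the three
resolutions of a rooted triplet with probability 1/3, so k conflict-free
markers give p = (1/3)^k: three markers (p = 0.037) reach α = 0.05. For
conflicting patterns [k l m] the test statistic is the support margin
k − max(l, m); the exact p-value sums trinomial(n, 1/3) probabilities of
all outcomes with at least the observed margin, by full enumeration. With
l = m = 0 the only qualifying outcome is (k, 0, 0), so the enumeration
reduces exactly to the closed form. No multiple-testing correction is
applied across edges.

## Synthetic generator

The generator produces coordinates and labels, not nucleotide sequences.
Along each branch of a rooted species tree (branch durations on the same
axis as family activities; the root's edge length, if any, acts as a stem),
each family inserts as a Poisson process with intensity
`insertion_rate · N(t; μ, σ)`, at uniform random genomic positions in a
growing coordinate line. An insertion landing at least `min_fragment`
inside an existing element splits it — continuous consensus coordinates,
a ground-truth nesting event; closer to an edge it truncates the host
instead, generating realistic near-miss negatives for the detector.
Insertions are inherited by all descendant tips; every insertion is a
presence/absence marker with a known gain edge. Ground-truth ledgers record
per-tip annotations and family counts, nesting events (flagged as
detectable when the final triple is still intact at the tip), gain edges,
and every perturbation.

Perturbations, applied to the matrix after inheritance and all logged:
missing data (`?`) masks cells at `missing_rate`; non-specific deletion
turns present cells into `d` at `deletion_rate`; incomplete lineage sorting
makes a marker gained on an internal edge fix discordantly — present in one
child lineage of its gain edge plus the sibling lineage, a non-clade set —
at `ils_rate`. This is a fixed hemiplasy pattern, not a coalescent model:
it produces the qualitative signature (matrix conflicts increasing with the
rate) without modelling population sizes or branch-length-dependent sorting
probabilities. Markers on tip branches are exempt, as they see no
speciation.

The default configuration is an 8-tip tree of depth ~1 with a stem, six
families (two old shared, one intermediate, two lineage-restricted younger,
one young) with overlapping activity windows, rates giving a few hundred
insertions per tip on a 200 kb line — enough nesting and per-edge marker
density (≥3 markers per internal edge) for exact tree recovery on clean
runs. What passing tests on this generator demonstrate: the detector,
estimator, and search are correct under the model's own assumptions
(random insertion sites, no precise excision, Gaussian activity). What they
do not demonstrate: robustness to alignment error, segmental duplication,
fragmented assemblies, insertion-site preference, or coalescent ILS — all
absent from the generator by design.

## Numerical choices and limitations

- DP infinities are `2^30` in int64 arithmetic: exact, overflow-safe for
  any realistic matrix.
- Search determinism: one `numpy` Generator drives taxon orders, tie
  breaks, and restarts; results are byte-stable for a fixed seed.
- The plateau-closure step makes the optimal-tree set complete but can be
  expensive when ties are astronomically numerous (heavily unresolved
  matrices); `keep_all_optimal=False` skips it and returns one best tree.
- The activity model assumes Gaussian activity and a constant per-copy
  hospitability; real families' activity profiles are skewed and target
  availability decays with divergence. Only relative, not absolute, time is
  estimated.
- `multinomial_p` enumerates O(n²) outcomes — instant for marker counts in
  the tens; it is not intended for thousands of markers.
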