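# Methods

This note documents the models and procedures `oyescan` implements, the
defaults that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was open.

## Phenotype-concordance screen

Proteomes are compared all-vs-all with global affine-gap alignment
(BLOSUM62; a length-n gap costs 11 + n; `X` scores 0 against everything).
Raw scores are mapped to bits with the gapped Karlin–Altschul constants
λ = 0.267, K = 0.041. For each genome pair, each gene's best hit is the
highest-scoring partner (ties broken by raw score, then lexicographic gene
id); mutual best hits at ≥ 50 bits become edges and orthogroups are the
connected components of the edge graph. Paralogs inside one genome count
once toward presence. A DIAMOND-style seed prefilter skips alignment of
pairs sharing < 5 % of 4-mers; it is conservative at the divergences the
screen targets (homologs at ≤ 30 % divergence share ≈ 25 % of 4-mers,
unrelated proteins ≈ 0.2 %) and can be disabled, and a test asserts it
leaves the orthogroups unchanged on a planted pangenome.

The screen itself is a row filter: orthogroups whose binary presence
vector equals the phenotype indicator. A label filter keeps orthogroups
with at least one member carrying a target annotation (e.g. the
Old Yellow Enzyme label) from a user-supplied gene → label table; the
original study's functional annotation pipeline is out of scope and
externalized to that table. The orthology threshold is expressed in bits
rather than the E-value scale of the original orthology tool, because
absolute E-values are not portable across aligners and calibrations;
presence/absence, not the cutoff itself, drives the screen.

## Alignments, trimming, profile HMMs

Progressive alignment uses a 3-mer distance matrix, an average-linkage
guide tree, and profile–profile merges scored by the expected BLOSUM62
substitution score between residue-frequency columns under the same gap
convention as the pairwise aligner, so two sequences reproduce the optimal
pairwise alignment exactly. Trimming excludes sequences below a minimum
unaligned length *first* (the family thresholds in the source analyses were
500 aa for the reductase set and 450 aa for the Δ⁶-reductase analog;
synthetic families use proportionally smaller values through the same
config knob), then cuts columns outside a reference-coordinate domain
window, then removes columns whose gap fraction is *strictly greater* than
0.95. Trimming is idempotent.

Profiles follow the classic match/insert/delete topology. Columns with
residue occupancy ≥ 0.5 become match states; emissions take Laplace
pseudocounts (α = 1 by default; a column with counts {A:2} gives
P(A) = 3/22); transitions are counted along each row's implied state path
with a pseudocount of 1 per legal transition; D→I events observed in a row
are not modeled (the residue is attributed to a fresh insert). Insert
states emit the background (Robinson–Robinson composition), so insert
emissions cancel in log-odds. Two scoring modes:

* **glocal** — model traversed begin→end, sequence fully consumed, terminal
  inserts absorbing flanks; verified against brute-force enumeration of
  all state paths to < 1e-9 nats on the small-model grid.
* **local** — uniform 1/K entry into and exit from any match state,
  unaligned flanks free; used for search. The Viterbi traceback carries the
  start coordinate, giving the envelope of matched residues.

E-values: `null_n` (≥ 200, default 300) i.i.d. background sequences of the
database's median length are scored in local mode and a Gumbel is fitted by
the method of moments (β = s·√6/π, μ = m − γβ) — stable at these sample
sizes with no iterative solver. E = database size × Gumbel survival. The
original study's E-value ceilings (1e-240/1e-220/1e-260) belong to a
different calibration and database scale and are not transferable; the
ceiling here is a config value (default 1e-5 against the synthetic null).

**Fusion decomposition.** A protein with ≥ 2 non-overlapping hits from
distinct models, ordered along the sequence, becomes a fusion call; each
adjacent pair is split at the floor midpoint of the inter-envelope gap, and
the domain subsequences are emitted separately — mirroring how fused
reductase⊕isomerase genes are split before read mapping.

## Genomic context

A target gene is *proximal* to a marker if some marker on the same contig
has at most `window_genes` (default 8) intervening genes or lies within
`window_bp` (default 10 kb) edge-to-edge; either suffices. The source
figures state "close proximity" without a number, so both radii are
explicit config values; distances are measured between nearest feature
edges, strand-agnostic. Rank distance is reported (1 = directly adjacent)
so either reading of "directly adjacent" can be tabulated. A genome with
markers only elsewhere is *same_genome*; with none, *absent*. Summaries
report n_targets ≥ n_copresent ≥ n_proximal.

## Trees, clades, residues, ancestral states

Distances between aligned family members are Poisson-corrected
(d = −ln(1−p) over columns where both rows have residues), capped at
d_max = 5 to avoid infinities on saturated pairs. Tree inference is
standard neighbor joining (the likelihood-based inference of the original
analysis is deliberately replaced by NJ; no bootstrap). Q-matrix ties break
at the lowest (row, column) pair; negative branch lengths are clamped to
zero with the deficit shifted to the sister edge; the final join yields a
trifurcating root, so three taxa reproduce the closed-form pendant lengths.
NJ recovers every randomly generated additive topology (RF = 0) in the
test battery and matches scikit-bio's implementation on a fixture.

Clade labels come from anchors: the tree is rooted on the edge separating a
(monophyletic) outgroup, each label's clade is the smallest rooted clade
containing all its anchors, and a leaf inherits the label of the unique
clade containing it ("unassigned" under nested or no claims; anchors keep
their own label). Residue positions of interest (e.g. 166/167/171/253 in
reference numbering) are mapped through the reference row's gap structure
to alignment columns, and per-clade frequency vectors over the 20 residues
plus gap are reported.

Ancestral states use Fitch parsimony with gap as a 21st state. The reported
per-node sets are the preliminary (bottom-up) Fitch sets — at the root these
are exactly the states attainable in some most-parsimonious reconstruction —
and the score is the number of union events, verified against exhaustive
minimization. This is a stated substitution for the probabilistic ancestral
reconstruction behind the original figures; posterior probabilities are out
of scope.

## Metagenome profiling

Reads are assigned by k-mer containment: each panel gene is indexed by the
union of its forward and reverse-complement k-mers (k = 21), and a read
goes to the gene sharing the largest fraction of its k-mers if that
fraction ≥ θ = 0.3; ties and sub-threshold reads stay unassigned. This
replaces the original short-read aligner with a deterministic,
dependency-free rule that is ample for presence/CPM at synthetic error
rates (a 150-bp read with two substitutions keeps ≥ 30 % of its 21-mers).
Counts are summed across runs per biosample *before* QC; samples under the
read floor (default 10⁶, a config value) are reported but excluded from
tests; CPM = count/total × 10⁶; presence ⇔ CPM strictly > 1.

Prevalence uses the one-sided pooled two-proportion z-test; the Yates
continuity correction is on by default (matching the common default of the
standard routine) with a flag to disable. Degenerate pooled proportions
return p = 1 (pooled 0) or p = 0.5 (pooled 1), flagged. Abundance uses the
one-sided Wilcoxon rank-sum test; following the standard R routine, the
exact distribution is used when both groups have < 50 tie-free values and
the normal approximation (midranks, tie-corrected variance, continuity)
otherwise — the approximation alone deviates from the exact tail by up to
0.06 when one group has ≤ 2 values, so the exact small-sample path is the
correct default. Zero-CPM samples are included by default (a flag
reproduces the plot-style exclusion); Benjamini–Hochberg adjusted p-values
are reported alongside raw ones when several genes are tested.

## Synthetic data: what it emulates, and what it does not

The pangenome generator plants exactly one family whose presence matches
the phenotype, decoys that each violate it somewhere, per-genome singleton
genes, a fused target⊕partner variant in designated carriers (with the
partner also present as a stand-alone gene in other positives, as in the
two-enzyme pathway), and marker genes adjacent to the target or on a
second contig. Proteins evolve by independent per-site substitution,
uniform over the 19 alternatives (default 0.15 per copy; pairwise
divergence ≈ 28 %) — no indels, so diagnostic-column logic stays exact.
Genes are tiled left-to-right with 200-bp spacers, "+" strand by default
(randomization behind a flag), and reverse-translated with seeded
synonymous-codon choice.

The family generator is a two-level clade model (ancestor → clade
ancestors → leaves, same per-branch substitution probability), with
diagnostic columns pinned per clade and never mutated; the expected
within-clade identity has the closed form (1−p)² + p²/19 per free site and
is tested against simulation.

The metagenome generator samples carriage per biosample (Bernoulli with the
group probability), then draws reads uniformly per base from the realized
community: five equal-abundance random background genomes (community
composition is unstated in the source setting; this is the chosen default)
plus each carried panel gene at 1 % of community bases. Reads get i.i.d.
substitution errors and flat Phred+33 quality "I". None of this emulates
real communities: no taxonomic abundance distributions, indels,
quality-dependent errors, host contamination, or strain variation — so
passing tests show the statistical machinery is correct under its stated
model, not that real-data accuracy matches.

## Problem sizes in tests and the acceptance script

The screen-recovery battery runs 100 seeds of 3+3 genomes with 10 decoys at
150-aa proteins. Fusion decomposition runs 50 planted cases over five
independently simulated model pairs. The metagenome recovery and type-I
batteries run 100 seeds each of 60+60 samples; the cohort uses 100-bp reads
at depth 1,000 per sample with 1 % panel abundance — a carried gene then
yields ~10 mapped reads, so detection is essentially certain (miss
probability ≈ 1e-4) and, exactly as at higher depth, the statistics are
driven by the Bernoulli carriage draw; a single 60+60 run at depth 10⁴ is
included as a fidelity check. The QC read floor is set at or below the
design depth in these synthetic cohorts (the 10⁶ default targets real
metagenomes). The recovery experiment evaluates the z-test without the
continuity correction: at this design (0.9 vs 0.6, n = 60/group, α = 0.01)
the exact power is 0.951 uncorrected versus 0.918 with Yates, i.e. the
corrected test is conservative enough to fall short of a 95 % rejection
target that the uncorrected test meets in expectation; the package default
for real analyses remains correction-on. Type-I control is measured at
equal carriage 0.75 and α = 0.05 (exact rejection rate 0.052 uncorrected).

## Known limitations

* The local-alignment entry/exit model (uniform 1/K) is simpler than
  HMMER's; bit scores and E-values are internally consistent but not
  comparable to HMMER's scales.
* The guide tree is not iteratively refined; alignments of very gappy or
  highly diverged families will be worse than a production MSA tool's.
* The k-mer mapper has no notion of multi-mapping beyond ties-→-unassigned
  and no base-quality awareness.
* NJ + Fitch substitute for the original likelihood tree and probabilistic
  ancestral reconstruction; topologies near short internal edges and
  ancestral-state confidence are accordingly cruder.
* Colocalization ignores strand and transcription units; it measures
  distance, not operon membership.
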