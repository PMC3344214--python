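# Methods

## Repeat decomposition and the notation grammar

An allele is modelled as `flank5 + major + flank3`, the major region an
ordered list of motif runs `(M)_k` and short interruption literals (1–2 nt).
The survey notation dialect is parsed directly: subscripts written `_k`,
ranges `n~m`, comma lists `n, m`, parenthesized motifs without a subscript
meaning one unit, and bare literals such as `AG` or `TC`. A range or comma
list denotes alternative alleles. When one pattern carries several
multi-valued subscripts of equal length they are read as positionally paired
alleles (so `(TG)_3, 8CG(TG)_1, 4` denotes two alleles, 3↔1 and 8↔4, the
reading consistent with the published allele counts); unequal lengths expand
as a Cartesian product; `list_mode` overrides either way. Canonical form
drops zero-count runs and merges adjacent same-motif runs, and requires at
least one run with one or more units.

Major-region detection seeds on every exact tandem array of the locus motif
with at least `min_seed_units` (default 3) units, then merges arrays across a
single interruption literal of ≤ 2 nt flanked by at least one unit on each
side. The merge window matches the data: every published interruption at
these loci is a single 1–2 nt event (AG, TA, CG, GG, CA, AT, TC). Among
candidate regions the longest wins; ties go leftmost, a deterministic rule
chosen because no published rule exists. Classification: **perfect** = a
single run with no literal; **compound** = adjacent runs of two different
motifs, both ≥ 3 units, with no literal between; everything else
(literal interruptions, or a ≤ 2-unit run of a second motif separating
locus-motif runs) is **interrupted**.

The boundary between tract and flank is only identifiable up to motif
content: if a flank substitution creates a motif unit within 2 nt of the
tract, decomposition legitimately absorbs it. This is rare (< 3% of alleles
under default simulation conditions) and extends the tract rather than
corrupting it.

## Alignment and consensus

Intraspecific flanks at one locus are near-identical, so pairwise global
Needleman–Wunsch with linear gap costs (match +1, mismatch −1, gap −2;
configurable) extended center-star-wise is used throughout; the center is
the sequence maximizing the summed pairwise score, gaps once introduced are
never removed, and trace-back prefers diagonal, then up, then left, making
every alignment deterministic. The 5′ and 3′ flanks are aligned separately
and joined at a recorded junction so the repeat tract never contaminates the
flank alignment. The score-only center-selection step is delegated to
Biopython's `PairwiseAligner` with identical scoring (the optimal score is
unique, so the two routes agree; a test asserts this); trace-back uses the
in-package dynamic program. Affine gap penalties and iterative refinement
are out of scope.

The per-column consensus is plurality-based: a residue with frequency > 1/2
is emitted; otherwise the IUPAC code of all observed residues (or, when
`ambiguity_threshold` > 0, of all residues at or above that frequency) is
emitted — this is how a polymorphic G/T site surfaces as `K`. Columns with
majority gaps are dropped: they are insertions private to a minority of
alleles. Columns with minority gaps keep the base call.

The cross-species alignment is computed locus by locus — each locus's four
species consensus sequences are center-star aligned, and the aligned blocks
are concatenated at the recorded junctions. Junctions are known homology
anchors; aligning the full ~460 bp concatenations instead lets indel
misplacement drift across locus boundaries and measurably degrades
downstream topology recovery (82/100 versus 88/100 over the fixed benchmark
seeds, before other refinements).

The site census classifies each cross-species column: any gap → indel site
(monomorphic when the non-gap residues are mutually compatible, polymorphic
otherwise); otherwise a substitution site when two rows carry disjoint IUPAC
base sets (overlapping ambiguity codes are compatible). Percentages are over
variable sites; base composition over unambiguous non-gap residues.

## Distances, neighbor-joining, bootstrap

Pairwise differences use complete deletion per pair: columns where either
row carries a gap or an ambiguity letter are excluded, so effective lengths
differ between pairs — consistent with the published per-pair difference
counts, which imply differing effective lengths. Ambiguity codes are
excluded rather than resolved because no resolution rule is published and
exclusion is deterministic. A↔G and C↔T are transitions; all other
mismatches transversions. K2P distances use the closed form above, with an
optional delta-method standard error
SE² = [c₁²P + c₃²Q − (c₁P + c₃Q)²]/L, c₁ = 1/(1−2P−Q), c₃ = ½(c₁ + 1/(1−2Q));
the saturated domain (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raises a "distance undefined"
error. Distances are reported to three decimals.

Neighbor-joining is the canonical Q-criterion agglomeration
(Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ), exact on additive matrices. Ties are
broken on the lexicographically smallest pair of cluster labels (a cluster
labelled by its smallest leaf); negative branch lengths are clamped to zero
with the deficit logged. For four taxa the single internal edge determines
the unrooted topology, so joining the minimal-Q pair or its complement is
equivalent. No rooting is attempted: with four taxa and no outgroup only the
unrooted split is inferable.

Bootstrap resamples alignment columns with replacement (default 1000
replicates; the seed is mandatory), recomputes distances and the NJ tree per
replicate, and reports each internal split's support as the percentage of
valid replicates containing it. Replicates with a saturated distance are
dropped and counted, with a warning past 10%.

## The simulator

`synthetic_data` evolves each locus down a 4-taxon species tree and then
fans each species ancestor into an allele pool by additional short-branch
(star) evolution; within-species coalescent structure is deliberately
simplified to a star because the study design is an allele pool per species
with no pedigree. Defaults are the study conditions:

* **Sampling depths** equal the published per-locus clone counts
  (274 alleles: 49 at AJ-1, 28 at AJ-8, 40 at AJ-9, 37 at AJMS-3, 60 at
  AJMS-6, 60 at AJMS-10, split by species as published).
* **Tree**: generating split {M,B} | {J,A}; leaf branches J = 0.023,
  A = 0.030, M = 0.022, B = 0.022 and internal edge 0.008 substitutions per
  flank site — a least-squares fit of the published consensus distance
  matrix (0.044–0.061).
* **Flanks**: per-locus 5′/3′ lengths (78, 80, 76, 76, 78, 79 nt summed per
  locus) put the concatenated consensus near 467 bp, inside the published
  458–469 bp; base composition 51.16% A+T as published. Ancestral flanks are
  constrained not to continue the repeat motif within 4 nt of the tract (by
  definition such bases would belong to the tract).
* **Substitutions**: K2P process with κ = 1.5 (Ts:Tv = κ:2 ≈ the published
  20:27 count ratio); per-site event counts are Poisson in the branch
  length, so multiple hits are possible.
* **Indels**: 1–2 nt, insertion or deletion with equal probability, per-site
  probability `flank_indel_rate × branch_length` with
  `flank_indel_rate = 0.33`, calibrated so the mean cross-species census
  yields ≈ 27 indel columns (the published count; calibration is against
  columns, not events, because a 2 nt event spans two columns and alignment
  can split blocks). Never inside the major region.
* **Slippage**: ±1 whole unit per event at `slip_rate = 0.005` per
  generation, reflecting at one unit, applied over
  `round(branch_length × generations_per_branch)` generations
  (`generations_per_branch = 20000`). Events strike runs in proportion to
  their length and only runs of ≥ `slip_min_units = 5` units — replication
  slippage needs a misalignable array, so short tracts are effectively
  immobile. Sub-unit indels are never introduced into the tract; a validator
  asserts this on every emitted dataset.
* **Interruptions**: point substitutions inside the tract at 10⁻⁵ per site
  per generation (≈ 8 interrupted lineages per dataset, matching the ~10
  published interrupted patterns), splitting a run into run + 2 nt literal +
  run. Events that would leave no ≥ 3-unit array are rejected: such a
  lineage would no longer be typed as a microsatellite (ascertainment).
* `allele` branches: flank substitution probability `flank_sub_rate = 0.004`
  per site (intraspecific polymorphism of a few substitutions per ~460 bp),
  with the same generations scaling for slippage.

A two-phase variant (multi-unit jumps) is not modelled; unequal
crossing-over is observationally indistinguishable from slippage at this
scale and is not modelled separately. Everything is driven by one
`numpy.random.Generator` seeded from the config, so datasets are
byte-reproducible.

**What the simulator does not emulate**: real coalescent genealogies within
species (allele pools are stars, so intraspecific repeat-number spread is
narrower than the published per-species ranges), PCR/cloning artefacts,
mutation-rate heterogeneity among loci, and homoplasy from repeated
identical interruptions. Passing recovery tests therefore show the pipeline
is correct and well-calibrated at study scale, not that four real taxa with
this divergence are always resolvable.

## Benchmarks computed by the test suite

On the fixed seed list 1–100 at default conditions the full pipeline
(decompose → consensus → per-locus cross-species alignment → K2P → NJ)
recovers the generating quartet split in 96/100 datasets; the acceptance
suite asserts ≥ 95. Mean census values over the same runs: 44.2 substitution
sites and 27.7 indel columns (published: 44 and 27); mean pairwise K2P
distance 0.053 (published range 0.044–0.061). The SMM moment checks use
10,000 walks of 100 generations; the bootstrap implementation is checked
against an independently coded resampling oracle at 2000 replicates (±3
support points).

## Numerical and degenerate-input choices

Zero-distance matrices (null simulations) produce a star tree with
zero-length edges via the NJ tie-break. Identical consensus rows yield a
census flagged `no_variation` with percentages reported as 0. All-gap
alignment columns are dropped with a logged warning. Report files are
written atomically (temp file + rename). Positions in reports are 1-based.
Newick output rounds branch lengths to a configurable number of decimals
(default 3) and writes bootstrap supports as internal-node labels.
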