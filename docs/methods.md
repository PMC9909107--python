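# Methods

This note records the models, conventions and numerical choices behind
`gadpopgen`, and what the synthetic-data experiments do and do not
demonstrate.

## Alignment model and gap policy

All analyses operate on codon-phased nucleotide alignments
(`seqio.CodingAlignment`).  Amino-acid-guided back-translation threads
each unaligned CDS through its amino-acid alignment row (one residue gap
→ one `---` codon gap), and ungapping the result reproduces the CDS
exactly.  Terminal stop codons are stripped when present in every
record; mixed presence is an error.  The genetic code defaults to NCBI
translation table 11 (bacterial) and is configurable everywhere.

**Complete deletion is applied per codon column**, not per nucleotide
column: any codon triplet containing `-` or `N` in any record is removed
in all records.  Nucleotide-level deletion could break frame and make
synonymous/nonsynonymous classification ill-defined; codon-level
deletion keeps every downstream quantity well-posed.  A provenance map
from retained to original codon columns is kept for coordinate
reporting.  `N` is the only ambiguity code accepted (treated as
missing); other IUPAC codes are rejected at parse time.

## Site counting and polymorphism classification

Synonymous/nonsynonymous site counts follow Nei & Gojobori (1986):
each codon position contributes the fraction of its one-step changes
that are synonymous, with changes to stop codons excluded from the
denominator, and the fractions are averaged over **all** ingroup
sequences (not a single reference), which is what produces the familiar
non-integer site totals.  Unweighted pathway counting is used (no
transition/transversion or codon-frequency weighting).

Codons differing at several positions are resolved by equal-weight
averaging over all orderings of the single steps whose intermediates are
not stops (all orderings if every one passes through a stop).  The
per-position profile sums to the classic pairwise (sd, nd) counts, and —
because both sites and differences are attributed to individual
nucleotide positions — global, per-domain and sliding-window statistics
are exactly additive over codon columns, and a full-length window equals
the global statistic by construction.

Variable columns are classified from codon context against the majority
allele (majority codon as context when a neighbouring position also
varies); a site's class label is the majority pathway fraction, ties to
nonsynonymous.  Multiallelic sites count once in S and (alleles − 1)
times in η.  Singleton = exactly two alleles with minor count 1;
parsimony-informative = at least two alleles with count ≥ 2.  The
outgroup is excluded from all within-species counts and used only for
polarization and divergence.  With pure-CDS input the "silent" class
equals the synonymous class.

π is the mean over unordered pairs of per-pair difference counts divided
by the class site count; for reporting, each pair's proportion p is
Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3), before averaging
(undefined at p ≥ 3/4, reported as an error).  Report tables emit θ and
π ×10⁴.

## Neutrality tests

Every statistic in the battery is a linear functional of the unfolded
site-frequency spectrum with zero expectation under the standard neutral
coalescent, studentized by an unbiased variance estimate.  The variance
of a numerator Σ w_i ξ_i is θ·Σ w_i²/i + θ²·wᵀσw, with the σ_ij of Fu
(1995); `sfs.sigma_matrix` implements them and the test suite verifies
the matrix against an exact enumeration of coalescent size-configuration
trajectories at small n (an entirely independent derivation).

The frozen constants are generated in one function
(`neutrality.test_constants`) from that exact machinery.  For Tajima's
D (plug-in via S and S(S−1); Tajima 1989 e₁/e₂), Fu & Li's D and D*
(plug-in via η and η²; Fu & Li 1993 with the Simonsen-style
corrections), Fay & Wu's normalized H and Zeng's E (plug-in via θ̂_W and
S(S−1)/(a₁²+a₂); Zeng et al. 2006) the generated constants equal the
published corrected closed forms to machine precision.  For Fu & Li's F
and F* the widely reprinted closed forms differ slightly from the exact
variance (a known history of typos in those constants); the exact values
are used.  Monte-Carlo checks (Var of the E numerator at n=10, θ=5:
simulated 2.199 ± 0.005 vs exact 2.193) support the exact route.

Achaz's Y is built in the same framework: symmetric weights that zero
the two singleton classes, evaluated on the folded minor-allele
spectrum, with θ and θ² estimated from the singleton-free S.

Undefined statistics (S = 0, n < 4, all-singleton data for Y, no
outgroup for H/E/D/F) propagate as NaN with a reason code, never as 0.

Significance: the default is a fixed-S coalescent null — neutral
genealogies with exactly S mutations multinomially placed by branch
length — with the two-tailed p doubling the smaller empirical tail
(add-one smoothing, capped at 1).  Tajima's beta approximation is
available for D only.  Report marks: `#` for 0.10 > p > 0.05, `*`, `**`,
`***` at 0.05/0.01/0.001.  No multiple-testing correction is applied to
the marks; a Benjamini–Hochberg column (clearly suffixed
`_bh_adjusted_extra`) is emitted alongside for transparency.

## McDonald–Kreitman family

P counts reuse the polymorphism classifications; D counts sites where
the ingroup is monomorphic and differs from the comparator, with the
comparator complete-deleted jointly with the ingroup so P and D share
one site universe.  NI and α are undefined (NaN, no pseudo-counts) when
a required cell is zero; DoS and the Fisher exact p (two-tailed, sum of
table probabilities ≤ the observed table's) are always reported.  A
verdict is `positive_selection` / `negative_selection` when p < 0.05
with DoS > 0 / < 0, else `neutral`.  No frequency filter is applied to
the polymorphism counts.

## Codon usage bias

The reference is a genome-wide Kazusa-format codon usage table.  w =
RSCU / max-RSCU within each synonymous family; zero-count codons get a
w floor of 0.01 (configurable) to keep the geometric mean finite.  CAI
is the geometric mean of w excluding single-codon families (Met, Trp)
and stops; CBI = (N_opt − N_rand)/(N_tot − N_rand) with N_rand the
expected optimal-codon count under uniform synonymous choice given the
gene's amino-acid composition.  The optimal set is the per-family RSCU
argmax (ties all optimal); this Kazusa-derived set stands in for
software-internal optimal-codon definitions that are not published.

## Protein chemistry

The residue table (class / charge at pH 7 / polarity) is frozen in
`proteinchem.AA_PROPERTIES`: aliphatic G A V L I, aromatic F W Y, basic
K R H (+), acidic D E (−), amide N Q, hydroxylic S T, sulfuric C M,
imino P.  Cysteine is classed nonpolar (hydrophobicity-scale
convention).  A change is conservative iff class, charge and polarity
are all unchanged.  The wild type for change tallies is a designated
change-free sequence, defaulting to the column-majority consensus.

Net charge is the Henderson–Hasselbalch sum over D, E, C, Y (acidic),
H, K, R (basic) and the two termini; the default pKa set (N-term 7.5,
C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0) is
an ExPASy-style set and the model is pluggable.  Q(pH) is strictly
decreasing, so the pI is the unique root, found by bisection on (0, 14)
to 1e-4.  Titration tables default to the acid-stress-relevant grid pH
4.00–7.00 in 0.25 steps.

## Coalescent simulator

`coalsim.simulate` draws a Kingman genealogy (exponential epochs at rate
m(m−1)/2; under exponential growth g the waiting times invert the
cumulative intensity e^{gt}), then places Poisson(θ/2 × total length)
mutations on branches proportionally to length.  The ancestral CDS is
uniform over sense codons.  Mutations follow an infinite-sites
convention at **codon** granularity — at most one hit per codon, redrawn
up to 100× then an error — which keeps every lineage stop-free and makes
each mutation's synonymous/nonsynonymous class exact in any context.
Selection is emulated by acceptance thinning: a nonsynonymous draw is
kept with probability `f_poly` (ingroup) or `f_div` (outgroup branch of
length `t_div`), otherwise redrawn.  This reproduces the statistical
structure the analyses detect — reduced π_N/π_S, MK asymmetries with
known direction — without a diffusion model, and the truth (per-mutation
class, carriers, genealogy length) is written alongside the FASTA +
population TSV so the whole pipeline runs on synthetic data unchanged.

`simulate_skewed_sfs` provides the two canonical spectrum distortions:
`growth` (rare-variant excess; negative Tajima/Fu–Li tests) and
`sweep_like` (a star-collapsed subtree at recent time; high-frequency
derived excess, negative H).

What the simulator does **not** emulate: recombination, migration
structure between the population labels (labels are cosmetic strata for
pipeline exercise), codon-model (GY94-style) substitution dynamics,
alignment error, or sequencing error.  Passing tests on synthetic data
therefore validate the estimators and their calibration, not robustness
to those real-data complications.

## Phylogenetics

ML tree inference is deliberately replaced by Jukes–Cantor distances +
Saitou–Nei neighbor joining: the discordance claims the package supports
are topology-comparison claims, which NJ serves at desk scale (exact on
additive matrices; Q-ties broken toward the lowest-index pair for
determinism).  Trees are compared unrooted by Robinson–Foulds
bipartition distance (via dendropy); midpoint rooting is cosmetic.
"Repeated gain/loss of operon structure" is operationalized as the Fitch
parsimony count of the operon-state character exceeding (number of
states − 1).

## Pipeline conventions

Within-species runs emit one row per gene for the pooled sample plus
each population; populations with n < 4 keep their diversity rows while
the tests are flagged undefined.  An operon aggregate concatenates the
member genes' codon columns over shared strain ids (coding regions
only).  Pooling applies no unequal-sampling correction.  Rank-based
group comparisons use Kruskal–Wallis (tie-corrected) for ≥3 groups and
the Wilcoxon rank-sum for two.  The CLI exposes simulate / within /
between / codonbias / protein / phylo; report tables are written by the
within/between commands directly rather than by a separate subcommand.

## Calibration experiments and problem sizes

The shared experiments (`gadpopgen.calibrate`) run at n = 20, θ = 5 per
gene, 500-codon genes — desk-scale conditions where every experiment
finishes in seconds to about a minute on one CPU: 2,000 replicates for
the neutral means and parameter recovery, 10,000 SFS-level trials with
per-S cached nulls (2,000 replicates each) for the type-I error, 200
common-random-number pairs for the π_N/π_S recovery, and 500 replicates
per direction for DoS recovery.

Two honest caveats from these runs.  First, the studentized statistics
are ratio statistics whose neutral *means* are not exactly zero at
finite θ (Tajima's D sits near −0.08 under these conditions); Zeng's E
is the most affected, with a mean near −0.12 that is a property of the
statistic, not an implementation artifact (verified against independent
samplers including msprime genealogies).  Second, fixed-S conditioning
shifts the Fu–Li D mean slightly negative relative to the unconditional
case; the numerators remain exactly zero-mean in expectation.

## Known limitations

* Classification of multiallelic columns uses majority-codon context;
  exhaustive multi-allele pathway resolution is not attempted (such
  columns are vanishingly rare at the diversities involved).
* Tajima's beta-approximation p-values are approximate at small S; the
  coalescent null is the default for a reason.
* The Fitch routine is exact on binary trees (NJ output); on input
  polytomies it is an upper bound.
* CAI/CBI require a genome-wide usage reference; no internal
  optimal-codon estimation from highly expressed gene sets is provided.
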