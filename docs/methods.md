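# Methods

This note documents the models, conventions and design choices behind
`cerealcas`, in the order the workflow runs.

## Target scanning and oligo design

A target site is a full-length protospacer window with the PAM immediately
adjacent on the nuclease's required side: NGG 3′ of a 20-nt window for
SpCas9, TTTV 5′ of a 23-nt window for LbCas12a.  IUPAC codes in the PAM
pattern are expanded (V = A/C/G, N = any); matching is case-insensitive
and `N` bases in the subject sequence never match, inside either the
protospacer or the PAM.  Both strands are scanned; minus-strand sites are
reported in their own reading orientation with `start` given as the
leftmost forward-strand coordinate of the protospacer, so scanning a
sequence and its reverse complement give strand-swapped mirrors (a tested
invariant, alongside exact agreement with a brute-force all-windows
scanner).

Design choices where the underlying system leaves room:

* **Cas12a protospacer length** defaults to 23 nt (the toolkit's worked
  template length) and is configurable; there is no single canonical
  LbCas12a spacer length in the literature.
* **No 5′-G requirement** is imposed on Cas9 protospacers for the pol III
  promoters — the toolkit's own template protospacer starts with T, and the
  U6/U3 cassettes supply their own transcription start context.
* **Cut offsets** (Cas9 blunt cut 3 bp 5′ of the PAM; Cas12a staggered cut
  after protospacer positions 18/23) are recorded on the nuclease spec but
  feed only the amplicon caller's default cut-window placement; both are
  configurable.
* Off-target enumeration and on-target efficacy scoring are out of scope;
  dedicated web tools do this better and genome-wide.

Oligo construction is purely deterministic: forward = overhang +
protospacer, reverse = overhang + reverse complement.  A Cas12a
protospacer beginning `TTT` triggers a warning (it usually means the TTTV
PAM was accidentally included), not an error, since genuine T-rich spacers
exist.

## Assembly planning

The planner encodes three rule sets as data: the nine-vector binary
catalogue (species × Cas9/Cas12a/dual × GRF-GIF option), the per-step
enzyme table (BsaI for oligo→level 1; BpiI for level 1→level M; BsaI +
BpiI for any →level 2), and the routing rule (≤ 4 inserts per ligation;
arrays larger than 4 go via level-M stacks).  Unsupported configurations
raise an error listing the nearest supported vectors rather than guessing.

* **Packing** is greedy fill-to-four.  It is deterministic, minimises the
  number of level-M vectors, and the per-step insert bound is the only
  constraint the system imposes; balanced packing was rejected as it adds
  vectors without reducing any step's complexity.
* **Capacity** is 26 guides per final construct, a property of the
  accepter/end-linker catalogue, encoded as a named constant rather than
  derived.
* **Positions**: level-M and level-2 accepters expose seven GoldenGate
  positions; level-1 accepters are position-specific parts, which is why
  step accepter ids carry their destination slot.  If a dual-nuclease
  build's direct-route inserts would exceed seven positions, multi-guide
  sub-arrays are re-routed through level M.
* **Promoter alternation**: unconstrained guides cycle U6-class ({TaU6})
  and U3-class ({TaU3, HvU3}) promoters so no two adjacent cassettes in a
  tandem array share a class — repetitive tandem promoters invite
  recombination during bacterial propagation.  Explicit preferences win;
  a forced same-class adjacency produces a warning, not an error.
* **Dual-nuclease builds** keep Cas9 and Cas12a guides as two independent
  sub-arrays routed separately into the one dual-cassette vector.

## Assembly simulation

Digestion–ligation is modelled at the sequence level.  A type-IIS cut is a
(top, bottom) strand cut pair downstream of the recognition site (BsaI:
1-nt spacer; BpiI: 2-nt; both leave 4-nt 5′ overhangs — standard enzyme
geometry, cross-checked in the tests against Bio.Restriction's REBASE
definitions).  Double-stranded fragments are represented by their
top-strand sequence spanning both cut regions, with each overhang stored
as the top-strand sequence of its single-stranded region; two ends are
ligatable exactly when those 4-mers are equal.  Circular parts are handled
on a doubled string, so all operations are rotation-invariant.

Ligation builds the overhang graph and succeeds only when a unique
Hamiltonian cycle covers every selected fragment.  Any overhang shared by
two 5′ ends, an unmatched end, a premature sub-cycle or an unused fragment
is reported as a diagnostic, never an exception — assembly failure is a
result, not a bug.  Backbone selection is annotation-driven, mirroring the
bench reality: the accepter fragment lacking the colour dropout
(LacZ/RFP) is the backbone, and when a plasmid serves as an insert its
vector-backbone fragment is discarded.  Products are finally re-scanned
for recognition sites of the reaction enzymes; a residual site means the
design is not a true one-pot GoldenGate and is flagged.

Not modelled, deliberately: methylation sensitivity, partial digestion,
ligation kinetics and yields.  The simulator answers "is the design
correct", not "how efficient is the reaction".

Fixture parts are fabricated, not downloaded.  The part factory builds
minimal circular accepters whose fusion sites are tailored to each plan
(which subsumes the role of physical end linkers); position overhangs are
invented 4-mers, globally distinct and G-free so that no type-IIS motif
can arise in filler sequence, and they are **not** the physical toolkit's
fusion sites.  Test protospacers are rejection-sampled to be free of
internal/junction BsaI/BpiI sites, the same domestication requirement real
GoldenGate cloning imposes.

## Amplicon mutation calling

Inputs are SAM alignments (any mapper; bwa mem with defaults is typical).
Unmapped, secondary and supplementary records are excluded; orphaned mates
and unknown references are counted, not fatal.  Coordinates are 0-based
half-open internally (SAM's 1-based starts converted on input); pattern
keys print 1-based positions.

1. **Boundaries**: the amplicon's two start points are the modes of the
   lower and upper mate start positions per locus, ties broken toward the
   smaller coordinate; they can be overridden per locus.
2. **Usable filter**: a pair is usable iff its two mate starts equal the
   two boundaries (orientation-agnostic).  A deletion upstream of a mate's
   start shifts that start and excludes the pair — an inherent property of
   filtering on exact starts, which is why amplicons should place the cut
   site inside one read's span.
3. **Patterns**: walking the CIGAR accumulates reference coordinates;
   deletions whose span touches the cut window and insertions whose
   insertion point lies inside it become events.  The pattern comes from
   the mate overlapping the window; if both overlap and disagree, the pair
   is flagged discordant and counted as mutant with the union pattern (a
   convention of this implementation).  Substitutions never count — NHEJ
   scoring is about indels, and counting mismatches would make the caller
   sensitive to sequencing error (a tested property: 0.5% substitution
   noise yields exactly 0% mutant).
4. **Report**: %WT = 100·WT/usable over usable pairs only, with the full
   pattern spectrum.  Zero usable pairs gives NaN percentages and a flag,
   not an exception.  No background subtraction is applied — amplicon
   assays carry a few-percent wild-type artifact floor and raw values keep
   that visible; an artifact floor can be annotated downstream.

**Insertions** are counted as mutant by default because Cas9 NHEJ
frequently produces +1 insertions; `deletions_only=True` restores strictly
deletion-based calling for comparison with deletion-pattern-only outputs.
The **cut window** defaults to the cut site ± 15 nt (configurable): wide
enough for NHEJ end-resection, narrow enough to ignore alignment artifacts
at read ends.

The Sanger classifier aligns a base-called read globally to the reference
with affine gaps (match +2, mismatch −1, gap open −6, gap extend −1 —
penalties favouring a single contiguous indel over scattered mismatches)
and flags mutation iff an alignment gap intersects the cut window.

## Efficiency statistics

Proportion data (k mutated of n plants per construct × gene) are fitted by
a binomial GLM with logit link via IRLS (statsmodels supplies the fits;
the tests verify coefficients and deviances against an independent
hand-rolled IRLS and a closed-form two-cell likelihood).  Terms are added
sequentially in the supplied order with treatment contrasts, and each term
is tested by the deviance drop against the chi-squared distribution.
Quasi-complete separation (all-0/all-n cells) gets a half-count continuity
adjustment with a warning rather than a divergent fit.  Type-I error of
the LRT is calibrated by simulation (1,000 seeded null replicates must
reject at 3–7% for α = 0.05).  No multiple-testing correction is applied;
raw p-values are reported.

Per-plant mutant-allele percentages are analysed by crossed ANOVA with
sequential (type-I) sums of squares, the `Gene * CDS` crossed
convention, validated against an explicit projection-matrix computation.
Residual degrees of freedom follow standard residual-df arithmetic.

Aggregation conventions: per-gene efficiency is 100·k/n; a construct's
mean is the unweighted mean over its genes; the quoted SE is
sd(per-gene %)/√(#genes) (the natural reading of "standard error of the
mean efficiency averaged over genes"); display values round to integer
percent while raw values are retained.  The all-targets rate is the
fraction of plants mutated in every targeted gene, computed over plants
with complete records (plants missing a gene record are excluded with a
warning).  It can never exceed the worst per-gene rate, and under nested
outcomes — where a latent per-plant competence orders the genes — it
equals that minimum.

**Synergy.**  With efficiencies for a base construct, each of two single
enhancements and their combination, the strict decomposition is
`synergy = combined − base − Δa − Δb`.  When the base construct's activity
is indistinguishable from the assay's artifact floor, the base term is not
a real editing rate, and the meaningful figure is the gain of the
combination over the summed single enhancements,
`enhancement_gain = combined − Δa − Δb` (= synergy + base).  The class
exposes both; at a recalcitrant locus with base 5%, summed enhancements of
20 points and a combined 68%, these give 43 and 48 points respectively.
Designs whose additive expectation exceeds 100% are flagged `saturated` —
there the synergy is unmeasurable because the single effects already hit
the ceiling.  Converting Illumina-mode percentages to binary "mutated"
uses a configurable threshold, default 10% mutant alleles, set above the
typical artifact floor.

## Synthetic data

All generators take a mandatory seed and are byte-deterministic.

* **References** use an exact GC quota (shuffled), so composition is a
  property, not an expectation.
* **Amplicon reads**: the amplicon spans the whole reference; mate 1
  starts at the left boundary and carries the indel (its CIGAR and
  sequence are derived by walking the reference through the pattern),
  mate 2 starts at `len(reference) − read_length` and is pure match —
  the geometry of a design whose cut site sits in the forward read.
  Pattern frequencies are allocated by largest-remainder quota, so small-n
  truth fractions are exact rather than Bernoulli-noisy.  A configurable
  off-boundary fraction emulates mispriming and exercises the boundary
  filter.  Substitution errors are uniform per base.  Not emulated:
  realistic error spectra, quality modelling, chimeric reads — so passing
  tests show the caller's logic is right, not that it is robust to every
  artefact of a real sequencer.
* **T0 cohorts**: the `nested_activity` model draws one latent competence
  a ~ U(0,1) per plant and mutates gene g iff a < e_g, reproducing the
  empirically observed nesting of multiplex outcomes (all-targets = lowest
  per-gene efficiency); this is our model of that observation, not a
  mechanistic claim.  The `independent` model draws per-gene Bernoulli
  outcomes for contrast.

## Problem sizes

The test suite and the acceptance script use 200 read pairs per calling
condition (grids down to 50 and up to 500 in property tests), cohorts of
20–5,000 plants depending on whether a rate or an asymptote is being
checked, 1,000 replicates for GLM calibration and 500 for power, and full
assembly simulation of every plan size from 1 to 26 guides.  These sizes
were chosen so every stochastic check sits well inside its tolerance while
the whole suite runs in well under a minute.

## Known limitations

* The simulator's fixture overhangs are self-consistent inventions; plans
  verified here are verified against the toolkit's *rules*, not against
  the physical plasmid sequences.
* The caller requires both mates at exact boundaries, inheriting that
  filter's blindness to indels that shift a mate's start.
* ANOVA denominator df follow standard residual arithmetic and are
  validated on synthetic data, not against any particular commercial
  statistics package.
* Ribozyme- and CSY4-based Cas9 guide architectures (single-transcript
  arrays) have no published oligo templates and are not designable here.
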