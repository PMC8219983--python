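# Methods

`slofe` infers selective RNA processing and stabilization (SRPS) regulation
from genome sequence. The underlying biological model: a polycistronic
transcript is cleaved by endonucleases; where a stable stem–loop (SL) sits in
the 3′ UTR of a gene, it blocks 3′-exoribonucleolytic decay of the upstream
sub-transcript; the thermodynamic stability (folding ΔG) of each protecting
hairpin therefore sets the steady-state abundance of the gene block it
covers, and the vector of ΔG values along an operon predicts the operon's
transcript- and protein-level stoichiometry. This note documents every model
component, its parameters, and the design choices made where the procedure
was genuinely open.

## Hairpin discovery

**Scanner.** Both strands are scanned for hairpin candidates under a
descriptor: stem 6–40 bp, loop 3–30 nt, GU pairs allowed (defaults; all
configurable). A candidate is defined constructively: for every possible
loop window the stem is grown outward from the obligatory innermost pair,
preferring pairs and spending at most `max_mismatch` (default 2) mispairs;
growth stops at the stem bound or when no extension is possible, and
trailing mispairs are trimmed so every candidate ends on a pair. This makes
the candidate set a deterministic function of the sequence, which the test
suite exploits: an independently written per-window enumerator must produce
the identical span set on multi-kilobase random genomes. Bulges are not
enumerated at scan time — they emerge at the folding step as interior loops.
Candidates containing `N` are discarded. Unbounded stem imperfection (as a
pure motif grammar would allow) is deliberately not attempted: the ΔG filter
downstream, not the scanner, determines the stable set, and the capped
scanner feeds the folder every span that could matter.

**Energy model.** Each candidate span is refolded to its minimum-free-energy
*single hairpin* by dynamic programming over all nested pairings whose
interior loops contain at most 10 unpaired nucleotides (configurable).
Energies are the published Turner 2004 nearest-neighbor parameters at 37 °C:
stacking terms for Watson–Crick and GU pairs, hairpin-loop initiation by
size (3–30, log-extrapolated beyond), hairpin terminal-mismatch terms, the
triloop closure rule (no mismatch stacking in 3-nt loops), bulge penalties
(size 1 retains the flanking stack), and a coarse interior-loop cost
(size-dependent initiation + 0.6 kcal/mol per nt of asymmetry, capped at
3.0). Stacking terms are stored in telescoped form — helix terminal
penalties are absorbed into the stack/hairpin terms — so the sum of stacks
plus the closure term reproduces the full Turner energy of a perfect
hairpin. Hairpin terminal mismatches are included (a deliberate choice: they
are cheap, and they keep the internal folder within ~0.1 kcal/mol of
ViennaRNA on perfect hairpins; without them common hairpins deviate by more
than 2 kcal/mol). Out of scope: multibranch structures, pseudoknots,
dangles, special tetraloop/hexaloop bonuses, and partition functions. An
*external* backend delegates folding to the ViennaRNA Python bindings when
installed; the internal backend is the default and the reproducible
reference. The DP is JIT-compiled with numba and falls back to pure Python
when numba is unavailable.

The DP is verified two ways: against exhaustive enumeration of every nested
single-hairpin pairing (scored with the same tables — the enumeration is the
independent path, the tables are shared physics) on sequences ≤ 28 nt, and
against ViennaRNA on random perfect hairpins (agreement band 2 kcal/mol;
observed ≤ 0.1 on hairpins without special loops).

## Post-processing

**Trimming.** Unpaired positions outside the outermost pair are removed;
coordinates are updated strand-aware. Idempotent by construction.

**Redundancy removal.** Four rules, applied most-stable-first (ties: the
5′-most SL wins, making the operation order-independent and idempotent):
identical (sequence, structure) duplicates collapse; a span contained in
another same-strand span is dropped; partially overlapping same-strand SLs
(overlap fraction of the shorter > 0.75 *or* aligned-overlap Hamming
distance < 3) keep the lower-ΔG member; and only SLs with ΔG strictly below
−5.0 kcal/mol survive. Because same-strand overlaps of a single genome are
identical sequence over the overlap (Hamming 0), the distance clause merges
*every* overlapping same-strand pair — which is exactly what makes the
output a non-overlapping set per strand. Both thresholds are exposed as
parameters for users who want looser merging.

**Stability selection.** Four stability factors are computed per SL:
`S1 = ΔG`, `S2 = ΔG/L`, `S3 = ΔG·sl`, `S4 = ΔG·sl/L` (L = stem–loop length,
sl = stem length). Scores are normalized by the cohort minimum so the most
stable SL scores 1.0, and the stable set is everything ≥ 0.60 (default score
S4). The 60% cutoff is interpreted as this normalized-score threshold; as a
diagnostic for the interpretation, `enrichment_per_100` reports the
intergenic fraction among top-ranked SLs in rank windows of 100, which is
the curve a user would inspect to compare S1–S4 or move the threshold.

## Mapping and classification

**Positional categories.** Each SL is intragenic (inside one gene),
intergenic (touching none), overlapped_on_3 / overlapped_on_5 (straddling
one gene boundary, read in the gene's own orientation), or
overlapped_with_two_genes. An SL engulfing a single whole gene counts as
crossing its 3′ boundary (tie-break; the case is vanishingly rare at hairpin
scale). Categories partition the SL set; an exhaustive sweep against a
brute-force interval classifier covers every offset of a toy annotation.

**Operon context.** An intergenic SL's flanking genes are the nearest genes
up- and downstream *on the strand it folded on* (convergent opposite-strand
genes never capture an SL). Both flanks in one operon → intra-operonic;
otherwise inter-operonic; no flanking gene on that strand at all →
not_applicable. The SL between two operons is attributed to its upstream
operon.

**U features.** The 10-nt genomic window immediately 3′ of the trimmed SL
(clipped at contig ends) yields `polyU_len` (longest U run), `U_content`
(total U), and a tail position:

* *downstream* — a run of ≥ 4 U starting within the first 3 window positions
  (the canonical intrinsic-terminator tail);
* *upstream* — ≥ 4 U paired within the lower (tail-proximal) 40% of the 3′
  stem side;
* *discontinuous* — U_content ≥ 4 scattered in runs of 2–3;
* *none* otherwise.

Two thresholds here are operational choices. Requiring the downstream run to
be ≥ 4 keeps short runs from masquerading as terminator tails; requiring a
discontinuous tail to contain a run of ≥ 2 distinguishes a scattered tail
(U_content 4–5 in short runs → STSL) from a genuinely tail-less low-U window
(isolated single U's → SSL). Both are module constants, and the 40%/≥4
definition of the upstream (in-stem) tail follows the canonical picture of a
GC stem whose lower 3′ side carries the U-rich segment.

**Classification.** Rules fire in fixed precedence:

1. **TSL** — polyU ≥ 4 AND U_content ≥ 7 AND downstream tail (conjunction);
2. **STSL priority** (default on) — a discontinuous or upstream tail forces
   STSL even when the SSL numeric bounds hold;
3. **SSL** — U_content ≤ 5 AND polyU ≤ 3 (conjunction);
4. **STSL** — discontinuous or upstream tail, or U_content > 5 (disjunction);
5. unclassified (excluded from SRPS identification, reported separately).

The conjunction/disjunction reading and the priority clause are the unique
combination that reproduces all four experimentally characterized example
patterns (a tail-less low-U stabilizer; a 6-nt-tail terminator; and the two
short/discontinuous-tail middle cases). `--no-stsl-priority` recovers the
bare numeric rules. Every feature combination maps to exactly one label
(property-tested), and the evaluated rule trace is attached to each call.

## SRPS identification and ratio prediction

An operon is SRPS when ≥ 1 of its intergenic intra-operonic stable SLs is
SSL or STSL. All intra-operonic SLs (including TSLs) become control SLs,
positioned after their upstream flanking gene; additionally, an
inter-operonic SL trailing the operon's last gene within 300 nt is attached
as the terminal control SL. The distance cap is this implementation's
addition: intrinsic terminators live in the 3′ UTR, and without the cap a
stable SL kilobases downstream (e.g. past an intervening opposite-strand
operon) would be credited as a terminator. 300 nt generously covers
bacterial 3′ UTR lengths; it is a parameter of `identify_srps`.

Ratio prediction implements the upstream-control-unit rule: gene *i* takes
the ΔG of the nearest control SL at-or-downstream of it; genes with no SL
before the operon end are predicted silent (value 0). Values are normalized
by the ΔG of the 5′-most control SL and rounded to two decimals (matching
how such ratios are conventionally printed). Internal TSLs are used as
control values by default (`--no-tsl-controls` restricts controls to
stabilizers); either way genes downstream of an internal TSL can only be
assigned from SLs downstream of it, so the gene blocks (UCUs) are always
contiguous.

## Validation

`NRD = (Rd5 − Rd3) / max(Rd5, Rd3)` with Rd5/Rd3 the read depths of the
genes flanking the SL. Antisymmetric, bounded in [−1, 1], undefined (and
flagged) when both depths are zero. A candidate passes at NRD strictly
greater than the threshold (default 0.5); only stabilizer-type SLs are
assessed, since a terminator drops coverage for a different reason. A
variant with the 5′-gene denominator `(Rd5 − Rd3)/Rd5` is available
(`denominator="5prime"`), reflecting the two denominators in circulation
for this statistic; the max-denominator form is the default because it is
the one the bound in [−1, 1] holds for. The optional ΔG-rescue
(`--dg-rescue`, default off) re-admits a failing SL when per-gene depth
correlates positively with |ΔG| of the controlling SLs across its operon —
the secondary argument used narratively for sub-threshold SLs flanked by
strongly protected genes.

Predicted ratios are scored against expression tables by Pearson r between
the predicted values and log10 abundances; genes with zero abundance are
excluded pairwise (a pseudocount mode exists), and r is not computed for
operons with < 3 usable genes or zero variance on either side (bicistronic
operons are predicted but never correlated).

## Baselines

Five per-gene predictors, each normalized by the first gene's score to form
an operon ratio: CAI (Sharp & Li geometric-mean relative adaptiveness;
single-codon families excluded; unobserved codons floored at w = 0.01);
RCBS (self-referential codon bias against the gene's own positional base
composition); RCA (codon frequency over the reference's positional
expectation, geometric mean, with small floors so unobserved codons and
bases stay finite); MELP (= MILC distance from the whole reference divided
by MILC distance from a highly-expressed set; MILC uses the per-amino-acid
2·Σ n·ln(f_gene/f_ref) goodness-of-fit with the (Σ(k_a − 1))/L correction);
and gene order (strictly decreasing n, n−1, …, 1 over n). The codon
reference defaults to all annotated CDS; MELP's highly-expressed set
defaults to the top 10% of genes by CAI (a stand-in for ribosomal-protein
sets when no such annotation exists; configurable). CAI is cross-checked in
the tests against Biopython's independent implementation on genes where the
two conventions coincide.

## Synthetic fixtures

The generator emulates the regulatory architecture the pipeline infers —
and nothing more. A genome (~12 kb, GC ≈ 0.37, Clostridium-like) carries 10
operons (half on each strand): five SRPS layouts (internal SSL/STSL controls
with or without a terminal TSL, including a no-terminal layout whose distal
genes are truly silent), one operon whose only internal SL is a TSL (a
mandatory negative), one with only a terminal TSL, and unregulated/mono- and
bicistronic negatives. Planted hairpins come in three tiers chosen jointly
with the pipeline's own selection rules:

| tier | ΔG band (kcal/mol) | stem | loop | role |
|---|---|---|---|---|
| strong | −42 … −36 | 16 | 26–30 | first control SL |
| mid | −29.5 … −26.5 | 12 | 10–12 | second control SL |
| weak | −20.5 … −18 | 14 | 3–4 | terminal TSL |

The geometries flatten S4 across tiers (S4 ≈ −10.3 / −9.6 / −8.6) so every
planted SL clears the 60% threshold even though the ΔG tiers span a factor
of two — including the antisense twins of planted hairpins, which are
genuine hairpins on the other strand (Watson–Crick pairing is
strand-symmetric) and join the S4 cohort. Junctions between a hairpin and
its flanks are guarded against pairing on *either* strand (a sense A·C
juxtaposition is an antisense G·U pair), and every planted hairpin is
verified at generation time by re-scanning its local region with the default
descriptor: the planted span must come back as the lowest-ΔG trimmed SL with
its designed structure and class, else pads/windows are resampled.

Read depths (and an independently noised protein table) follow
`depth = 1000 · (|ΔG_control| / 40)^γ · 10^ε`, ε ~ N(0, σ), σ = 0.1
(log10), γ = 6, and exactly 0 for silent genes. The map is monotone in |ΔG|
as the SRPS model requires; the convexity (γ) is a generator design
parameter set so that each planted stabilizer SL's depth step exceeds the
NRD = 0.5 threshold with > 3σ of noise margin under the tier bands above —
a strictly linear depth–|ΔG| map cannot produce > 2× depth drops within a ΔG
range that also survives the 60% stability threshold, so convexity is
forced by the two constraints jointly. Depth is a pure function of the
controlling SL; real coverage (positional decay, library effects,
condition dependence) is *not* emulated, so passing tests demonstrate
correct inference under the model's own assumptions, not robustness to real
dRNA-Seq artifacts.

Everything derives from one `numpy` PCG64 generator seeded by the spec, and
equal seeds produce byte-identical output files.

## Numerical choices and degenerate inputs

ΔG values are reported to 0.01 kcal/mol; ratio values to two decimals.
Unfoldable candidates return an all-dot structure at ΔG 0 and are dropped.
The ΔG floor is strict (−5.0 itself is excluded). An all-zero S4 cohort
normalizes to 1.0 (nothing is filtered). NRD at rd5 = rd3 = 0 is flagged
undefined rather than invented; passing is strict (> threshold), so a
threshold of exactly 1.0 is unreachable by construction — saturated records
(rd3 = 0) pass any threshold below 1. Dedup tie-breaks at equal ΔG keep the
5′-most SL. Multi-contig genomes are supported with contig-qualified SL
identifiers; SLs on contigs without annotation are categorized intergenic
with not_applicable context and excluded downstream.

## Problem sizes

The test suite runs the full pipeline on the ~12-kb default fixture (one
session-scoped run shared across tests), scanner-oracle equality on 3–10-kb
random genomes, and folder-oracle enumeration on ≤ 28-nt sequences; the
whole suite completes in well under a minute after JIT warm-up. These sizes
were chosen as the smallest at which every pipeline behavior (both strands,
all operon layouts, all three SL classes, silent tails, negatives) is
exercised; the scanner and folder scale linearly in genome length and have
been run on multi-megabase inputs.

## Known limitations

* The internal folder is single-hairpin by construction; candidates whose
  true MFE structure is multibranched get the best hairpin embedded in them,
  which is the object of interest here but not the global MFE.
* Genome-scale counts from real genomes depend on the exact motif grammar
  and folding build used; this implementation's scanner is deterministic and
  documented but not a byte-level clone of RNAMotif, so absolute candidate
  counts are not comparable across tools — downstream stable sets, which are
  ΔG-driven, are.
* The 60% stability threshold, the upstream-tail stem fraction, and the
  discontinuous-tail definition are operationalizations of qualitative
  descriptions; all are exposed as parameters and flagged here rather than
  silently hard-coded.
* Classification uses sequence features only; no expression information
  feeds back into the labels.
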