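# Methods

## The dual-haplotype reference model

A fused hybrid carries two parental haploid genomes that stay
distinguishable because the parents diverged densely before fusion.
`taqsv` keeps both parental references ("haplome A", "haplome B") and
maps reads-derived signals onto parental coordinates. The two
coordinate systems are related by sparse anchor pairs with linear
interpolation between anchors; the simulator lays anchors at every
InDel, making liftover exact outside the InDels themselves (error
bounded by the InDel length, ≤10 bp at defaults). Coordinates are
0-based half-open internally; VCF/BED dialects apply only at file
boundaries.

Restriction sites are indexed by exact forward-strand motif matching.
`TCGA` is its own reverse complement, so one strand suffices; a
non-palindromic motif requires an explicit both-strands scan, and `N`
never matches (conservative site calling). On i.i.d. uniform sequence a
4-bp motif occurs once per 4⁴ = 256 bp, which the tests verify
empirically within 3 binomial standard deviations on 1 Mb.

## Junction accounting

A junction is the ordered join `A[:a] + B[b:]` of two forward-strand
flanks. Since the flanks may share sequence, the physical breakpoint is
only defined up to an ambiguity window: `ov_left` (common suffix of the
left flanks) plus `ov_right` (common prefix of the right flanks). All
junctions — planted truth and detected calls alike — are canonicalised
by left-alignment, so "base-exact recovery" is a well-defined equality
of canonical keys even for joins inside homologous sequence. The
mechanism signatures:

- **direct religation** (`taqi_direct`): cleavage of `T^CGA` on both
  strands leaves 5′ `CG` overhangs; ligating two half-sites from
  different loci reconstitutes `TCGA` across the join with zero net
  loss. The classifier requires a motif occurrence that strictly
  contains an admissible breakpoint, and zero inserted/deleted bases.
- **microhomology** (`microhomology`): total overlap of exactly 2–3 nt
  with no spanning site — the MMEJ/A-NHEJ footprint.
- **repeat-mediated** (`homologous`): both canonical breakpoints within
  same-family repeat annotations ±50 bp. This rule is checked first,
  because recombination between repeats need not preserve any
  junction-level signature (the overlap there is long and
  uninformative).

Rules are mutually exclusive by construction (a property test draws
random junction feature combinations and checks that exactly one rule,
or none, fires).

## Detection pipeline

**Coverage callers.** Depth is binned (default 100 bp) per haplotype.
Normalization divides by the genome-wide median of unmasked bins
(telomeres and the rDNA array are mask-flagged; masks never enter
statistics but can bridge run merging). Aneuploidy uses the combined
homolog-pair ratio (mean of the two per-haplotype ratios, so 1.0 is
euploid): a chromosome is called when its median ratio crosses
`1 ± 0.7/p` for ploidy `p` — midway between euploid and a single-copy
change, 1.35/0.65 for a diploid — **and** the median array probe
log₁₀ ratio crosses ±log₁₀ 1.25. Calls lacking either platform stay
`unconfirmed`; the dual-support gate is enforced by the call type
itself. Local CNVs are maximal threshold-crossing runs merged across
≤merge-gap holes (run-length segmentation rather than CBS/HMM: the
procedure being modelled is threshold-based, and the operation contract
would let a fancier segmenter swap in). Median statistics are used
throughout for robustness to focal events.

**Homolog events.** Candidate tracts are maximal unmasked runs of bins
at depth ≤0 (length ≥500 bp, merge gap 200 bp). Each candidate is
lifted to the homolog; reciprocity passes when the homolog's mean
normalized ratio over the lifted interval reaches 1.6 (expected 2.0
for a clean conversion; 1.6 separates true doubling from depth noise at
80×). Passing tracts that reach a chromosome end — within the telomere
mask plus 1 kb slack — are BIR (reported through the telomere to the
end, since the masked tail cannot testify either way); internal tracts
are SGC; a tract covering the entire chromosome is routed to
aneuploidy/LOH review instead. The donor is the haplotype showing the
doubled coverage. Boundaries are approximate by nature (homologous
junctions have no base-exact breakpoint); at 100 bp bins the tests
require ≤1 bin of error.

**Breakpoint junctions.** Soft-clip records are clustered per
(haplotype, chromosome, clip side) within 200 bp; a cluster becomes a
boundary region when its clipped-read fraction exceeds 10% of depth.
The per-column-majority consensus of the clipped tails is aligned
against the whole dual reference by the internal aligner; the best hit
under e < 1e−4 names the partner locus, with a reciprocal-best-hit
check from the partner side and confirmation by ≥2 properly oriented
discordant pairs. When the consensus ends inside locally identical
sequence (a SNP-free homolog window, a repeat copy), the best hit ties
across copies; ties are resolved by which candidate has discordant-pair
support, since pairs carry the true partner's identity — the same role
pair confirmation plays in the three-step validation this pipeline
follows. Unresolvable ambiguous calls that re-describe an already
resolved junction (same clip-derived locus, same role) are dropped;
genuinely unresolved junctions stay flagged. rDNA-context junctions are
reported but flagged non-verifiable.

**Aligner.** Seeds are exact 11-mers in a sorted 2-bit index; each
candidate diagonal is scored ungapped by a maximum-scoring-substring
pass (match +1, mismatch −2). Gap penalties (−5 open, −2 extend) are
part of the scoring interface but no gapped extension is performed:
clipped junction tails are contiguous copies of their source locus, so
gaps cannot arise in the intended inputs. λ solves
Σ pᵢpⱼ e^{λ sᵢⱼ} = 1 at uniform base composition (λ ≈ 1.34 for +1/−2);
K is approximated as 0.3. The approximation only needs to separate
~250-bp verbatim copies (E ≪ 1e−100) from chance ~10-bp matches
(E ≫ 1), so its crudeness is harmless at the e < 1e−4 threshold; a
test cross-checks best-hit placement against command-line BLAST when
available.

## Variant post-filters

Both rule sets are pure per-record predicates, so the survivor set is
independent of application order (tested by permutation). Yeast:
masked regions (AT-rich/rDNA/telomere BEDs), local coverage strictly
below 50% of the sample average, and variants present in every sample.
Plant: control-shared records; allele frequency strictly > 0.4; InDels
additionally need fewer than 2 control reads — an InDel with no control
evidence is held as unresolved rather than passed — and locus
uniqueness, operationalised as "no second candidate InDel within 10 bp"
(the source procedure names the criterion without defining it; the
choice is recorded in the filter report). SNVs at multi-allelic loci
are excluded. An `at_rich_mask` helper (A+T fraction > 0.80 over 100 bp
windows) documents an explicit default where no curated mask exists.

## 3D proximity

A chromosome coordinate model is a polyline per chromosome (anchors at
genomic positions, x/y/z in µm); loci interpolate linearly and never
extrapolate. The null draws n = 10,000 locus pairs, both loci uniform
per base pair of total anchored length (a flag switches to uniform per
chromosome), and stores the empirical distance CDF; observed pairs are
placed by rank. Seed-to-seed stability of the null mean is asserted
within the 3·SD/√n CLT bound. The synthetic coordinate model is a
confined Gaussian random walk (step SD 0.08 µm per 10 kb anchor)
folded into a 2 µm-diameter sphere — sufficient for the null's
geometry, but it does not emulate centromere clustering or the Rabl
configuration of a real nucleus, so absolute distances from it are not
comparable to published microscopy values; feeding a real coordinate
model TSV reproduces the published-style analysis.

## The simulator as the study's stand-in

`simulate_parental_pair` builds an ancestor with planted repeat
families — dispersed Ty-like elements (default 12 copies × 5 kb,
~1%/copy divergence), a tandem rDNA array, short transposons — and
derives the second haplome at 6.5 SNPs/kb and 0.7 InDels/kb (≈0.72%
total divergence; the generator exposes SNP and InDel densities
separately since the aggregate figure in the literature mixes the two).
InDels are routed around repeat annotations so dispersed copies keep a
common length; SNVs fall everywhere.

`plant_events` applies edits on a segment representation of each
derived chromosome, so copy number per parental base pair is exact
bookkeeping, then emits sequences. Translocations are planted as
reciprocal exchanges (both derivative chromosomes kept), which makes
them copy-number neutral and keeps the coverage channel orthogonal to
the junction channel; unbalanced rearrangements are covered by the
deletion/tandem-duplication event types, whose junctions are direct
religation or (with probability `microhomology_fraction`, default
0.31) planted 2–3 nt microhomology joins audited to have no chance
extension and no spanning motif. Repeat-mediated crossovers are placed
in the distal 200–600 bp of the element so that clipped tails reach
unique flanking sequence — without this, partner location inside a
near-identical repeat would be systematically ambiguous, which is a
modelling choice, not a claim about where HR resolves in vivo. BIR may
run to either chromosome end; SGC lengths are log-uniform on 0.7–30 kb.
Roughly 200 DSBs are drawn per cell (Poisson) but only the requested
events resolve into records: the rest religate silently, as most
cohesive-ended breaks do, and leave nothing for sequencing to see.

Derived data are synthesised from the copy-number oracle rather than by
read simulation and alignment: coverage is negative-binomial
(gamma-Poisson) around `depth × copy_number` per bin (default 80×,
dispersion 0.1, within the 73–254× range of the emulated data); aCGH
probes report log₁₀(combined copy / ploidy) + Gaussian noise (SD 0.05),
floored at 0.05 copies for zero-copy loci; junction evidence emits
soft-clips (tails 50–250 nt of verbatim partner sequence, 2 × 300 bp
read regime) and discordant pairs at Poisson rates proportional to
depth, plus scattered background clips (0.05/kb). BIR/SGC boundaries
emit no clips: reads cross a homolog conversion with only SNP-level
mismatches and still align. Consequences of these choices: passing
tests demonstrate the callers' logic — thresholds, reciprocity,
canonicalisation, mechanism rules — under realistic depth noise, but
not robustness to alignment artefacts (mapping bias near SNPs, clipped
bases lost to adapter trimming, repeat-induced mismapping), to GC or
insert-size bias (not modelled, hence no GC correction in the CNV
caller), or to imprecise clip positions. Same seed and spec give
byte-identical outputs; the seed is recorded in truth metadata.

## Problem sizes and defaults

The bundled study-scale configuration is 13 chromosomes × 154 kb per
haplome (two ~2 Mb parental genomes) carrying 6 direct-join TLs, 3
repeat-mediated TLs, 10 BIRs, 40 SGCs, one gained and one lost
chromosome — the event spectrum of the emulated screen — at 80× depth.
One simulate-and-detect round trip takes a few seconds on one CPU; the
noise-robustness suite re-noises the same genome 20 times. These sizes
are the package's test configuration, chosen so the full spectrum fits
on small chromosomes with one BIR per chromosome pair; nothing in the
callers assumes them.

## Known limitations

- Only forward-strand (head-to-tail) junctions are modelled and
  detected; inversion-type joins would need strand-aware clip handling.
- Liftover assumes collinear homologs (no inter-haplotype inversions).
- The homolog-event caller summarises the allele-level evidence by
  coverage reciprocity; it does not re-check variant alleles inside the
  tract (an optional concordance hook exists but is not required).
- Segmentation is thresholding, not change-point inference; events
  smaller than ~2 bins or shallower than the thresholds are invisible
  by design.
- The E-value constant K is approximate; E-values near the threshold
  should not be over-interpreted.
- Chromosome-length chance: two aneuploidies plus 10 single-BIR pairs
  need ≥12 chromosome pairs; the planter raises a collision error
  rather than silently degrading when a spec does not fit its genome.
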