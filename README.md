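# taqsv

Detection, classification, and simulation of restriction-enzyme-induced
genome rearrangements on a dual-haplotype hybrid reference.

## The problem

Conditionally activating a 4-bp restriction endonuclease (TaqI, which
cuts the palindrome `TCGA` leaving 2-nt 5′ `CG` cohesive overhangs)
inside a living cell produces hundreds of simultaneous double-strand
breaks. In a hybrid diploid whose two parental genomes differ densely
(~6.5 SNPs/kb and ~0.7 InDels/kb, ~0.72% overall), the repair outcomes
leave distinct, readable footprints in short-read resequencing data:

- **aneuploidy** — whole-chromosome gain/loss, seen as a chromosome-wide
  depth-ratio shift that must be confirmed on both sequencing and
  tiling-array (aCGH) platforms;
- **BIR** (break-induced repair/replication) — one-ended repair copying
  the homolog from an internal breakpoint to the chromosome end:
  reciprocal zero/double coverage on the two haplotypes, reaching a
  telomere;
- **SGC** (short gene conversion) — the same reciprocal signature for an
  internal 0.7–30 kb tract;
- **translocations (TL)** — soft-clipped and discordant read clusters at
  the junction; the reconstructed junction sequence identifies the
  repair pathway: direct religation of two cohesive half-sites
  (C-NHEJ; the motif is reconstituted with zero net loss), 2–3 nt
  microhomology without a spanning site (MMEJ/A-NHEJ), or recombination
  between dispersed repeats (HR; Ty-like elements, rDNA).

`taqsv` implements the full calling pipeline for these footprints, the
breakpoint-mechanism classifier, a resampling null for asking whether
translocation partners were 3D-proximal (from a chromosome coordinate
model), the post-filters used for small-variant calls, and — because the
original data live in sequencing archives — a mechanism-faithful
simulator that fabricates restructured hybrids with exact truth sets,
so every stage is testable on a desk.

It is aimed at people analysing engineered genome-restructuring screens
(yeast or plant), and at anyone who needs a self-contained, truth-set-
driven test bed for structural-variant calling on hybrid references.

## Core definitions

For a junction joining the left flank of locus *a* (reference *A*) to
the right flank of locus *b* (reference *B*), the derived sequence is
`A[:a] + B[b:]`. Because the flanks may share sequence at the join, all
breakpoints are **left-aligned**: with `ov_left` the common suffix of
`A[:a]`, `B[:b]` and `ov_right` the common prefix of `A[a:]`, `B[b:]`,
the canonical junction is `(a - ov_left, b - ov_left)` and the total
homologous overlap is `ov_left + ov_right`. Mechanism rules, in priority
order:

1. *homologous* — both canonical breakpoints inside same-family repeat
   annotations (±50 bp);
2. *taqi_direct* — a `TCGA` occurrence strictly spans an admissible
   breakpoint and the junction has zero net deleted/inserted bases;
3. *microhomology* — overlap length ∈ {2, 3} and no spanning site;
4. otherwise *unclassified*.

Aneuploidy calling compares each chromosome's median depth ratio
(combined over haplotypes, 1.0 = euploid) against thresholds
`1 ± 0.7/p` for ploidy *p* (1.35/0.65 for a diploid) **and** the median
probe log₁₀ ratio against ±log₁₀ 1.25; only dual-support calls are
labelled aneuploidy. Partner search for clipped tails uses an internal
seed-and-extend local aligner with Karlin–Altschul significance
(E = K·m·n·e^(−λS), threshold e < 1e−4) plus a reciprocal-best-hit
check and ≥2 properly oriented discordant pairs.

## Worked example

```python
from taqsv.pipeline import simulate_case, run_detection
from taqsv.report import tally_events

# two ~2 Mb parental haplomes, full event spectrum, noise-free
case = simulate_case([154_000] * 13, seed=11, noise="none")
result = run_detection(case.dual_ref, case.tracks, case.array, case.evidence)

for call in result.translocations[:3]:
    j = call.junction
    print(f"TL {j.locus_a.haplotype}_{j.locus_a.chrom}:{j.locus_a.pos} -> "
          f"{j.locus_b.haplotype}_{j.locus_b.chrom}:{j.locus_b.pos} "
          f"[{call.mechanism.mechanism}] overlap={j.overlap_seq!r} pairs={call.n_pairs}")
print("aneuploidy:", [(c.chrom, c.direction, c.status) for c in result.aneuploidy])
print("homolog events:", len(result.homolog_events), "junctions:", len(result.junctions))
```

prints

```
TL A_chr03:29703 -> B_chr05:68817 [taqi_direct] overlap='TCGAA' pairs=17
TL B_chr01:73155 -> B_chr05:132051 [taqi_direct] overlap='TCGA' pairs=21
TL B_chr05:68817 -> A_chr03:29703 [taqi_direct] overlap='TCGAA' pairs=22
aneuploidy: [('chr04', 'loss', 'aneuploidy'), ('chr08', 'gain', 'aneuploidy')]
homolog events: 50 junctions: 18
```

The first junction reads: a derived chromosome joins the left arm of
parent-A chr03 (breakpoint 29,703) to the right arm of parent-B chr05;
the reconstituted `TCGA` across the join with zero net loss marks it as
direct religation of two cohesive cut sites, supported by 17 discordant
pairs. The 18 junction calls are the two sides of 9 reciprocal
exchanges (6 direct-join + 3 repeat-mediated); the 50 homolog events
are the 10 planted BIRs and 40 SGCs, and both planted aneuploidies are
called with dual-platform support.

The same pipeline is scriptable from the shell:

```bash
taqsv simulate --n-chrom 13 --chrom-length 154000 --seed 11 --outdir run/
taqsv scan-cnv run/ && taqsv scan-homolog run/ && taqsv scan-breakpoints run/
taqsv report run/
```

## Layout

| module | contents |
| --- | --- |
| `taqsv.genome` | haplomes, restriction-site index, variant map, liftover |
| `taqsv.simulate` | parental-pair generator, event planting, coverage/aCGH/evidence/3D simulation |
| `taqsv.cnv` | normalization, aneuploidy (dual-platform) and local-CNV segmentation |
| `taqsv.homolog` | zero-coverage scan, homolog reciprocity, BIR/SGC classification |
| `taqsv.breakpoints` | boundary regions, partner search, junction reconstruction, mechanism calls |
| `taqsv.align` | k-mer seeded ungapped local aligner with E-values |
| `taqsv.filters` | yeast and plant small-variant post-filters |
| `taqsv.proximity` | coordinate model, random-pair null, pair placement |
| `taqsv.report` | tallies, rates, F-test, circular-plot exports |
| `taqsv.cli` | `taqsv` command-line interface |

See `docs/methods.md` for the model, parameter choices and limitations.
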