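# chromarch

Chromosome-architecture analyses for avian-style genomes, with a synthetic
test bench: every analysis stage can be exercised on simulated genomes with
planted, recorded truth — no downloads required.

## What it does

| Module | Role |
| --- | --- |
| `chromarch.core_io` | FASTA / BED / bedGraph / PAF / nucmer-coords / COO-matrix readers and writers, genome windowing, GC tracks |
| `chromarch.simulate` | Synthetic genomes (macro/micro autosomes, Z with terminal PAR, W derived from Z at planted divergence levels), sexed depth tracks, Hi-C matrices with TADs and compartments, alignment blocks with planted inversions, expression matrices |
| `chromarch.sexlink` | Z / W / autosome classification from male/female depth ratios (Z: ratio 1.5–2.5 with ≥80 % coverage in both sexes; W: depth or coverage ratio ≤ 0.25), PAR boundary detection by two-segment changepoint fit, M/F expression ratios, tissue-specificity index τ |
| `chromarch.strata` | W-scaffold placement on the Z, 10-kb windowed W/Z divergence, evolutionary-strata segmentation by exact least-squares changepoint DP with BIC model selection |
| `chromarch.hic_arch` | ICE matrix balancing, square insulation score, TAD boundary calls (local minima with strength threshold), A/B compartments (first eigenvector of the O/E correlation matrix), PWM motif scanning, convergent-pair "loop anchor" detection, boundary annotation, cross-species boundary sharing |
| `chromarch.rearrange` | Synteny chaining, inversion calling (reverse-strand chains > 10 kb), outgroup polarization, breakpoint extraction, breakpoint–boundary permutation enrichment, rank-sum region comparisons |
| `chromarch.repeats` | Windowed monomer/motif counting (centromeres, telomeres, ITRs) and inverted-repeat palindrome detection by k-mer seeding with X-drop arm extension |
| `chromarch.pipeline` | End-to-end orchestration from one TOML config with a JSON results bundle and truth-recovery table |

## CLI

```bash
chromarch simulate --out sim/ --seed 1          # synthetic genome + truth.json
chromarch run --config config.toml              # full synthetic workflow

chromarch sexlink --male-depth M.bedgraph --female-depth F.bedgraph \
    --chrom-sizes chrom.sizes --windows 5000
chromarch strata --w-z-paf w_vs_z.paf --z-length 84500000 --window 10000 --k auto
chromarch hic --matrix chr1.coo --binsize 10000 --ins-window 10 --min-strength 0.1
chromarch inversions --focal-vs-b duck_chicken.paf --focal-vs-outgroup duck_emu.paf
chromarch bp-overlap --breakpoints bp.bed --boundaries tad.bed \
    --chrom-length 200000000 --slack 10000 --nperm 1000 --seed 1
chromarch repeats --fasta genome.fa --monomer-fasta monomer.fa --telomere-motif TTAGGG
chromarch palindromes --fasta chrW.fa --min-arm 2000 --max-spacer 50000
```

A minimal pipeline config:

```toml
outdir = "run1"
seed = 7
[simulate]            # or [inputs] for real data paths
par_len = 100000
```

## Conventions

All coordinates are 0-based half-open internally; BED on disk; the `coords`
alignment dialect (1-based closed) is converted on read. Window grids are
anchored at position 0. Missing window values are NaN, never 0. All
stochastic stages are bit-reproducible under a fixed seed.
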