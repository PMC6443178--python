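# hervscan

Element-level somatic-mutation hotspot scanning for endogenous retrovirus
(ERV) annotations. Given an element table, somatic SNVs (VCF or TSV) and a
coding-region BED, the pipeline tests each element for over- or
under-representation of variants against a uniform-genome null:

- per-element hit probability `p_F = n_F / L` (element length over region
  length), expectation `n_E = N * p_F`, exact binomial tail p-values,
  Bonferroni family-wise error control;
- coding / non-coding partitioning of variants by a supplied exon BED;
- taxonomy (group / supergroup / canonical) and per-cancer cross-tabs;
- functional-track overlap (lncRNA, intron, TFBS, ...) in both
  multi-count and exclusive-precedence modes;
- a random fixed-width window scan for checking the background density;
- a seeded synthetic-landscape generator so every stage runs with no
  external data.

## CLI

```sh
# synthetic landscape: elements.tsv, coding.bed, snvs.vcf, tracks.bed, truth.json
hervscan simulate --seed 1 --out out/sim

# enrichment scan (results.tsv + manhattan.tsv + manifest.json)
hervscan scan --elements out/sim/elements.tsv --snvs out/sim/snvs.vcf \
    --coding-bed out/sim/coding.bed --region-class noncoding \
    --fragment-size 1000 --out out/scan

# summaries: group_summary.tsv, cancer_crosstab.tsv, functional_*.tsv
hervscan report --results out/scan/results.tsv --elements out/sim/elements.tsv \
    --snvs out/sim/snvs.vcf --tracks out/sim/tracks.bed --out out/report

# all of the above in one go
hervscan run --seed 1 --out out/full
```

Useful scan options: `--alpha`, `--n-tests` (integer or `auto`),
`--tail-mode {exact_binomial,poisson,normal_paper_compat}`,
`--count-mode {sites,events}`, `--genome-length` (defaults to the sum of
VCF contig lengths when present). Exit codes: 0 success, 2 usage,
3 input-format error, 4 runtime failure.

## Library layout

| module                | contents |
|-----------------------|----------|
| `hervscan.model`      | domain types (intervals, elements, SNVs, background, results) |
| `hervscan.io`         | TSV/VCF/BED readers and writers |
| `hervscan.intervals`  | interval index, SNV-to-element assignment, region classification |
| `hervscan.enrichment` | binomial/Poisson/normal tails, Bonferroni, the scan, fragment sampling |
| `hervscan.report`     | group summaries, cancer crosstabs, functional overlap, site annotation |
| `hervscan.simulate`   | synthetic landscapes and the four-element worked-example fixture |
| `hervscan.cli`        | `simulate` / `scan` / `report` / `run` subcommands |

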