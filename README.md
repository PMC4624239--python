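# seedscan

Permutation-tolerant enhancer similarity scanning.

`seedscan` scores the similarity between a known enhancer (query) and sliding
windows of a target sequence without requiring co-linearity. It builds a
profile of *motifs* — ungapped, mismatch-containing matches grown from perfect
8-mer seeds — resolves overlaps on both axes, sums above-noise motif scores
into a basic window score (`PURE`), and adds a weighted bonus for co-linear
motif chains detected through elliptical diagonal search spaces (`COMB`).
Candidate regions are runs of windows scoring above `median + 3·MAD` of the
scan's window-score distribution, ranked and reported as BED + TSV.

The package also ships the candidate-assessment tooling (orthologous
flanking-gene classification, random motif sets, conservation-track
comparison via Wilcoxon rank-sum) and a synthetic-evolution simulator that
generates planted-enhancer fixtures (conserved motif blocks, fast-evolving
spacers, optional block permutation) so the whole pipeline is testable with
no external data.

## CLI

```sh
# genome scan: each query FASTA record against each target record
seedscan scan --query enhancers.fa --target genome.fa --out out/ \
    --score-type both --dump-windows

# classify predictions by orthologous flanking genes
seedscan annotate --predictions out/hs1.PURE.bed \
    --query-region chr3:193660817-193662478 \
    --query-genes human_genes.bed --target-genes fish_genes.bed \
    --orthologs orthologs.tsv --out flanks.tsv

# compare real motif conservation against random same-size motif sets
seedscan conservation --motifs motifs.bed --track scores.bedgraph \
    --region chr1:1-50000 --seed 7 --out conservation.tsv

# generate a planted-enhancer fixture (query, genome, truth BED, bedGraph)
seedscan simulate --out fixture/ --seed 3 --permute
```

Inputs are plain-text formats: FASTA (lowercase = soft-masked; masked bases
never seed), BED/GFF3 gene annotations, two-column ortholog TSV, bedGraph or
fixed-step wiggle conservation tracks. Outputs are BED6 (0-based half-open)
plus full-precision sidecar TSVs. Printed genome-browser coordinates are
interpreted as 1-based inclusive everywhere on the CLI.

## Scoring parameters

All defaults are overridable via CLI flags or `ScoringParams`: match +1,
mismatch −1, seed size 8 nt, noise threshold = score of a perfect 12-mer,
window = query length stepping 25 %, pattern limits `max_distance` 200 nt and
`max_shift` 25 nt, region threshold multiplier 3, top 25 predictions per
query.

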