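# ldrefine

Population-LD draft-genome refinement and comparative rearrangement
analysis, with a synthetic-data module so every stage is verifiable
without external downloads.

The pipeline has two halves:

1. **Refinement** — score linkage disequilibrium (composite genotype r²)
   between the edge SNP windows of draft scaffolds using population VCF
   data, build a scaffold-terminal graph, order and orient scaffolds by
   maximum-weight matching, linearize cycles at a threshold derived from a
   robust Gaussian fit to the score null, and emit super-scaffolds as
   FASTA + AGP with assembly statistics (N50/N90 etc.).
2. **Comparison** — parse MUMmer `show-coords`-style alignment tables,
   filter blocks (≥ 2 kb, ≥ 90 % identity), intersect homologous regions
   across genomes (> 80 % reciprocal overlap of the shorter interval),
   build three-way synteny blocks (> 10 kb), classify inversions and
   translocations from signed block permutations, and reconstruct
   majority-rule ancestral adjacencies for a three-genome topology.

## Layout

| module | role |
| --- | --- |
| `ldrefine.simpop` | synthetic chromosome, scaffold fragmentation, founder-mosaic population genotypes, coords fixtures with planted rearrangements, truth records |
| `ldrefine.variants` | VCF input (biallelic SNPs), site/scaffold filters, edge SNP windows |
| `ldrefine.ldscore` | r² statistics, terminal linkage-score matrix, null model + threshold |
| `ldrefine.scaffolder` | terminal matching, cycle linearization, FASTA/AGP emission, truth comparison |
| `ldrefine.metrics` | assembly length statistics and fold-change reports |
| `ldrefine.synteny` | coords parsing, block filters, multi-genome intersection, synteny blocks |
| `ldrefine.rearrange` | inversion/translocation calls, ancestral adjacency reconstruction |

## CLI

```sh
# simulate a fragmented chromosome + population VCF + truth files
ldrefine simulate --config sim.yaml --outdir data --seed 1

# full refinement (threshold fitted from the score null unless --threshold)
ldrefine build-scaffolds --vcf data/variants.vcf --fasta data/scaffolds.fasta \
    --outdir refined --truth data/truth_adjacencies.tsv

# assembly statistics / deltas
ldrefine stats --fasta refined/super_scaffolds.fasta --before data/scaffolds.fasta

# comparative side
ldrefine synteny-filter --coords aln.coords --out aln.filtered.coords
ldrefine synteny-intersect --coords sheep=a.coords --coords goat=b.coords --out-prefix shared
ldrefine rearrange --coords aln.filtered.coords --out calls.tsv
ldrefine ancestral --orders block_orders.tsv --out ancestor.json
```

Filter defaults follow the study this reimplements: 500 edge SNPs,
missing rate < 0.15, minor allele count ≥ 4, scaffolds ≥ 20 kb with ≥ 100
SNPs, alignment blocks ≥ 2 kb at ≥ 90 % identity, overlap > 0.8, three-way
blocks > 10 kb; every threshold is exposed as a flag.

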