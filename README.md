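# divscan

A genome-scan toolkit for comparing two closely related populations or
species from **all-sites VCFs** (invariant + variant records). It computes
missing-data-aware windowed statistics, extracts **high-diversity regions**
(HDRs: jointly low FST / high π in both groups), characterises them against
repeat and gene annotations, runs hierarchy-aware GO overrepresentation,
and contrasts short-read π with haplotype-resolved coding-sequence π at
copy-number-variable gene clusters. Seed-deterministic simulators generate
every input with known ground truth, including the collapsed-paralog
mechanism that inflates short-read heterozygosity.

## Components

| module | purpose |
| --- | --- |
| `divscan.allsites` | all-sites VCF I/O, population maps, GATK-style site/genotype hard filters |
| `divscan.windows` | per-window π, dxy and Weir–Cockerham FST as ratios of sums; interval π; Pearson track correlation |
| `divscan.hdr` | joint-percentile window selection (strict FST < q5, π > q95 in both groups) and region merging |
| `divscan.annotate` | RepeatMasker `.out` parsing, union repeat coverage per window, Welch's t, GFF3 gene overlap |
| `divscan.goenrich` | OBO DAG, gene→GO map building with ancestor propagation, classic Fisher and elim algorithms, Bonferroni |
| `divscan.clusters` | per-haplotype copy-number tables, aligned-CDS π (mean pairwise p-distance), long- vs short-read comparison |
| `divscan.simulate` | split-model coalescent all-sites VCFs, collapsed CNV clusters, composite genomes, missingness, GO/repeat/gene/recomb/CDS fixtures |
| `divscan.pipeline` / `divscan.cli` | end-to-end scan with manifest; `divscan` command line |

### Estimator notes

- π and dxy use the all-pairs allele-comparison counts per site
  (`diffs = c_ref·c_alt`, `comps = n(n−1)/2` within; `n1·n2` between) and
  are aggregated per window as **Σdiffs / Σcomps**, with invariant sites in
  the denominator — unbiased under random genotype missingness.
- FST sums the per-site Weir–Cockerham variance components and reports
  `Σa / Σ(a+b+c)`; per-site ratios are never averaged, negative estimates
  are not clipped.
- Windows with any undefined statistic are flagged and excluded before
  percentile thresholds are computed.

## CLI

```sh
# simulate a two-population split and scan it
divscan simulate split --n1 10 --n2 10 --sites 50000 --theta 0.005 \
    --split-time 1.0 --seed 1 --out-vcf sim.vcf --out-popmap sim.popmap
divscan windows --vcf sim.vcf --popmap sim.popmap --window-size 5000 --out windows.tsv
divscan hdr --windows windows.tsv --out-bed hdr.bed --out-tsv hdr.tsv

# GO overrepresentation
divscan go --obo go.obo --gene2go gene2go.tsv --study study.txt --algorithm elim --out go_BP.tsv

# aligned-CDS diversity
divscan cds-pi --fasta aligned_cds.fa --out cds_pi.tsv

# full pipeline from a YAML config (see divscan.pipeline.ScanConfig fields)
divscan run --config scan.yaml --outdir results/
```

Default filters follow common short-read joint-calling practice: sites
removed at `FS>60, MQRankSum<-12.5, MQ<40, QD<2, ReadPosRankSum<-8, SOR>3`;
genotypes masked at `GQ<20`, `DP<2` or `DP>100`; indels dropped. All are
configurable (`--site-filters`, `--gq-min`, ...).

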