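# nucago

Analysis toolkit for **nuclear AGO2 eCLIP** studies: where does Argonaute-2
engage nuclear RNA, which miRNAs does it carry, and do its intronic binding
sites coincide with alternative-splicing changes seen when the RNAi machinery
is knocked out?

The package implements, as a tested and reusable library, the complete
downstream analysis of such a study:

1. **Cluster calling with knockout background subtraction.** Candidate
   binding clusters are called per IP replicate from the stranded read pileup
   (per-position Poisson test, *P* < 0.001). Each cluster is tested for
   enrichment of IP reads over the *combined background* — the size-matched
   input plus the IP library from AGO2-knockout cells — with a two-sided
   Fisher exact test on total-normalised counts (Yates' χ² for large tables).
   Significant clusters (*P* < 0.05 **and** log₂ fold change ≥ 2) must
   reproduce across both replicates (≥ 1/3 overlap of their total length,
   same strand) and are merged to the union span. Final clusters are
   annotated by priority: CDS exon > 3′-UTR > 5′-UTR > protein-coding intron
   > noncoding exon > noncoding intron > intergenic.
2. **miRNA abundance profiling.** Reads are matched to mature miRNAs
   allowing one substitution, normalised by total mapped reads, then
   quantile-normalised across samples; compartments (nucleus vs cytoplasm)
   are compared by top-100 overlap, family percentages, and rank
   concordance.
3. **PSI-based splicing quantification.** SE/MXE/A5SS/A3SS events are
   extracted from the annotation; PSI = inclusion-supporting junction reads
   over total junction support; differential calls pool replicates per
   condition and use Fisher's exact test with Benjamini–Hochberg FDR
   (significant: FDR < 0.05 and |ΔPSI| ≥ 0.1).
4. **Integration across knockout lines.** Significant events are intersected
   across knockouts (Venn logic keyed by event and direction), shared events
   are linked to same-gene intronic clusters to form the candidate list,
   inclusion/exclusion ratios are correlated between conditions (Pearson *r*
   with OLS fit and confidence band), and clusters are classified by
   proximity to external protein-binding sites (overlap / <10 nt / ≤200 nt).
5. **miRNA site scanning.** Candidate clusters are scanned with a
   self-contained RNA–RNA duplex minimum-free-energy dynamic program
   (nearest-neighbour stack energies, affine loop penalties, GU wobble
   allowed); the scan is restricted to the top-100 most abundant miRNAs and
   reports sites with MFE ≤ −14 kcal/mol.

Because the real sequencing data are not needed to exercise any of this, the
package ships a first-class **synthetic-data generator**
(`nucago.simulate`): a toy 2-Mb chromosome with all seven annotation
categories, eCLIP read sets with planted 8-fold-enriched clusters, miRNA
read populations drawn from a shared Zipf abundance vector, and
junction-count tables with ΔPSI = 0.3 effects planted at genes carrying
intronic clusters — all with a machine-readable ground truth for scoring.

## Worked example

```bash
python examples/06_end_to_end.py
```

runs every stage on a 500-kb simulated dataset and prints:

```
final clusters: 19
top-N categories: {'pc_intron': 8, 'UTR3': 2, 'nc_exon': 7, 'CDS_exon': 1, 'nc_intron': 1}
miRNA top-100 overlap: 50
significant events per knockout: {'AGO1-KO': 1, 'AGO2-KO': 3, 'AGO12-KO': 4, 'AGO123-KO': 6, 'DROSHA-KO': 2}
candidates (shared + intronic cluster): 2
cluster recovery vs ground truth: {'recall': 0.95, 'fdp': 0.0}
```

Reading: 19 final clusters passed enrichment + replication, dominated by
protein-coding introns as expected for nuclear AGO2; both compartments share
the full 50-miRNA catalog among their top ranks; 2 splicing events are both
changed in the shared knockouts *and* carry an intronic AGO2 cluster — these
are the candidate genes, and `site_hits.tsv` lists the miRNAs predicted to
bind their clusters. Recovery vs the planted truth (recall 0.95, FDP 0.0)
confirms the pipeline found what was planted and nothing else.

The other scripts in `examples/` demonstrate each capability on its own:
simulation, cluster calling, miRNA profiling, differential splicing, and the
duplex site scan.

A thin CLI mirrors the library:

```bash
nucago simulate --seed 1 --outdir sim/
nucago run-all --seed 1 --outdir run/
nucago clusters --ip-rep1 ... --gtf ... --out clusters.tsv
```

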