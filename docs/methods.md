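# Methods

This note documents the models, statistical procedures, numerical choices and
known limitations of `nucago`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Coordinate and format conventions

All internal coordinates are 0-based half-open on a named chromosome with an
explicit strand (BED convention). GTF's 1-based inclusive coordinates are
converted at the I/O boundary, and the conversion is an involution (tested by
write→read round trips). Strand-aware operations never count features on
opposite strands as overlapping. FASTA input is upper-cased and U→T
normalised on read, with the original alphabet recorded per record.

## Cluster pipeline

**Candidate calling.** The initial caller is a per-position Poisson depth
test, applied per strand: a position is significant when its read depth `d`
satisfies `P(X ≥ d) < 0.001` under `X ~ Poisson(λ)` with λ the strand-wide
mean depth. Runs of significant positions separated by at most `merge_gap`
(10 nt) are joined; runs shorter than `min_width` (20 nt) are discarded. This
is a deliberately simple density caller standing in for a spline-fitting peak
caller; it operates on the same quantity the downstream statistics use
(cluster read counts) and at the same initial significance level.

Coverage around a binding site of width *w*, from reads of length *L*, is a
trapezoid whose half-maximum span is *w* + *L*. Each candidate run is
therefore trimmed to its half-max span and then shrunk by *L*/2 per end,
which recovers the site boundaries instead of the read-length overhang. This
matters quantitatively: without the shrink, the fold-change of a true 8-fold
site measured over the overhang-widened interval is diluted toward the
significance boundary.

**Enrichment statistic.** For a cluster with `ip` of `ip_total` IP reads and
`bg` of `bg_total` background reads,

    log2fc = log2( ((ip + 1) / ip_total) / ((bg + 1) / bg_total) )

with a pseudocount of 1 on both counts (configurable, and disabled in
exactness tests). The background is the **sum** of the size-matched input
and the knockout-IP counts, with totals summed likewise — a sum rather than
a mean because the exact test operates on raw counts; a mean mode is
available. The knockout input is not part of the background.

The p-value is a two-sided Fisher exact test on
`[[ip, ip_total − ip], [bg, bg_total − bg]]`, computed by summing
hypergeometric probabilities of all tables at the observed margins whose
probability does not exceed the observed table's (with the standard
`1 + 1e-7` relative tie tolerance). When every expected cell count is at
least 1000 the pipeline switches to Yates-corrected χ², which is numerically
indistinguishable at that scale and avoids large-factorial work; the switch
point is configurable. Exactness is verified against an independent
enumeration oracle using exact integer binomials on all 2×2 tables with both
row margins ≤ 30 (agreement to 1e-10).

One structural caveat: the two-sided minimum-likelihood exact p is not
strictly monotone in `ip` when the observed count shifts the table margins;
the fold change is strictly monotone, and the large-sample χ² branch is
monotone in the enriched direction.

**Significance and reproducibility.** A cluster is significant when
`p < 0.05` (strict) **and** `log2fc ≥ 2` (inclusive). Significant clusters
from the two replicates are linked when on the same strand and overlapping
by at least 1/3 of their *union* length (the "each cluster's own length"
reading is available behind a switch); connected components containing both
replicates are merged to their union span, counts are re-aggregated over the
union (both IP replicates summed), and the statistic is re-computed. Merging
is symmetric in replicate order and agrees with a brute-force
connected-components oracle.

**Annotation.** Among all same-strand features overlapping a cluster by ≥ 1
nt, the highest-priority category wins: CDS exon > 3′-UTR > 5′-UTR >
protein-coding intron > noncoding exon > noncoding intron > intergenic.
Overlap with a miRNA locus additionally sets an `is_mirna` flag used for the
top-N partitioning. Ranking sorts by ascending p, then descending log2fc,
then genomic coordinate, so results are deterministic under ties.

No multiple-testing correction is applied to cluster p-values by default
(the per-cluster `p < 0.05` rule is the procedure being modelled); an
optional Benjamini–Hochberg mode exists.

## miRNA profiling

Reads are assigned to mature miRNAs by Hamming distance at most 1 over the
full mature length; longer reads are 3′-trimmed to the mature length,
shorter reads never match, and indels are not considered (one "mismatch" is
read as a substitution). Reads tied between several miRNAs at the best
distance are split fractionally, which conserves total counts exactly.

Counts are divided by the per-sample total of mapped reads and then
quantile-normalised: each sample's order statistics are replaced by the
across-sample means of the order statistics. Ties within a sample receive
the mean of the rank-range means, making the transform invariant to tie
ordering and idempotent. Compartment comparison reports the top-N (default
100) intersection size, family-aggregated percentages of top-N abundance,
and the Spearman rank correlation over the union of the two top-N sets.

## Splicing quantification

Events are extracted from pairwise transcript comparison within each gene:

* **SE** — an exon present in one transcript and absent from the other, with
  its flanking exons consecutive in the other transcript;
* **MXE** — two non-overlapping exons with shared flanks that never co-occur
  in any transcript of the gene;
* **A5SS / A3SS** — two exons sharing one boundary and differing at the
  donor (5′ splice site) or acceptor (3′ splice site) boundary, donor/acceptor
  being strand-dependent, with the relevant flanking exon shared.

PSI is a proportion of junction support: for SE,
`PSI = ((up_inc + down_inc)/2) / ((up_inc + down_inc)/2 + skip)`; for
A5SS/A3SS, `proximal / (proximal + distal)`; for MXE, exon-1 support over
exon-1 + exon-2 support (each the mean of its two junctions). PSI is
undefined (NaN) at zero denominator, and scale-invariant in the counts.

Differential calls pool replicate junction counts per condition and apply a
two-sided Fisher exact test to the pooled inclusion/exclusion table, with
Benjamini–Hochberg FDR across events; an event is significant at FDR < 0.05
and |ΔPSI| ≥ 0.1 (both configurable). ΔPSI = PSI(knockout) − PSI(wild-type);
"gained" means ΔPSI > 0. Swapping condition labels negates ΔPSI and leaves p
unchanged. This Fisher-on-pooled-junctions procedure is a defined,
self-contained stand-in — it is not a reimplementation of any published
splicing caller, and intron retention is out of scope by design.

## Integration

Candidate events are differential events linked to intronic clusters
(`pc_intron`/`nc_intron`) of the same gene on the same strand. "Nearby" is
not quantified by the upstream analyses this models, so two modes are
exposed: same-gene (default) and a flanking mode that caps the cluster's
distance to the event's alternative region (default 1500 nt, about one
intron). Venn intersections across knockouts key events by (event id,
direction). The inclusion/exclusion ratio used for cross-condition
correlation is `PSI/(1−PSI)` clipped at 50; correlation is Pearson's *r*
with the two-sided p from the t-distribution on n−2 df (which agrees with a
permutation null within Monte-Carlo error at small n) and an OLS fit with a
95% confidence band. Proximity to external binding sites is classified from
the nearest same-strand site as overlap, gap < 10 nt, gap ≤ 200 nt, or none,
where the gap counts bases strictly between intervals.

## Duplex MFE model

The site scan uses an intermolecular-only dynamic program over non-crossing
base pairings of a miRNA (5′→3′) against a target window. The energy of a
structure is the sum of nearest-neighbour stack terms for adjacent pairs
plus an affine penalty for interior loops and bulges:

    E(loop) = 4.0 + 1.0·(l1 + l2) + 0.5·|l1 − l2|   (kcal/mol)

with at most 10 unpaired nt per side between consecutive pairs, no
intramolecular structure, no helix-end or initiation terms (so a perfect
k-mer complement scores exactly the sum of its k−1 stack energies — a tested
identity). Watson–Crick stack energies are Turner-style published values
shipped as an editable table (`nucago/data/stack_energies.tsv`); stacks
involving GU wobbles use representative values (−1.2 with a Watson–Crick
neighbour, −0.3 between two wobbles). The table satisfies the 180°
rotational symmetry `E(XY/ZW) = E(WZ/YX)`, which makes the MFE symmetric
under exchanging which strand is the query. Absolute energies are therefore
internally consistent rather than tool-calibrated; the DP is verified
against exhaustive enumeration of all valid duplex structures on short
sequences. The inner loop is jit-compiled with numba when available, with a
pure-Python fallback.

Scanning slides a window of miRNA length + 5 nt (step 1) across the cluster
sequence in transcript orientation (minus-strand clusters are
reverse-complemented first), restricted to the top-100 most abundant miRNAs.
The binding threshold of 14 kcal/mol is interpreted as ΔG ≤ −14 kcal/mol
(binding free energies are negative); both the sign convention and the
magnitude are configuration options. Overlapping hit windows for one miRNA
collapse to the best-scoring (leftmost on ties). A seed flag records
Watson–Crick pairing of miRNA bases 2–8 but is informational only — hits are
filtered by rank and MFE, not seed status.

## Synthetic data generator

The generator emulates the study design, not sequencing physics. On a 2-Mb
toy chromosome (default), ~80 genes are laid out with intergenic gaps:
protein-coding genes (5–8 exons of 80–300 nt, introns 250–1200 nt, CDS with
flanking UTR halves, two transcripts realising one planted SE/MXE/A5SS/A3SS
event), multi-exon noncoding genes, and single-exon miRNA loci (60–90 nt).
The first three genes always cover the three gene classes so every
annotation category exists in any non-trivial simulation.

* **eCLIP**: every sample receives uniform Poisson background at 50 reads/kb
  (read length 100 nt, strand following the host gene, random in intergenic
  space). The two wild-type IP replicates additionally receive
  `(enrichment − 1) × background` reads inside each of the 60 planted
  clusters, so in-cluster IP density is exactly `enrichment` (default 8)
  times background. Knockout IP and both inputs carry background only.
  Planted clusters each lie fully inside a single feature of their category;
  ~30% sit on miRNA loci, the rest favour introns, mirroring a
  nuclear-binding category profile. The calibration statement is exact for
  gene-interior clusters; at gene-edge loci the strand-aware count window
  reaches intergenic space where strands are random, deflating strand-aware
  counts geometrically (the tests measure interior clusters for this
  reason). Crosslink-site truncation is intentionally not modelled: the
  downstream statistics consume cluster read counts, not truncation
  positions.
* **miRNAs**: 150 mature sequences (20–23 nt) with Zipf-distributed true
  abundance (exponent 1.1); nucleus and cytoplasm draw multinomially from
  the same vector. Reads are mature sequences with at most one substitution
  planted per erroneous read at a 0.5% per-base error rate.
* **Junctions**: for every extractable event, a base PSI is drawn uniform in
  [0.35, 0.65]; inclusion junction reads are Binomial(depth, PSI) and
  exclusion reads Binomial(depth, 1−PSI) at depth 200 per junction, three
  replicates per condition. The binomial is the minimal noise model
  consistent with PSI being a proportion. Cluster-linked events (default 6,
  hosted by SE genes that carry a planted intronic cluster in the upstream
  intron) shift PSI by a signed ΔPSI of 0.3 in all shared knockout
  conditions (AGO1/2, AGO1/2/3, DROSHA); every other event responds in a
  single knockout drawn from the AGO pool. This separation encodes the
  design logic: the shared-knockout Venn core is the candidate signature,
  and "extras" in the recovered candidate list are then a meaningful error
  measure.
* **Sites**: the three top-abundance miRNAs get perfect complements written
  into the genome inside distinct cluster-linked intronic clusters
  (orientation respecting the host gene's strand), so the site scan has
  recoverable ground truth far below the −14 kcal/mol threshold.

All outputs are pure functions of (config, seed): each stage derives its
generator from `(seed, stage_index)`, and byte-identical files across
repeated runs are tested. `planted_enrichment = 1` is the supported null
(no signal anywhere).

**What passing tests do and do not show.** The simulator has uniform
background, no PCR duplicates, no adapter artifacts, no mappability
structure, no overdispersion beyond Poisson/binomial, and planted effects of
a single size. Recovery and FDR numbers on it validate the pipeline's logic
and calibration under its own assumptions; they are not performance claims
for real libraries, where background is structured and effect sizes vary.

## Problem sizes in tests and the acceptance script

The statistical checks use: all 2×2 tables with row margins ≤ 30 for the
Fisher oracle; 20 seeds of the full 2-Mb cluster pipeline for recovery and
for the null; 50 seeds for splicing power and 1000 events for null FDR; 500
random short pairs for the duplex oracle; 20 seeds for end-to-end candidate
recovery with the site scan verified on one seed's dataset. The acceptance
script re-runs the same computations at 10 simulation seeds per quantity
(50 for power, 200 pairs for the duplex check), chosen as the point where
the Monte-Carlo error of the reported means is comfortably below the margins
being tested.

## Known limitations

* The candidate caller is a density test; it will not separate two planted
  sites closer than the merge gap and has no sub-peak resolution.
* Fractional multi-mapping assignment makes miRNA counts non-integral;
  downstream normalisation treats them as rates, which is intended.
* MXE PSI uses junction support only; exon-body reads are ignored.
* The duplex energy table is internally consistent but not calibrated to
  any published thermodynamic parameter set's absolute scale; thresholds
  transfer qualitatively, not numerically, to other tools.
* `rbp_proximity` is O(clusters × sites); adequate at desk scale, not for
  genome-wide site catalogs.
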