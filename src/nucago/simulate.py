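"""Synthetic data generator with planted ground truth.

Emulates the study design end to end on a toy chromosome: a gene annotation
covering all seven genomic categories (including miRNA loci), an eCLIP
experiment with two wild-type IP replicates, a size-matched input, and IP +
input libraries in an AGO2-knockout background with enrichment planted at
known clusters; miRNA read populations sharing an abundance vector between
nuclear and cytoplasmic compartments; and junction-count tables across
knockout conditions with splicing effects planted at genes carrying intronic
clusters. Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import (
    AnnotationModel,
    Gene,
    Transcript,
    _derive_features,
    write_bed,
    write_fasta,
    write_gtf,
)
from . import splicing as _splicing

_RC = str.maketrans("ACGT", "TGCA")

ECLIP_SAMPLES = ("ip_wt_rep1", "ip_wt_rep2", "input_wt", "ip_ko", "input_ko")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SimulationConfig:
    """Study conditions for the simulator (defaults define the test bench)."""

    seed: int = 0
    chrom: str = "chrT"
    genome_length: int = 2_000_000
    # gene structure
    n_genes: int = 80
    mirna_gene_fraction: float = 0.25
    noncoding_fraction: float = 0.15
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (250, 1200)
    intergenic_gap: tuple[int, int] = (500, 3000)
    mirna_locus_length: tuple[int, int] = (60, 90)
    # eCLIP
    read_length: int = 100
    n_planted_clusters: int = 60
    planted_cluster_width: tuple[int, int] = (60, 150)
    planted_enrichment: float = 8.0
    background_density: float = 50.0  # reads per kb per sample
    planted_mirna_fraction: float = 0.3
    # miRNA profiling
    n_mirnas: int = 150
    mirna_abundance_shape: float = 1.1  # Zipf exponent
    mirna_length: tuple[int, int] = (20, 23)
    mirna_read_depth: int = 50_000
    mirna_error_rate: float = 0.005
    # splicing
    n_splicing_events_per_type: int = 8
    n_cluster_linked_events: int = 6
    n_planted_sites: int = 3
    base_psi: tuple[float, float] = (0.35, 0.65)
    planted_delta_psi: float = 0.3
    junction_depth: int = 200
    n_replicates: int = 3
    conditions: tuple[str, ...] = (
        "WT", "AGO1-KO", "AGO2-KO", "AGO12-KO", "AGO123-KO", "DROSHA-KO"
    )
    # cluster-linked events respond in all of these (the shared Venn core);
    # every other planted event responds in a single knockout from the pool
    affected_conditions: tuple[str, ...] = ("AGO12-KO", "AGO123-KO", "DROSHA-KO")
    single_ko_pool: tuple[str, ...] = (
        "AGO1-KO", "AGO2-KO", "AGO12-KO", "AGO123-KO"
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_delta_psi <= 1.0:
            raise ValueError("planted_delta_psi must lie in [0, 1]")
        if self.planted_enrichment < 1.0:
            raise ValueError("planted_enrichment must be >= 1 (1 is the null)")
        if self.n_genes < 0 or self.n_mirnas < 1:
            raise ValueError("n_genes must be >= 0 and n_mirnas >= 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class PlantedCluster:
    interval: GenomicInterval
    category: str
    gene_id: str
    is_mirna: bool = False
    enrichment: float = 1.0
    site_mirna: str = ""  # miRNA with a planted complementary site, if any
    site_start: int = -1  # genomic start of the planted site


@dataclass
class PlantedEvent:
    gene_id: str
    etype: str
    delta_psi: float  # signed
    affected_conditions: tuple[str, ...]
    cluster_linked: bool
    event_id: str = ""


@dataclass
class GroundTruth:
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    planted_events: list[PlantedEvent] = field(default_factory=list)
    mirna_true_abundance: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_clusters": [
                {
                    "chrom": c.interval.chrom, "start": c.interval.start,
                    "end": c.interval.end, "strand": c.interval.strand,
                    "category": c.category, "gene_id": c.gene_id,
                    "is_mirna": c.is_mirna, "enrichment": c.enrichment,
                    "site_mirna": c.site_mirna, "site_start": c.site_start,
                }
                for c in self.planted_clusters
            ],
            "planted_events": [asdict(e) for e in self.planted_events],
            "mirna_true_abundance": self.mirna_true_abundance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gt = cls()
        for c in payload["planted_clusters"]:
            gt.planted_clusters.append(
                PlantedCluster(
                    GenomicInterval(c["chrom"], c["start"], c["end"], c["strand"]),
                    c["category"], c["gene_id"], c["is_mirna"], c["enrichment"],
                    c["site_mirna"], c["site_start"],
                )
            )
        for e in payload["planted_events"]:
            e = dict(e)
            e["affected_conditions"] = tuple(e["affected_conditions"])
            gt.planted_events.append(PlantedEvent(**e))
        gt.mirna_true_abundance = payload["mirna_true_abundance"]
        return gt


@dataclass
class _GeneRecord:
    gene_id: str
    gene_type: str
    strand: str
    exons: list[tuple[int, int]]
    event: str | None = None
    alt_exon_index: int = -1  # index of the alternative exon (SE/MXE/A5SS/A3SS)


@dataclass
class SimulatedGenome:
    """Annotation + genome + planted-truth skeleton produced by stage one."""

    config: SimulationConfig
    annotation: AnnotationModel
    genome: str
    mirna_catalog: dict[str, str]  # id -> RNA mature sequence
    family_map: dict[str, str]
    ground_truth: GroundTruth
    strand_of_position: np.ndarray  # 0:'+', 1:'-', 2: intergenic (random)


# ---------------------------------------------------------------------------
# Stage 1: annotation + genome
# ---------------------------------------------------------------------------

def _gene_plans(config: SimulationConfig) -> list[str]:
    n = config.n_genes
    n_mirna = int(round(config.mirna_gene_fraction * n))
    n_nc = int(round(config.noncoding_fraction * n))
    n_pc = max(n - n_mirna - n_nc, 0)
    plans = (["pc"] * n_pc + ["nc"] * n_nc + ["mirna"] * n_mirna)[:n]
    if n >= 3:  # construction guarantees every category appears
        plans[0], plans[1], plans[2] = "pc", "nc", "mirna"
    return plans


def _mature_mirnas(config: SimulationConfig, rng):
    """Mature catalog, family map and Zipf true-abundance vector."""
    lo, hi = config.mirna_length
    catalog: dict[str, str] = {}
    family_map: dict[str, str] = {}
    fam_idx, i = 0, 0
    bases = np.array(list("ACGU"))
    while i < config.n_mirnas:
        fam_size = min(int(rng.integers(1, 4)), config.n_mirnas - i)
        fam_idx += 1
        for _ in range(fam_size):
            mid = f"mir-{i + 1}"
            length = int(rng.integers(lo, hi + 1))
            catalog[mid] = "".join(rng.choice(bases, size=length))
            family_map[mid] = f"fam-{fam_idx}"
            i += 1
    ranks = np.arange(1, config.n_mirnas + 1, dtype=float)
    weights = ranks ** (-config.mirna_abundance_shape)
    weights /= weights.sum()
    ids = list(catalog)
    rng.shuffle(ids)
    abundance = {mid: float(w) for mid, w in zip(ids, weights)}
    return catalog, family_map, abundance


def _layout_genes(config: SimulationConfig, rng) -> list[_GeneRecord]:
    plans = _gene_plans(config)
    etypes = ["SE", "MXE", "A5SS", "A3SS"]
    budget = {t: config.n_splicing_events_per_type for t in etypes}
    records: list[_GeneRecord] = []
    cursor = int(rng.integers(*config.intergenic_gap)) if plans else 0
    pc_seen = 0
    for g_idx, plan in enumerate(plans):
        gene_id = f"G{g_idx:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if plan == "mirna":
            length = int(rng.integers(*config.mirna_locus_length))
            exons = [(cursor, cursor + length)]
            rec = _GeneRecord(gene_id, "miRNA", strand, exons)
        else:
            lo_e, hi_e = config.exons_per_gene
            n_ex = int(rng.integers(max(lo_e, 5 if plan == "pc" else lo_e), hi_e + 1))
            exons = []
            pos = cursor
            for e in range(n_ex):
                elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
                exons.append((pos, pos + elen))
                pos += elen
                if e < n_ex - 1:
                    pos += int(
                        rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                    )
            event = None
            if plan == "pc":
                want = etypes[pc_seen % 4]
                order = [want] + [t for t in etypes if t != want]
                for t in order:
                    if budget[t] > 0:
                        event = t
                        budget[t] -= 1
                        break
                pc_seen += 1
            rec = _GeneRecord(
                gene_id, "protein_coding" if plan == "pc" else "lincRNA",
                strand, exons, event,
            )
        if rec.exons[-1][1] + config.intergenic_gap[1] > config.genome_length:
            raise ValueError(
                f"gene structures do not fit on {config.chrom} "
                f"({config.genome_length} nt); reduce n_genes or feature sizes"
            )
        records.append(rec)
        cursor = rec.exons[-1][1] + int(rng.integers(*config.intergenic_gap))
    return records


def _install_gene(model: AnnotationModel, rec: _GeneRecord, config, rng,
                  planted_events: list[PlantedEvent]) -> None:
    chrom, strand = config.chrom, rec.strand
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in rec.exons]
    span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    model.genes[rec.gene_id] = Gene(rec.gene_id, rec.gene_type, span)
    if rec.gene_type != "protein_coding":
        t1 = Transcript(f"{rec.gene_id}.t1", rec.gene_id, strand, exons=exons)
        model.transcripts[t1.transcript_id] = t1
        return
    cds_lo = exons[0].start + exons[0].length // 2
    cds_hi = exons[-1].end - exons[-1].length // 2
    n = len(exons)
    chain1, chain2 = list(exons), None
    etype = rec.event
    if etype == "SE" and n >= 4:
        i = int(rng.integers(1, n - 1))
        rec.alt_exon_index = i
        chain2 = exons[:i] + exons[i + 1:]
    elif etype == "MXE" and n >= 5:
        i = int(rng.integers(1, n - 3))
        rec.alt_exon_index = i
        chain1 = exons[:i + 1] + exons[i + 2:]  # keeps exon i, drops i+1
        chain2 = exons[:i] + exons[i + 1:]      # drops exon i, keeps i+1
    elif etype in ("A5SS", "A3SS") and n >= 3:
        i = int(rng.integers(1, n - 1))
        ex = exons[i]
        delta = int(rng.integers(40, 90))
        extend_right = (etype == "A5SS") == (strand == "+")
        new = None
        if extend_right and ex.end + delta < exons[i + 1].start - 20:
            new = GenomicInterval(chrom, ex.start, ex.end + delta, strand)
        elif not extend_right and ex.start - delta > exons[i - 1].end + 20:
            new = GenomicInterval(chrom, ex.start - delta, ex.end, strand)
        if new is not None:
            rec.alt_exon_index = i
            chain2 = exons[:i] + [new] + exons[i + 1:]
        else:
            rec.event = etype = None
    else:
        rec.event = etype = None
    t1 = Transcript(f"{rec.gene_id}.t1", rec.gene_id, strand, exons=chain1)
    t1.cds = _cds_pieces(chain1, cds_lo, cds_hi)
    model.transcripts[t1.transcript_id] = t1
    if chain2 is not None:
        t2 = Transcript(f"{rec.gene_id}.t2", rec.gene_id, strand, exons=chain2)
        t2.cds = _cds_pieces(chain2, cds_lo, cds_hi)
        model.transcripts[t2.transcript_id] = t2
        sign = 1.0 if rng.random() < 0.5 else -1.0
        planted_events.append(
            PlantedEvent(
                gene_id=rec.gene_id, etype=etype,
                delta_psi=sign * config.planted_delta_psi,
                affected_conditions=tuple(config.affected_conditions),
                cluster_linked=False,
            )
        )


def _cds_pieces(exons, lo, hi):
    pieces = []
    for ex in exons:
        s, e = max(ex.start, lo), min(ex.end, hi)
        if s < e:
            pieces.append(GenomicInterval(ex.chrom, s, e, ex.strand))
    return pieces


def _place_within(host: GenomicInterval, width_range, rng, margin: int = 3):
    """A sub-interval fully inside ``host`` with a small safety margin."""
    lo_w = min(width_range[0], host.length - 2 * margin)
    hi_w = min(width_range[1], host.length - 2 * margin)
    if hi_w < 20:
        return None
    w = int(rng.integers(lo_w, hi_w + 1)) if hi_w > lo_w else int(hi_w)
    start = int(rng.integers(host.start + margin, host.end - margin - w + 1))
    return GenomicInterval(host.chrom, start, start + w, host.strand)


def _safe_introns(model: AnnotationModel, gene_id: str) -> list[GenomicInterval]:
    """Introns of every transcript of the gene, not overlapped by any exon."""
    txs = model.transcripts_of(gene_id)
    if not txs:
        return []
    all_exons = [e for t in txs for e in t.exons]
    out = []
    for iv in txs[0].introns():
        if all(iv.intersection_length(e) == 0 for e in all_exons):
            if all(
                any(iv.intersection_length(j) == iv.length for j in t.introns())
                for t in txs
            ):
                out.append(iv)
    return out


def _plant_clusters(config, rng, model, records, gt: GroundTruth) -> None:
    width = config.planted_cluster_width
    by_id = {r.gene_id: r for r in records}
    planted: list[PlantedCluster] = []

    # cluster-linked events: intronic clusters in the intron upstream of the
    # alternative exon of SE events (fall back to any safe intron)
    se_events = [e for e in gt.planted_events if e.etype == "SE"]
    for ev in se_events[: config.n_cluster_linked_events]:
        rec = by_id[ev.gene_id]
        i = rec.alt_exon_index
        host = None
        if i > 0:
            cand = GenomicInterval(
                config.chrom, rec.exons[i - 1][1], rec.exons[i][0], rec.strand
            )
            safe = _safe_introns(model, ev.gene_id)
            host = next((iv for iv in safe if iv.start == cand.start), None)
            if host is None and safe:
                host = safe[0]
        if host is None:
            continue
        iv = _place_within(host, width, rng)
        if iv is None:
            continue
        ev.cluster_linked = True
        planted.append(PlantedCluster(iv, "pc_intron", ev.gene_id))

    n_mirna = int(round(config.planted_mirna_fraction * config.n_planted_clusters))
    mirna_genes = [r for r in records if r.gene_type == "miRNA"]
    rng.shuffle(mirna_genes)
    for rec in mirna_genes[:n_mirna]:
        s, e = rec.exons[0]
        planted.append(
            PlantedCluster(
                GenomicInterval(config.chrom, s, e, rec.strand),
                "nc_exon", rec.gene_id, is_mirna=True,
            )
        )

    # remaining clusters across the other categories
    hosts: list[tuple[str, GenomicInterval, str]] = []  # (category, host, gene)
    for rec in records:
        if rec.gene_type == "protein_coding":
            for iv in _safe_introns(model, rec.gene_id):
                hosts.append(("pc_intron", iv, rec.gene_id))
            t1 = model.transcripts[f"{rec.gene_id}.t1"]
            shared = [
                e for e in t1.exons
                if all(
                    any(e == o for o in t.exons)
                    for t in model.transcripts_of(rec.gene_id)
                )
            ]
            internal = [e for e in shared[1:-1]] if len(shared) > 2 else []
            for e in internal[:1]:
                hosts.append(("CDS_exon", e, rec.gene_id))
            first, last = t1.exons[0], t1.exons[-1]
            cds_lo = first.start + first.length // 2
            cds_hi = last.end - last.length // 2
            utr_left = GenomicInterval(config.chrom, first.start, cds_lo, rec.strand)
            utr_right = GenomicInterval(config.chrom, cds_hi, last.end, rec.strand)
            if rec.strand == "+":
                hosts.append(("UTR5", utr_left, rec.gene_id))
                hosts.append(("UTR3", utr_right, rec.gene_id))
            else:
                hosts.append(("UTR3", utr_left, rec.gene_id))
                hosts.append(("UTR5", utr_right, rec.gene_id))
        elif rec.gene_type == "lincRNA":
            exons = [
                GenomicInterval(config.chrom, s, e, rec.strand) for s, e in rec.exons
            ]
            hosts.append(("nc_exon", exons[0], rec.gene_id))
            for a, b in zip(exons, exons[1:]):
                hosts.append(
                    ("nc_intron",
                     GenomicInterval(config.chrom, a.end, b.start, rec.strand),
                     rec.gene_id)
                )
    # favour introns (the study's dominant category), then exonic categories
    weights = {"pc_intron": 0.55, "CDS_exon": 0.15, "UTR3": 0.10,
               "UTR5": 0.05, "nc_exon": 0.08, "nc_intron": 0.07}
    used_hosts: set[tuple[int, int]] = set()
    remaining = config.n_planted_clusters - len(planted)
    by_cat: dict[str, list] = {}
    for cat, iv, gid in hosts:
        by_cat.setdefault(cat, []).append((iv, gid))
    for lst in by_cat.values():
        rng.shuffle(lst)
    cats = list(weights)
    probs = np.array([weights[c] for c in cats])
    probs /= probs.sum()
    attempts = 0
    while remaining > 0 and attempts < 10 * config.n_planted_clusters:
        attempts += 1
        cat = cats[int(rng.choice(len(cats), p=probs))]
        pool = by_cat.get(cat, [])
        pick = None
        for iv, gid in pool:
            if (iv.start, iv.end) not in used_hosts:
                pick = (iv, gid)
                break
        if pick is None:
            continue
        iv, gid = pick
        placed = _place_within(iv, width, rng)
        if placed is None:
            used_hosts.add((iv.start, iv.end))
            continue
        used_hosts.add((iv.start, iv.end))
        planted.append(PlantedCluster(placed, cat, gid))
        remaining -= 1
    gt.planted_clusters = planted


def _plant_sites(config, rng, gt: GroundTruth) -> None:
    """Designate top-abundance miRNAs with perfect complements inside
    cluster-linked intronic clusters."""
    linked = [
        c for c in gt.planted_clusters
        if c.category == "pc_intron"
        and any(
            e.cluster_linked and e.gene_id == c.gene_id for e in gt.planted_events
        )
    ]
    ranked = sorted(
        gt.mirna_true_abundance, key=lambda m: -gt.mirna_true_abundance[m]
    )
    top = ranked[: max(10, config.n_planted_sites)]
    for k, cluster in enumerate(linked[: config.n_planted_sites]):
        mid = top[k]
        cluster.site_mirna = mid
        cluster.site_start = -2  # placeholder; fixed in genome build


def _build_genome(config, rng, gt: GroundTruth, catalog) -> str:
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=config.genome_length)
    genome = bytearray(b"".join(arr))
    for cluster in gt.planted_clusters:
        if not cluster.site_mirna:
            continue
        mature = catalog[cluster.site_mirna].replace("U", "T")
        if cluster.interval.strand == "+":
            seg = _revcomp_dna(mature)
        else:
            seg = mature
        width = cluster.interval.length
        if len(seg) > width:
            continue
        offset = (width - len(seg)) // 2
        start = cluster.interval.start + offset
        genome[start: start + len(seg)] = seg.encode()
        cluster.site_start = start
    return genome.decode()


def generate_annotation(config: SimulationConfig) -> SimulatedGenome:
    """Build the toy annotation, genome sequence and planted-truth skeleton.

    Raises a sizing error when the configured gene structures cannot fit on
    the toy chromosome.
    """
    rng = config.rng(1)
    catalog, family_map, abundance = _mature_mirnas(config, rng)
    gt = GroundTruth(mirna_true_abundance=abundance)
    records = _layout_genes(config, rng)
    model = AnnotationModel()
    for rec in records:
        _install_gene(model, rec, config, rng, gt.planted_events)
    _derive_features(model, [])
    _plant_clusters(config, rng, model, records, gt)
    _plant_sites(config, rng, gt)
    # knockout response structure: linked events share the full affected set,
    # unlinked events respond in one knockout only
    pool = [c for c in config.single_ko_pool if c in config.conditions]
    for ev in gt.planted_events:
        if not ev.cluster_linked and pool:
            ev.affected_conditions = (pool[int(rng.integers(0, len(pool)))],)
    genome = _build_genome(config, rng, gt, catalog)
    strand_map = np.full(config.genome_length, 2, dtype=np.int8)
    for rec in records:
        s, e = rec.exons[0][0], rec.exons[-1][1]
        strand_map[s:e] = 0 if rec.strand == "+" else 1
    return SimulatedGenome(
        config=config, annotation=model, genome=genome,
        mirna_catalog=catalog, family_map=family_map,
        ground_truth=gt, strand_of_position=strand_map,
    )


# ---------------------------------------------------------------------------
# Stage 2: eCLIP reads
# ---------------------------------------------------------------------------

def simulate_eclip(sim: SimulatedGenome) -> dict[str, list[GenomicInterval]]:
    """Poisson background reads for all five samples plus planted IP signal.

    Background is uniform at ``background_density`` reads/kb in every sample;
    inside planted clusters the wild-type IP replicates receive additional
    reads so that their in-cluster density is ``planted_enrichment`` times the
    background. Read strand follows the host gene's strand (random in
    intergenic space).
    """
    config = sim.config
    rng = config.rng(2)
    L = config.read_length
    g_len = config.genome_length
    reads: dict[str, list[GenomicInterval]] = {}
    for sample in ECLIP_SAMPLES:
        n_bg = rng.poisson(config.background_density * g_len / 1000.0)
        starts = rng.integers(0, max(g_len - L, 1), size=n_bg)
        strand_codes = sim.strand_of_position[starts].copy()
        random_mask = strand_codes == 2
        strand_codes[random_mask] = rng.integers(0, 2, size=int(random_mask.sum()))
        sample_reads = [
            GenomicInterval(config.chrom, int(s), int(s) + L, "+" if c == 0 else "-")
            for s, c in zip(starts, strand_codes)
        ]
        if sample in ("ip_wt_rep1", "ip_wt_rep2") and config.planted_enrichment > 1:
            for cluster in sim.ground_truth.planted_clusters:
                iv = cluster.interval
                lam = (
                    (config.planted_enrichment - 1.0)
                    * config.background_density
                    * (iv.length + L - 1) / 1000.0
                )
                n_extra = rng.poisson(lam)
                lo = max(0, iv.start - L + 1)
                extra_starts = rng.integers(lo, iv.end, size=n_extra)
                sample_reads.extend(
                    GenomicInterval(
                        config.chrom, int(s), min(int(s) + L, g_len), iv.strand
                    )
                    for s in extra_starts
                )
        reads[sample] = sample_reads
    for cluster in sim.ground_truth.planted_clusters:
        cluster.enrichment = config.planted_enrichment
    return reads


# ---------------------------------------------------------------------------
# Stage 3: miRNA reads
# ---------------------------------------------------------------------------

def simulate_mirna_reads(sim: SimulatedGenome) -> dict[str, Counter]:
    """Nuclear and cytoplasmic miRNA read sets sharing one abundance vector.

    Reads are mature sequences (DNA alphabet, as sequenced cDNA) with at most
    one substitution planted per erroneous read at the configured per-base
    error rate. Returned as ``Counter`` objects (sequence -> multiplicity).
    """
    config = sim.config
    rng = config.rng(3)
    ids = list(sim.mirna_catalog)
    probs = np.array([sim.ground_truth.mirna_true_abundance[m] for m in ids])
    probs = probs / probs.sum()
    out: dict[str, Counter] = {}
    bases = "ACGT"
    for compartment in ("nucleus", "cytoplasm"):
        counts = rng.multinomial(config.mirna_read_depth, probs)
        pool: Counter = Counter()
        for mid, c in zip(ids, counts):
            if c == 0:
                continue
            seq = sim.mirna_catalog[mid].replace("U", "T")
            p_err = 1.0 - (1.0 - config.mirna_error_rate) ** len(seq)
            n_err = rng.binomial(c, p_err) if p_err > 0 else 0
            pool[seq] += c - n_err
            for _ in range(n_err):
                pos = int(rng.integers(0, len(seq)))
                alt = bases[int(rng.integers(0, 4))]
                while alt == seq[pos]:
                    alt = bases[int(rng.integers(0, 4))]
                pool[seq[:pos] + alt + seq[pos + 1:]] += 1
        out[compartment] = pool
    return out


# ---------------------------------------------------------------------------
# Stage 4: junction counts
# ---------------------------------------------------------------------------

def simulate_junction_counts(sim: SimulatedGenome) -> pd.DataFrame:
    """Binomial junction counts per condition and replicate.

    Inclusion-supporting junction reads are Binomial(depth, PSI) and
    exclusion-supporting reads Binomial(depth, 1 - PSI); PSI in affected
    conditions is the base PSI shifted by the planted (signed) delta. Event
    ids of planted events are filled into the ground truth.
    """
    config = sim.config
    rng = config.rng(4)
    events = _splicing.extract_events(sim.annotation)
    planted = {(e.gene_id, e.etype): e for e in sim.ground_truth.planted_events}
    depth = int(config.junction_depth)
    rows = []
    for ev in events:
        base = float(rng.uniform(*config.base_psi))
        pe = planted.get((ev.gene_id, ev.etype))
        if pe is not None:
            pe.event_id = ev.event_id
        for cond in config.conditions:
            psi = base
            if pe is not None and cond in pe.affected_conditions:
                psi = float(np.clip(base + pe.delta_psi, 0.02, 0.98))
            for rep in range(1, config.n_replicates + 1):
                sample = f"{cond}_rep{rep}"
                for role, jid in ev.junctions.items():
                    p = psi if role in _splicing.INCLUSION_ROLES[ev.etype] else 1 - psi
                    count = int(rng.binomial(depth, p)) if depth > 0 else 0
                    rows.append(
                        {"event_id": ev.event_id, "junction_id": jid,
                         "sample": sample, "count": count}
                    )
    return pd.DataFrame(rows, columns=["event_id", "junction_id", "sample", "count"])


# ---------------------------------------------------------------------------
# Orchestration and file output
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    sim: SimulatedGenome
    eclip_reads: dict[str, list[GenomicInterval]]
    mirna_reads: dict[str, Counter]
    junction_counts: pd.DataFrame

    @property
    def config(self) -> SimulationConfig:
        return self.sim.config

    @property
    def ground_truth(self) -> GroundTruth:
        return self.sim.ground_truth


def simulate_all(config: SimulationConfig, outdir=None) -> SimulatedData:
    """Run every simulation stage; optionally write all standard-format files."""
    sim = generate_annotation(config)
    eclip = simulate_eclip(sim)
    mirna_reads = simulate_mirna_reads(sim)
    junctions = simulate_junction_counts(sim)
    data = SimulatedData(sim, eclip, mirna_reads, junctions)
    if outdir is not None:
        write_outputs(data, outdir)
    return data


def write_outputs(data: SimulatedData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = data.config
    write_fasta(outdir / "genome.fa", {config.chrom: data.sim.genome})
    write_gtf(outdir / "annotation.gtf", data.sim.annotation)
    for sample, reads in data.eclip_reads.items():
        write_bed(outdir / f"{sample}.bed", reads)
    write_fasta(outdir / "mirnas.fa", data.sim.mirna_catalog)
    fam = pd.DataFrame(
        {"mirna_id": list(data.sim.family_map),
         "family": list(data.sim.family_map.values())}
    )
    fam.to_csv(outdir / "mirna_families.tsv", sep="\t", index=False)
    for compartment, pool in data.mirna_reads.items():
        with open(outdir / f"mirna_reads_{compartment}.fa", "w") as fh:
            i = 0
            for seq, mult in sorted(pool.items()):
                for _ in range(mult):
                    fh.write(f">read_{i}\n{seq}\n")
                    i += 1
    data.junction_counts.to_csv(outdir / "junction_counts.tsv", sep="\t", index=False)
    data.ground_truth.to_json(outdir / "ground_truth.json")
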