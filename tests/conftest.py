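import pytest

from nucago.intervals import GenomicInterval
from nucago.io import AnnotationModel, Gene, Transcript, _derive_features


def build_annotation(genes):
    """Assemble an AnnotationModel from compact specs.

    ``genes``: list of dicts with keys gene_id, gene_type, strand and
    transcripts = list of dicts with exons = [(start, end), ...] and optional
    cds = (lo, hi) genomic window intersected with the exons.
    """
    model = AnnotationModel()
    for g in genes:
        chrom = g.get("chrom", "chrT")
        strand = g["strand"]
        all_exons = [iv for t in g["transcripts"] for iv in t["exons"]]
        span = GenomicInterval(
            chrom, min(s for s, _e in all_exons), max(e for _s, e in all_exons), strand
        )
        model.genes[g["gene_id"]] = Gene(g["gene_id"], g["gene_type"], span)
        for k, t in enumerate(g["transcripts"]):
            tx = Transcript(f"{g['gene_id']}.t{k + 1}", g["gene_id"], strand)
            tx.exons = [GenomicInterval(chrom, s, e, strand) for s, e in t["exons"]]
            if "cds" in t:
                lo, hi = t["cds"]
                for ex in tx.exons:
                    s, e = max(ex.start, lo), min(ex.end, hi)
                    if s < e:
                        tx.cds.append(GenomicInterval(chrom, s, e, strand))
            model.transcripts[tx.transcript_id] = tx
    _derive_features(model, [])
    return model


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across tests."""
    from nucago.simulate import SimulationConfig, generate_annotation

    config = SimulationConfig(
        seed=11,
        genome_length=600_000,
        n_genes=36,
        n_planted_clusters=24,
        n_mirnas=60,
        n_splicing_events_per_type=3,
        n_cluster_linked_events=3,
        n_planted_sites=2,
        mirna_read_depth=20_000,
    )
    return generate_annotation(config)


@pytest.fixture(scope="session")
def pc_gene_annotation():
    """One protein-coding gene (+ strand) with CDS, UTRs and introns, and one
    noncoding miRNA gene on the - strand."""
    return build_annotation(
        [
            {
                "gene_id": "PC1",
                "gene_type": "protein_coding",
                "strand": "+",
                "transcripts": [
                    {
                        "exons": [(100, 300), (500, 700), (900, 1100)],
                        "cds": (200, 1000),
                    }
                ],
            },
            {
                "gene_id": "MIR1",
                "gene_type": "miRNA",
                "strand": "-",
                "transcripts": [{"exons": [(2000, 2080)]}],
            },
            {
                "gene_id": "NC1",
                "gene_type": "lincRNA",
                "strand": "+",
                "transcripts": [{"exons": [(3000, 3200), (3500, 3700)]}],
            },
        ]
    )
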