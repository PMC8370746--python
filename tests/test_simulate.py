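"""Synthetic-data generator: determinism, planted structure, calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucago.clusters import ReadSet
from nucago.io import CATEGORY_PRIORITY, read_gtf
from nucago.mirna import match_reads_to_mirnas
from nucago.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    simulate_all,
    simulate_eclip,
    simulate_junction_counts,
    simulate_mirna_reads,
)
from nucago.splicing import INCLUSION_ROLES, attach_counts, extract_events, compute_psi


class TestConfigValidation:
    def test_delta_psi_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(planted_delta_psi=1.5)

    def test_enrichment_below_null_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(planted_enrichment=0.5)

    def test_oversized_genes_raise_sizing_error(self):
        cfg = SimulationConfig(genome_length=20_000, n_genes=40)
        with pytest.raises(ValueError, match="fit"):
            generate_annotation(cfg)


class TestAnnotationGeneration:
    def test_twenty_genes_cover_every_category(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genes=20, genome_length=400_000)
        sim = generate_annotation(cfg)
        simulate_all_cats = {f.category for f in sim.annotation.features}
        assert simulate_all_cats == set(CATEGORY_PRIORITY) - {"intergenic"}
        assert len(sim.annotation.genes) == 20

    def test_zero_genes_is_empty_not_error(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genes=0, n_planted_clusters=0,
                               n_splicing_events_per_type=0,
                               n_cluster_linked_events=0, n_planted_sites=0,
                               genome_length=50_000)
        out = simulate_all(cfg, tmp_path)
        assert (tmp_path / "annotation.gtf").read_text() == ""

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = dict(seed=5, n_genes=14, genome_length=300_000,
                   n_planted_clusters=8, n_mirnas=20, mirna_read_depth=4000,
                   n_splicing_events_per_type=1, n_cluster_linked_events=1,
                   n_planted_sites=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_all(SimulationConfig(**cfg), d1)
        simulate_all(SimulationConfig(**cfg), d2)
        for name in ("genome.fa", "annotation.gtf", "ip_wt_rep1.bed",
                     "junction_counts.tsv", "ground_truth.json",
                     "mirna_reads_nucleus.fa"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_planted_clusters_sit_inside_single_features(self, small_sim):
        for pc in small_sim.ground_truth.planted_clusters:
            hosts = [
                f for f in small_sim.annotation.features
                if f.category == pc.category
                and f.interval.strand == pc.interval.strand
                and f.interval.contains(pc.interval)
            ]
            assert hosts, pc

    def test_cluster_linked_events_have_intronic_cluster_in_gene(self, small_sim):
        gt = small_sim.ground_truth
        linked = [e for e in gt.planted_events if e.cluster_linked]
        assert linked
        for ev in linked:
            assert any(
                c.gene_id == ev.gene_id and c.category == "pc_intron"
                for c in gt.planted_clusters
            )

    def test_ground_truth_round_trips_through_json(self, small_sim, tmp_path):
        p = tmp_path / "gt.json"
        small_sim.ground_truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back == small_sim.ground_truth

    def test_written_gtf_reparses_to_same_features(self, tmp_path, small_sim):
        from nucago.io import write_gtf

        p = tmp_path / "ann.gtf"
        write_gtf(p, small_sim.annotation)
        model = read_gtf(p)
        want = {
            (f.interval.start, f.interval.end, f.category) for f in small_sim.annotation.features
        }
        got = {(f.interval.start, f.interval.end, f.category) for f in model.features}
        assert got == want


class TestEclipSimulation:
    def test_in_cluster_ip_density_matches_planted_enrichment(self):
        """Across >= 200 planted clusters the mean IP-WT in-cluster read count
        is the planted multiple of the mean input count.

        Only gene-interior clusters (introns, CDS exons) are tallied: at
        gene-edge loci the strand-aware count window reaches intergenic
        space, where read strands are random, which deflates both samples'
        counts by the same geometry but the planted IP reads are all sense —
        the density calibration statement applies to the interior case.
        """
        interior = {"pc_intron", "CDS_exon", "nc_intron"}
        ip_sum, input_sum = 0.0, 0.0
        n_clusters = 0
        for seed in (101, 102, 103, 104, 105, 106):
            cfg = SimulationConfig(
                seed=seed, genome_length=1_000_000, n_genes=60,
                n_planted_clusters=50, planted_mirna_fraction=0.0,
                n_mirnas=30, mirna_read_depth=1000,
                n_splicing_events_per_type=2, n_cluster_linked_events=2,
                n_planted_sites=0,
            )
            sim = generate_annotation(cfg)
            reads = simulate_eclip(sim)
            ip = ReadSet(reads["ip_wt_rep1"])
            inp = ReadSet(reads["input_wt"])
            for pc in sim.ground_truth.planted_clusters:
                if pc.category not in interior:
                    continue
                ip_sum += ip.count_overlapping(pc.interval)
                input_sum += inp.count_overlapping(pc.interval)
                n_clusters += 1
        assert n_clusters >= 200
        ratio = ip_sum / input_sum
        assert ratio == pytest.approx(8.0, rel=0.08)

    def test_knockout_samples_receive_no_signal(self, small_sim):
        reads = simulate_eclip(small_sim)
        ko = ReadSet(reads["ip_ko"])
        inp = ReadSet(reads["input_wt"])
        ko_counts = sum(
            ko.count_overlapping(c.interval)
            for c in small_sim.ground_truth.planted_clusters
        )
        inp_counts = sum(
            inp.count_overlapping(c.interval)
            for c in small_sim.ground_truth.planted_clusters
        )
        # both are pure background: two-sample rate test should be null
        p = stats.poisson_means_test(ko_counts, ko.total, inp_counts, inp.total).pvalue
        assert p > 0.01

    def test_read_strand_follows_host_feature(self, small_sim):
        reads = simulate_eclip(small_sim)
        genes = list(small_sim.annotation.genes.values())
        by_strand = {}
        for r in reads["input_wt"]:
            by_strand.setdefault((r.start, r.strand), None)
        mismatches = 0
        checked = 0
        for gene in genes[:12]:
            for r in reads["input_wt"]:
                if gene.interval.start <= r.start < gene.interval.end:
                    checked += 1
                    mismatches += r.strand != gene.interval.strand
        assert checked > 0 and mismatches == 0


class TestMirnaSimulation:
    def test_zero_error_rate_reads_match_exactly(self):
        cfg = SimulationConfig(seed=3, n_genes=6, genome_length=200_000,
                               n_mirnas=25, mirna_error_rate=0.0,
                               mirna_read_depth=5000, n_planted_clusters=4,
                               n_splicing_events_per_type=1,
                               n_cluster_linked_events=0, n_planted_sites=0)
        sim = generate_annotation(cfg)
        pools = simulate_mirna_reads(sim)
        counts, unassigned = match_reads_to_mirnas(
            pools["nucleus"], sim.mirna_catalog, max_mismatches=0
        )
        assert unassigned == 0

    def test_single_mirna_gets_every_read(self):
        cfg = SimulationConfig(seed=3, n_genes=4, genome_length=200_000,
                               n_mirnas=1, mirna_read_depth=2000,
                               n_planted_clusters=2,
                               n_splicing_events_per_type=1,
                               n_cluster_linked_events=0, n_planted_sites=0)
        sim = generate_annotation(cfg)
        pools = simulate_mirna_reads(sim)
        counts, unassigned = match_reads_to_mirnas(pools["nucleus"], sim.mirna_catalog)
        assert counts.iloc[0] + unassigned == 2000
        assert counts.iloc[0] >= 1990  # only multi-error reads can drop out

    def test_rank_correlation_with_truth_at_depth_100k(self):
        cfg = SimulationConfig(seed=4, n_genes=6, genome_length=200_000,
                               n_mirnas=100, mirna_read_depth=100_000,
                               n_planted_clusters=4,
                               n_splicing_events_per_type=1,
                               n_cluster_linked_events=0, n_planted_sites=0)
        sim = generate_annotation(cfg)
        pools = simulate_mirna_reads(sim)
        counts, _ = match_reads_to_mirnas(pools["nucleus"], sim.mirna_catalog)
        truth = sim.ground_truth.mirna_true_abundance
        rho, _p = stats.spearmanr(
            [truth[m] for m in counts.index], counts.values
        )
        assert rho > 0.95


class TestJunctionSimulation:
    def test_recovered_delta_psi_close_to_planted(self, small_sim):
        table = simulate_junction_counts(small_sim)
        events = extract_events(small_sim.annotation)
        attach_counts(events, table)
        planted = {e.event_id: e for e in small_sim.ground_truth.planted_events}
        errors = []
        for ev in events:
            pe = planted.get(ev.event_id)
            if pe is None or not pe.affected_conditions:
                continue
            cond = pe.affected_conditions[0]
            psis = {}
            for who in ("WT", cond):
                vals = [
                    compute_psi(ev, ev.counts[s])
                    for s in ev.counts
                    if s.startswith(who + "_")
                ]
                psis[who] = float(np.nanmean(vals))
            errors.append((psis[cond] - psis["WT"]) - pe.delta_psi)
        assert errors
        assert abs(float(np.mean(errors))) < 0.05

    def test_zero_depth_gives_missing_psi(self):
        cfg = SimulationConfig(seed=3, n_genes=12, genome_length=300_000,
                               junction_depth=0, n_mirnas=5,
                               mirna_read_depth=100, n_planted_clusters=4,
                               n_splicing_events_per_type=1,
                               n_cluster_linked_events=1, n_planted_sites=0)
        sim = generate_annotation(cfg)
        table = simulate_junction_counts(sim)
        assert (table["count"] == 0).all()
        events = extract_events(sim.annotation)
        attach_counts(events, table)
        for ev in events:
            for counts in ev.counts.values():
                assert math.isnan(compute_psi(ev, counts))

    def test_every_event_has_all_junction_roles(self, small_sim):
        table = simulate_junction_counts(small_sim)
        events = extract_events(small_sim.annotation)
        by_event = table.groupby("event_id")["junction_id"].nunique()
        for ev in events:
            assert by_event[ev.event_id] == len(set(ev.junctions.values()))
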