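"""End-to-end orchestration: simulate -> clusters -> miRNA -> splicing ->
integration -> site scan, with a machine-readable report.

Stages communicate via files under the run directory so each stage is
independently inspectable and replaceable; the report embeds the exact
configuration and checksums of every file it derives from.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import integrate as _integrate
from . import mirna as _mirna
from . import simulate as _simulate
from . import sitescan as _sitescan
from . import splicing as _splicing
from .clusters import ClusterParams, clusters_to_frame, run_cluster_pipeline, rank_and_partition
from .io import read_bed, read_fasta, read_gtf

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, config_hash: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (config {config_hash}): {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully serialisable configuration of an end-to-end run."""

    outdir: str = "nucago_run"
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    # paths used when simulate=False
    gtf: str | None = None
    genome_fasta: str | None = None
    ip_rep1: str | None = None
    ip_rep2: str | None = None
    input_wt: str | None = None
    ip_ko: str | None = None
    mirna_fasta: str | None = None
    family_tsv: str | None = None
    junction_tsv: str | None = None
    external_sites_bed: str | None = None
    # stage parameters
    cluster_params: dict = field(default_factory=dict)
    n_top_clusters: int = 200
    n_top_mirnas: int = 100
    wt_condition: str = "WT"
    ko_conditions: tuple[str, ...] = ()
    intersection_pair: tuple[str, str] = ("AGO12-KO", "AGO123-KO")
    correlation_pair: tuple[str, str] = ("AGO123-KO", "DROSHA-KO")
    splice_alpha: float = 0.05
    splice_min_dpsi: float = 0.1
    mfe_threshold: float = -14.0
    scan_top_n: int = 100
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            ("&".join(k) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(obj, dict)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (pd.Series,)):
        return {str(k): float(v) for k, v in obj.items()}
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the report bundle."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"config": config.to_dict(), "config_hash": chash, "stages": {}}
    timings = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except FileNotFoundError:
                raise  # missing input: caller maps this to an input error
            except Exception as exc:  # abort with stage name + config hash
                raise StageError(name, chash, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", name, timings[name])
            return result
        return deco

    # ----- inputs -------------------------------------------------------
    ground_truth = None
    if config.simulate:
        def _sim():
            sim_cfg = _simulate.SimulationConfig(
                seed=config.seed, **config.sim_overrides
            )
            return _simulate.simulate_all(sim_cfg, outdir / "sim")
        data = stage("simulate")(_sim)
        annotation = data.sim.annotation
        genome = {data.config.chrom: data.sim.genome}
        reads = data.eclip_reads
        mirna_catalog = data.sim.mirna_catalog
        family_map = data.sim.family_map
        mirna_reads = data.mirna_reads
        junction_table = data.junction_counts
        genome_length = data.config.genome_length
        ground_truth = data.ground_truth
        conditions = [c for c in data.config.conditions if c != config.wt_condition]
    else:
        def _load():
            if config.gtf is None or not Path(config.gtf).exists():
                raise FileNotFoundError(
                    f"annotation GTF not found: {config.gtf!r} (or pass --simulate)"
                )
            annotation = read_gtf(config.gtf)
            genome = read_fasta(config.genome_fasta) if config.genome_fasta else {}
            reads = {
                "ip_wt_rep1": read_bed(config.ip_rep1),
                "ip_wt_rep2": read_bed(config.ip_rep2),
                "input_wt": read_bed(config.input_wt),
                "ip_ko": read_bed(config.ip_ko),
            }
            mirna_catalog = dict(read_fasta(config.mirna_fasta)) if config.mirna_fasta else {}
            family_map = {}
            if config.family_tsv:
                fam = pd.read_csv(config.family_tsv, sep="\t")
                family_map = dict(zip(fam["mirna_id"], fam["family"]))
            junction_table = (
                pd.read_csv(config.junction_tsv, sep="\t") if config.junction_tsv else None
            )
            return annotation, genome, reads, mirna_catalog, family_map, junction_table
        (annotation, genome, reads, mirna_catalog, family_map, junction_table) = stage(
            "load_inputs"
        )(_load)
        mirna_reads = None
        genome_length = max(
            (g.interval.end for g in annotation.genes.values()), default=0
        ) + 10_000
        conditions = list(config.ko_conditions)

    # ----- clusters -----------------------------------------------------
    def _clusters():
        params = ClusterParams(**config.cluster_params)
        final = run_cluster_pipeline(
            reads["ip_wt_rep1"], reads["ip_wt_rep2"],
            reads["input_wt"], reads["ip_ko"],
            annotation, genome_length, params,
        )
        frame = clusters_to_frame(final)
        frame.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        return final
    final_clusters = stage("clusters")(_clusters)
    ranking = rank_and_partition(final_clusters, config.n_top_clusters)
    report["stages"]["clusters"] = {
        "n_final": len(final_clusters),
        "category_counts_all": _jsonable(
            dict(pd.Series([c.category for c in final_clusters]).value_counts())
        ) if final_clusters else {},
        "n_mirna_in_top": ranking["n_mirna_in_top"],
        "category_counts_top": _jsonable(ranking["category_counts"]),
        "category_counts_top_non_mirna": _jsonable(
            ranking["category_counts_non_mirna"]
        ),
    }

    # ----- miRNA profiles ----------------------------------------------
    profile = None
    if mirna_reads is not None and mirna_catalog:
        def _mirna_stage():
            counts = {}
            for compartment, pool in mirna_reads.items():
                vec, _un = _mirna.match_reads_to_mirnas(pool, mirna_catalog)
                counts[compartment] = vec
            raw = pd.DataFrame(counts)
            prof = _mirna.normalize_and_quantile(raw, family_map)
            prof.abundance.to_csv(outdir / "mirna_abundance.tsv", sep="\t")
            comparison = _mirna.compare_compartments(
                prof, "nucleus", prof, "cytoplasm", config.n_top_mirnas
            )
            return prof, comparison
        profile, comparison = stage("mirna")(_mirna_stage)
        report["stages"]["mirna"] = {
            "top_n": comparison["n_top"],
            "overlap": comparison["overlap"],
            "spearman_rho": comparison["spearman_rho"],
            "families_nucleus": _jsonable(comparison["families_a"]),
            "families_cytoplasm": _jsonable(comparison["families_b"]),
        }

    # ----- splicing -----------------------------------------------------
    per_condition_significant: dict[str, list] = {}
    events = []
    if junction_table is not None:
        def _splice():
            evs = _splicing.extract_events(annotation)
            _splicing.attach_counts(evs, junction_table)
            sample_conditions = {
                s: s.rsplit("_rep", 1)[0] for s in junction_table["sample"].unique()
            }
            sig = {}
            for ko in conditions:
                _splicing.differential_splicing(
                    evs, sample_conditions, config.wt_condition, ko,
                    alpha=config.splice_alpha, min_delta_psi=config.splice_min_dpsi,
                )
                sig[ko] = [copy.deepcopy(ev) for ev in evs if ev.significant]
            _splicing.events_to_frame(evs).to_csv(
                outdir / "events.tsv", sep="\t", index=False
            )
            return evs, sig
        events, per_condition_significant = stage("splice")(_splice)
        report["stages"]["splice"] = {
            "n_events": len(events),
            "n_significant_per_condition": {
                k: len(v) for k, v in per_condition_significant.items()
            },
            "per_type_counts": _jsonable(
                dict(pd.Series([e.etype for e in events]).value_counts())
            ) if events else {},
        }

    # ----- integration --------------------------------------------------
    candidates = []
    if per_condition_significant and len(per_condition_significant) >= 2:
        def _integration():
            venn = _integrate.shared_events(per_condition_significant)
            pair = config.intersection_pair
            shared = None
            if all(p in per_condition_significant for p in pair):
                shared = _integrate.intersection_candidates(
                    per_condition_significant, pair
                )
                shared_keys = set(shared["lost"]) | set(shared["gained"])
                pool = [
                    ev for ev in per_condition_significant[pair[0]]
                    if ev.event_id in shared_keys
                ]
            else:
                pool = []
            cands = _integrate.associate_events_with_clusters(pool, final_clusters)
            corr = None
            cpair = config.correlation_pair
            if all(p in per_condition_significant for p in cpair):
                ids_a = {
                    ev.event_id: ev for ev in per_condition_significant[cpair[0]]
                }
                paired = [
                    (ids_a[ev.event_id], ev)
                    for ev in per_condition_significant[cpair[1]]
                    if ev.event_id in ids_a
                ]
                if len(paired) >= 3:
                    ra = [
                        _integrate.inclusion_exclusion_ratio(a.psi[cpair[0]])
                        for a, _b in paired
                    ]
                    rb = [
                        _integrate.inclusion_exclusion_ratio(b.psi[cpair[1]])
                        for _a, b in paired
                    ]
                    corr = _integrate.correlate_inclusion_ratios(ra, rb)
            rows = [
                {
                    "event_id": c.event.event_id,
                    "type": c.event.etype,
                    "gene_id": c.event.gene_id,
                    "direction": c.event.direction,
                    "n_linked_clusters": len(c.linked_clusters),
                    "linked_clusters": ";".join(
                        str(i) for i, _d in c.linked_clusters
                    ),
                }
                for c in cands
            ]
            pd.DataFrame(
                rows, columns=["event_id", "type", "gene_id", "direction",
                               "n_linked_clusters", "linked_clusters"]
            ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            return venn, shared, cands, corr
        venn, shared, candidates, corr = stage("integrate")(_integration)
        report["stages"]["integrate"] = {
            "venn": _jsonable(venn["region_counts"]),
            "union_size": venn["union_size"],
            "intersection_pair": list(config.intersection_pair),
            "shared_by_direction": _jsonable(shared) if shared else None,
            "n_candidates": len(candidates),
            "correlation": _jsonable(corr) if corr else None,
        }

    # ----- external binding-site proximity ------------------------------
    if config.external_sites_bed and final_clusters:
        def _proximity():
            sites = read_bed(config.external_sites_bed)
            classes = _integrate.rbp_proximity(final_clusters, sites)
            return dict(pd.Series(classes).value_counts())
        report["stages"]["rbp_proximity"] = _jsonable(stage("rbp_proximity")(_proximity))

    # ----- site scan ----------------------------------------------------
    if candidates and profile is not None and genome:
        def _scan():
            ranked = profile.ranking("nucleus")
            chrom_seq = next(iter(genome.values()))
            hits_rows = []
            seen = set()
            for cand in candidates:
                for idx, _dist in cand.linked_clusters:
                    if idx in seen:
                        continue
                    seen.add(idx)
                    cl = final_clusters[idx]
                    seq = chrom_seq[cl.interval.start: cl.interval.end]
                    if cl.interval.strand == "-":
                        seq = _simulate._revcomp_dna(seq)
                    hits = _sitescan.scan_cluster(
                        seq, mirna_catalog, ranked,
                        mfe_threshold=config.mfe_threshold,
                        top_n=config.scan_top_n,
                    )
                    for h in hits:
                        hits_rows.append(
                            {
                                "cluster_index": idx,
                                "chrom": cl.interval.chrom,
                                "cluster_start": cl.interval.start,
                                "cluster_end": cl.interval.end,
                                "strand": cl.interval.strand,
                                "mirna_id": h.mirna_id,
                                "rank": h.rank,
                                "site_start": h.start,
                                "site_end": h.end,
                                "mfe": h.mfe,
                                "seed_matched": h.seed_matched,
                                "pairing": h.pairing,
                            }
                        )
            frame = pd.DataFrame(
                hits_rows,
                columns=["cluster_index", "chrom", "cluster_start", "cluster_end",
                         "strand", "mirna_id", "rank", "site_start", "site_end",
                         "mfe", "seed_matched", "pairing"],
            )
            frame.to_csv(outdir / "site_hits.tsv", sep="\t", index=False)
            return frame
        hits_frame = stage("scan_sites")(_scan)
        report["stages"]["scan_sites"] = {
            "n_hits": int(len(hits_frame)),
            "n_mirnas_with_hits": int(hits_frame["mirna_id"].nunique())
            if len(hits_frame) else 0,
        }

    # ----- ground-truth confusion (simulation only) ---------------------
    if ground_truth is not None:
        from .evaluate import cluster_confusion, candidate_recovery

        confusion = cluster_confusion(final_clusters, ground_truth)
        report["stages"]["ground_truth"] = _jsonable(confusion)
        if candidates:
            report["stages"]["ground_truth"]["candidate_recovery"] = _jsonable(
                candidate_recovery(candidates, ground_truth, config.intersection_pair)
            )

    logger.info("stage timings (s): %s", timings)  # kept out of the report so
    # that repeated runs with the same seed produce byte-identical reports
    report["file_checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
    return report
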