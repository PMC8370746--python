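"""Scoring of pipeline output against simulated ground truth."""

from __future__ import annotations

from .clusters import Cluster
from .simulate import GroundTruth


def cluster_confusion(final_clusters: list[Cluster], truth: GroundTruth) -> dict:
    """Recall and false-discovery proportion of final clusters vs planted ones.

    A planted cluster counts as recovered when at least one final cluster
    overlaps it by >= 1 nt on the same strand; a final cluster not overlapping
    any planted cluster is a false discovery.
    """
    planted = [c.interval for c in truth.planted_clusters]
    recovered = 0
    for p in planted:
        if any(
            p.same_strand(f.interval) and p.intersection_length(f.interval) > 0
            for f in final_clusters
        ):
            recovered += 1
    false = 0
    for f in final_clusters:
        if not any(
            p.same_strand(f.interval) and p.intersection_length(f.interval) > 0
            for p in planted
        ):
            false += 1
    n_planted = len(planted)
    n_final = len(final_clusters)
    return {
        "n_planted": n_planted,
        "n_final": n_final,
        "n_recovered": recovered,
        "n_false": false,
        "recall": recovered / n_planted if n_planted else float("nan"),
        "fdp": false / n_final if n_final else 0.0,
    }


def candidate_recovery(candidates, truth: GroundTruth, condition_pair) -> dict:
    """Recovery of planted cluster-linked events shared between two conditions."""
    wanted = {
        e.event_id
        for e in truth.planted_events
        if e.cluster_linked
        and all(c in e.affected_conditions for c in condition_pair)
        and e.event_id
    }
    got = {c.event.event_id for c in candidates}
    recovered = wanted & got
    extras = got - wanted
    return {
        "k_planted": len(wanted),
        "n_candidates": len(got),
        "n_recovered": len(recovered),
        "n_extras": len(extras),
        "recall": len(recovered) / len(wanted) if wanted else float("nan"),
        "extra_rate": len(extras) / len(got) if got else 0.0,
    }


def planted_site_recovery(final_clusters, hits_frame, truth: GroundTruth) -> dict:
    """Fraction of planted miRNA-complementary sites reported by the scan.

    A planted site is recovered when some reported hit names its miRNA on a
    final cluster overlapping the planted cluster that carries the site.
    """
    planted_sites = [
        c for c in truth.planted_clusters if c.site_mirna and c.site_start >= 0
    ]
    n_recovered = 0
    for site in planted_sites:
        ok = False
        for _idx, row in hits_frame.iterrows():
            if row["mirna_id"] != site.site_mirna:
                continue
            if row["strand"] != site.interval.strand:
                continue
            if (
                row["cluster_start"] < site.interval.end
                and row["cluster_end"] > site.interval.start
            ):
                ok = True
                break
        n_recovered += ok
    return {
        "n_planted_sites": len(planted_sites),
        "n_recovered": n_recovered,
        "recovery": n_recovered / len(planted_sites) if planted_sites else float("nan"),
    }
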