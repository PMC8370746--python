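"""Integration of cluster and splicing results across knockout lines.

Links differential splicing events to intronic AGO2 clusters in the same
gene, intersects significant events across knockout conditions (Venn logic),
correlates inclusion/exclusion ratios between conditions, and classifies
cluster proximity to external protein-binding sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clusters import Cluster
from .intervals import GenomicInterval
from .splicing import SplicingEvent

INTRONIC = ("pc_intron", "nc_intron")


@dataclass
class CandidateEvent:
    """A differential splicing event with its linked intronic clusters."""

    event: SplicingEvent
    linked_clusters: list[tuple[int, int]] = field(default_factory=list)
    # (cluster index, distance in nt from cluster to the event's alt region)
    shared_in: set[str] = field(default_factory=set)


def associate_events_with_clusters(
    events: list[SplicingEvent],
    clusters: list[Cluster],
    max_distance: int | None = None,
    mode: str = "same_gene",
) -> list[CandidateEvent]:
    """Link events to same-gene intronic clusters.

    A cluster links to an event when its category is intronic and its gene id
    matches the event's. ``mode="same_gene"`` (default) accepts any position
    within the gene; ``mode="flanking"`` restricts to clusters within
    ``max_distance`` nt of the event's alternative region (default 1500 nt,
    approximately one intron, standing in for the flanking introns). An
    explicit ``max_distance`` applies in either mode. Only events carrying at
    least one link are returned.
    """
    if mode not in ("same_gene", "flanking"):
        raise ValueError(f"unknown association mode {mode!r}")
    if mode == "flanking" and max_distance is None:
        max_distance = 1500
    out = []
    for ev in events:
        links: list[tuple[int, int]] = []
        for idx, cl in enumerate(clusters):
            if cl.category not in INTRONIC:
                continue
            if not cl.gene_id or cl.gene_id != ev.gene_id:
                continue
            if cl.interval.strand != ev.strand:
                continue
            dist = cl.interval.gap_to(ev.alt_region)
            if max_distance is not None and dist > max_distance:
                continue
            links.append((idx, dist))
        if links:
            out.append(CandidateEvent(event=ev, linked_clusters=sorted(links)))
    return out


def shared_events(
    per_condition: dict[str, list[SplicingEvent]],
) -> dict:
    """Venn partition of significant events across conditions.

    Events are keyed by (event_id, direction). Returns every Venn region
    count (keyed by the sorted tuple of member conditions) plus the event
    keys of each region; region counts sum to the size of the union.
    """
    if len(per_condition) < 2:
        raise ValueError("need at least two conditions")
    keysets = {
        cond: {(ev.event_id, ev.direction) for ev in evs}
        for cond, evs in per_condition.items()
    }
    conds = sorted(keysets)
    universe = set().union(*keysets.values())
    regions: dict[tuple[str, ...], list] = {}
    for key in universe:
        member = tuple(c for c in conds if key in keysets[c])
        regions.setdefault(member, []).append(key)
    return {
        "conditions": conds,
        "region_counts": {m: len(v) for m, v in sorted(regions.items())},
        "regions": {m: sorted(v) for m, v in sorted(regions.items())},
        "union_size": len(universe),
    }


def intersection_candidates(
    per_condition: dict[str, list[SplicingEvent]],
    condition_pair: tuple[str, str],
) -> dict[str, list]:
    """Events significant (same direction) in both named conditions,
    split by direction (lost = exon skipping increased, gained = inclusion)."""
    a, b = condition_pair
    keys_a = {(ev.event_id, ev.direction): ev for ev in per_condition[a]}
    keys_b = {(ev.event_id, ev.direction) for ev in per_condition[b]}
    shared = [ev for key, ev in keys_a.items() if key in keys_b]
    return {
        "lost": sorted(ev.event_id for ev in shared if ev.direction == "lost"),
        "gained": sorted(ev.event_id for ev in shared if ev.direction == "gained"),
    }


def inclusion_exclusion_ratio(psi: float, cap: float = 50.0) -> float:
    """PSI/(1-PSI), clipped at ``cap`` as PSI approaches 1."""
    if math.isnan(psi):
        return float("nan")
    if psi >= 1.0:
        return cap
    return min(psi / (1.0 - psi), cap)


def correlate_inclusion_ratios(
    ratios_a: list[float], ratios_b: list[float], conf: float = 0.95
) -> dict:
    """Pearson correlation and OLS fit between paired inclusion ratios.

    Returns r, the two-sided p from the t-distribution with n-2 df, the OLS
    slope/intercept, and a confidence band (half-widths at each x). Requires
    at least three pairs.
    """
    x = np.asarray(ratios_a, dtype=float)
    y = np.asarray(ratios_b, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired ratios")
    r, p = stats.pearsonr(x, y)
    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    band = pred.conf_int(alpha=1 - conf)
    return {
        "n": n,
        "r": float(r),
        "p": float(p),
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "conf_low": band[:, 0].tolist(),
        "conf_high": band[:, 1].tolist(),
    }


def rbp_proximity(
    clusters: list[Cluster],
    external_sites: list[GenomicInterval],
    near: int = 10,
    window: int = 200,
) -> list[str]:
    """Classify each cluster's proximity to the nearest same-strand site.

    Classes: ``overlap`` (>=1 shared base), ``<10nt`` (gap strictly below
    ``near``), ``<=200nt`` (gap at most ``window``), else ``none``. The gap
    counts bases strictly between the intervals.
    """
    out = []
    for cl in clusters:
        best_gap = None
        overlap = False
        for site in external_sites:
            if not cl.interval.same_strand(site):
                continue
            if cl.interval.intersection_length(site) > 0:
                overlap = True
                break
            gap = cl.interval.gap_to(site)
            if best_gap is None or gap < best_gap:
                best_gap = gap
        if overlap:
            out.append("overlap")
        elif best_gap is None:
            out.append("none")
        elif best_gap < near:
            out.append("<10nt")
        elif best_gap <= window:
            out.append("<=200nt")
        else:
            out.append("none")
    return out
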