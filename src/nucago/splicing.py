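"""Alternative-splicing quantification from junction counts.

Events of four types are extracted from the annotation by pairwise transcript
comparison: skipped exon (SE), mutually exclusive exons (MXE), alternative 5'
splice site (A5SS) and alternative 3' splice site (A3SS). PSI (percent
spliced in) is a proportion of inclusion-supporting junction reads; the two
inclusion junctions of an SE/MXE exon are averaged. Differential calls pool
replicate junction counts per condition and use a two-sided Fisher exact test
with Benjamini-Hochberg FDR across events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .io import AnnotationModel
from .clusters import fisher_exact_two_sided

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS")

# roles carrying inclusion-supporting vs exclusion-supporting junction reads
INCLUSION_ROLES = {
    "SE": ("inc_up", "inc_down"),
    "MXE": ("inc_up", "inc_down"),
    "A5SS": ("proximal",),
    "A3SS": ("proximal",),
}
EXCLUSION_ROLES = {
    "SE": ("skip",),
    "MXE": ("exc_up", "exc_down"),
    "A5SS": ("distal",),
    "A3SS": ("distal",),
}


def _jid(chrom: str, left_end: int, right_start: int, strand: str) -> str:
    return f"{chrom}:{left_end}-{right_start}:{strand}"


@dataclass
class SplicingEvent:
    event_id: str
    etype: str
    gene_id: str
    chrom: str
    strand: str
    alt_region: GenomicInterval
    junctions: dict[str, str]  # role -> junction id
    counts: dict[str, dict[str, float]] = field(default_factory=dict)  # sample -> role -> n
    psi: dict[str, float] = field(default_factory=dict)  # condition -> PSI
    delta_psi: float = float("nan")
    p_value: float = float("nan")
    fdr: float = float("nan")
    direction: str = ""
    significant: bool = False


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

def _exon_key(iv: GenomicInterval) -> tuple[int, int]:
    return (iv.start, iv.end)


def extract_events(annotation: AnnotationModel) -> list[SplicingEvent]:
    """Enumerate SE/MXE/A5SS/A3SS events from pairwise transcript comparison.

    Events are deduplicated by their junction coordinates; genes with a single
    transcript yield none.
    """
    events: dict[tuple, SplicingEvent] = {}
    for gene_id, gene in annotation.genes.items():
        txs = annotation.transcripts_of(gene_id)
        if len(txs) < 2:
            continue
        chains = [sorted(t.exons, key=lambda iv: iv.start) for t in txs]
        exon_sets = [set(map(_exon_key, ch)) for ch in chains]
        strand = gene.interval.strand
        chrom = gene.interval.chrom
        for a in range(len(chains)):
            for b in range(len(chains)):
                if a == b:
                    continue
                _find_se(events, chains[a], exon_sets[b], chains[b], gene_id, chrom, strand)
                if a < b:
                    _find_mxe(
                        events, chains[a], chains[b], exon_sets, gene_id, chrom, strand
                    )
                    _find_alt_ss(
                        events, chains[a], chains[b], gene_id, chrom, strand
                    )
    return sorted(events.values(), key=lambda e: (e.chrom, e.alt_region.start, e.event_id))


def _consecutive_in(chain: list[GenomicInterval], up, down) -> bool:
    keys = [_exon_key(e) for e in chain]
    ku, kd = _exon_key(up), _exon_key(down)
    for i in range(len(keys) - 1):
        if keys[i] == ku and keys[i + 1] == kd:
            return True
    return False


def _find_se(events, chain, other_set, other_chain, gene_id, chrom, strand):
    for i in range(1, len(chain) - 1):
        e, up, down = chain[i], chain[i - 1], chain[i + 1]
        if _exon_key(e) in other_set:
            continue
        if any(e.intersection_length(o) > 0 for o in other_chain):
            continue
        if not _consecutive_in(other_chain, up, down):
            continue
        junctions = {
            "inc_up": _jid(chrom, up.end, e.start, strand),
            "inc_down": _jid(chrom, e.end, down.start, strand),
            "skip": _jid(chrom, up.end, down.start, strand),
        }
        key = ("SE", tuple(sorted(junctions.values())))
        if key not in events:
            events[key] = SplicingEvent(
                event_id=f"SE:{chrom}:{e.start}-{e.end}:{strand}",
                etype="SE", gene_id=gene_id, chrom=chrom, strand=strand,
                alt_region=e, junctions=junctions,
            )


def _find_mxe(events, chain1, chain2, exon_sets, gene_id, chrom, strand):
    keys2 = [_exon_key(e) for e in chain2]
    for i in range(1, len(chain1) - 1):
        e = chain1[i]
        if _exon_key(e) in keys2:
            continue
        up, down = chain1[i - 1], chain1[i + 1]
        ku, kd = _exon_key(up), _exon_key(down)
        for j in range(1, len(chain2) - 1):
            f = chain2[j]
            if keys2[j - 1] != ku or keys2[j + 1] != kd:
                continue
            if _exon_key(f) == _exon_key(e) or e.intersection_length(f) > 0:
                continue
            # mutually exclusive: no transcript carries both
            if any(
                _exon_key(e) in s and _exon_key(f) in s for s in exon_sets
            ):
                continue
            first, second = sorted([e, f], key=lambda iv: iv.start)
            junctions = {
                "inc_up": _jid(chrom, up.end, first.start, strand),
                "inc_down": _jid(chrom, first.end, down.start, strand),
                "exc_up": _jid(chrom, up.end, second.start, strand),
                "exc_down": _jid(chrom, second.end, down.start, strand),
            }
            key = ("MXE", tuple(sorted(junctions.values())))
            if key not in events:
                events[key] = SplicingEvent(
                    event_id=(
                        f"MXE:{chrom}:{first.start}-{first.end}|"
                        f"{second.start}-{second.end}:{strand}"
                    ),
                    etype="MXE", gene_id=gene_id, chrom=chrom, strand=strand,
                    alt_region=GenomicInterval(chrom, first.start, second.end, strand),
                    junctions=junctions,
                )


def _find_alt_ss(events, chain1, chain2, gene_id, chrom, strand):
    for i, e1 in enumerate(chain1):
        for j, e2 in enumerate(chain2):
            if e1.intersection_length(e2) == 0 or _exon_key(e1) == _exon_key(e2):
                continue
            same_start = e1.start == e2.start
            same_end = e1.end == e2.end
            if same_start and not same_end:
                # differ at the genomic-right boundary
                etype = "A5SS" if strand == "+" else "A3SS"
                long_e, short_e = (e1, e2) if e1.end > e2.end else (e2, e1)
                # shared flanking exon genomically right of both
                nxt1 = chain1[i + 1] if i + 1 < len(chain1) else None
                nxt2 = chain2[j + 1] if j + 1 < len(chain2) else None
                if nxt1 is None or nxt2 is None or _exon_key(nxt1) != _exon_key(nxt2):
                    continue
                flank = nxt1
                junctions = {
                    "proximal": _jid(chrom, long_e.end, flank.start, strand),
                    "distal": _jid(chrom, short_e.end, flank.start, strand),
                }
                alt = GenomicInterval(chrom, short_e.end, long_e.end, strand)
            elif same_end and not same_start:
                etype = "A3SS" if strand == "+" else "A5SS"
                long_e, short_e = (e1, e2) if e1.start < e2.start else (e2, e1)
                prv1 = chain1[i - 1] if i > 0 else None
                prv2 = chain2[j - 1] if j > 0 else None
                if prv1 is None or prv2 is None or _exon_key(prv1) != _exon_key(prv2):
                    continue
                flank = prv1
                junctions = {
                    "proximal": _jid(chrom, flank.end, long_e.start, strand),
                    "distal": _jid(chrom, flank.end, short_e.start, strand),
                }
                alt = GenomicInterval(chrom, long_e.start, short_e.start, strand)
            else:
                continue
            key = (etype, tuple(sorted(junctions.values())))
            if key not in events:
                events[key] = SplicingEvent(
                    event_id=f"{etype}:{chrom}:{alt.start}-{alt.end}:{strand}",
                    etype=etype, gene_id=gene_id, chrom=chrom, strand=strand,
                    alt_region=alt, junctions=junctions,
                )


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def _support(counts: dict[str, float], roles: tuple[str, ...]) -> float:
    vals = [counts.get(r, 0.0) for r in roles]
    if any(v < 0 for v in vals):
        raise ValueError("junction counts must be non-negative")
    return float(np.mean(vals)) if vals else 0.0


def compute_psi(event: SplicingEvent, counts: dict[str, float]) -> float:
    """PSI for one sample's role->count mapping; NaN when unsupported.

    SE: mean of the two inclusion junctions over (that mean + skip);
    MXE: exon-1 support over exon-1 + exon-2 support;
    A5SS/A3SS: proximal over proximal + distal.
    """
    inc = _support(counts, INCLUSION_ROLES[event.etype])
    exc = _support(counts, EXCLUSION_ROLES[event.etype])
    denom = inc + exc
    if denom <= 0:
        return float("nan")
    return inc / denom


def attach_counts(events: list[SplicingEvent], table: pd.DataFrame) -> None:
    """Fill per-sample role counts from a long-format junction-count table.

    Expected columns: event_id, junction_id, sample, count.
    """
    required = {"event_id", "junction_id", "sample", "count"}
    if not required.issubset(table.columns):
        raise ValueError(f"junction table must have columns {sorted(required)}")
    grouped = {
        eid: sub for eid, sub in table.groupby("event_id")
    }
    for ev in events:
        sub = grouped.get(ev.event_id)
        if sub is None:
            continue
        jid_to_role = {v: k for k, v in ev.junctions.items()}
        ev.counts = {}
        for _idx, row in sub.iterrows():
            role = jid_to_role.get(row["junction_id"])
            if role is None:
                continue
            ev.counts.setdefault(row["sample"], {})[role] = float(row["count"])


# ---------------------------------------------------------------------------
# Differential splicing
# ---------------------------------------------------------------------------

def _pooled_inc_exc(
    event: SplicingEvent, samples: list[str]
) -> tuple[int, int]:
    inc = sum(_support(event.counts.get(s, {}), INCLUSION_ROLES[event.etype]) for s in samples)
    exc = sum(_support(event.counts.get(s, {}), EXCLUSION_ROLES[event.etype]) for s in samples)
    return int(round(inc)), int(round(exc))


def differential_splicing(
    events: list[SplicingEvent],
    sample_conditions: dict[str, str],
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    min_delta_psi: float = 0.1,
) -> list[SplicingEvent]:
    """Call differential events between two conditions.

    Replicate junction counts are pooled per condition; p comes from a
    two-sided Fisher exact test on the pooled inclusion/exclusion table, FDR
    is Benjamini-Hochberg across events, and an event is significant when
    FDR < ``alpha`` and |delta PSI| >= ``min_delta_psi``. ``delta_psi`` is
    PSI(condition_b) - PSI(condition_a); direction "gained" means
    delta_psi > 0. Returns the events (mutated in place) for chaining.
    """
    samples_a = [s for s, c in sample_conditions.items() if c == condition_a]
    samples_b = [s for s, c in sample_conditions.items() if c == condition_b]
    if not samples_a:
        raise ValueError(f"condition {condition_a!r} has no samples")
    if not samples_b:
        raise ValueError(f"condition {condition_b!r} has no samples")
    pvals, tested = [], []
    for ev in events:
        inc_a, exc_a = _pooled_inc_exc(ev, samples_a)
        inc_b, exc_b = _pooled_inc_exc(ev, samples_b)
        psi_a = inc_a / (inc_a + exc_a) if inc_a + exc_a > 0 else float("nan")
        psi_b = inc_b / (inc_b + exc_b) if inc_b + exc_b > 0 else float("nan")
        ev.psi[condition_a] = psi_a
        ev.psi[condition_b] = psi_b
        ev.delta_psi = psi_b - psi_a
        ev.significant = False
        ev.fdr = float("nan")
        if math.isnan(ev.delta_psi):
            ev.p_value = float("nan")
            ev.direction = ""
            continue
        ev.p_value = fisher_exact_two_sided(inc_a, exc_a, inc_b, exc_b)
        ev.direction = "gained" if ev.delta_psi > 0 else ("lost" if ev.delta_psi < 0 else "")
        pvals.append(ev.p_value)
        tested.append(ev)
    if tested:
        _rej, fdrs, _a, _b = multipletests(pvals, method="fdr_bh")
        for ev, q in zip(tested, fdrs):
            ev.fdr = float(q)
            ev.significant = bool(
                ev.fdr < alpha and abs(ev.delta_psi) >= min_delta_psi
            )
    return events


def events_to_frame(events: list[SplicingEvent], conditions=None) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "type": ev.etype,
            "gene_id": ev.gene_id,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "alt_start": ev.alt_region.start,
            "alt_end": ev.alt_region.end,
            "delta_psi": ev.delta_psi,
            "p_value": ev.p_value,
            "fdr": ev.fdr,
            "direction": ev.direction,
            "significant": ev.significant,
        }
        for cond, val in ev.psi.items():
            row[f"psi_{cond}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
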