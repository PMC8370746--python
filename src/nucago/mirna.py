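"""miRNA abundance profiling from eCLIP-derived small-RNA reads.

Reads are assigned to mature miRNAs by Hamming distance (at most one
substitution over the full mature length, longer reads 3'-trimmed), counts are
normalised by total mapped reads and then quantile-normalised across samples,
and compartments (e.g. nucleus vs cytoplasm) are compared through top-N
overlap, family percentages, and rank concordance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seqs: list[str], length: int) -> np.ndarray:
    arr = np.empty((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i] = [_BASE_CODE.get(b, 4) for b in s[:length]]
    return arr


def match_reads_to_mirnas(
    reads: list[str] | Counter,
    mirnas: dict[str, str],
    max_mismatches: int = 1,
) -> tuple[pd.Series, float]:
    """Assign reads to mature miRNAs allowing up to ``max_mismatches``.

    A read maps to a miRNA when its 3'-trimmed prefix of the mature length is
    within Hamming distance ``max_mismatches`` of the mature sequence; reads
    shorter than the mature sequence never match it. Reads tied between
    several miRNAs at the best distance are split fractionally, conserving
    counts. Returns ``(counts per miRNA, number of unassigned reads)``.
    """
    if isinstance(reads, Counter):
        read_counts = reads
    else:
        read_counts = Counter(reads)
    read_counts = Counter(
        {k.upper().replace("U", "T"): v for k, v in read_counts.items()}
    )
    mirnas = {i: s.upper().replace("U", "T") for i, s in mirnas.items()}
    ids = list(mirnas)
    counts = pd.Series(0.0, index=ids, dtype=float)
    unassigned = 0.0
    if not ids:
        return counts, float(sum(read_counts.values()))

    by_len: dict[int, tuple[list[str], np.ndarray]] = {}
    for length in {len(s) for s in mirnas.values()}:
        group = [i for i in ids if len(mirnas[i]) == length]
        by_len[length] = (group, _encode([mirnas[i] for i in group], length))

    uniq = sorted(read_counts)
    for read in uniq:
        weight = read_counts[read]
        best_dist = max_mismatches + 1
        best_ids: list[str] = []
        for length, (group, enc) in by_len.items():
            if len(read) < length:
                continue
            r = np.array([_BASE_CODE.get(b, 4) for b in read[:length]], dtype=np.uint8)
            dists = (enc != r).sum(axis=1)
            lo = int(dists.min())
            if lo < best_dist:
                best_dist = lo
                best_ids = [group[j] for j in np.flatnonzero(dists == lo)]
            elif lo == best_dist and lo <= max_mismatches:
                best_ids.extend(group[j] for j in np.flatnonzero(dists == lo))
        if best_dist <= max_mismatches and best_ids:
            share = weight / len(best_ids)
            for i in best_ids:
                counts[i] += share
        else:
            unassigned += weight
    return counts, unassigned


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standard quantile normalisation (rank-wise mean substitution).

    Each sample's sorted values are replaced by the across-sample means of the
    order statistics; tied values within a sample receive the mean of the
    rank-range means, so the transform is invariant to the ordering of ties.
    """
    sorted_means = np.sort(matrix.values, axis=0).mean(axis=1)
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for col in matrix.columns:
        vals = matrix[col].values
        order = np.argsort(vals, kind="mergesort")
        assigned = np.empty(len(vals))
        assigned[order] = sorted_means
        # average the assigned means over ties
        ser = pd.Series(assigned, index=vals).groupby(level=0).mean()
        out[col] = [ser[v] for v in vals]
    return out


@dataclass
class MiRNAProfile:
    """miRNA x sample abundance matrix with family map and per-sample rankings."""

    raw_counts: pd.DataFrame
    abundance: pd.DataFrame
    family_map: dict[str, str] = field(default_factory=dict)

    def ranking(self, sample: str) -> list[str]:
        col = self.abundance[sample]
        order = sorted(col.index, key=lambda i: (-col[i], i))
        return order

    def top(self, sample: str, n_top: int) -> list[str]:
        return self.ranking(sample)[:n_top]


def normalize_and_quantile(
    raw_counts: pd.DataFrame, family_map: dict[str, str] | None = None
) -> MiRNAProfile:
    """Total-mapped-read normalisation followed by quantile normalisation.

    Raises on an all-zero sample (no mapped reads to normalise by), naming it.
    """
    if raw_counts.shape[0] < 1 or raw_counts.shape[1] < 1:
        raise ValueError("need at least one miRNA and one sample")
    totals = raw_counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero mapped reads: {list(zero.index)}")
    fractions = raw_counts / totals
    abundance = quantile_normalize(fractions)
    return MiRNAProfile(
        raw_counts=raw_counts, abundance=abundance, family_map=dict(family_map or {})
    )


def family_percentages(
    profile: MiRNAProfile, sample: str, n_top: int
) -> pd.Series:
    """Percentage of the top-N miRNAs' total abundance carried by each family."""
    top = profile.top(sample, n_top)
    ab = profile.abundance.loc[top, sample]
    fam = pd.Series({m: profile.family_map.get(m, m) for m in top})
    pct = ab.groupby(fam).sum() / ab.sum() * 100.0
    return pct.sort_values(ascending=False)


def compare_compartments(
    profile_a: MiRNAProfile,
    sample_a: str,
    profile_b: MiRNAProfile,
    sample_b: str,
    n_top: int = 100,
) -> dict:
    """Compare two compartments' miRNA populations (top-N logic).

    Returns the size of the top-N intersection, per-family percentage tables
    for each compartment, and the Spearman rank correlation of abundances over
    the union of the two top-N sets. ``n_top`` is capped at the catalog size.
    """
    catalog = profile_a.abundance.index.intersection(profile_b.abundance.index)
    if n_top > len(catalog):
        import logging

        logging.getLogger(__name__).warning(
            "n_top=%d exceeds shared catalog of %d; capping", n_top, len(catalog)
        )
        n_top = len(catalog)
    top_a = [m for m in profile_a.top(sample_a, n_top) if m in catalog]
    top_b = [m for m in profile_b.top(sample_b, n_top) if m in catalog]
    union = sorted(set(top_a) | set(top_b))
    overlap = len(set(top_a) & set(top_b))
    if len(union) >= 2:
        rho, _p = stats.spearmanr(
            profile_a.abundance.loc[union, sample_a],
            profile_b.abundance.loc[union, sample_b],
        )
    else:
        rho = 1.0
    return {
        "n_top": n_top,
        "overlap": overlap,
        "spearman_rho": float(rho),
        "families_a": family_percentages(profile_a, sample_a, n_top),
        "families_b": family_percentages(profile_b, sample_b, n_top),
        "top_a": top_a,
        "top_b": top_b,
    }
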