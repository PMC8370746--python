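"""miRNA binding-site scanning by RNA-RNA duplex minimum free energy.

A self-contained intermolecular dynamic program scores miRNA/target duplexes
with a nearest-neighbor stack-energy table (Turner-style values shipped as a
package data file) and an affine interior-loop/bulge penalty; no
intramolecular structure is considered. Candidate miRNAs are restricted to
the most abundant (top 100 by default) and a site is reported when the duplex
MFE reaches the threshold (default -14 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}
_WOBBLE = {"GU", "UG"}
_RNA = "ACGU"
_COMPLEMENT = str.maketrans("ACGUT", "UGCAA")

# interior-loop / bulge penalty: base + per-nt + asymmetry (kcal/mol)
LOOP_BASE = 4.0
LOOP_PER_NT = 1.0
LOOP_ASYMMETRY = 0.5
MAX_LOOP = 10


def revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(_RNA)
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")
    return s


def load_stack_table() -> np.ndarray:
    """6x6 stack-energy matrix indexed by (5' pair, 3' pair) type."""
    table = np.zeros((6, 6))
    text = (
        resources.files("nucago").joinpath("data/stack_energies.tsv").read_text()
    )
    for line in text.splitlines()[1:]:
        p, q, e = line.split("\t")
        table[_PAIR_INDEX[p], _PAIR_INDEX[q]] = float(e)
    return table


_STACKS = None


def _stacks() -> np.ndarray:
    global _STACKS
    if _STACKS is None:
        _STACKS = load_stack_table()
    return _STACKS


def _pair_matrix(mirna: str, target_rev: str, allow_gu: bool) -> np.ndarray:
    """Pair-type index per (miRNA position, reversed-target position); -1 if unpaired."""
    mat = np.full((len(mirna), len(target_rev)), -1, dtype=np.int8)
    for i, a in enumerate(mirna):
        for k, b in enumerate(target_rev):
            p = a + b
            idx = _PAIR_INDEX.get(p, -1)
            if idx >= 0 and (allow_gu or p not in _WOBBLE):
                mat[i, k] = idx
    return mat


def _dp_core(pairmat, stacks, max_loop, loop_base, loop_per_nt, loop_asym):
    """Fill DP tables: energy of the best structure ending in pair (i, k)."""
    M, T = pairmat.shape
    INF = 1e30
    energy = np.full((M, T), INF)
    parent_i = np.full((M, T), -1, dtype=np.int32)
    parent_k = np.full((M, T), -1, dtype=np.int32)
    for i in range(M):
        for k in range(T):
            p = pairmat[i, k]
            if p < 0:
                continue
            best = 0.0  # opening a new helix costs nothing
            bi = -1
            bk = -1
            di_max = min(i, max_loop + 1)
            dk_max = min(k, max_loop + 1)
            for di in range(1, di_max + 1):
                for dk in range(1, dk_max + 1):
                    i2 = i - di
                    k2 = k - dk
                    prev = energy[i2, k2]
                    if prev >= INF:
                        continue
                    q = pairmat[i2, k2]
                    l1 = di - 1
                    l2 = dk - 1
                    if l1 == 0 and l2 == 0:
                        e = prev + stacks[q, p]
                    else:
                        e = prev + loop_base + loop_per_nt * (l1 + l2) + loop_asym * abs(l1 - l2)
                    if e < best:
                        best = e
                        bi = i2
                        bk = k2
            energy[i, k] = best
            parent_i[i, k] = bi
            parent_k[i, k] = bk
    return energy, parent_i, parent_k


try:  # jit-compile the inner loop when numba is available
    from numba import njit

    _dp_core = njit(cache=True)(_dp_core)
except ImportError:  # pragma: no cover - numba is a declared dependency
    pass


@dataclass
class DuplexResult:
    """A miRNA/target hybridisation with its minimum free energy."""

    mfe: float
    pairing: str
    pairs: list[tuple[int, int]]  # (miRNA index, target index), both 5'->3'

    @property
    def is_hit(self) -> bool:
        return math.isfinite(self.mfe)


def duplex_mfe(
    mirna_seq: str,
    target_seq: str,
    allow_gu: bool = True,
    max_loop: int = MAX_LOOP,
) -> DuplexResult:
    """Minimum free energy over all intermolecular non-crossing pairings.

    Both sequences are read 5'->3' (DNA input is treated as its RNA
    transcript). Energy is the sum of nearest-neighbor stack terms for
    adjacent pairs plus affine penalties for interior loops/bulges (at most
    ``max_loop`` unpaired nt per side between consecutive pairs). When no
    structure has negative energy the result carries ``mfe = +inf``.
    """
    if len(mirna_seq) > 40 or len(target_seq) > 40:
        raise ValueError("duplex_mfe supports sequences up to 40 nt")
    m = _normalize_rna(mirna_seq, "miRNA sequence")
    t = _normalize_rna(target_seq, "target sequence")
    if not m or not t:
        return DuplexResult(math.inf, "", [])
    t_rev = t[::-1]
    pairmat = _pair_matrix(m, t_rev, allow_gu)
    energy, parent_i, parent_k = _dp_core(
        pairmat, _stacks(), max_loop, LOOP_BASE, LOOP_PER_NT, LOOP_ASYMMETRY
    )
    flat = int(np.argmin(energy))
    i, k = divmod(flat, energy.shape[1])
    mfe = float(energy[i, k])
    if mfe >= 0.0:
        return DuplexResult(math.inf, "", [])
    pairs_rev = []
    while i >= 0:
        pairs_rev.append((i, k))
        i, k = int(parent_i[i, k]), int(parent_k[i, k])
        if i < 0:
            break
    # drop any leading pairs past the point where the helix was restarted:
    # the traceback already only contains the chain contributing to the mfe
    pairs = [(pi, len(t) - 1 - pk) for pi, pk in reversed(pairs_rev)]
    m_line = ["."] * len(m)
    t_line = ["."] * len(t)
    for pi, pj in pairs:
        m_line[pi] = "("
        t_line[pj] = ")"
    pairing = "".join(m_line) + "&" + "".join(t_line)
    return DuplexResult(mfe, pairing, pairs)


def seed_matched(result: DuplexResult, mirna_seq: str, target_seq: str) -> bool:
    """Watson-Crick pairing of miRNA seed bases 2-8 (1-based)."""
    if not result.is_hit:
        return False
    m = _normalize_rna(mirna_seq, "miRNA sequence")
    t = _normalize_rna(target_seq, "target sequence")
    paired = dict(result.pairs)
    for i in range(1, min(8, len(m))):
        j = paired.get(i)
        if j is None:
            return False
        if m[i] + t[j] in _WOBBLE or m[i] + t[j] not in _PAIR_INDEX:
            return False
    return True


@dataclass
class DuplexHit:
    """A reported miRNA site within a cluster sequence."""

    mirna_id: str
    start: int  # within the scanned (transcript-orientation) cluster sequence
    end: int
    mfe: float
    pairing: str
    seed_matched: bool
    rank: int


def scan_cluster(
    cluster_seq: str,
    mirna_catalog: dict[str, str],
    ranked_ids: list[str],
    mfe_threshold: float = -14.0,
    top_n: int = 100,
    window_slop: int = 5,
    allow_gu: bool = True,
) -> list[DuplexHit]:
    """Scan a cluster sequence for candidate miRNA binding sites.

    Only the ``top_n`` most abundant miRNAs (``ranked_ids`` order) are
    considered. A sliding window of miRNA length + ``window_slop`` nt (step 1)
    is scored with :func:`duplex_mfe`; windows reaching ``mfe_threshold`` are
    hits, and overlapping hit windows of the same miRNA are collapsed to the
    best-scoring one (leftmost on ties). The cluster sequence must already be
    in transcript orientation (reverse-complemented for minus-strand
    clusters).
    """
    if not cluster_seq:
        raise ValueError("cluster sequence unavailable (empty)")
    seq = _normalize_rna(cluster_seq, "cluster sequence")
    hits: list[DuplexHit] = []
    for rank, mid in enumerate(ranked_ids[:top_n], start=1):
        m = _normalize_rna(mirna_catalog[mid], f"miRNA {mid}")
        win = min(len(m) + window_slop, len(seq))
        t_rev_full = seq[::-1]
        pairmat_full = _pair_matrix(m, t_rev_full, allow_gu)
        raw: list[tuple[int, int, DuplexResult]] = []
        for start in range(0, len(seq) - win + 1):
            end = start + win
            # window [start, end) of seq maps to reversed coords
            k_lo = len(seq) - end
            sub = np.ascontiguousarray(pairmat_full[:, k_lo : k_lo + win])
            energy, parent_i, parent_k = _dp_core(
                sub, _stacks(), MAX_LOOP, LOOP_BASE, LOOP_PER_NT, LOOP_ASYMMETRY
            )
            mfe = float(energy.min())
            if mfe <= mfe_threshold:
                res = duplex_mfe(m, seq[start:end], allow_gu=allow_gu)
                raw.append((start, end, res))
        # collapse overlapping windows: greedy by position, keep the best
        raw.sort(key=lambda x: x[0])
        group: list[tuple[int, int, DuplexResult]] = []
        groups = []
        for item in raw:
            if group and item[0] < group[-1][1]:
                group.append(item)
            else:
                if group:
                    groups.append(group)
                group = [item]
        if group:
            groups.append(group)
        for grp in groups:
            start, end, res = min(grp, key=lambda x: (x[2].mfe, x[0]))
            hits.append(
                DuplexHit(
                    mirna_id=mid,
                    start=start,
                    end=end,
                    mfe=res.mfe,
                    pairing=res.pairing,
                    seed_matched=seed_matched(res, m, seq[start:end]),
                    rank=rank,
                )
            )
    hits.sort(key=lambda h: (h.start, h.mfe))
    return hits
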