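"""Event extraction, PSI arithmetic and differential splicing calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_annotation
from nucago.splicing import (
    SplicingEvent,
    compute_psi,
    differential_splicing,
    extract_events,
)
from nucago.intervals import GenomicInterval


def _gene(transcripts, strand="+", gene_type="protein_coding"):
    return build_annotation(
        [
            {
                "gene_id": "G",
                "gene_type": gene_type,
                "strand": strand,
                "transcripts": [{"exons": ex} for ex in transcripts],
            }
        ]
    )


class TestExtractEvents:
    def test_skipped_exon(self):
        ann = _gene(
            [
                [(0, 100), (200, 300), (400, 500)],
                [(0, 100), (400, 500)],
            ]
        )
        events = extract_events(ann)
        assert [e.etype for e in events] == ["SE"]
        ev = events[0]
        assert ev.alt_region == GenomicInterval("chrT", 200, 300, "+")
        assert ev.junctions == {
            "inc_up": "chrT:100-200:+",
            "inc_down": "chrT:300-400:+",
            "skip": "chrT:100-400:+",
        }

    def test_single_transcript_yields_nothing(self):
        ann = _gene([[(0, 100), (200, 300)]])
        assert extract_events(ann) == []

    def test_mutually_exclusive_exons(self):
        ann = _gene(
            [
                [(0, 100), (200, 300), (600, 700)],
                [(0, 100), (400, 500), (600, 700)],
            ]
        )
        events = extract_events(ann)
        assert [e.etype for e in events] == ["MXE"]
        ev = events[0]
        assert ev.junctions["inc_up"] == "chrT:100-200:+"
        assert ev.junctions["exc_up"] == "chrT:100-400:+"

    def test_a5ss_plus_strand(self):
        # second exon's donor (right) boundary differs; acceptor shared
        ann = _gene(
            [
                [(0, 100), (200, 300), (500, 600)],
                [(0, 100), (200, 350), (500, 600)],
            ]
        )
        events = extract_events(ann)
        assert [e.etype for e in events] == ["A5SS"]
        ev = events[0]
        assert ev.alt_region == GenomicInterval("chrT", 300, 350, "+")
        assert ev.junctions == {
            "proximal": "chrT:350-500:+",
            "distal": "chrT:300-500:+",
        }

    def test_same_structure_on_minus_strand_is_a3ss(self):
        ann = _gene(
            [
                [(0, 100), (200, 300), (500, 600)],
                [(0, 100), (200, 350), (500, 600)],
            ],
            strand="-",
        )
        events = extract_events(ann)
        assert [e.etype for e in events] == ["A3SS"]

    def test_a3ss_plus_strand(self):
        # acceptor (left) boundary differs; donor side shared
        ann = _gene(
            [
                [(0, 100), (200, 300), (500, 600)],
                [(0, 100), (150, 300), (500, 600)],
            ]
        )
        events = extract_events(ann)
        assert [e.etype for e in events] == ["A3SS"]
        assert events[0].junctions == {
            "proximal": "chrT:100-150:+",
            "distal": "chrT:100-200:+",
        }

    def test_duplicate_events_across_transcript_pairs_deduplicated(self):
        ann = _gene(
            [
                [(0, 100), (200, 300), (400, 500)],
                [(0, 100), (400, 500)],
                [(0, 100), (200, 300), (400, 500), (600, 700)],
            ]
        )
        events = [e for e in extract_events(ann) if e.etype == "SE"]
        assert len(events) == 1


def _se_event():
    return SplicingEvent(
        event_id="SE:test",
        etype="SE",
        gene_id="G",
        chrom="chrT",
        strand="+",
        alt_region=GenomicInterval("chrT", 200, 300, "+"),
        junctions={"inc_up": "j1", "inc_down": "j2", "skip": "j3"},
    )


class TestComputePsi:
    def test_balanced_counts_give_half(self):
        ev = _se_event()
        psi = compute_psi(ev, {"inc_up": 10, "inc_down": 10, "skip": 10})
        assert psi == pytest.approx(0.5)

    def test_no_skipping_gives_one(self):
        ev = _se_event()
        assert compute_psi(ev, {"inc_up": 8, "inc_down": 6, "skip": 0}) == 1.0

    def test_no_support_is_missing(self):
        ev = _se_event()
        assert math.isnan(compute_psi(ev, {"inc_up": 0, "inc_down": 0, "skip": 0}))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(_se_event(), {"inc_up": -1, "inc_down": 0, "skip": 0})

    def test_scale_invariance(self):
        ev = _se_event()
        base = {"inc_up": 7, "inc_down": 9, "skip": 13}
        psi1 = compute_psi(ev, base)
        psi2 = compute_psi(ev, {k: 10 * v for k, v in base.items()})
        assert psi1 == pytest.approx(psi2)


def _with_counts(inc_a, exc_a, inc_b, exc_b, reps=1):
    ev = _se_event()
    for r in range(reps):
        ev.counts[f"A_rep{r+1}"] = {
            "inc_up": inc_a, "inc_down": inc_a, "skip": exc_a
        }
        ev.counts[f"B_rep{r+1}"] = {
            "inc_up": inc_b, "inc_down": inc_b, "skip": exc_b
        }
    samples = {s: s.rsplit("_rep", 1)[0] for s in ev.counts}
    return ev, samples


class TestDifferential:
    def test_identical_conditions_are_null(self):
        ev, samples = _with_counts(10, 10, 10, 10)
        differential_splicing([ev], samples, "A", "B")
        assert ev.p_value == pytest.approx(1.0)
        assert ev.delta_psi == pytest.approx(0.0)
        assert not ev.significant

    def test_label_swap_negates_delta_and_preserves_p(self):
        ev1, samples = _with_counts(30, 10, 10, 30)
        differential_splicing([ev1], samples, "A", "B")
        ev2, _ = _with_counts(30, 10, 10, 30)
        differential_splicing([ev2], samples, "B", "A")
        assert ev1.delta_psi == pytest.approx(-ev2.delta_psi)
        assert ev1.p_value == pytest.approx(ev2.p_value)

    def test_direction_follows_delta_sign(self):
        ev, samples = _with_counts(10, 40, 40, 10)
        differential_splicing([ev], samples, "A", "B")
        assert ev.delta_psi > 0 and ev.direction == "gained"

    def test_absent_condition_is_error(self):
        ev, samples = _with_counts(10, 10, 10, 10)
        with pytest.raises(ValueError, match="no samples"):
            differential_splicing([ev], samples, "A", "Z")

    def test_missing_support_gives_nan_without_test(self):
        ev, samples = _with_counts(0, 0, 10, 10)
        differential_splicing([ev], samples, "A", "B")
        assert math.isnan(ev.psi["A"]) and math.isnan(ev.p_value)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40),
        st.floats(0.01, 0.2),
    )
    def test_bh_fdr_matches_brute_force_step_up(self, pvals, alpha):
        """The BH-adjusted values behind significance calls agree with a
        direct implementation of the step-up procedure."""
        from statsmodels.stats.multitest import multipletests

        _rej, got, _a, _b = multipletests(pvals, method="fdr_bh")
        m = len(pvals)
        order = np.argsort(pvals, kind="mergesort")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, pvals[idx] * m / rank)
            adj[idx] = running
        assert got == pytest.approx(adj, abs=1e-12)
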