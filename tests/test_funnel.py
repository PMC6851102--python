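import math

import numpy as np
import pandas as pd
import pytest

from zebscreen import funnel as fn
from zebscreen.io import BedInterval


# --- brute-force oracles ----------------------------------------------------

def overlap_oracle(a, b):
    """All-pairs intersection, then merge, as flat (chrom,start,end) tuples."""
    pieces = []
    for x in a:
        for y in b:
            if x.chrom != y.chrom:
                continue
            lo, hi = max(x.start, y.start), min(x.end, y.end)
            if lo < hi:
                pieces.append((x.chrom, lo, hi))
    pieces.sort()
    merged = []
    for chrom, lo, hi in pieces:
        if merged and merged[-1][0] == chrom and lo <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], hi)
        else:
            merged.append([chrom, lo, hi])
    return [tuple(m) for m in merged]


def ebox_oracle(seq, motif):
    rc = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(motif))
    count = 0
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i : i + len(motif)]
        if window == motif or window == rc:
            count += 1
    return count


def random_peaks(rng, n, span=1000):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        peaks.append(
            BedInterval(f"chr{rng.integers(1, 3)}", start, start + int(rng.integers(1, 60)))
        )
    return peaks


class TestOverlapPeaks:
    def test_basic_intersection(self):
        got = fn.overlap_peaks(
            [BedInterval("chr1", 100, 200)], [BedInterval("chr1", 150, 250)]
        )
        assert [(iv.start, iv.end) for iv in got] == [(150, 200)]

    def test_half_open_abutment_no_overlap(self):
        got = fn.overlap_peaks(
            [BedInterval("chr1", 100, 200)], [BedInterval("chr1", 200, 300)]
        )
        assert got == []

    def test_different_chromosomes_no_overlap(self):
        got = fn.overlap_peaks(
            [BedInterval("chr1", 100, 200)], [BedInterval("chr2", 100, 200)]
        )
        assert got == []

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = random_peaks(rng, int(rng.integers(0, 50)))
            b = random_peaks(rng, int(rng.integers(0, 50)))
            got = [(iv.chrom, iv.start, iv.end) for iv in fn.overlap_peaks(a, b)]
            assert got == overlap_oracle(a, b)


class TestAssignToTss:
    def ann(self, tss=1000):
        return pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "tss": [tss], "strand": ["+"]}
        )

    def test_covering_peak_distance_zero(self):
        got = fn.assign_to_tss([BedInterval("chr1", 950, 1050)], self.ann())
        assert got.loc[0, "tss_distance"] == 0
        assert bool(got.loc[0, "tss_pass"])

    def test_peak_beyond_window_fails(self):
        got = fn.assign_to_tss([BedInterval("chr1", 1300, 1400)], self.ann(), window=250)
        assert got.loc[0, "tss_distance"] == 300
        assert not got.loc[0, "tss_pass"]

    def test_boundary_exactly_at_window_passes(self):
        got = fn.assign_to_tss([BedInterval("chr1", 1250, 1400)], self.ann(), window=250)
        assert got.loc[0, "tss_distance"] == 250
        assert bool(got.loc[0, "tss_pass"])

    def test_chromosome_absent_infinite_distance(self):
        got = fn.assign_to_tss([BedInterval("chr9", 0, 10)], self.ann())
        assert math.isinf(got.loc[0, "tss_distance"])
        assert not got.loc[0, "tss_pass"]

    def test_upstream_peak_distance_uses_nearest_base(self):
        # peak [100, 200): nearest covered base is 199; TSS 1000 -> 801
        got = fn.assign_to_tss([BedInterval("chr1", 100, 200)], self.ann())
        assert got.loc[0, "tss_distance"] == 801

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            peaks = random_peaks(rng, 30, span=5000)
            ann = pd.DataFrame(
                {
                    "gene": [f"g{i}" for i in range(10)],
                    "chrom": [f"chr{rng.integers(1, 3)}" for _ in range(10)],
                    "tss": rng.integers(0, 5000, size=10),
                    "strand": "+",
                }
            )
            got = fn.assign_to_tss(peaks, ann).set_index("gene")["tss_distance"]
            for rec in ann.itertuples(index=False):
                dists = [
                    fn.tss_distance(int(rec.tss), p)
                    for p in peaks
                    if p.chrom == rec.chrom
                ]
                expected = min(dists) if dists else math.inf
                assert got[rec.gene] == expected


class TestExpressionFilter:
    def test_published_rows(self):
        expr = fn.load_candidate_expression()
        flags = fn.expression_filter(expr)
        assert bool(flags.loc["KCNK1", "expr_pass"])  # fold 0.003, p 0.000
        # TTC21A fails the primary-significance clause (p = 0.368)
        assert not flags.loc["TTC21A", "expr_pass"]
        assert not flags.loc["TTC21A", "OE_393P_sig"]

    def test_second_clause_required(self):
        expr = pd.DataFrame(
            {
                "OE_393P_fold": [0.4],
                "OE_393P_p": [0.01],
                "miR200_344SQ_fold": [1.0],
                "miR200_344SQ_p": [0.5],
            },
            index=pd.Index(["g"], name="gene"),
        )
        flags = fn.expression_filter(expr)
        assert not flags.loc["g", "expr_pass"]

    def test_missing_cells_non_significant(self):
        expr = pd.DataFrame(
            {
                "OE_393P_fold": [0.1],
                "OE_393P_p": [0.001],
                "miR200_344SQ_fold": [np.nan],
                "miR200_344SQ_p": [np.nan],
            },
            index=pd.Index(["g"], name="gene"),
        )
        flags = fn.expression_filter(expr)
        assert not flags.loc["g", "expr_pass"]

    def test_primary_absent_fatal(self):
        with pytest.raises(fn.FunnelError, match="primary"):
            fn.expression_filter(pd.DataFrame({"x_fold": [1.0]}))

    def test_tightening_alpha_never_adds_genes(self):
        expr = fn.load_candidate_expression()
        loose = set(fn.expression_filter(expr, alpha=0.05).query("expr_pass").index)
        tight = set(fn.expression_filter(expr, alpha=0.01).query("expr_pass").index)
        assert tight <= loose

    def test_tightening_fold_never_adds_genes(self):
        expr = fn.load_candidate_expression()
        loose = set(fn.expression_filter(expr, max_fold=0.5).query("expr_pass").index)
        tight = set(fn.expression_filter(expr, max_fold=0.2).query("expr_pass").index)
        assert tight <= loose


class TestScanEbox:
    def test_forward_and_reverse_hits(self):
        count, positions = fn.scan_ebox("CACCTGCAGGTG")
        assert count == 2
        assert positions == [0, 6]

    def test_no_hits(self):
        assert fn.scan_ebox("AAAAAA")[0] == 0

    def test_forward_only(self):
        assert fn.scan_ebox("CAGGTG", both_strands=False)[0] == 0
        assert fn.scan_ebox("CACCTG", both_strands=False)[0] == 1

    def test_n_never_matches(self):
        assert fn.scan_ebox("CACCTGN" + "CACCTN")[0] == 1

    def test_overlapping_matches_counted(self):
        # CACCTG shifted overlaps are impossible, but palindromic-ish overlap
        # of forward/reverse patterns is: CACCTG at 0 and CAGGTG at 3 in
        # CACCAGGTG? verify against the oracle instead on random sequences
        rng = np.random.default_rng(2)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGTN"), size=50))
            assert fn.scan_ebox(seq)[0] == ebox_oracle(seq, "CACCTG")

    def test_bad_characters_error(self):
        with pytest.raises(fn.FunnelError):
            fn.scan_ebox("ACGU")


class TestRunFunnel:
    def test_planted_targets_recovered_exactly(self, funnel_sim):
        audit = fn.run_funnel(
            funnel_sim.peaks_a,
            funnel_sim.peaks_b,
            funnel_sim.annotation,
            funnel_sim.expression,
            promoters=funnel_sim.promoters,
        ).set_index("gene")
        planted = set(funnel_sim.truth.index[funnel_sim.truth])
        assert set(audit.index[audit["candidate"]]) == planted

    def test_empty_peak_set_zero_cobound(self, funnel_sim):
        audit = fn.run_funnel(
            [], funnel_sim.peaks_b, funnel_sim.annotation, funnel_sim.expression
        )
        assert audit["cobound"].sum() == 0
        assert audit["candidate"].sum() == 0

    def test_funnel_stages_nested(self, funnel_sim):
        audit = fn.run_funnel(
            funnel_sim.peaks_a,
            funnel_sim.peaks_b,
            funnel_sim.annotation,
            funnel_sim.expression,
            promoters=funnel_sim.promoters,
        )
        assert (audit["tss_pass"] <= audit["expr_pass"]).all()
        assert (audit["expr_pass"] <= audit["cobound"]).all()
        assert (audit["validated"] <= audit["tss_pass"]).all()

    def test_audit_completeness(self, funnel_sim):
        audit = fn.run_funnel(
            funnel_sim.peaks_a,
            funnel_sim.peaks_b,
            funnel_sim.annotation,
            funnel_sim.expression,
        )
        assert sorted(audit["gene"]) == sorted(funnel_sim.annotation["gene"])
        assert audit["gene"].is_unique
        assert set(audit["stage_reached"]) <= set(fn.STAGES)

    def test_tightening_window_never_adds(self, funnel_sim):
        args = (
            funnel_sim.peaks_a, funnel_sim.peaks_b,
            funnel_sim.annotation, funnel_sim.expression,
        )
        wide = fn.run_funnel(*args, config=fn.FunnelConfig(tss_window=500))
        narrow = fn.run_funnel(*args, config=fn.FunnelConfig(tss_window=100))
        assert set(narrow.loc[narrow["candidate"], "gene"]) <= set(
            wide.loc[wide["candidate"], "gene"]
        )

    def test_require_ebox_filters(self, funnel_sim):
        # strip E-boxes from one planted target's promoter
        planted = list(funnel_sim.truth.index[funnel_sim.truth])
        promoters = dict(funnel_sim.promoters)
        promoters[planted[0]] = "A" * 300
        audit = fn.run_funnel(
            funnel_sim.peaks_a,
            funnel_sim.peaks_b,
            funnel_sim.annotation,
            funnel_sim.expression,
            promoters=promoters,
            config=fn.FunnelConfig(require_ebox=True),
        ).set_index("gene")
        assert not audit.loc[planted[0], "candidate"]
        assert set(audit.index[audit["candidate"]]) == set(planted[1:])

    def test_validation_stratification(self, funnel_sim):
        planted = list(funnel_sim.truth.index[funnel_sim.truth])
        validation = pd.DataFrame(
            {
                "fold_oe": [0.3, 0.9, 0.9],
                "fold_rescue": [1.0, 2.5, 1.2],
            },
            index=pd.Index(planted[:3], name="gene"),
        )
        audit = fn.run_funnel(
            funnel_sim.peaks_a,
            funnel_sim.peaks_b,
            funnel_sim.annotation,
            funnel_sim.expression,
            config=fn.FunnelConfig(),
            validation=validation,
        ).set_index("gene")
        assert bool(audit.loc[planted[0], "validated"])  # fold_oe <= 0.5
        assert bool(audit.loc[planted[1], "validated"])  # fold_rescue >= 2
        assert not audit.loc[planted[2], "validated"]

    def test_stage_counts(self, funnel_sim):
        audit = fn.run_funnel(
            funnel_sim.peaks_a,
            funnel_sim.peaks_b,
            funnel_sim.annotation,
            funnel_sim.expression,
        )
        counts = fn.stage_counts(audit)
        assert counts["input"] == 100
        assert (
            counts["input"] >= counts["cobound"] >= counts["expression"]
            >= counts["tss"] >= counts["validated"]
        )
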