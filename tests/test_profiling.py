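"""Posterior profiles, segment-call filtering, class summaries, export."""

import numpy as np
import pandas as pd
import pytest

from alnseg import SegmentationModel, call_segments, posterior_profile
from alnseg.encoding import CONS2, PAIR8, EncodedSequence
from alnseg.profiling import (
    PosteriorProfile,
    SegmentCall,
    export_bed,
    export_class_fasta,
    fixed_boundary_report,
    read_calls_bed,
    summarize_counts,
)


def _profile(probs, seq=None, boundaries=(), coords=None):
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    if seq is None:
        seq = EncodedSequence(
            np.zeros(n, dtype=np.uint8), CONS2, fixed_boundaries=list(boundaries),
            coords=coords,
        )
    return PosteriorProfile(probs=probs, k_mean=0.0, length_mean=float(n), seq=seq)


def _two_class(p1):
    p1 = np.asarray(p1, dtype=float)
    return np.stack([p1, 1 - p1], axis=1)


class TestCallSegments:
    def test_min_run_filter(self):
        """Above-threshold runs of 5, 7, 8 and 12 positions: only those
        of at least eight positions are called."""
        p = np.zeros(50)
        runs = [(0, 5), (8, 15), (18, 26), (30, 42)]
        for a, b in runs:
            p[a:b] = 0.9
        calls = [
            c for c in call_segments(_profile(_two_class(p)), threshold=0.5, min_run=8)
            if c.class_index == 0
        ]
        lengths = sorted(c.length for c in calls)
        assert lengths == [8, 12]
        assert min(lengths) == 8

    def test_threshold_inclusive(self):
        p = np.full(10, 0.5)
        calls = call_segments(_profile(_two_class(p)), threshold=0.5, min_run=8)
        assert len(calls) == 1 and calls[0].length == 10

    def test_run_split_at_fixed_boundary(self):
        p = np.full(20, 0.95)
        calls = call_segments(
            _profile(_two_class(p), boundaries=[10]), threshold=0.5, min_run=8
        )
        assert [c.length for c in calls] == [10, 10]
        # and with an off-centre cut only the long part survives
        calls = call_segments(
            _profile(_two_class(p), boundaries=[5]), threshold=0.5, min_run=8
        )
        assert [c.length for c in calls] == [15]

    def test_split_at_coordinate_gap(self):
        coords = pd.DataFrame(
            {"chrom": "c", "pos": list(range(100, 110)) + list(range(200, 210)),
             "strand": "+"}
        )
        p = np.full(20, 0.9)
        calls = call_segments(
            _profile(_two_class(p), coords=coords), threshold=0.5, min_run=8
        )
        assert [(c.start, c.end) for c in calls] == [(100, 110), (200, 210)]

    def test_calls_disjoint_and_classwise(self):
        p = np.concatenate([np.full(10, 0.9), np.full(10, 0.1)])
        calls = call_segments(_profile(_two_class(p)), threshold=0.5, min_run=8)
        assert {c.class_index for c in calls} == {0, 1}
        spans = sorted((c.seq_start, c.seq_end) for c in calls)
        for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
            assert b1 <= a2


class TestPosteriorProfile:
    def test_k1_probability_one_everywhere(self, control_seq_small):
        res = SegmentationModel(control_seq_small, n_classes=1).fit(
            iterations=300, seed=8
        )
        prof = posterior_profile(res)
        assert np.all(prof.probs == 1.0)

    def test_rows_sum_to_one(self, planted3_fit):
        prof = posterior_profile(planted3_fit)
        assert np.allclose(prof.probs.sum(axis=1), 1.0)

    def test_planted_majority_recovered(self, planted3, planted3_fit):
        _, truth = planted3
        prof = posterior_profile(planted3_fit)
        pred = prof.probs.argmax(axis=1)
        true_lab = truth.position_labels(len(planted3_fit.seq))
        from scipy.optimize import linear_sum_assignment

        conf = np.array(
            [[np.sum((pred == p) & (true_lab == t)) for t in range(3)] for p in range(3)]
        )
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / len(pred) > 0.9


class TestClassSummary:
    def test_hand_computed_ratios(self):
        counts = np.array([50, 1, 5, 1, 1, 40, 1, 1])
        out = summarize_counts(counts, PAIR8)
        assert out["conservation"] == pytest.approx(0.9)
        assert out["GC"] == pytest.approx(0.43)
        assert out["Ts/Tv"] == pytest.approx(1.5)

    def test_pure_match_class_undefined_ratio(self):
        counts = np.zeros(8)
        counts[0] = 10
        out = summarize_counts(counts, PAIR8)
        assert out["conservation"] == 1.0
        assert out["GC"] == 0.0
        assert np.isnan(out["Ts/Tv"])

    def test_zero_transversions_infinite(self):
        counts = np.zeros(8)
        counts[[0, 2]] = [5, 5]  # matches and transitions only
        assert np.isinf(summarize_counts(counts, PAIR8)["Ts/Tv"])

    def test_summary_recovers_planted_values(self, planted3, planted3_fit):
        _, truth = planted3
        summ = planted3_fit.class_summary()
        truth_cons = sorted(truth.class_freqs[:, [0, 5]].sum(axis=1))
        got_cons = sorted(summ["conservation"])
        assert np.allclose(got_cons, truth_cons, atol=0.05)
        truth_gc = sorted(truth.class_freqs[:, 4:].sum(axis=1))
        assert np.allclose(sorted(summ["GC"]), truth_gc, atol=0.05)

    def test_summary_agrees_with_state_recomputation(self, planted3_fit):
        """Trace-mean summaries match direct recomputation from raw
        symbols assigned by the stored states."""
        res = planted3_fit
        keep = np.flatnonzero(res.state_iters >= res.burn_in_index)
        agg = np.zeros((res.n_classes, 8))
        sym = res.seq.symbols
        for st in keep:
            perm = res.permutations[res.state_iters[st]]
            lab = perm[res.state_labels[st]]
            for c in range(res.n_classes):
                agg[c] += np.bincount(sym[lab == c], minlength=8)
        direct = [summarize_counts(agg[c], PAIR8)["conservation"] for c in range(3)]
        summ = res.class_summary()
        assert np.allclose(sorted(direct), sorted(summ["conservation"]), atol=0.02)


class TestExport:
    def _calls(self):
        return [
            SegmentCall(3, "chr2L", 100, 120, 0.97, 0, 20),
            SegmentCall(1, "chr2L", 300, 310, 0.60, 40, 50),
        ]

    def test_bed_format(self, tmp_path):
        path = tmp_path / "calls.bed"
        export_bed(self._calls(), path)
        line = path.read_text().splitlines()[0]
        assert line == "chr2L\t100\t120\tclass_3\t970\t+"

    def test_bed_roundtrip(self, tmp_path):
        path = tmp_path / "calls.bed"
        calls = self._calls()
        export_bed(calls, path)
        back = read_calls_bed(path)
        assert [(c.class_index, c.chrom, c.start, c.end) for c in back] == [
            (c.class_index, c.chrom, c.start, c.end) for c in calls
        ]

    def test_fasta_lengths(self, tmp_path):
        ref = tmp_path / "ref.fa"
        ref.write_text(">chr2L\n" + "ACGT" * 100 + "\n")
        out = tmp_path / "cls.fa"
        export_class_fasta(self._calls(), ref, out)
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(out), "fasta"))
        assert [len(r.seq) for r in recs] == [20, 10]
        assert recs[0].id == "chr2L:100-120|class_3"

    def test_missing_contig(self, tmp_path):
        with pytest.raises(KeyError, match="contig"):
            export_class_fasta(self._calls(), {"chrX": "ACGT"}, tmp_path / "x.fa")


class TestFixedBoundaryReport:
    def test_concatenated_blocks(self):
        seq = EncodedSequence(np.zeros(12, dtype=np.uint8), CONS2, fixed_boundaries=[4, 8])
        assert fixed_boundary_report(seq) == 2

    def test_empty(self):
        seq = EncodedSequence(np.empty(0, dtype=np.uint8), CONS2)
        assert fixed_boundary_report(seq) == 0

    def test_control_inherits_template_boundaries(self, control_seq_small):
        from alnseg import simulate as sim

        ctrl = sim.single_class_control(template=control_seq_small, seed=1)
        assert fixed_boundary_report(ctrl) == fixed_boundary_report(control_seq_small)
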