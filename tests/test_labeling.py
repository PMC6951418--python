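"""Permutation-null labeling of enhancer- vs promoter-like transcripts."""

import collections
import itertools
import math

import numpy as np
import pytest

from elincnet.labeling import (
    MarkCounts,
    build_null,
    filter_by_signal,
    label_high_confidence,
    label_transcripts,
    labels_to_frame,
    observed_ratio,
    read_markcounts_tsv,
    write_labels_tsv,
)
from elincnet.simulate import make_null_markcounts


def mc(me1, me3, tid="t"):
    return MarkCounts(tid, me1, me3)


class TestObservedRatio:
    @pytest.mark.parametrize(
        "me1,me3,expected", [(19, 9, 2.0), (7, 7, 1.0), (0, 0, 1.0), (0, 9, 0.1)]
    )
    def test_pseudocounted_ratio(self, me1, me3, expected):
        assert observed_ratio(mc(me1, me3)) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mc(-1, 5)


class TestBuildNull:
    def test_deterministic_given_seed(self):
        counts = [mc(i * 3, 20 - i, f"t{i}") for i in range(8)]
        a = build_null(counts, n_perm=50, seed=42)
        b = build_null(counts, n_perm=50, seed=42)
        assert np.array_equal(a.ratios, b.ratios)
        c = build_null(counts, n_perm=50, seed=43)
        assert not np.array_equal(a.ratios, c.ratios)

    def test_too_few_transcripts_rejected(self):
        with pytest.raises(ValueError):
            build_null([mc(5, 5)], n_perm=10, seed=0)

    def test_matches_exhaustive_enumeration_on_three_transcripts(self):
        # independent shuffles of each mark realize every (me1_i, me3_j)
        # pairing; the distinct null values must equal the exhaustive set,
        # each pairing appearing with equal expected frequency
        counts = [mc(10, 40, "a"), mc(25, 15, "b"), mc(70, 5, "c")]
        null = build_null(counts, n_perm=3000, seed=1)
        exhaustive = {
            (a.me1 + 1) / (b.me3 + 1)
            for a, b in itertools.product(counts, counts)
        }
        assert set(np.round(null.ratios, 12)) == {round(v, 12) for v in exhaustive}
        freqs = collections.Counter(np.round(null.ratios, 12))
        expected = len(null.ratios) / len(exhaustive)
        for v, n in freqs.items():
            assert abs(n - expected) < 6 * math.sqrt(expected)

    def test_degenerate_identical_counts_label_nobody(self):
        counts = [mc(30, 15, f"t{i}") for i in range(5)]
        null = build_null(counts, n_perm=20, seed=0)
        assert np.all(null.ratios == null.ratios[0])
        labels = label_transcripts(counts, null)
        assert all(l.label == "unlabeled" for l in labels)

    def test_nearest_rank_thresholds(self):
        counts = [mc(i, 10, f"t{i}") for i in range(10, 30)]
        null = build_null(counts, n_perm=25, seed=0)
        n = len(null.ratios)
        assert null.hi_threshold == null.ratios[math.ceil(0.95 * n) - 1]
        assert null.lo_threshold == null.ratios[math.ceil(0.05 * n) - 1]


class TestLabelTranscripts:
    def background(self):
        # ratios near 1 with mild spread
        rng = np.random.default_rng(0)
        return [
            mc(int(a), int(b), f"bg{i}")
            for i, (a, b) in enumerate(zip(rng.poisson(50, 60), rng.poisson(50, 60)))
        ]

    def test_extreme_ratio_labeled_elinc(self):
        counts = self.background() + [mc(100, 1, "hot")]
        kept = filter_by_signal(counts)
        null = build_null(kept, n_perm=400, seed=2)
        labels = {l.transcript_id: l for l in label_transcripts(kept, null)}
        assert labels["hot"].label == "elinc"
        assert labels["hot"].percentile > 95

    def test_low_signal_excluded(self):
        counts = self.background() + [mc(4, 6, "dim")]
        labels, _ = label_high_confidence(counts, n_perm=200, seed=0)
        assert {l.transcript_id: l.label for l in labels}["dim"] == "excluded"

    def test_percentile_bound_validation(self):
        counts = self.background()
        null = build_null(counts, n_perm=50, seed=0)
        for hi, lo in [(95, 0), (101, 5), (5, 95), (50, 50)]:
            with pytest.raises(ValueError):
                label_transcripts(counts, null, hi_pct=hi, lo_pct=lo)

    def test_monotone_in_me1(self):
        counts = self.background()
        null = build_null(counts, n_perm=400, seed=3)
        order = {"canonical": 0, "unlabeled": 1, "elinc": 2}
        probes = [mc(me1, 20, f"p{me1}") for me1 in range(0, 200, 5)]
        ranks = [order[l.label] for l in label_transcripts(probes, null)]
        assert ranks == sorted(ranks)

    def test_labels_invariant_to_input_order(self):
        counts = self.background()
        null = build_null(counts, n_perm=200, seed=4)
        fwd = {l.transcript_id: l.label for l in label_transcripts(counts, null)}
        rev = {l.transcript_id: l.label for l in label_transcripts(counts[::-1], null)}
        assert fwd == rev

    def test_calibration_under_exchangeable_null(self):
        # iid Poisson counts for both marks: ~5% per class expected
        counts = make_null_markcounts(500, mean=50, seed=11)
        labels, _ = label_high_confidence(counts, n_perm=1000, seed=12)
        frac = collections.Counter(l.label for l in labels)
        se = math.sqrt(0.05 * 0.95 / 500)
        for cls in ("elinc", "canonical"):
            assert abs(frac[cls] / 500 - 0.05) < 3 * se


class TestRecoveryRegimes:
    def make_universe(self, n_elinc, n_canon, seed=5):
        rng = np.random.default_rng(seed)
        counts = [
            mc(int(a), int(b), f"e{i}")
            for i, (a, b) in enumerate(
                zip(rng.poisson(100, n_elinc), rng.poisson(25, n_elinc))
            )
        ] + [
            mc(int(a), int(b), f"c{i}")
            for i, (a, b) in enumerate(
                zip(rng.poisson(25, n_canon), rng.poisson(100, n_canon))
            )
        ]
        return counts

    def test_minority_elinc_recovered_at_high_rate(self):
        # enhancer-like transcripts are a minority of the labeling universe
        # (the regime of real data); planted me1/me3 ratio = 4
        counts = self.make_universe(60, 540)
        labels, _ = label_high_confidence(counts, n_perm=1000, seed=6)
        by = {l.transcript_id: l.label for l in labels}
        rate = np.mean([by[f"e{i}"] == "elinc" for i in range(60)])
        assert rate >= 0.8

    def test_balanced_universe_recovery_capped(self):
        # with balanced classes the elinc cluster itself forms 25% of the
        # pooled null, structurally capping recovery near (100-95)%/0.25 = 20%
        counts = self.make_universe(300, 300)
        labels, _ = label_high_confidence(counts, n_perm=1000, seed=7)
        by = {l.transcript_id: l.label for l in labels}
        rate = np.mean([by[f"e{i}"] == "elinc" for i in range(300)])
        assert 0.1 <= rate <= 0.35


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        counts = [mc(19, 9, "a"), mc(3, 7, "b")]
        path = tmp_path / "counts.tsv"
        path.write_text("transcript_id\tme1\tme3\na\t19\t9\nb\t3\t7\n")
        back = read_markcounts_tsv(path)
        assert back == counts

    def test_labels_table(self, tmp_path):
        counts = [mc(50, 50, f"t{i}") for i in range(5)]
        labels, _ = label_high_confidence(counts, n_perm=50, seed=0)
        out = tmp_path / "labels.tsv"
        write_labels_tsv(labels, out)
        df = labels_to_frame(labels)
        assert list(df.columns) == ["transcript_id", "label", "observed_ratio", "percentile"]
        assert out.read_text().startswith("transcript_id\t")
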