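"""Independent-label construction and chromatin-state randomization checks.

Two validation procedures that do not reuse the permutation-test labels:

* :func:`label_by_overlap` builds an independent test set from enhancer and
  promoter annotations: a transcript that covers more than half of some
  enhancer is an elincRNA, more than half of some promoter a canonical
  lincRNA; transcripts qualifying for both are flagged as conflicts and
  excluded from test sets.
* :func:`chromstate_enrichment` asks whether transcripts overlap
  enhancer- or promoter-like chromatin-state segments more than expected by
  chance: each null round re-places every transcript uniformly at random on
  its own chromosome with its length preserved and recounts how many exceed
  the coverage threshold. The empirical p-value uses the add-one rule
  (1 + exceedances) / (1 + rounds), so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, Transcript


@dataclass(frozen=True)
class OverlapLabel:
    transcript_id: str
    label: str  # elinc | canonical | conflict | none
    best_fraction: float


@dataclass
class EnrichmentResult:
    observed: int
    null_counts: np.ndarray
    n_perm: int
    empirical_p: float
    seed: int

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())


def _tree_by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _best_covered_fraction(
    t: Transcript, trees: dict[str, IntervalTree]
) -> float:
    """Largest fraction of any annotation element covered by the transcript."""
    tree = trees.get(t.chrom)
    if tree is None:
        return 0.0
    best = 0.0
    for iv in tree.overlap(t.interval.start, t.interval.end):
        ov = min(iv.end, t.interval.end) - max(iv.begin, t.interval.start)
        best = max(best, ov / (iv.end - iv.begin))
    return best


def label_by_overlap(
    transcripts: Sequence[Transcript],
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    min_frac: float = 0.5,
) -> list[OverlapLabel]:
    """Label transcripts by which annotation elements they mostly cover.

    *elinc* if some enhancer has strictly more than ``min_frac`` of its
    length inside the transcript; *canonical* likewise for promoters;
    *conflict* if both, *none* if neither.
    """
    if not enhancers and not promoters:
        raise ValueError("both annotation sets are empty")
    enh_trees = _tree_by_chrom(enhancers)
    pro_trees = _tree_by_chrom(promoters)
    out = []
    for t in transcripts:
        ef = _best_covered_fraction(t, enh_trees)
        pf = _best_covered_fraction(t, pro_trees)
        is_e, is_p = ef > min_frac, pf > min_frac
        if is_e and is_p:
            label, best = "conflict", max(ef, pf)
        elif is_e:
            label, best = "elinc", ef
        elif is_p:
            label, best = "canonical", pf
        else:
            label, best = "none", max(ef, pf)
        out.append(OverlapLabel(t.id, label, best))
    return out


class _CoverageIndex:
    """Merged state intervals with prefix sums for O(log m) coverage queries."""

    def __init__(self, states: Sequence[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in states:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.cum: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            merged = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            self.starts[chrom] = starts
            self.ends[chrom] = ends
            self.cum[chrom] = np.concatenate([[0], np.cumsum(ends - starts)])

    def covered_len(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Vectorized covered base count for query intervals [qs, qe)."""
        if chrom not in self.starts:
            return np.zeros(len(qs), dtype=np.int64)
        starts, ends, cum = self.starts[chrom], self.ends[chrom], self.cum[chrom]
        lo = np.searchsorted(ends, qs, side="right")
        hi = np.searchsorted(starts, qe, side="left")
        full = cum[np.maximum(hi, lo)] - cum[lo]
        # trim partial overlap at the two boundary segments
        trim_left = np.where(
            lo < hi, np.maximum(0, qs - starts[np.minimum(lo, len(starts) - 1)]), 0
        )
        trim_right = np.where(
            lo < hi, np.maximum(0, ends[np.maximum(hi - 1, 0)] - qe), 0
        )
        return full - trim_left - trim_right


def chromstate_enrichment(
    transcripts: Sequence[Transcript],
    states: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    cov_threshold: float = 0.3,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Randomization test of chromatin-state coverage of transcripts.

    ``observed`` counts transcripts whose covered fraction (by the merged
    state intervals) strictly exceeds ``cov_threshold``. Each null round
    places a length-matched random interval uniformly on each transcript's
    own chromosome and recounts.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    index = _CoverageIndex(states)

    by_chrom: dict[str, list[Transcript]] = {}
    for t in transcripts:
        clen = chrom_lengths.get(t.chrom)
        if clen is None:
            raise KeyError(f"no chromosome length for {t.chrom}")
        if t.length > clen:
            raise ValueError(f"transcript {t.id} longer than chromosome {t.chrom}")
        by_chrom.setdefault(t.chrom, []).append(t)

    observed = 0
    for chrom, ts in by_chrom.items():
        qs = np.array([t.interval.start for t in ts])
        qe = np.array([t.interval.end for t in ts])
        frac = index.covered_len(chrom, qs, qe) / (qe - qs)
        observed += int(np.sum(frac > cov_threshold))

    rng = np.random.default_rng(seed)
    null_counts = np.zeros(n_perm, dtype=np.int64)
    for chrom, ts in by_chrom.items():
        lengths = np.array([t.length for t in ts])
        max_start = chrom_lengths[chrom] - lengths  # inclusive upper bound
        for r in range(n_perm):
            starts = rng.integers(0, max_start + 1)
            frac = index.covered_len(chrom, starts, starts + lengths) / lengths
            null_counts[r] += int(np.sum(frac > cov_threshold))

    empirical_p = (1 + int(np.sum(null_counts >= observed))) / (1 + n_perm)
    return EnrichmentResult(observed, null_counts, n_perm, empirical_p, seed)


def overlap_labels_to_frame(labels: Sequence[OverlapLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [l.transcript_id for l in labels],
            "label": [l.label for l in labels],
            "best_fraction": [l.best_fraction for l in labels],
        }
    )
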