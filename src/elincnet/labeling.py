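"""High-confidence class labels from the H3K4me1/H3K4me3 permutation test.

Enhancer-associated lincRNAs (elincRNAs) carry high H3K4me1 and low H3K4me3
at their TSS; promoter-like (canonical) lincRNAs the reverse. Rather than a
fixed ratio cutoff, labels come from an empirical null: the per-transcript
H3K4me1 and H3K4me3 TSS read counts are each independently shuffled across
transcripts, per-transcript ratios recomputed, and the pooled ratios over
many rounds (default 10,000) form the null distribution. A transcript is
labeled *elinc* when its observed ratio ranks strictly above the 95th
percentile of the null, *canonical* when strictly below the 5th.

Transcripts where both marks have fewer than ``min_signal`` reads are
excluded before the test. A pseudocount of 1 on both counts keeps ratios
finite and order-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MarkCounts:
    """TSS-interval read counts for the two H3K4 marks of one transcript."""

    transcript_id: str
    me1: int
    me3: int

    def __post_init__(self) -> None:
        if self.me1 < 0 or self.me3 < 0:
            raise ValueError(f"{self.transcript_id}: negative mark counts")


@dataclass
class PermutationNull:
    """Pooled empirical null of shuffled-count ratios.

    ``ratios`` is sorted ascending; thresholds use the nearest-rank
    percentile definition.
    """

    ratios: np.ndarray
    n_perm: int
    seed: int
    hi_pct: float = 95.0
    lo_pct: float = 5.0

    @property
    def hi_threshold(self) -> float:
        return self._nearest_rank(self.hi_pct)

    @property
    def lo_threshold(self) -> float:
        return self._nearest_rank(self.lo_pct)

    def _nearest_rank(self, pct: float) -> float:
        n = len(self.ratios)
        rank = max(1, int(np.ceil(pct / 100.0 * n)))
        return float(self.ratios[rank - 1])

    def percentile_of(self, value: float) -> float:
        """Percentage of null ratios strictly below ``value``."""
        idx = np.searchsorted(self.ratios, value, side="left")
        return 100.0 * idx / len(self.ratios)


@dataclass(frozen=True)
class ConfidenceLabel:
    transcript_id: str
    label: str  # elinc | canonical | unlabeled | excluded
    observed_ratio: float
    percentile: float


def observed_ratio(c: MarkCounts, pseudocount: float = 1.0) -> float:
    """(me1 + pseudocount) / (me3 + pseudocount)."""
    return (c.me1 + pseudocount) / (c.me3 + pseudocount)


def filter_by_signal(
    counts: Sequence[MarkCounts], min_signal: int = 10
) -> list[MarkCounts]:
    """Keep transcripts with at least one mark count >= ``min_signal``."""
    return [c for c in counts if max(c.me1, c.me3) >= min_signal]


def build_null(
    counts: Sequence[MarkCounts],
    n_perm: int = 10_000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> PermutationNull:
    """Permutation null of mark-count ratios.

    Each round independently shuffles the me1 and me3 count vectors across
    transcripts (breaking the within-transcript pairing of the two marks),
    recomputes per-transcript ratios, and pools them; ratios from all rounds
    form the null. ``counts`` should already be signal-filtered so the null
    is built on the same universe that is labeled.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 transcripts to build a permutation null")
    me1 = np.array([c.me1 for c in counts], dtype=float) + pseudocount
    me3 = np.array([c.me3 for c in counts], dtype=float) + pseudocount
    n = len(counts)
    rng = np.random.default_rng(seed)
    pooled = np.empty(n * n_perm, dtype=float)
    for r in range(n_perm):
        pooled[r * n : (r + 1) * n] = me1[rng.permutation(n)] / me3[rng.permutation(n)]
    pooled.sort()
    return PermutationNull(ratios=pooled, n_perm=n_perm, seed=seed)


def label_transcripts(
    counts: Sequence[MarkCounts],
    null: PermutationNull,
    min_signal: int = 10,
    hi_pct: float = 95.0,
    lo_pct: float = 5.0,
    pseudocount: float = 1.0,
) -> list[ConfidenceLabel]:
    """Assign high-confidence labels against the permutation null.

    *excluded* if both marks are below ``min_signal``; *elinc* if the
    observed ratio is strictly above the ``hi_pct`` nearest-rank quantile of
    the null; *canonical* if strictly below the ``lo_pct`` quantile;
    *unlabeled* otherwise.
    """
    if not (0.0 < lo_pct < hi_pct < 100.0):
        raise ValueError("require 0 < lo_pct < hi_pct < 100")
    hi = null._nearest_rank(hi_pct)
    lo = null._nearest_rank(lo_pct)
    out = []
    for c in counts:
        ratio = observed_ratio(c, pseudocount)
        pct = null.percentile_of(ratio)
        if max(c.me1, c.me3) < min_signal:
            label = "excluded"
        elif ratio > hi:
            label = "elinc"
        elif ratio < lo:
            label = "canonical"
        else:
            label = "unlabeled"
        out.append(ConfidenceLabel(c.transcript_id, label, ratio, pct))
    return out


def label_high_confidence(
    counts: Sequence[MarkCounts],
    n_perm: int = 10_000,
    seed: int = 0,
    min_signal: int = 10,
    hi_pct: float = 95.0,
    lo_pct: float = 5.0,
    pseudocount: float = 1.0,
) -> tuple[list[ConfidenceLabel], PermutationNull | None]:
    """Filter, build the null on the filtered universe, and label everything.

    Transcripts failing the signal filter are reported as *excluded* and do
    not contribute to the null. If fewer than two transcripts pass the
    filter there is no universe to permute: everything is excluded or
    unlabeled and the returned null is ``None``.
    """
    kept = filter_by_signal(counts, min_signal)
    if len(kept) < 2:
        labels = [
            ConfidenceLabel(
                c.transcript_id,
                "excluded" if max(c.me1, c.me3) < min_signal else "unlabeled",
                observed_ratio(c, pseudocount),
                float("nan"),
            )
            for c in counts
        ]
        return labels, None
    null = build_null(kept, n_perm=n_perm, seed=seed, pseudocount=pseudocount)
    return (
        label_transcripts(counts, null, min_signal, hi_pct, lo_pct, pseudocount),
        null,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_markcounts_tsv(path: str | Path) -> list[MarkCounts]:
    """Read (transcript_id, me1, me3) from a TSV with or without a header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    try:
        int(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    return [
        MarkCounts(row.iloc[0], int(row.iloc[1]), int(row.iloc[2]))
        for _, row in df.iterrows()
    ]


def labels_to_frame(labels: Sequence[ConfidenceLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [l.transcript_id for l in labels],
            "label": [l.label for l in labels],
            "observed_ratio": [l.observed_ratio for l in labels],
            "percentile": [l.percentile for l in labels],
        }
    )


def write_labels_tsv(labels: Sequence[ConfidenceLabel], path: str | Path) -> None:
    labels_to_frame(labels).to_csv(path, sep="\t", index=False)
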