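"""Per-assay signal tracks and the three primitive region statistics.

A :class:`SignalTrack` holds one assay's data in one of three kinds:

* ``reads`` — read alignment intervals (BED); supports :func:`count_reads`
  and :func:`coverage_ratio`.
* ``coverage`` — covered intervals, e.g. from a bedGraph or an annotation
  BED (CpG islands, repeats, peaks); supports :func:`coverage_ratio`.
* ``beta`` — per-position DNA-methylation beta values in [0, 1]; supports
  :func:`mean_beta`.

Coverage ratio is the base-level fraction of a region overlapped by at least
one track interval — a fraction of bases, not a depth average. bedGraph rows
with value >= ``min_value`` (default 1 read) count as covered.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

KINDS = ("reads", "coverage", "beta")


class SignalTrack:
    """Range-query-indexed signal for one assay."""

    def __init__(self, assay: str, kind: str):
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
        self.assay = assay
        self.kind = kind
        self._trees: dict[str, IntervalTree] = {}
        # beta storage: chrom -> (sorted positions, values)
        self._beta_pos: dict[str, np.ndarray] = {}
        self._beta_val: dict[str, np.ndarray] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_intervals(
        cls, assay: str, kind: str, intervals: Iterable[GenomicInterval]
    ) -> "SignalTrack":
        if kind == "beta":
            raise ValueError("use from_beta for beta tracks")
        track = cls(assay, kind)
        for iv in intervals:
            track._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        return track

    @classmethod
    def from_beta(
        cls, assay: str, sites: Iterable[tuple[str, int, float]]
    ) -> "SignalTrack":
        """Build a beta track from (chrom, position, beta) triples."""
        track = cls(assay, "beta")
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for chrom, pos, beta in sites:
            if not (0.0 <= beta <= 1.0):
                raise ValueError(f"beta value {beta} at {chrom}:{pos} outside [0, 1]")
            by_chrom.setdefault(chrom, []).append((pos, beta))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            track._beta_pos[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            track._beta_val[chrom] = np.array([b for _, b in pairs], dtype=float)
        return track

    @classmethod
    def from_bed(cls, path: str | Path, assay: str, kind: str = "reads") -> "SignalTrack":
        """Read a BED3+ file of read or covered intervals."""
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                try:
                    ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
                except (ValueError, IndexError):
                    log.warning("%s:%d: skipping malformed BED line", path, lineno)
        return cls.from_intervals(assay, kind, ivs)

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, assay: str, min_value: float = 1.0
    ) -> "SignalTrack":
        """Read a 4-column bedGraph as a coverage track.

        Intervals whose value is >= ``min_value`` are treated as covered.
        """
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                try:
                    chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
                except (ValueError, IndexError):
                    log.warning("%s:%d: skipping malformed bedGraph line", path, lineno)
                    continue
                if value >= min_value:
                    ivs.append(GenomicInterval(chrom, start, end))
        return cls.from_intervals(assay, "coverage", ivs)

    @classmethod
    def from_beta_file(cls, path: str | Path, assay: str = "DNAme") -> "SignalTrack":
        """Read a methylation track: tab-separated (chrom, pos, beta) rows."""
        sites = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                try:
                    sites.append((f[0], int(f[1]), float(f[2])))
                except (ValueError, IndexError):
                    log.warning("%s:%d: skipping malformed beta line", path, lineno)
        return cls.from_beta(assay, sites)

    # -- queries ------------------------------------------------------------

    def intervals_in(self, region: GenomicInterval) -> list[tuple[int, int]]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        return [(max(iv.begin, region.start), min(iv.end, region.end))
                for iv in tree.overlap(region.start, region.end)]

    def __len__(self) -> int:
        if self.kind == "beta":
            return sum(len(p) for p in self._beta_pos.values())
        return sum(len(t) for t in self._trees.values())

    def __repr__(self) -> str:
        return f"SignalTrack({self.assay!r}, kind={self.kind!r}, n={len(self)})"


def count_reads(track: SignalTrack, region: GenomicInterval) -> int:
    """Number of read intervals overlapping ``region`` by >= 1 bp."""
    if track.kind != "reads":
        raise ValueError(f"count_reads requires a reads track, got {track.kind!r}")
    tree = track._trees.get(region.chrom)
    if tree is None:
        return 0
    return len(tree.overlap(region.start, region.end))


def coverage_ratio(track: SignalTrack, region: GenomicInterval) -> float:
    """Fraction of ``region`` bases overlapped by >= 1 track interval."""
    if track.kind == "beta":
        raise ValueError("coverage_ratio is undefined for beta tracks")
    if region.width <= 0:
        raise ValueError("region must have positive width")
    clipped = sorted(track.intervals_in(region))
    covered = 0
    cur_start, cur_end = None, None
    for s, e in clipped:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / region.width


def mean_beta(track: SignalTrack, region: GenomicInterval) -> float | None:
    """Mean beta over positions in ``region``; ``None`` if no positions."""
    if track.kind != "beta":
        raise ValueError(f"mean_beta requires a beta track, got {track.kind!r}")
    pos = track._beta_pos.get(region.chrom)
    if pos is None:
        return None
    lo = np.searchsorted(pos, region.start, side="left")
    hi = np.searchsorted(pos, region.end, side="left")
    if hi == lo:
        return None
    return float(track._beta_val[region.chrom][lo:hi].mean())


def region_statistic(track: SignalTrack, region: GenomicInterval) -> float:
    """The track's natural region summary: mean beta for beta tracks
    (missing imputed to 0), base-coverage fraction otherwise."""
    if track.kind == "beta":
        value = mean_beta(track, region)
        if value is None:
            log.debug("no beta positions in %s:%d-%d; imputing 0",
                      region.chrom, region.start, region.end)
            return 0.0
        return value
    return coverage_ratio(track, region)
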