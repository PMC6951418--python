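"""Assemble the transcripts x features table.

Each feature is a (region, assay) pair: the region is the TSS interval or
the gene body, and the statistic is the base-coverage fraction for histone
marks, transcription factors, CpG islands and repeats, or the mean
methylation beta for DNA-methylation tracks. All values lie in [0, 1], so
no further scaling is needed before regression.

Feature columns are named ``<Region>_<Assay>`` with Region in {TSS, Body},
e.g. ``TSS_H3K4me1``, ``Body_DNAme``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Transcript, make_body_region, make_tss_interval
from .signal import SignalTrack, region_statistic

log = logging.getLogger(__name__)

REGIONS = ("TSS", "Body")


@dataclass(frozen=True)
class FeatureSpec:
    name: str  # "<Region>_<Assay>"
    region: str
    assay: str
    statistic: str  # coverage_ratio | mean_beta


class FeatureMatrix:
    """Transcripts x named features, all values in [0, 1]."""

    def __init__(self, values: pd.DataFrame, specs: Sequence[FeatureSpec] | None = None):
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("feature matrix contains non-finite values")
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("feature values must lie in [0, 1]")
        self.values = values
        self.specs = list(specs) if specs is not None else [
            _spec_from_name(c) for c in values.columns
        ]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        return cls(df)

    def __repr__(self) -> str:
        return f"FeatureMatrix({self.shape[0]} transcripts x {self.shape[1]} features)"


def _spec_from_name(name: str) -> FeatureSpec:
    region, _, assay = name.partition("_")
    if region not in REGIONS or not assay:
        raise ValueError(f"feature name {name!r} is not of the form <Region>_<Assay>")
    return FeatureSpec(name, region, assay, "unknown")


def build_features(
    transcripts: Sequence[Transcript],
    tracks: Mapping[str, SignalTrack],
    annotations: Mapping[str, Sequence[GenomicInterval]] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    flank: int = 500,
) -> FeatureMatrix:
    """One column per (region, assay) over every transcript.

    ``tracks`` maps assay name to a signal track (coverage, reads, or beta);
    ``annotations`` maps annotation names (CGI, repeat classes, ...) to
    interval lists, turned into coverage tracks internally. Transcripts too
    short to have a gene body are dropped with a log entry.
    """
    all_tracks: dict[str, SignalTrack] = dict(tracks)
    for name, ivs in (annotations or {}).items():
        if name in all_tracks:
            raise ValueError(f"assay name collision: {name!r}")
        all_tracks[name] = SignalTrack.from_intervals(name, "coverage", ivs)
    if not all_tracks:
        raise ValueError("no assays given")

    specs = []
    for assay in all_tracks:
        stat = "mean_beta" if all_tracks[assay].kind == "beta" else "coverage_ratio"
        for region in REGIONS:
            specs.append(FeatureSpec(f"{region}_{assay}", region, assay, stat))

    rows, ids = [], []
    for t in transcripts:
        try:
            body = make_body_region(t, flank)
        except ValueError:
            log.info("dropping %s: no gene body at flank %d", t.id, flank)
            continue
        clen = chrom_lengths.get(t.chrom) if chrom_lengths else None
        tss = make_tss_interval(t, flank, clen)
        regions = {"TSS": tss, "Body": body}
        rows.append(
            [region_statistic(all_tracks[s.assay], regions[s.region]) for s in specs]
        )
        ids.append(t.id)

    df = pd.DataFrame(rows, index=ids, columns=[s.name for s in specs], dtype=float)
    return FeatureMatrix(df, specs)


def subset_features(m: FeatureMatrix, names: Sequence[str]) -> FeatureMatrix:
    """Column-subset of a feature matrix, row order preserved."""
    if len(names) == 0:
        raise ValueError("empty feature selection")
    missing = [n for n in names if n not in m.values.columns]
    if missing:
        raise KeyError(f"unknown feature(s): {missing}")
    specs = {s.name: s for s in m.specs}
    return FeatureMatrix(m.values[list(names)], [specs[n] for n in names])
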