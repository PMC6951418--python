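"""Synthetic genomes, transcripts and signal tracks for desk-scale runs.

The generator emulates the statistical structure the classifier assumes:
two transcript classes (enhancer-associated vs canonical) whose TSS and
gene-body regions differ in coverage of specific assays and in DNA
methylation, in the directions of the published coefficient signs:

* higher in the elincRNA class: TSS and body DNA methylation, TSS H3K4me1,
  body H3K122ac;
* higher in the canonical class: body H3K36me3, TSS H3K9ac, TSS H3K4me3;
* uninformative: the remaining region-assay pairs and ``n_noise_assays``
  extra assays, identically distributed in both classes.

Per-transcript target fractions are drawn from class-specific Beta
distributions (mean per class, shared concentration) and realized as a
single contiguous covered interval sized to the drawn fraction, so the
region's base-coverage fraction reproduces the draw exactly (up to 1-bp
rounding). Methylation is realized as evenly spaced probes all carrying the
drawn beta. The two H3K4 marks are additionally emitted as raw read
intervals with class-dependent Poisson counts in the TSS window, so the
permutation labeler can be exercised end to end. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    Transcript,
    make_body_region,
    make_tss_interval,
    write_bed12,
)
from .labeling import MarkCounts
from .signal import SignalTrack

#: Beta-distribution means per planted feature, (elinc, canonical).
DEFAULT_CLASS_MEANS: dict[str, tuple[float, float]] = {
    "TSS_DNAme": (0.8, 0.2),
    "TSS_H3K4me1": (0.8, 0.2),
    "Body_DNAme": (0.8, 0.2),
    "Body_H3K122ac": (0.8, 0.2),
    "Body_H3K36me3": (0.2, 0.8),
    "TSS_H3K9ac": (0.2, 0.8),
    "TSS_H3K4me3": (0.2, 0.8),
}

INFORMATIVE_ASSAYS = ("DNAme", "H3K4me1", "H3K4me3", "H3K9ac", "H3K36me3", "H3K122ac")


@dataclass
class SimConfig:
    seed: int = 0
    n_per_class: int = 200
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrSim1": 3_000_000, "chrSim2": 3_000_000}
    )
    flank: int = 500
    length_range: tuple[int, int] = (2_000, 8_000)
    min_gap: int = 2_000
    concentration: float = 20.0
    # TSS read depths for the H3K4 marks (Poisson means)
    elinc_me1_depth: float = 100.0
    elinc_me3_depth: float = 25.0
    canonical_me1_depth: float = 25.0
    canonical_me3_depth: float = 100.0
    read_length: int = 50
    n_probes_per_region: int = 5
    n_noise_assays: int = 5
    class_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )

    def __post_init__(self) -> None:
        for name, (m_e, m_c) in self.class_means.items():
            if not (0.0 < m_e < 1.0 and 0.0 < m_c < 1.0):
                raise ValueError(f"class means for {name} must lie in (0, 1)")
        for d in (
            self.elinc_me1_depth,
            self.elinc_me3_depth,
            self.canonical_me1_depth,
            self.canonical_me3_depth,
        ):
            if d <= 0:
                raise ValueError("read depths must be positive")

    @property
    def assays(self) -> list[str]:
        return list(INFORMATIVE_ASSAYS) + [
            f"noise{i + 1}" for i in range(self.n_noise_assays)
        ]


@dataclass
class SimTruth:
    classes: pd.Series  # transcript_id -> elinc | canonical
    planted_direction: dict[str, int]  # feature name -> +1 / -1 / 0

    def to_tsv(self, path: str | Path) -> None:
        self.classes.rename("true_class").to_csv(
            path, sep="\t", index_label="transcript_id"
        )


@dataclass
class SimResult:
    transcripts: list[Transcript]
    tracks: dict[str, SignalTrack]  # feature tracks: coverage + beta
    read_tracks: dict[str, SignalTrack]  # raw reads for H3K4me1 / H3K4me3
    truth: SimTruth
    expression: pd.DataFrame  # columns: transcript_id, fpkm
    config: SimConfig

    def mark_counts(self) -> list[MarkCounts]:
        """TSS-window H3K4 read counts, as the labeler consumes them."""
        from .signal import count_reads

        out = []
        for t in self.transcripts:
            tss = make_tss_interval(
                t, self.config.flank, self.config.chrom_lengths[t.chrom]
            )
            out.append(
                MarkCounts(
                    t.id,
                    count_reads(self.read_tracks["H3K4me1"], tss),
                    count_reads(self.read_tracks["H3K4me3"], tss),
                )
            )
        return out


def _place_transcripts(config: SimConfig, rng: np.random.Generator) -> list[Transcript]:
    """Place non-overlapping transcripts sequentially with random gaps."""
    n_total = 2 * config.n_per_class
    chroms = list(config.chrom_lengths)
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, n_total)
    transcripts = []
    ci = 0
    pos = config.min_gap
    for i in range(n_total):
        length = int(lengths[i])
        gap = int(rng.integers(config.min_gap, 2 * config.min_gap))
        while ci < len(chroms) and pos + length + config.min_gap > config.chrom_lengths[chroms[ci]]:
            ci += 1
            pos = config.min_gap
        if ci >= len(chroms):
            raise ValueError(
                "cannot place transcripts without overlap: chromosomes too short "
                "for the requested number/length of transcripts"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chroms[ci], pos, pos + length, strand)
        transcripts.append(Transcript(f"sim{i:04d}", iv))
        pos += length + gap
    return transcripts


def _mean_for(config: SimConfig, region: str, assay: str, cls: str) -> float:
    name = f"{region}_{assay}"
    if name in config.class_means:
        m_e, m_c = config.class_means[name]
        return m_e if cls == "elinc" else m_c
    return 0.5


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate transcripts, feature tracks, H3K4 read tracks and truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    transcripts = _place_transcripts(config, rng)

    n_total = len(transcripts)
    classes = np.array(["elinc", "canonical"]).repeat(config.n_per_class)
    classes = classes[rng.permutation(n_total)]

    cover_ivs: dict[str, list[GenomicInterval]] = {a: [] for a in config.assays if a != "DNAme"}
    beta_sites: list[tuple[str, int, float]] = []
    read_ivs: dict[str, list[GenomicInterval]] = {"H3K4me1": [], "H3K4me3": []}

    conc = config.concentration
    for t, cls in zip(transcripts, classes):
        clen = config.chrom_lengths[t.chrom]
        regions = {
            "TSS": make_tss_interval(t, config.flank, clen),
            "Body": make_body_region(t, config.flank),
        }
        for region_name, region in regions.items():
            for assay in config.assays:
                mean = _mean_for(config, region_name, assay, cls)
                frac = float(rng.beta(mean * conc, (1 - mean) * conc))
                if assay == "DNAme":
                    positions = np.linspace(
                        region.start, region.end - 1, config.n_probes_per_region
                    ).astype(int)
                    beta_sites.extend((t.chrom, int(p), frac) for p in np.unique(positions))
                else:
                    cov_len = int(round(frac * region.width))
                    if cov_len > 0:
                        off = int(rng.integers(0, region.width - cov_len + 1))
                        cover_ivs[assay].append(
                            GenomicInterval(
                                t.chrom, region.start + off, region.start + off + cov_len
                            )
                        )
        # raw H3K4 reads in the TSS window, class-dependent depths
        tss = regions["TSS"]
        depths = {
            "H3K4me1": config.elinc_me1_depth if cls == "elinc" else config.canonical_me1_depth,
            "H3K4me3": config.elinc_me3_depth if cls == "elinc" else config.canonical_me3_depth,
        }
        for mark, depth in depths.items():
            n_reads = int(rng.poisson(depth))
            if n_reads:
                starts = rng.integers(
                    tss.start, max(tss.start + 1, tss.end - config.read_length), n_reads
                )
                read_ivs[mark].extend(
                    GenomicInterval(t.chrom, int(s), int(s) + config.read_length)
                    for s in starts
                )

    tracks = {
        assay: SignalTrack.from_intervals(assay, "coverage", ivs)
        for assay, ivs in cover_ivs.items()
    }
    tracks["DNAme"] = SignalTrack.from_beta("DNAme", beta_sites)
    read_tracks = {
        mark: SignalTrack.from_intervals(mark, "reads", ivs)
        for mark, ivs in read_ivs.items()
    }

    fpkm = rng.lognormal(mean=1.0, sigma=0.8, size=n_total)
    for t, f in zip(transcripts, fpkm):
        t.fpkm = float(f)
    expression = pd.DataFrame(
        {"transcript_id": [t.id for t in transcripts], "fpkm": fpkm}
    )

    planted = {name: (1 if m[0] > m[1] else -1) for name, m in config.class_means.items()}
    truth = SimTruth(
        classes=pd.Series(classes, index=[t.id for t in transcripts]),
        planted_direction=planted,
    )
    return SimResult(transcripts, tracks, read_tracks, truth, expression, config)


def make_null_markcounts(
    n: int, mean: float, seed: int = 0
) -> list[MarkCounts]:
    """Exchangeable null: me1 and me3 iid Poisson(mean) per transcript."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    rng = np.random.default_rng(seed)
    me1 = rng.poisson(mean, n)
    me3 = rng.poisson(mean, n)
    return [MarkCounts(f"null{i:05d}", int(a), int(b)) for i, (a, b) in enumerate(zip(me1, me3))]


def write_outputs(result: SimResult, outdir: str | Path) -> None:
    """Write all simulated data in the formats the other modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed12(result.transcripts, outdir / "transcripts.bed12")
    with open(outdir / "chrom_lengths.tsv", "w") as fh:
        for chrom, length in result.config.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    result.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    result.truth.to_tsv(outdir / "truth.tsv")
    for assay, track in result.tracks.items():
        if track.kind == "beta":
            with open(outdir / f"{assay}.beta.tsv", "w") as fh:
                for chrom in sorted(track._beta_pos):
                    for pos, val in zip(track._beta_pos[chrom], track._beta_val[chrom]):
                        fh.write(f"{chrom}\t{pos}\t{val:.6f}\n")
        else:
            with open(outdir / f"{assay}.bedgraph", "w") as fh:
                for chrom in sorted(track._trees):
                    for iv in sorted(track._trees[chrom]):
                        fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\t1\n")
    for mark, track in result.read_tracks.items():
        with open(outdir / f"{mark}.reads.bed", "w") as fh:
            for chrom in sorted(track._trees):
                for iv in sorted(track._trees[chrom]):
                    fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))
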