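"""End-to-end workflow: filter -> label -> features -> train -> evaluate -> predict.

Reads a flat key=value config, runs every stage in order on files already on
disk (typically produced by ``elincnet simulate`` or by upstream processing),
and writes each stage's artifact plus a manifest recording the config hash
and seed. All randomness flows from the single top-level seed through fixed
per-stage offsets, so a rerun with the same config and seed reproduces every
artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evaluation, labeling, regnet
from .features import build_features
from .intervals import (
    attach_expression,
    expressed_filter,
    make_tss_interval,
    read_bed12,
    read_expression_tsv,
)
from .labeling import MarkCounts
from .signal import SignalTrack, count_reads
from .simulate import read_chrom_lengths

log = logging.getLogger(__name__)

SEED_OFFSETS = {"label": 11, "train": 23, "evaluate": 37}


@dataclass
class RunConfig:
    indir: Path
    outdir: Path
    seed: int = 0
    flank: int = 500
    min_fpkm: float = 0.5
    min_signal: int = 10
    hi_pct: float = 95.0
    lo_pct: float = 5.0
    n_perm: int = 10_000
    alpha: str | float = "auto"
    alphas: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    folds: int = 10
    n_lambda: int = 100
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file."""
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs: dict = {"raw": dict(raw)}
        kwargs["indir"] = Path(raw.pop("indir"))
        kwargs["outdir"] = Path(raw.pop("outdir"))
        for key, cast in [
            ("seed", int), ("flank", int), ("min_fpkm", float), ("min_signal", int),
            ("hi_pct", float), ("lo_pct", float), ("n_perm", int), ("folds", int),
            ("n_lambda", int),
        ]:
            if key in raw:
                kwargs[key] = cast(raw.pop(key))
        if "alpha" in raw:
            a = raw.pop("alpha")
            kwargs["alpha"] = a if a == "auto" else float(a)
        if "alphas" in raw:
            kwargs["alphas"] = tuple(float(x) for x in raw.pop("alphas").split(","))
        return cls(**kwargs)

    def digest(self) -> str:
        keys = {
            k: str(v)
            for k, v in self.__dict__.items()
            if k not in ("raw", "outdir")
        }
        return hashlib.sha256(json.dumps(keys, sort_keys=True).encode()).hexdigest()


def compute_mark_counts(transcripts, read_tracks, chrom_lengths, flank=500):
    """H3K4me1/H3K4me3 read counts in each transcript's TSS window."""
    counts = []
    for t in transcripts:
        tss = make_tss_interval(t, flank, chrom_lengths.get(t.chrom))
        counts.append(
            MarkCounts(
                t.id,
                count_reads(read_tracks["H3K4me1"], tss),
                count_reads(read_tracks["H3K4me3"], tss),
            )
        )
    return counts


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Expects in ``config.indir`` the files ``elincnet simulate`` writes:
    transcripts.bed12, chrom_lengths.tsv, expression.tsv, ``<assay>.bedgraph``
    coverage tracks, ``DNAme.beta.tsv``, and ``<mark>.reads.bed`` for the two
    H3K4 marks.
    """
    indir, outdir = Path(config.indir), Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name):
        log.info("stage: %s", name)

    # -- load + expression filter
    stage("filter")
    transcripts = read_bed12(indir / "transcripts.bed12")
    chrom_lengths = read_chrom_lengths(indir / "chrom_lengths.tsv")
    fpkm = read_expression_tsv(indir / "expression.tsv")
    transcripts = attach_expression(transcripts, fpkm)
    expressed = expressed_filter(transcripts, config.min_fpkm)
    log.info("%d/%d transcripts expressed", len(expressed), len(transcripts))

    # -- permutation labeling
    stage("label")
    read_tracks = {
        mark: SignalTrack.from_bed(indir / f"{mark}.reads.bed", mark, "reads")
        for mark in ("H3K4me1", "H3K4me3")
    }
    counts = compute_mark_counts(expressed, read_tracks, chrom_lengths, config.flank)
    labels, _ = labeling.label_high_confidence(
        counts,
        n_perm=config.n_perm,
        seed=config.seed + SEED_OFFSETS["label"],
        min_signal=config.min_signal,
        hi_pct=config.hi_pct,
        lo_pct=config.lo_pct,
    )
    labeling.write_labels_tsv(labels, outdir / "labels.tsv")
    artifacts["labels"] = "labels.tsv"
    by_label = {l.transcript_id: l.label for l in labels}

    # -- features
    stage("features")
    tracks: dict[str, SignalTrack] = {}
    for bg in sorted(indir.glob("*.bedgraph")):
        assay = bg.stem
        tracks[assay] = SignalTrack.from_bedgraph(bg, assay)
    for bt in sorted(indir.glob("*.beta.tsv")):
        assay = bt.name.replace(".beta.tsv", "")
        tracks[assay] = SignalTrack.from_beta_file(bt, assay)
    features = build_features(expressed, tracks, chrom_lengths=chrom_lengths,
                              flank=config.flank)
    features.to_tsv(outdir / "features.tsv")
    artifacts["features"] = "features.tsv"

    # -- train on the high-confidence set
    stage("train")
    train_ids = [
        i for i in features.transcript_ids if by_label.get(i) in ("elinc", "canonical")
    ]
    if len(set(by_label[i] for i in train_ids)) < 2:
        raise RuntimeError("train: high-confidence set does not contain both classes")
    Xtrain = features.values.loc[train_ids]
    y_labels = [by_label[i] for i in train_ids]
    y = regnet.response_vector(y_labels)
    model, path = regnet.train(
        Xtrain, y,
        alpha=config.alpha, alphas=config.alphas,
        k=config.folds, n_lambda=config.n_lambda,
        seed=config.seed + SEED_OFFSETS["train"],
    )
    model.to_json(outdir / "model.json")
    artifacts["model"] = "model.json"

    # -- evaluate by outer CV on the training set
    stage("evaluate")
    pooled, _ = evaluation.cross_validate(
        Xtrain, y_labels,
        fit_config={"alpha": model.alpha, "n_lambda": config.n_lambda},
        k=config.folds,
        seed=config.seed + SEED_OFFSETS["evaluate"],
    )
    evaluation.write_metrics_tsv(pooled, outdir / "cv_metrics.tsv")
    artifacts["cv_metrics"] = "cv_metrics.tsv"

    # -- predict the transcripts outside the high-confidence set
    stage("predict")
    rest_ids = [i for i in features.transcript_ids if i not in set(train_ids)]
    scores = regnet.score(model, features.values.loc[rest_ids]) if rest_ids else []
    classes = regnet.classify(model, features.values.loc[rest_ids]) if rest_ids else []
    pd.DataFrame(
        {"transcript_id": rest_ids, "score": scores, "predicted_class": classes}
    ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    artifacts["predictions"] = "predictions.tsv"

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_transcripts": len(transcripts),
        "n_expressed": len(expressed),
        "n_train": len(train_ids),
        "alpha": model.alpha,
        "lambda": model.lam,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
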