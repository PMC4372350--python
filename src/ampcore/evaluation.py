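"""Residue-level metrics, family-level k-fold CV, and feature ablation.

The positive class is CRITICAL.  Cross-validation splits *families* (one
labeled carrier each) across folds, never residues, so near-duplicate
context cannot leak between train and test.  Fold confusion counts are
pooled before the metrics are computed once; per-fold rows are kept so the
averaged view is recoverable too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import crf
from .families import CRITICAL
from .features import (
    CHANNELS,
    DEFAULT_CONFIG,
    FeatureConfig,
    FeatureTracks,
    align_track,
    gapless_search,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


class LabelLengthError(ValueError):
    pass


def confusion(pred: Sequence[str], gold: Sequence[str]) -> ConfusionCounts:
    """Residue-level confusion counts with CRITICAL as the positive class."""
    if len(pred) != len(gold):
        raise LabelLengthError(
            f"prediction has {len(pred)} labels, gold has {len(gold)}"
        )
    tp = tn = fp = fn = 0
    for p, g in zip(pred, gold):
        if g == CRITICAL:
            if p == CRITICAL:
                tp += 1
            else:
                fn += 1
        else:
            if p == CRITICAL:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


@dataclass(frozen=True)
class MetricRow:
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    mcc: float
    degenerate_mcc: bool = False


def metrics(c: ConfusionCounts) -> MetricRow:
    """Sensitivity TP/(TP+FN), specificity TN/(FP+TN), accuracy, and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Percentages are on the 0-100 scale.  A zero marginal makes the MCC
    denominator vanish; the conventional value 0 is returned with a flag.
    """
    if c.total == 0:
        raise ValueError("metrics of an empty confusion table")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = 100.0 * c.tn / (c.fp + c.tn) if (c.fp + c.tn) else 0.0
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return MetricRow(sens, spec, acc, 0.0, degenerate_mcc=True)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricRow(sens, spec, acc, mcc)


# -- cross-validation ---------------------------------------------------------


@dataclass(frozen=True)
class CVRecord:
    """One family's training item: labeled carrier tracks plus its core.

    ``tracks`` may carry a placeholder ALIGN channel; cross-validation
    recomputes ALIGN per fold against the training-fold core database.
    """

    family_id: str
    tracks: FeatureTracks
    labels: tuple[str, ...]
    core: str


@dataclass(frozen=True)
class EvalReport:
    feature_set: tuple[str, ...]
    pooled: MetricRow
    counts: ConfusionCounts
    per_fold: tuple[MetricRow, ...]

    @property
    def mcc(self) -> float:
        return self.pooled.mcc


def kfold_split(family_ids: Sequence[str], k: int = 10, seed: int = 0) -> list[int]:
    """Deterministic family-level fold assignment; sizes differ by <= 1.

    Returns one fold index per input family (input order preserved).
    """
    n = len(family_ids)
    if n < k:
        raise ValueError(f"{n} families cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    # permute by family id so the assignment is input-order invariant
    order = sorted(range(n), key=lambda i: family_ids[i])
    perm = rng.permutation(n)
    assignment = [0] * n
    for pos, oi in enumerate(perm):
        assignment[order[oi]] = pos % k
    return assignment


def fold_align_tracks(
    records: Sequence[CVRecord],
    assignment: Sequence[int],
    k: int,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> list[list[FeatureTracks]]:
    """Per fold, recompute every record's ALIGN channel against the core
    database of the *training* families of that fold (no self-hits for
    held-out families)."""
    out: list[list[FeatureTracks]] = []
    for fold in range(k):
        core_db = [
            (r.family_id, r.core)
            for r, a in zip(records, assignment)
            if a != fold
        ]
        fold_tracks = []
        for r in records:
            seq = "".join(r.tracks.channels["PRIMARY"])
            hits = gapless_search(
                seq,
                r.tracks.sequence_id,
                core_db,
                min_run_length=config.align_min_run,
                min_normalized_score=config.align_min_norm_score,
            )
            channels = dict(r.tracks.channels)
            channels["ALIGN"] = tuple(align_track(seq, hits, config))
            fold_tracks.append(
                FeatureTracks(
                    sequence_id=r.tracks.sequence_id,
                    length=r.tracks.length,
                    channels=channels,
                )
            )
        out.append(fold_tracks)
    return out


def cross_validate(
    records: Sequence[CVRecord],
    templates: Sequence[crf.FeatureTemplate] | str = "default",
    k: int = 10,
    seed: int = 0,
    l2_sigma2: float = 10.0,
    max_iter: int = 100,
    config: FeatureConfig = DEFAULT_CONFIG,
    exclude_channel: str | None = None,
    _fold_tracks: Sequence[Sequence[FeatureTracks]] | None = None,
) -> EvalReport:
    """Family-level k-fold cross-validation of the CRF labeler."""
    if isinstance(templates, str):
        templates = crf.load_templates(templates)
    if exclude_channel is not None:
        templates = crf.drop_channel(templates, exclude_channel)
        feature_set = tuple(c for c in CHANNELS if c != exclude_channel)
    else:
        feature_set = CHANNELS
    assignment = kfold_split([r.family_id for r in records], k=k, seed=seed)
    if _fold_tracks is None:
        _fold_tracks = fold_align_tracks(records, assignment, k, config)

    pooled = ConfusionCounts()
    per_fold: list[MetricRow] = []
    for fold in range(k):
        tracks_f = _fold_tracks[fold]
        train_set = [
            (tracks_f[i], list(records[i].labels))
            for i in range(len(records))
            if assignment[i] != fold
        ]
        test_idx = [i for i in range(len(records)) if assignment[i] == fold]
        result = crf.train(
            train_set, templates=templates, l2_sigma2=l2_sigma2, max_iter=max_iter
        )
        fold_counts = ConfusionCounts()
        for i in test_idx:
            pred = crf.viterbi(result.model, tracks_f[i])
            fold_counts = fold_counts + confusion(pred, records[i].labels)
        pooled = pooled + fold_counts
        per_fold.append(metrics(fold_counts))
    return EvalReport(
        feature_set=feature_set,
        pooled=metrics(pooled),
        counts=pooled,
        per_fold=tuple(per_fold),
    )


def ablation(
    records: Sequence[CVRecord],
    channels: Sequence[str] = CHANNELS,
    templates: Sequence[crf.FeatureTemplate] | str = "default",
    k: int = 10,
    seed: int = 0,
    l2_sigma2: float = 10.0,
    max_iter: int = 100,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, EvalReport]:
    """One-feature-at-a-time ablation: the full set plus one row per
    left-out channel.  Keys: ``"All"`` and ``"- <channel>"``."""
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    if isinstance(templates, str):
        templates = crf.load_templates(templates)
    assignment = kfold_split([r.family_id for r in records], k=k, seed=seed)
    fold_tracks = fold_align_tracks(records, assignment, k, config)
    common = dict(
        k=k, seed=seed, l2_sigma2=l2_sigma2, max_iter=max_iter, config=config,
        _fold_tracks=fold_tracks,
    )
    out: dict[str, EvalReport] = {}
    out["All"] = cross_validate(records, templates, **common)
    for ch in channels:
        out[f"- {ch}"] = cross_validate(
            records, templates, exclude_channel=ch, **common
        )
    return out


def ablation_table(reports: Mapping[str, EvalReport]) -> str:
    """TSV rendering with Features / Sensitivity / Specificity / Accuracy /
    MCC columns, one row per configuration."""
    lines = ["Features\tSensitivity\tSpecificity\tAccuracy\tMCC"]
    for name, rep in reports.items():
        m = rep.pooled
        lines.append(
            f"{name}\t{m.sensitivity:.1f}\t{m.specificity:.1f}"
            f"\t{m.accuracy:.1f}\t{m.mcc:.2f}"
        )
    return "\n".join(lines) + "\n"
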