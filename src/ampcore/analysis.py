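"""Descriptive statistics of cores versus background.

Compares the labeled critical regions (cores) of a corpus with a background
population — by default the full carrier sequences, switchable to only
their non-critical residues — over amino-acid composition, secondary
structure, net charge and amphipathicity, plus a positional log-odds
analysis of the residues flanking the core boundaries (the residue just
outside the core, P(-1), against the first residue inside it, P1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .families import CRITICAL, LabeledSequence
from .features import (
    DEFAULT_CONFIG,
    FeatureConfig,
    PropensityScale,
    hydrophobic_moment,
    load_scale,
    net_charge,
)
from .sequences import ALPHABET

Background = Literal["carrier", "noncritical"]


@dataclass(frozen=True)
class DistributionSummary:
    """Per-group distribution of one variable for CORE vs BACKGROUND."""

    variable: str
    core: pd.DataFrame  # per-sequence rows, per-category columns
    background: pd.DataFrame

    @property
    def core_mean(self) -> pd.Series:
        return self.core.mean()

    @property
    def core_median(self) -> pd.Series:
        return self.core.median()

    @property
    def background_mean(self) -> pd.Series:
        return self.background.mean()

    @property
    def background_median(self) -> pd.Series:
        return self.background.median()


def _split_populations(
    labeled: Sequence[LabeledSequence], background: Background
) -> tuple[list[str], list[str]]:
    cores, bgs = [], []
    for ls in labeled:
        res = ls.sequence.residues
        core = "".join(r for r, l in zip(res, ls.labels) if l == CRITICAL)
        if background == "carrier":
            bg = res
        else:
            bg = "".join(r for r, l in zip(res, ls.labels) if l != CRITICAL)
        cores.append(core)
        bgs.append(bg)
    return cores, bgs


def composition_summary(
    labeled: Sequence[LabeledSequence], background: Background = "carrier"
) -> DistributionSummary:
    """Per-sequence residue percentages within cores and within background,
    summarized by group mean and median per amino acid."""
    if not labeled:
        raise ValueError("no labeled sequences")
    cores, bgs = _split_populations(labeled, background)

    def table(pop: list[str]) -> pd.DataFrame:
        rows = []
        for p in pop:
            if not p:
                continue
            counts = {aa: 100.0 * p.count(aa) / len(p) for aa in ALPHABET}
            rows.append(counts)
        return pd.DataFrame(rows, columns=list(ALPHABET))

    return DistributionSummary("composition", table(cores), table(bgs))


def charge_distribution(
    labeled: Sequence[LabeledSequence], background: Background = "carrier"
) -> DistributionSummary:
    """Integer-binned histogram of per-sequence net charge, as proportions."""
    cores, bgs = _split_populations(labeled, background)
    qc = [net_charge(p) for p in cores if p]
    qb = [net_charge(p) for p in bgs if p]
    lo = min(qc + qb)
    hi = max(qc + qb)
    bins = list(range(lo, hi + 1))

    def hist(values: list[int]) -> pd.DataFrame:
        prop = {b: values.count(b) / len(values) for b in bins}
        return pd.DataFrame([prop], columns=bins)

    return DistributionSummary("net_charge", hist(qc), hist(qb))


def ss_distribution(
    labeled: Sequence[LabeledSequence],
    ss_tracks: Mapping[str, Sequence[str]],
    background: Background = "carrier",
) -> DistributionSummary:
    """Fractions of H/E/C residues in cores vs background.

    ``ss_tracks`` maps carrier sequence id to its per-residue H/E/C track.
    """
    rows_c, rows_b = [], []
    for ls in labeled:
        track = list(ss_tracks[ls.sequence.id])
        if len(track) != len(ls.labels):
            raise ValueError(
                f"{ls.sequence.id}: secondary-structure track length "
                f"{len(track)} != {len(ls.labels)}"
            )
        core_sym = [s for s, l in zip(track, ls.labels) if l == CRITICAL]
        if background == "carrier":
            bg_sym = track
        else:
            bg_sym = [s for s, l in zip(track, ls.labels) if l != CRITICAL]
        for syms, rows in ((core_sym, rows_c), (bg_sym, rows_b)):
            if syms:
                rows.append(
                    {c: syms.count(c) / len(syms) for c in ("H", "E", "C")}
                )
    return DistributionSummary(
        "secondary_structure",
        pd.DataFrame(rows_c, columns=["H", "E", "C"]),
        pd.DataFrame(rows_b, columns=["H", "E", "C"]),
    )


def amphipathicity_distribution(
    labeled: Sequence[LabeledSequence],
    config: FeatureConfig = DEFAULT_CONFIG,
    scale: PropensityScale | None = None,
    background: Background = "carrier",
) -> DistributionSummary:
    """Per-sequence hydrophobic moment of cores vs background.

    The statistic is the mean of the windowed moment over all full windows
    (window length from ``config``, truncated to the sequence when
    shorter): a segment that is coherently periodic throughout scores high,
    while a long sequence with incoherent phases scores low even if it
    contains one amphipathic stretch.
    """
    if scale is None:
        scale = load_scale("eisenberg")
    cores, bgs = _split_populations(labeled, background)

    def mean_moment(p: str) -> float:
        w = min(config.amph_window, len(p))
        vals = [
            hydrophobic_moment(p[i : i + w], scale, config.amph_angle_deg)
            for i in range(len(p) - w + 1)
        ]
        return float(np.mean(vals))

    mu_c = [mean_moment(p) for p in cores if p]
    mu_b = [mean_moment(p) for p in bgs if p]
    return DistributionSummary(
        "amphipathicity",
        pd.DataFrame({"mu_H": mu_c}),
        pd.DataFrame({"mu_H": mu_b}),
    )


# -- boundary coupling --------------------------------------------------------


@dataclass(frozen=True)
class BoundaryCouplingMatrix:
    """20x20 natural-log odds of boundary residue pairs vs independence.

    For the N side, rows are the residue at P(-1) (last residue before the
    core) and columns the residue at P1 (first core residue).  For the C
    side, rows are the last core residue and columns the first residue
    after the core.
    """

    side: Literal["N", "C"]
    log_odds: pd.DataFrame  # rows/cols = ALPHABET
    counts: pd.DataFrame
    pseudocount: float
    n_boundaries: int

    def top_pairs(self, n: int = 5) -> list[tuple[str, str, float]]:
        stacked = self.log_odds.stack().sort_values(ascending=False)
        return [(a, b, float(v)) for (a, b), v in stacked.head(n).items()]


def boundary_pairs(
    labeled: Sequence[LabeledSequence], side: Literal["N", "C"]
) -> list[tuple[str, str]]:
    """The (P(-1), P1) residue pairs at core boundaries with a non-empty
    flank on the requested side; terminal cores are skipped for that side."""
    pairs = []
    for ls in labeled:
        iv = ls.core_interval
        if iv is None:
            continue
        start, end = iv
        res = ls.sequence.residues
        if side == "N":
            if start > 0:
                pairs.append((res[start - 1], res[start]))
        else:
            if end < len(res):
                pairs.append((res[end - 1], res[end]))
    return pairs


def boundary_coupling(
    labeled: Sequence[LabeledSequence],
    side: Literal["N", "C"] = "N",
    pseudocount: float | None = None,
) -> BoundaryCouplingMatrix:
    """Log-odds of each boundary pair against the independence background.

    The expected count of a pair is the product of the observed marginal
    frequencies of its two positions times the number of boundaries;
    log-odds (natural log) is log of the pseudocounted observed/expected
    count ratio, so every entry is finite.

    ``pseudocount=None`` (the default) uses the mean count per cell
    (n/400, floored at 0.5).  A flat sub-count pseudocount lets cells with
    expected counts below one dominate the ranking through sampling noise;
    shrinking by the average cell keeps the ranking governed by
    well-supported cells while still vanishing, in relative terms, as the
    number of boundaries grows.
    """
    pairs = boundary_pairs(labeled, side)
    if not pairs:
        raise ValueError(f"no qualifying {side}-side boundaries")
    if pseudocount is None:
        pseudocount = max(0.5, len(pairs) / 400.0)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    idx = {aa: i for i, aa in enumerate(ALPHABET)}
    counts = np.zeros((20, 20))
    for a, b in pairs:
        if a in idx and b in idx:
            counts[idx[a], idx[b]] += 1
    total = counts.sum()
    row_freq = counts.sum(axis=1, keepdims=True) / total
    col_freq = counts.sum(axis=0, keepdims=True) / total
    # expected count under independence of the two boundary positions;
    # the pseudocount enters the ratio, keeping empty cells finite and
    # near zero rather than inflating them
    expected = total * row_freq * col_freq
    log_odds = np.log((counts + pseudocount) / (expected + pseudocount))
    cols = list(ALPHABET)
    return BoundaryCouplingMatrix(
        side=side,
        log_odds=pd.DataFrame(log_odds, index=cols, columns=cols),
        counts=pd.DataFrame(counts, index=cols, columns=cols),
        pseudocount=pseudocount,
        n_boundaries=len(pairs),
    )


def plot_boundary_heatmap(matrix: BoundaryCouplingMatrix, path) -> None:
    """Save the boundary log-odds matrix as a heat map (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(matrix.log_odds.values, cmap="gray", aspect="equal")
    ax.set_xticks(range(20), list(ALPHABET))
    ax.set_yticks(range(20), list(ALPHABET))
    ax.set_xlabel("P1 (first residue of the core side)")
    ax.set_ylabel("P(-1) (residue outside the boundary)")
    ax.set_title(f"{matrix.side}-boundary coupling (natural-log odds)")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_composition(summary: DistributionSummary, path) -> None:
    """Save a grouped bar chart of core vs background composition means."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(summary.core.columns))
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.bar(x - 0.2, summary.core_mean.values, width=0.4, label="core")
    ax.bar(x + 0.2, summary.background_mean.values, width=0.4, label="background")
    ax.set_xticks(x, [str(c) for c in summary.core.columns])
    ax.set_ylabel("mean per-sequence value")
    ax.set_title(summary.variable)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def boundary_count_matrix(
    labeled: Sequence[LabeledSequence],
    side: Literal["N", "C"] = "N",
    flank: int = 5,
) -> pd.DataFrame:
    """Sequence-logo-ready position x residue count matrix for a window of
    ``flank`` residues on each side of the requested core boundary.

    Positions are labeled P-flank..P-1, P1..P+flank (no P0), matching the
    usual boundary-window convention.
    """
    pos_labels = [f"P{-(flank - i)}" for i in range(flank)] + [
        f"P{i + 1}" for i in range(flank)
    ]
    counts = pd.DataFrame(
        0, index=pos_labels, columns=list(ALPHABET), dtype=int
    )
    for ls in labeled:
        iv = ls.core_interval
        if iv is None:
            continue
        start, end = iv
        res = ls.sequence.residues
        anchor = start if side == "N" else end
        for w in range(-flank, flank):
            p = anchor + w
            if 0 <= p < len(res) and res[p] in counts.columns:
                label = pos_labels[w + flank]
                counts.loc[label, res[p]] += 1
    return counts
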