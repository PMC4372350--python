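"""Per-residue observation channels for core labeling.

Eight aligned categorical tracks are computed per sequence and consumed by
the CRF as observations:

=========  =========================  =============================
channel    alphabet                   meaning
=========  =========================  =============================
PRIMARY    20 amino-acid letters      the residue itself
SS         H / E / C                  secondary structure class
DOMAIN     IN / OUT                   inside a conserved domain
ALIGN      IN / OUT                   covered by a gapless core hit
AMPA       IN / OUT                   inside a bactericidal stretch
AGGR       IN / OUT                   inside an aggregation hot spot
CHARGE     LEADING/POSITIVE/          sign of the net charge of the
           NONPOSITIVE                trailing N-mer window
AMPH       IN / OUT                   in a high hydrophobic-moment
                                      window (amphipathic segment)
=========  =========================  =============================

All tracks are pure functions of their inputs; the same sequence and
configuration always yield byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .sequences import ALPHABET

CHANNELS = ("PRIMARY", "SS", "DOMAIN", "ALIGN", "AMPA", "AGGR", "CHARGE", "AMPH")

IN, OUT = "IN", "OUT"
LEADING, POSITIVE, NONPOSITIVE = "LEADING", "POSITIVE", "NONPOSITIVE"

POSITIVE_RESIDUES = frozenset("KR")  # His excluded by default
NEGATIVE_RESIDUES = frozenset("DE")


class ScaleCoverageError(KeyError):
    """A residue has no value in the requested propensity scale."""


@dataclass(frozen=True)
class PropensityScale:
    """A named per-residue real-valued scale (20 entries)."""

    name: str
    values: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(ALPHABET) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues {sorted(missing)}")
        if any(not math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name} has non-finite values")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise ScaleCoverageError(
                f"residue {residue!r} not covered by scale {self.name}"
            ) from None

    def as_array(self, residues: str) -> np.ndarray:
        return np.array([self[r] for r in residues], dtype=float)


def load_scale(name: str) -> PropensityScale:
    """Load a packaged scale file (``eisenberg``, ``ampa_pv``, ``aggrescan_a3v``)."""
    text = (
        importlib_resources.files("ampcore.data").joinpath(f"{name}.scale").read_text()
    )
    values: dict[str, float] = {}
    provenance = []
    for line in text.splitlines():
        if line.startswith("#"):
            provenance.append(line.lstrip("# "))
            continue
        if not line.strip():
            continue
        res, val = line.split()
        values[res] = float(val)
    return PropensityScale(name=name, values=values, provenance=" ".join(provenance))


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters for the observation channels.

    Defaults follow the conventions of the tools each channel emulates:
    a 7-residue net-charge window, a 10-residue 100-degree hydrophobic
    moment window with an amphipathicity cutoff of 0.35 on the Eisenberg
    scale, the antimicrobial-stretch defaults (window 7, threshold 0.225,
    min stretch 4) and the aggregation hot-spot rule (window ladder by
    length, threshold -0.02, min run 5, proline breaks runs).
    """

    window_half_width: int = 2
    charge_window: int = 7
    count_his_positive: bool = False
    amph_window: int = 10
    amph_angle_deg: float = 100.0
    amph_threshold: float = 0.35
    ampa_window: int = 7
    ampa_threshold: float = 0.225
    ampa_min_stretch: int = 4
    aggr_threshold: float = -0.02
    aggr_min_run: int = 5
    align_min_norm_score: float = 2.5
    align_min_run: int = 7

    def __post_init__(self) -> None:
        if min(self.charge_window, self.amph_window, self.ampa_window) < 1:
            raise ValueError("all windows must be >= 1")
        if not 0 < self.amph_angle_deg < 360:
            raise ValueError("helical angle must be in (0, 360) degrees")


DEFAULT_CONFIG = FeatureConfig()


# -- net charge and the CHARGE track -----------------------------------------


def net_charge(peptide: str, count_his_positive: bool = False) -> int:
    """count(K, R) - count(D, E); histidine optionally counted positive."""
    if not peptide:
        raise ValueError("net_charge of empty peptide")
    pos = POSITIVE_RESIDUES | ({"H"} if count_his_positive else set())
    return sum(r in pos for r in peptide) - sum(r in NEGATIVE_RESIDUES for r in peptide)


def charge_track(seq: str, config: FeatureConfig = DEFAULT_CONFIG) -> list[str]:
    """Classify each residue by the net charge of the N-mer window ending at it.

    The first N-1 positions carry the LEADING symbol (no full window ends
    there); sequences shorter than N are all LEADING.
    """
    n = config.charge_window
    out = [LEADING] * min(n - 1, len(seq))
    for i in range(n - 1, len(seq)):
        q = net_charge(seq[i - n + 1 : i + 1], config.count_his_positive)
        out.append(POSITIVE if q > 0 else NONPOSITIVE)
    return out


# -- hydrophobic moment and the AMPH track -----------------------------------


def hydrophobic_moment(
    window: str, scale: PropensityScale, angle_deg: float = 100.0
) -> float:
    """Mean hydrophobic moment of a window at a fixed helical angle.

    mu_H = (1/N) * | sum_n H_n exp(i n delta) |, delta = angle in radians,
    n = 0..N-1.  100 degrees per residue corresponds to an alpha-helix;
    high mu_H means one hydrophobic face and one hydrophilic face.
    """
    if not window:
        raise ValueError("hydrophobic_moment of empty window")
    h = scale.as_array(window)
    delta = math.radians(angle_deg)
    n = np.arange(len(window))
    s = float(np.dot(h, np.sin(n * delta)))
    c = float(np.dot(h, np.cos(n * delta)))
    return math.hypot(s, c) / len(window)


def amphipathic_track(seq: str, scale: PropensityScale,
                      config: FeatureConfig = DEFAULT_CONFIG) -> list[str]:
    """IN for residues covered by >= 1 full window with mu_H >= threshold."""
    w = config.amph_window
    n = len(seq)
    flags = np.zeros(n, dtype=bool)
    for start in range(0, n - w + 1):
        mu = hydrophobic_moment(seq[start : start + w], scale, config.amph_angle_deg)
        if mu >= config.amph_threshold:
            flags[start : start + w] = True
    return [IN if f else OUT for f in flags]


# -- bactericidal-propensity (AMPA-style) track ------------------------------


def ampa_track(seq: str, scale: PropensityScale,
               config: FeatureConfig = DEFAULT_CONFIG) -> list[str]:
    """IN inside maximal runs of residues whose windowed mean propensity is
    below the bactericidal threshold, runs shorter than the minimum stretch
    discarded.  Windows at the sequence ends are truncated.
    """
    prof = _windowed_mean(scale.as_array(seq), config.ampa_window)
    below = prof < config.ampa_threshold
    return _runs_to_track(below, config.ampa_min_stretch)


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _runs_to_track(flags: np.ndarray, min_run: int) -> list[str]:
    out = [OUT] * len(flags)
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = [IN] * (j - i)
            i = j
        else:
            i += 1
    return out


# -- aggregation hot-spot (AGGRESCAN-style) track ----------------------------


def aggrescan_window(length: int) -> int:
    """Window ladder of the aggregation profiler: 5 / 7 / 9 / 11 by length."""
    if length < 75:
        return 5
    if length <= 175:
        return 7
    if length <= 300:
        return 9
    return 11


def aggregation_track(seq: str, scale: PropensityScale,
                      config: FeatureConfig = DEFAULT_CONFIG) -> list[str]:
    """IN inside aggregation hot spots: >= ``aggr_min_run`` consecutive
    residues whose window-averaged propensity exceeds the threshold, with
    proline (an aggregation breaker) interrupting runs.
    """
    window = aggrescan_window(len(seq))
    prof = _windowed_mean(scale.as_array(seq), window)
    hot = (prof > config.aggr_threshold) & np.array([r != "P" for r in seq])
    return _runs_to_track(hot, config.aggr_min_run)


# -- gapless BLOSUM62 search and the ALIGN track -----------------------------


@dataclass(frozen=True)
class GaplessHit:
    """A maximal gapless run where every aligned pair scores >= 0."""

    query_id: str
    target_core_id: str
    query_start: int
    target_start: int
    run_length: int
    raw_score: int

    @property
    def normalized_score(self) -> float:
        return self.raw_score / self.run_length

    @property
    def query_interval(self) -> tuple[int, int]:
        return self.query_start, self.query_start + self.run_length


_BLOSUM62 = None
_B62_EXT = None
_B62_INDEX = {r: i for i, r in enumerate(ALPHABET)}
_SEP = 20  # sentinel index: separator between concatenated cores / unknown residue


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a 20x20 integer array in alphabetical residue order."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        m = substitution_matrices.load("BLOSUM62")
        arr = np.zeros((20, 20), dtype=np.int64)
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                arr[i, j] = int(m[a, b])
        _BLOSUM62 = arr
    return _BLOSUM62


def _extended_blosum() -> np.ndarray:
    # 21x21: row/column 20 scores -1 against everything, so sentinel
    # positions (core separators, unknown residues) always break runs.
    global _B62_EXT
    if _B62_EXT is None:
        ext = np.full((21, 21), -1, dtype=np.int64)
        ext[:20, :20] = blosum62_matrix()
        _B62_EXT = ext
    return _B62_EXT


def encode(seq: str) -> np.ndarray:
    """Residues as indices into the extended matrix; unknowns -> sentinel."""
    return np.array([_B62_INDEX.get(r, _SEP) for r in seq], dtype=np.intp)


def gapless_search(
    query: str,
    query_id: str,
    core_db: Sequence[tuple[str, str]],
    matrix: np.ndarray | None = None,
    min_run_length: int = 1,
    min_normalized_score: float | None = None,
) -> list[GaplessHit]:
    """Scan every query x core diagonal for maximal non-negative runs.

    Only substitutions scoring >= 0 under BLOSUM62 are allowed inside a run;
    each maximal run yields one hit with raw score = sum of pair scores and
    normalized score = raw / run length.  Hits are ranked by normalized
    score (descending), ties by raw score then coordinates.  The optional
    thresholds drop short / weak runs before hits are materialized, which
    matters when scanning a large core database.

    The cores are scanned as one concatenated, sentinel-separated target so
    the diagonal run bookkeeping is a single vectorized recurrence over
    query rows rather than a per-diagonal loop.
    """
    if not core_db:
        return []
    if matrix is None:
        matrix = _extended_blosum()
    elif matrix.shape == (20, 20):
        ext = np.full((21, 21), -1, dtype=np.int64)
        ext[:20, :20] = matrix
        matrix = ext

    core_ids = [cid for cid, _ in core_db]
    starts = np.cumsum([0] + [len(c) + 1 for _, c in core_db])[:-1]
    concat = np.concatenate(
        [np.concatenate([encode(c), [_SEP]]) for _, c in core_db]
    ).astype(np.intp)
    q = encode(query)

    scores = matrix[q[:, None], concat[None, :]]  # (m, N)
    inside = scores >= 0
    m, big_n = scores.shape
    run_len = np.zeros((m, big_n), dtype=np.int64)
    run_sum = np.zeros((m, big_n), dtype=np.int64)
    run_len[0] = inside[0]
    run_sum[0] = np.where(inside[0], scores[0], 0)
    for i in range(1, m):
        run_len[i, 0] = inside[i, 0]
        run_sum[i, 0] = scores[i, 0] if inside[i, 0] else 0
        cont = inside[i, 1:]
        run_len[i, 1:] = np.where(cont, run_len[i - 1, :-1] + 1, 0)
        run_sum[i, 1:] = np.where(cont, run_sum[i - 1, :-1] + scores[i, 1:], 0)

    # a run ends where it cannot be extended down-right
    ends = inside.copy()
    ends[:-1, :-1] &= ~inside[1:, 1:]
    lengths = np.where(ends, run_len, 0)
    keep = lengths >= max(1, min_run_length)
    if min_normalized_score is not None:
        keep &= run_sum >= min_normalized_score * lengths
    ii, jj = np.nonzero(keep)
    end_lens = run_len[ii, jj]
    end_sums = run_sum[ii, jj]
    concat_starts = jj - end_lens + 1
    core_idx = np.searchsorted(starts, concat_starts, side="right") - 1

    hits = [
        GaplessHit(
            query_id=query_id,
            target_core_id=core_ids[ci],
            query_start=int(i - ln + 1),
            target_start=int(cs - starts[ci]),
            run_length=int(ln),
            raw_score=int(rs),
        )
        for i, cs, ci, ln, rs in zip(
            ii.tolist(), concat_starts.tolist(), core_idx.tolist(),
            end_lens.tolist(), end_sums.tolist(),
        )
    ]
    hits.sort(
        key=lambda h: (
            -h.normalized_score,
            -h.raw_score,
            h.target_core_id,
            h.query_start,
            h.target_start,
        )
    )
    return hits


def align_track(
    seq: str, hits: Iterable[GaplessHit], config: FeatureConfig = DEFAULT_CONFIG
) -> list[str]:
    """IN for residues covered by >= 1 accepted hit.

    A hit is accepted when its normalized score reaches
    ``align_min_norm_score`` and its run spans >= ``align_min_run`` residues
    (short incidental runs have inflated per-residue scores).
    """
    flags = np.zeros(len(seq), dtype=bool)
    for h in hits:
        if (
            h.normalized_score >= config.align_min_norm_score
            and h.run_length >= config.align_min_run
        ):
            a, b = h.query_interval
            flags[a:b] = True
    return [IN if f else OUT for f in flags]


# -- secondary-structure track -----------------------------------------------

# Chou-Fasman conformational propensities (helix, sheet) used by the
# built-in fallback predictor. Lower fidelity than a neural predictor;
# external per-residue predictions are preferred when available.
_CF_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
    "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
    "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
    "Y": 0.69, "V": 1.06,
}
_CF_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
    "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
    "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
    "Y": 1.47, "V": 1.70,
}


class TrackLengthError(ValueError):
    """An externally supplied per-residue annotation has the wrong length."""


def fallback_ss_predict(seq: str, window: int = 5) -> list[str]:
    """Propensity-smoothing fallback secondary-structure predictor.

    Window-averaged helix and sheet propensities; a residue is H (resp. E)
    when the corresponding smoothed propensity exceeds 1.0 and dominates,
    else C (coil).  A deliberately simple stand-in for an external
    neural-network predictor, exposed through the same interface.
    """
    ph = _windowed_mean(np.array([_CF_HELIX[r] for r in seq]), window)
    pe = _windowed_mean(np.array([_CF_SHEET[r] for r in seq]), window)
    out = []
    for h, e in zip(ph, pe):
        if h > 1.0 and h >= e:
            out.append("H")
        elif e > 1.0:
            out.append("E")
        else:
            out.append("C")
    return out


def ss_track(seq: str, source: Sequence[str] | None = None) -> list[str]:
    """Per-residue H/E/C symbols from an external prediction or the fallback.

    ``source`` is a per-residue symbol list (e.g. parsed from a prediction
    file); ``None`` invokes the built-in fallback predictor.
    """
    if source is None:
        return fallback_ss_predict(seq)
    symbols = list(source)
    if len(symbols) != len(seq):
        raise TrackLengthError(
            f"secondary-structure annotation has {len(symbols)} rows "
            f"for a {len(seq)}-residue sequence"
        )
    bad = sorted(set(symbols) - {"H", "E", "C"})
    if bad:
        raise ValueError(f"invalid secondary-structure symbols {bad}")
    return symbols


def read_ss_file(path) -> list[str]:
    """Parse an external secondary-structure file.

    Accepts a 3-column TSV (index, residue, symbol) or an ``ss2``-style
    layout (index, residue, symbol, then per-class confidences).  Comment
    and blank lines are skipped.
    """
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            symbols.append(parts[2].upper())
    return symbols


# -- conserved-domain track ---------------------------------------------------


def domain_track(seq: str, intervals: Sequence[tuple[int, int]]) -> list[str]:
    """IN on the union of 0-based half-open intervals (conserved domains)."""
    flags = np.zeros(len(seq), dtype=bool)
    for start, end in intervals:
        if not 0 <= start <= end <= len(seq):
            raise ValueError(
                f"domain interval [{start}, {end}) out of range for "
                f"length {len(seq)}"
            )
        flags[start:end] = True
    return [IN if f else OUT for f in flags]


# -- orchestration -------------------------------------------------------------


@dataclass(frozen=True)
class FeatureTracks:
    """The eight aligned per-residue channels of one sequence."""

    sequence_id: str
    length: int
    channels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name in CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing channel {name}")
            if len(self.channels[name]) != self.length:
                raise ValueError(
                    f"channel {name} has {len(self.channels[name])} entries "
                    f"for length {self.length}"
                )

    def column(self, i: int) -> tuple[str, ...]:
        return tuple(self.channels[c][i] for c in CHANNELS)


@dataclass
class FeatureResources:
    """Bundled inputs for featurization: scales, core DB, annotations."""

    hydrophobicity: PropensityScale = field(default_factory=lambda: load_scale("eisenberg"))
    bactericidal: PropensityScale = field(default_factory=lambda: load_scale("ampa_pv"))
    aggregation: PropensityScale = field(default_factory=lambda: load_scale("aggrescan_a3v"))
    core_db: list[tuple[str, str]] = field(default_factory=list)
    ss_annotations: Mapping[str, Sequence[str]] | None = None
    domain_annotations: Mapping[str, Sequence[tuple[int, int]]] | None = None
    use_fallback_ss: bool = True


def featurize(
    seq: str,
    seq_id: str,
    config: FeatureConfig = DEFAULT_CONFIG,
    resources: FeatureResources | None = None,
) -> FeatureTracks:
    """Compute all eight observation channels for one sequence."""
    if resources is None:
        resources = FeatureResources()
    channels: dict[str, tuple[str, ...]] = {}

    def _run(name: str, fn: Callable[[], list[str]]) -> None:
        try:
            channels[name] = tuple(fn())
        except Exception as exc:  # annotate failures with the channel name
            raise RuntimeError(f"channel {name} failed for {seq_id}: {exc}") from exc

    _run("PRIMARY", lambda: list(seq))
    if resources.ss_annotations and seq_id in resources.ss_annotations:
        _run("SS", lambda: ss_track(seq, resources.ss_annotations[seq_id]))
    elif resources.use_fallback_ss:
        _run("SS", lambda: ss_track(seq, None))
    else:
        _run("SS", lambda: ["C"] * len(seq))
    dom = (resources.domain_annotations or {}).get(seq_id, [])
    _run("DOMAIN", lambda: domain_track(seq, dom))
    hits = (
        gapless_search(
            seq,
            seq_id,
            resources.core_db,
            min_run_length=config.align_min_run,
            min_normalized_score=config.align_min_norm_score,
        )
        if resources.core_db
        else []
    )
    _run("ALIGN", lambda: align_track(seq, hits, config))
    _run("AMPA", lambda: ampa_track(seq, resources.bactericidal, config))
    _run("AGGR", lambda: aggregation_track(seq, resources.aggregation, config))
    _run("CHARGE", lambda: charge_track(seq, config))
    _run("AMPH", lambda: amphipathic_track(seq, resources.hydrophobicity, config))
    return FeatureTracks(sequence_id=seq_id, length=len(seq), channels=channels)
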