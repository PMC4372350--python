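"""Synthetic nested-AMP-family generator with known ground truth.

Emulates the statistical structure of real core-containing families so
that extraction, featurization, training, evaluation and the descriptive
analyses are all testable without any external download: planted cores are
7-40 residues, cationic (K/R placed on the polar face of an ideal helix
with ~3.6 residues per turn, hence periodically amphipathic), enriched in
glycine and depleted in D/E/M; flanks are drawn from an explicit background
frequency table with a configurable acidic tilt.  Every family nests the
core itself inside >= 1 longer member with random flanks.

The generator does not simulate microbiology (organisms, MIC values) —
only the sequence statistics the labeler and analyses consume.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Sequence

import numpy as np

from .evaluation import CVRecord
from .families import CRITICAL, NONCRITICAL, CoreAnnotation, LabeledSequence, NestedFamily
from .features import DEFAULT_CONFIG, FeatureConfig, FeatureResources, featurize
from .sequences import ALPHABET, AminoAcidSequence

_HYDRO_RESIDUES = tuple("LIFVAWG")
_HYDRO_WEIGHTS = (0.25, 0.15, 0.15, 0.15, 0.12, 0.05, 0.13)
_POLAR_RESIDUES = tuple("GSTNQHDE")
_POLAR_WEIGHTS = (0.30, 0.20, 0.15, 0.15, 0.10, 0.05, 0.025, 0.025)


def load_background_frequencies() -> dict[str, float]:
    """The packaged background amino-acid frequency table, normalized."""
    text = (
        importlib_resources.files("ampcore.data")
        .joinpath("background_freqs.tsv")
        .read_text()
    )
    freqs = {}
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        res, val = line.split()
        freqs[res] = float(val)
    total = sum(freqs.values())
    return {r: v / total for r, v in freqs.items()}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic corpus.

    ``core_amph_period`` is in residues per helical turn (3.6 for an
    alpha-helix, i.e. 100 degrees per residue); ``core_cationic_fraction``
    is the probability that a polar-face core position carries K or R;
    ``flank_acidic_fraction`` mixes extra D/E mass into the flank
    background.  ``boundary_rg_odds`` > 1 tilts the joint distribution of
    the (P(-1), P1) boundary pair toward (R, G) at that odds ratio.
    """

    n_families: int
    seed: int
    core_length_range: tuple[int, int] = (7, 40)
    flank_length_range: tuple[int, int] = (5, 30)
    members_per_family_range: tuple[int, int] = (2, 4)
    core_cationic_fraction: float = 0.45
    core_amph_period: float = 3.6
    flank_acidic_fraction: float = 0.15
    mutation_rate_for_near_duplicates: float = 0.10
    boundary_rg_odds: float = 1.0

    def __post_init__(self) -> None:
        for name in ("core_length_range", "flank_length_range", "members_per_family_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.members_per_family_range[0] < 2:
            raise ValueError("families need >= 2 members")
        for name in ("core_cationic_fraction", "flank_acidic_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_families < 0 or self.seed is None:
            raise ValueError("n_families must be >= 0 and a seed is mandatory")


def _sample_core_residue(
    rng: np.random.Generator, config: SimConfig, n: int, phase_deg: float
) -> str:
    """Residue for core position ``n`` on an ideal helical wheel."""
    angle = math.radians(phase_deg + n * 360.0 / config.core_amph_period)
    if math.cos(angle) >= 0:  # hydrophobic face
        return rng.choice(_HYDRO_RESIDUES, p=_HYDRO_WEIGHTS)
    if rng.random() < config.core_cationic_fraction:
        return "K" if rng.random() < 0.6 else "R"
    return rng.choice(_POLAR_RESIDUES, p=_POLAR_WEIGHTS)


def generate_core(rng: np.random.Generator, config: SimConfig) -> str:
    """One planted core: periodic cationic/hydrophobic faces, G-enriched.

    The helical wheel starts at a random phase so which face the core's
    first residue sits on varies between families.
    """
    lo, hi = config.core_length_range
    length = int(rng.integers(lo, hi + 1))
    phase = float(rng.uniform(0.0, 360.0))
    return "".join(
        _sample_core_residue(rng, config, n, phase) for n in range(length)
    )


def _flank_distribution(config: SimConfig) -> tuple[tuple[str, ...], np.ndarray]:
    base = load_background_frequencies()
    af = config.flank_acidic_fraction
    probs = {
        r: (1 - af) * base[r] + af * (0.5 if r in "DE" else 0.0) for r in ALPHABET
    }
    residues = tuple(sorted(probs))
    p = np.array([probs[r] for r in residues])
    return residues, p / p.sum()


def generate_flank(rng: np.random.Generator, config: SimConfig, length: int) -> str:
    residues, p = _flank_distribution(config)
    if length == 0:
        return ""
    return "".join(rng.choice(residues, size=length, p=p))


def _tilted_boundary_pair(rng: np.random.Generator, config: SimConfig) -> tuple[str, str]:
    """Sample the (P(-1), P1) pair; rejection sampling gives the (R, G)
    cell an odds ratio of ``boundary_rg_odds`` against independence."""
    omega = config.boundary_rg_odds
    residues, p = _flank_distribution(config)
    while True:
        a = str(rng.choice(residues, p=p))
        b = _sample_core_residue(rng, config, 0, float(rng.uniform(0.0, 360.0)))
        if (a, b) == ("R", "G") or omega <= 1 or rng.random() < 1.0 / omega:
            return a, b


def generate_family(
    rng: np.random.Generator, config: SimConfig, family_id: str
) -> tuple[NestedFamily, CoreAnnotation]:
    """One nested family plus its ground-truth core annotation.

    The shortest member is the core itself; every other member embeds the
    core once between random flanks.  Member lengths are kept distinct so
    the carrier (longest member) is unambiguous, and flanks are redrawn if
    they happen to re-contain the core.
    """
    lo_f, hi_f = config.flank_length_range
    core = generate_core(rng, config)
    if config.boundary_rg_odds != 1.0:
        a, b = _tilted_boundary_pair(rng, config)
        core = b + core[1:]
    else:
        a = None
    lo_k, hi_k = config.members_per_family_range
    k = int(rng.integers(lo_k, hi_k + 1))

    members = [AminoAcidSequence(id=f"{family_id}_m1", residues=core,
                                 description="planted core")]
    lengths_seen = {len(core)}
    for j in range(2, k + 1):
        for _attempt in range(100):
            left = int(rng.integers(lo_f, hi_f + 1))
            right = int(rng.integers(lo_f, hi_f + 1))
            lflank = generate_flank(rng, config, left)
            rflank = generate_flank(rng, config, right)
            if a is not None and left > 0:
                lflank = lflank[:-1] + a
            seq = lflank + core + rflank
            if len(seq) in lengths_seen or seq.count(core) != 1:
                continue
            lengths_seen.add(len(seq))
            members.append(
                AminoAcidSequence(
                    id=f"{family_id}_m{j}", residues=seq, description="extension"
                )
            )
            break
        else:
            raise RuntimeError(f"{family_id}: could not place core uniquely")
    family = NestedFamily(family_id=family_id, members=tuple(members))
    carrier = family.longest
    start = carrier.residues.find(core)
    truth = CoreAnnotation(
        family_id=family_id,
        carrier_id=carrier.id,
        start=start,
        end=start + len(core),
        core_residues=core,
    )
    return family, truth


def generate_families(
    config: SimConfig,
) -> list[tuple[NestedFamily, CoreAnnotation]]:
    """``n_families`` independent families with no cross-family containment.

    A family is redrawn if its core appears inside any member of another
    family (which would merge the two containment components).
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[NestedFamily, CoreAnnotation]] = []
    all_members: list[str] = []
    cores: list[str] = []
    for n in range(config.n_families):
        for _attempt in range(50):
            family, truth = generate_family(rng, config, f"S{n + 1:04d}")
            new_members = [m.residues for m in family.members]
            clash = any(truth.core_residues in m for m in all_members) or any(
                c in m for c in cores for m in new_members
            )
            if not clash:
                break
        else:
            raise RuntimeError("could not generate a containment-free family")
        out.append((family, truth))
        all_members.extend(new_members)
        cores.append(truth.core_residues)
    return out


def label_from_truth(
    family: NestedFamily, truth: CoreAnnotation
) -> LabeledSequence:
    carrier = family.longest
    labels = tuple(
        CRITICAL if truth.start <= i < truth.end else NONCRITICAL
        for i in range(len(carrier.residues))
    )
    return LabeledSequence(sequence=carrier, labels=labels)


@dataclass
class SyntheticDataset:
    config: SimConfig
    families: list[NestedFamily]
    annotations: list[CoreAnnotation]
    labeled: list[LabeledSequence]
    records: list[CVRecord]
    manifest: dict

    def to_manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=1, sort_keys=True)


def generate_dataset(
    config: SimConfig,
    feature_config: FeatureConfig = DEFAULT_CONFIG,
    featurized: bool = True,
) -> SyntheticDataset:
    """Reproducible labeled (and optionally featurized) corpus + manifest.

    The ALIGN channel of the featurized records is computed against the
    full planted-core database; cross-validation recomputes it per fold.
    """
    pairs = generate_families(config)
    families = [f for f, _ in pairs]
    annotations = [t for _, t in pairs]
    labeled = [label_from_truth(f, t) for f, t in pairs]

    records: list[CVRecord] = []
    if featurized and pairs:
        core_db = [(t.family_id, t.core_residues) for t in annotations]
        resources = FeatureResources(core_db=core_db)
        for fam, truth, ls in zip(families, annotations, labeled):
            tracks = featurize(
                ls.sequence.residues, ls.sequence.id, feature_config, resources
            )
            records.append(
                CVRecord(
                    family_id=fam.family_id,
                    tracks=tracks,
                    labels=ls.labels,
                    core=truth.core_residues,
                )
            )

    manifest = {
        "config": dataclasses.asdict(config),
        "families": [
            {
                "family_id": f.family_id,
                "members": {m.id: m.residues for m in f.members},
                "carrier_id": t.carrier_id,
                "core": t.core_residues,
                "core_start": t.start,
                "core_end": t.end,
            }
            for f, t in pairs
        ],
    }
    return SyntheticDataset(
        config=config,
        families=families,
        annotations=annotations,
        labeled=labeled,
        records=records,
        manifest=manifest,
    )


def mutate_sequence(rng: np.random.Generator, residues: str, rate: float) -> str:
    """Point-mutate each position with probability ``rate`` (to a different
    residue), for building near-duplicate carriers."""
    out = []
    for r in residues:
        if rng.random() < rate:
            choices = [a for a in ALPHABET if a != r]
            out.append(str(rng.choice(choices)))
        else:
            out.append(r)
    return "".join(out)
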