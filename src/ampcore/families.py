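"""Nested AMP families: grouping, core determination, labeling, clustering.

A *nested family* is a set of >= 2 peptide sequences related by substring
containment: short experimentally validated peptides nested inside longer
source proteins.  The family's *critical region* (core) is its shortest
member, provided that member is a substring of every other member and its
length lies in [7, 40].  The longest member (the *carrier*) is labeled
per-residue CRITICAL on the core interval and NONCRITICAL elsewhere; those
labeled carriers are the CRF training material.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from Bio import Align

from .sequences import AminoAcidSequence

CRITICAL = "CRITICAL"
NONCRITICAL = "NONCRITICAL"

MIN_CORE_LEN = 7
MAX_CORE_LEN = 40


class RejectionReason(enum.Enum):
    """Why a candidate family yields no accepted core annotation."""

    TOO_SHORT = "TOO_SHORT"
    TOO_LONG = "TOO_LONG"
    NO_COMMON_MEMBER = "NO_COMMON_MEMBER"


class CoreRejection(Exception):
    def __init__(self, reason: RejectionReason, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason.value}: {detail}" if detail else reason.value)


@dataclass(frozen=True)
class NestedFamily:
    """>= 2 sequences where at least one is a substring of all the others."""

    family_id: str
    members: tuple[AminoAcidSequence, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"{self.family_id}: a nested family needs >= 2 members")

    @property
    def longest(self) -> AminoAcidSequence:
        # tie-break: lexicographically smallest id, for reproducibility
        return min(self.members, key=lambda s: (-len(s.residues), s.id))


@dataclass(frozen=True)
class CoreAnnotation:
    """The minimal common substring (core) located on the carrier.

    Coordinates are 0-based, half-open on the carrier sequence.
    """

    family_id: str
    carrier_id: str
    start: int
    end: int
    core_residues: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.core_residues):
            raise ValueError("core interval length != core_residues length")


@dataclass(frozen=True)
class LabeledSequence:
    """A carrier with a per-residue CRITICAL/NONCRITICAL label track."""

    sequence: AminoAcidSequence
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence.residues):
            raise ValueError(
                f"{self.sequence.id}: {len(self.labels)} labels for "
                f"{len(self.sequence.residues)} residues"
            )

    @property
    def core_interval(self) -> tuple[int, int] | None:
        """(start, end) of the CRITICAL run, or None if no CRITICAL labels."""
        idx = [i for i, l in enumerate(self.labels) if l == CRITICAL]
        if not idx:
            return None
        return idx[0], idx[-1] + 1


class FamilyPartition(NamedTuple):
    families: list[NestedFamily]
    orphans: list[AminoAcidSequence]


def deduplicate(sequences: Iterable[AminoAcidSequence]) -> list[AminoAcidSequence]:
    """Collapse exact residue-string duplicates, merging ids into the description."""
    by_res: dict[str, AminoAcidSequence] = {}
    for s in sequences:
        prev = by_res.get(s.residues)
        if prev is None:
            by_res[s.residues] = s
        else:
            merged_ids = f"{prev.description} duplicate_of:{s.id}".strip()
            by_res[s.residues] = AminoAcidSequence(
                id=prev.id, residues=prev.residues, description=merged_ids
            )
    return list(by_res.values())


def build_nested_families(sequences: Sequence[AminoAcidSequence]) -> FamilyPartition:
    """Group sequences into nested families by substring containment.

    Families are the connected components of the containment relation
    ("a is a substring of b"), restricted to components that contain at
    least one member which is a substring of *all* others.  Components that
    fail this, singletons, and sequences carrying unknown residues (``X``)
    are returned as orphans.

    The grouping is order-invariant: shuffling the input changes family ids
    only (ids are assigned on sorted member order).
    """
    seqs = deduplicate(sequences)
    standard = [s for s in seqs if s.is_standard]
    orphans: list[AminoAcidSequence] = [s for s in seqs if not s.is_standard]

    # union-find over containment edges; compare short-vs-long only
    order = sorted(range(len(standard)), key=lambda i: len(standard[i].residues))
    parent = list(range(len(standard)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for a_pos, ia in enumerate(order):
        ra = standard[ia].residues
        for ib in order[a_pos + 1 :]:
            rb = standard[ib].residues
            if len(ra) < len(rb) and ra in rb:
                union(ia, ib)

    components: dict[int, list[AminoAcidSequence]] = {}
    for i, s in enumerate(standard):
        components.setdefault(find(i), []).append(s)

    families: list[NestedFamily] = []
    qualifying: list[list[AminoAcidSequence]] = []
    for comp in components.values():
        if len(comp) < 2:
            orphans.extend(comp)
            continue
        if _common_member(comp) is None:
            orphans.extend(comp)
            continue
        qualifying.append(comp)

    # deterministic family ids regardless of input order
    qualifying.sort(key=lambda comp: min(s.residues for s in comp))
    for n, comp in enumerate(qualifying):
        members = tuple(sorted(comp, key=lambda s: (len(s.residues), s.id)))
        families.append(NestedFamily(family_id=f"F{n + 1:04d}", members=members))
    orphans.sort(key=lambda s: s.id)
    return FamilyPartition(families, orphans)


def _common_member(members: Sequence[AminoAcidSequence]) -> AminoAcidSequence | None:
    """The shortest member that is a substring of all others, or None."""
    for cand in sorted(members, key=lambda s: (len(s.residues), s.id)):
        if all(cand.residues in m.residues for m in members):
            return cand
    return None


def determine_core(
    family: NestedFamily,
    min_len: int = MIN_CORE_LEN,
    max_len: int = MAX_CORE_LEN,
) -> CoreAnnotation:
    """Locate the family core: the shortest member contained in all members.

    Raises :class:`CoreRejection` with reason ``NO_COMMON_MEMBER`` if no
    member is a substring of every other, or ``TOO_SHORT``/``TOO_LONG`` if
    the common member's length falls outside [7, 40].  When the core occurs
    more than once in the carrier, the leftmost occurrence is annotated and
    a warning records the occurrence count.
    """
    shortest = _common_member(family.members)
    if shortest is None:
        raise CoreRejection(RejectionReason.NO_COMMON_MEMBER, family.family_id)
    core = shortest.residues
    if len(core) < min_len:
        raise CoreRejection(
            RejectionReason.TOO_SHORT, f"{family.family_id}: |core|={len(core)}"
        )
    if len(core) > max_len:
        raise CoreRejection(
            RejectionReason.TOO_LONG, f"{family.family_id}: |core|={len(core)}"
        )
    carrier = family.longest
    start = carrier.residues.find(core)
    n_occ = _count_occurrences(carrier.residues, core)
    if n_occ > 1:
        warnings.warn(
            f"{family.family_id}: core occurs {n_occ}x in carrier "
            f"{carrier.id}; labeling leftmost occurrence",
            stacklevel=2,
        )
    return CoreAnnotation(
        family_id=family.family_id,
        carrier_id=carrier.id,
        start=start,
        end=start + len(core),
        core_residues=core,
    )


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1  # overlapping occurrences count


def label_carrier(family: NestedFamily, core: CoreAnnotation) -> LabeledSequence:
    """Per-residue labels on the carrier: CRITICAL on [start, end)."""
    carrier = family.longest
    if carrier.id != core.carrier_id:
        raise ValueError(
            f"core annotated on {core.carrier_id} but family carrier is {carrier.id}"
        )
    n = len(carrier.residues)
    labels = tuple(
        CRITICAL if core.start <= i < core.end else NONCRITICAL for i in range(n)
    )
    return LabeledSequence(sequence=carrier, labels=labels)


# -- representative selection (greedy identity clustering) --------------------


def pairwise_identity(a: str, b: str) -> float:
    """Sequence identity: max matched residues / length of the shorter.

    Matches are counted as the better of (i) the best gapless diagonal and
    (ii) a gap-tolerant global alignment maximizing matches (match=1,
    mismatch/gap=0).  Normalizing by the shorter length follows the greedy
    clustering convention of CD-HIT-style tools.
    """
    if not a or not b:
        return 0.0
    best = _best_diagonal_matches(a, b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    best = max(best, int(aligner.score(a, b)))
    return best / min(len(a), len(b))


def _best_diagonal_matches(a: str, b: str) -> int:
    best = 0
    for off in range(-(len(b) - 1), len(a)):
        m = sum(
            1
            for i in range(max(0, off), min(len(a), off + len(b)))
            if a[i] == b[i - off]
        )
        best = max(best, m)
    return best


def select_representatives(
    labeled: Sequence[LabeledSequence], identity_threshold: float = 0.70
) -> list[LabeledSequence]:
    """Greedy incremental clustering of carriers; returns cluster seeds.

    Carriers are visited by decreasing length (ties: id); each joins the
    first existing cluster whose seed it matches at > ``identity_threshold``
    identity, else it founds a new cluster.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity threshold must be in (0, 1)")
    ordered = sorted(labeled, key=lambda l: (-len(l.sequence.residues), l.sequence.id))
    seeds: list[LabeledSequence] = []
    for cand in ordered:
        for seed in seeds:
            ident = pairwise_identity(cand.sequence.residues, seed.sequence.residues)
            if ident > identity_threshold:
                break
        else:
            seeds.append(cand)
    return seeds
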