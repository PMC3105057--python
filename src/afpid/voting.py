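"""Jury voting: sequence-level AFP calls and residue-level vote maps.

A jury member contributes (a) a binary verdict from its scheme classifier
and (b) residue votes: every residue inside the footprint of every
occurrence of one of the member's GA-selected attributes gains one vote,
accumulating across members and overlapping occurrences.

Tier boundaries for the vote map: red >= 6 votes, yellow 4-5, gray <= 3.
The published legend leaves exactly 3 and 6 unassigned (">6", "4 or 5",
"<3"); this implementation closes the gaps downward (3 -> gray) and
upward (6 -> red), consistent with the only printed key-residue call,
which has 8 votes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np

from .features import SchemeSpec, compute_features, iter_matches
from .seqio import AFP, NONAFP

RED_MIN = 6
YELLOW_MIN = 4

ABSTAIN = "ABSTAIN"


class JuryMember(Protocol):
    """What voting needs from a trained scheme classifier."""

    scheme: SchemeSpec
    attribute_order: list[str]

    @property
    def selected_attributes(self) -> list[str]: ...

    def predict(self, X) -> tuple[list[str], "np.ndarray"]: ...


class UndecidableError(ValueError):
    """Every jury member abstained; no verdict can be returned."""


@dataclass
class JuryConfig:
    members: list
    sequence_vote_threshold: int | None = None  # None -> strict majority

    def __post_init__(self):
        if not self.members:
            raise ValueError("jury must have at least one member")
        if self.sequence_vote_threshold is None:
            # strict majority: more than half (7 for the 13-scheme jury)
            self.sequence_vote_threshold = len(self.members) // 2 + 1
        if not 1 <= self.sequence_vote_threshold <= len(self.members):
            raise ValueError("threshold must lie in [1, n_members]")


@dataclass
class VoteProfile:
    sequence_id: str
    sequence: str
    votes: np.ndarray  # per-residue non-negative ints
    tiers: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.votes = np.asarray(self.votes, dtype=int)
        if self.votes.shape != (len(self.sequence),):
            raise ValueError("votes length must equal sequence length")
        if (self.votes < 0).any():
            raise ValueError("votes must be non-negative")


def tier_of(votes: int) -> str:
    if votes >= RED_MIN:
        return "red"
    if votes >= YELLOW_MIN:
        return "yellow"
    return "gray"


def tier_residues(profile: VoteProfile) -> VoteProfile:
    profile.tiers = [tier_of(int(v)) for v in profile.votes]
    return profile


def _member_verdict(sequence: str, member, alphabets=None) -> str:
    if len(sequence) < member.scheme.min_length():
        return ABSTAIN
    vec = compute_features(sequence, member.scheme, alphabets)
    labels, _ = member.predict(vec.as_array(member.attribute_order))
    return labels[0]


def classify_sequence(
    sequence: str, jury: JuryConfig, alphabets=None
) -> tuple[str, list[str]]:
    """AFP iff positive verdicts reach the (abstention-rescaled) threshold.

    Members whose scheme needs a longer sequence abstain; the majority
    threshold is rescaled proportionally to the number of active members.
    Returns the verdict and the per-member verdict list for audit.
    """
    verdicts = [_member_verdict(sequence, m, alphabets) for m in jury.members]
    active = [v for v in verdicts if v != ABSTAIN]
    if not active:
        raise UndecidableError("all jury members abstained (sequence too short)")
    threshold = jury.sequence_vote_threshold
    if len(active) < len(jury.members):
        threshold = max(1, math.ceil(threshold * len(active) / len(jury.members)))
    n_pos = sum(v == AFP for v in active)
    return (AFP if n_pos >= threshold else NONAFP), verdicts


def residue_votes(
    sequence: str,
    jury: JuryConfig,
    sequence_id: str = "query",
    alphabets=None,
) -> VoteProfile:
    """Accumulate one vote per footprint residue per selected-attribute
    occurrence per jury member, then assign tiers."""
    votes = np.zeros(len(sequence), dtype=int)
    for member in jury.members:
        if len(sequence) < member.scheme.min_length():
            continue
        selected = set(member.selected_attributes)
        if not selected:
            continue
        for match in iter_matches(sequence, member.scheme, alphabets):
            if match.attribute in selected:
                for pos in match.positions:
                    votes[pos] += 1
    return tier_residues(VoteProfile(sequence_id, sequence, votes))


def write_vote_table(profile: VoteProfile, fh) -> None:
    """Per-residue TSV: 1-based position, residue, votes, tier."""
    fh.write("#position\tresidue\tvotes\ttier\n")
    for i, (res, v, tier) in enumerate(
        zip(profile.sequence, profile.votes, profile.tiers), start=1
    ):
        fh.write(f"{i}\t{res}\t{int(v)}\t{tier}\n")


def annotation_string(profile: VoteProfile) -> str:
    """Compact annotation: uppercase=red, lowercase=yellow, dot=gray."""
    out = []
    for res, tier in zip(profile.sequence, profile.tiers):
        out.append(res if tier == "red" else res.lower() if tier == "yellow" else ".")
    return "".join(out)


def classify_batch(
    records: Iterable, jury: JuryConfig, alphabets=None
) -> list[tuple[str, str, int, int]]:
    """(id, verdict, positive_votes, abstentions) per record."""
    rows = []
    for rec in records:
        verdict, member_verdicts = classify_sequence(rec.sequence, jury, alphabets)
        rows.append(
            (
                rec.id,
                verdict,
                sum(v == AFP for v in member_verdicts),
                sum(v == ABSTAIN for v in member_verdicts),
            )
        )
    return rows
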