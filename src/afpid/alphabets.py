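"""Reduced amino-acid alphabets used by the coding schemes.

Eight alphabets are provided: ``A`` (the identity alphabet over the 20
canonical residues), the three-class physicochemical descriptors ``H``
(hydrophobicity), ``V`` (normalized van der Waals volume), ``Z``
(polarizability) and ``P`` (polarity), and the coarser partitions ``F``
(4 groups), ``S`` (7 groups) and ``E`` (8 groups).

H/V/Z/P follow the standard three-class descriptor tables.  The exact
F/S/E memberships are not fixed by any single convention, so they are
loaded from a bundled TSV (``data/alphabet_groups.tsv``) and can be
overridden with :func:`load_alphabet_table`; the shipped defaults are
documented approximations, not canonical constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seqio import CANONICAL_RESIDUES

EXPECTED_GROUP_COUNTS = {"A": 20, "H": 3, "V": 3, "Z": 3, "P": 3, "F": 4, "S": 7, "E": 8}


class AlphabetDefinitionError(ValueError):
    """A group table does not partition the 20 canonical residues."""


@dataclass(frozen=True)
class ReducedAlphabet:
    """An ordered partition of the 20 residues into labelled groups.

    Group symbols are ``"1".."k"`` in declared order, except for the
    identity alphabet ``A`` whose symbols are the residues themselves so
    that attribute names stay human-readable.
    """

    name: str
    groups: tuple[str, ...]  # each group is a string of member residues
    symbols: tuple[str, ...] = field(default=())
    symbol_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        covered = "".join(self.groups)
        if sorted(covered) != sorted(CANONICAL_RESIDUES):
            raise AlphabetDefinitionError(
                f"alphabet {self.name!r}: groups must partition the 20 canonical "
                f"residues exactly (got {''.join(sorted(covered))!r})"
            )
        if not self.symbols:
            if len(self.groups) == 20:
                symbols = tuple(g for g in self.groups)
            else:
                symbols = tuple(str(i + 1) for i in range(len(self.groups)))
            object.__setattr__(self, "symbols", symbols)
        mapping = {}
        for sym, members in zip(self.symbols, self.groups):
            for res in members:
                mapping[res] = sym
        object.__setattr__(self, "symbol_of", mapping)

    @property
    def size(self) -> int:
        return len(self.groups)

    def encode(self, sequence: str) -> str:
        """Rewrite *sequence* in group symbols; length-preserving."""
        try:
            return "".join(self.symbol_of[c] for c in sequence)
        except KeyError as exc:
            raise AlphabetDefinitionError(
                f"alphabet {self.name!r} has no group for residue {exc.args[0]!r}"
            ) from exc


def encode_sequence(sequence: str, alphabet: ReducedAlphabet) -> str:
    return alphabet.encode(sequence)


# Three-class descriptor groupings (hydrophobicity, van der Waals volume,
# polarizability, polarity).  Order within each alphabet fixes the group
# symbols 1..3.
_THREE_CLASS = {
    # polar, neutral, hydrophobic
    "H": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    # small, medium, large volume
    "V": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    # low, medium, high polarizability
    "Z": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    # hydrophobic, neutral, polar
    "P": ("LIFWCMVY", "PATGS", "HQRKNED"),
}


def _bundled_table_lines() -> list[str]:
    text = resources.files("afpid").joinpath("data/alphabet_groups.tsv").read_text()
    return text.splitlines()


def _parse_group_table(lines: list[str]) -> dict[str, list[tuple[str, str]]]:
    table: dict[str, list[tuple[str, str]]] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise AlphabetDefinitionError(
                f"alphabet table: expected 3 columns (name, symbol, residues), got {line!r}"
            )
        name, symbol, residues = parts
        table.setdefault(name, []).append((symbol, residues.upper()))
    return table


def load_alphabet_table(path: str | Path) -> dict[str, ReducedAlphabet]:
    """Load alphabet overrides from a TSV of (name, group symbol, residues)."""
    with open(path) as fh:
        table = _parse_group_table(fh.read().splitlines())
    out = {}
    for name, rows in table.items():
        out[name] = ReducedAlphabet(
            name=name,
            groups=tuple(residues for _, residues in rows),
            symbols=tuple(sym for sym, _ in rows),
        )
    return out


def builtin_alphabets(
    overrides: str | Path | None = None,
) -> dict[str, ReducedAlphabet]:
    """Return the eight named alphabets, optionally merged with overrides."""
    registry: dict[str, ReducedAlphabet] = {
        "A": ReducedAlphabet("A", tuple(CANONICAL_RESIDUES))
    }
    for name, groups in _THREE_CLASS.items():
        registry[name] = ReducedAlphabet(name, groups)
    for name, rows in _parse_group_table(_bundled_table_lines()).items():
        registry[name] = ReducedAlphabet(
            name,
            groups=tuple(residues for _, residues in rows),
            symbols=tuple(sym for sym, _ in rows),
        )
    if overrides is not None:
        registry.update(load_alphabet_table(overrides))
    for name, expected in EXPECTED_GROUP_COUNTS.items():
        if name in registry and registry[name].size != expected:
            raise AlphabetDefinitionError(
                f"alphabet {name!r}: expected {expected} groups, got {registry[name].size}"
            )
    return registry
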