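"""Coding-scheme feature vectors and attribute-to-residue position maps.

Four kinds of scheme are supported:

* ``npeptide`` — frequencies of the contiguous length-n words of the
  (alphabet-encoded) sequence;
* ``partitioned`` — the n-peptide composition computed separately on k
  contiguous near-equal segments, attributes namespaced by segment;
* ``gapped_dipeptide`` — frequencies of ordered residue pairs ``a (x)_g b``
  separated by exactly g intervening residues of any type;
* ``window`` — for every residue type c, the composition of the residues
  pooled from windows of odd length l centered on each occurrence of c
  (center excluded, windows truncated at the sequence ends).

Every attribute value can be traced back to the exact residue positions
that produced it via :func:`match_attribute_positions`; the voting stage
relies on this to credit residues for GA-selected attributes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .alphabets import ReducedAlphabet, builtin_alphabets
from .seqio import ProteinRecord

SCHEME_KINDS = ("npeptide", "partitioned", "gapped_dipeptide", "window")


class DegenerateInputError(ValueError):
    """Sequence too short for the scheme's precondition."""


class UnknownAttributeError(KeyError):
    """Attribute name does not belong to the scheme."""


@dataclass(frozen=True)
class SchemeSpec:
    """Definition of one coding scheme.

    The conventional short names follow the composition notation: ``C`` is
    the plain amino-acid composition, ``X5`` the 5-segment partitioned
    composition, ``D3`` the 3-gap dipeptide composition, ``H3X5`` the
    5-segment tripeptide composition over the hydrophobicity alphabet and
    ``W7`` the length-7 window composition.
    """

    kind: str
    alphabet: str = "A"
    n: int = 1  # n-peptide order (npeptide / partitioned)
    k: int = 1  # partition count (partitioned)
    g: int = 0  # gap length (gapped_dipeptide)
    l: int = 3  # window length (window), odd

    def __post_init__(self):
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.n < 1 or self.k < 1 or self.g < 0:
            raise ValueError(f"bad scheme parameters: {self}")
        if self.kind == "window" and (self.l < 3 or self.l % 2 == 0):
            raise ValueError(f"window length must be odd and >=3, got {self.l}")

    @property
    def name(self) -> str:
        if self.kind == "npeptide":
            if self.alphabet == "A" and self.n == 1:
                return "C"
            return f"{self.alphabet}{self.n}"
        if self.kind == "partitioned":
            prefix = "" if (self.alphabet == "A" and self.n == 1) else f"{self.alphabet}{self.n}"
            return f"{prefix}X{self.k}"
        if self.kind == "gapped_dipeptide":
            return f"D{self.g}"
        return f"W{self.l}"

    def min_length(self) -> int:
        if self.kind == "npeptide":
            return self.n
        if self.kind == "partitioned":
            return self.k * self.n
        if self.kind == "gapped_dipeptide":
            return self.g + 2
        return 1


@dataclass
class FeatureVector:
    scheme: SchemeSpec
    values: dict[str, float]

    def as_array(self, attribute_order: Sequence[str]) -> np.ndarray:
        return np.array([self.values[a] for a in attribute_order], dtype=float)


@dataclass(frozen=True)
class AttributeMatch:
    """One occurrence of an attribute: the 0-based residue indices it covers."""

    attribute: str
    positions: tuple[int, ...]


def _registry(alphabets: dict[str, ReducedAlphabet] | None) -> dict[str, ReducedAlphabet]:
    return alphabets if alphabets is not None else builtin_alphabets()


def _alphabet(scheme: SchemeSpec, alphabets) -> ReducedAlphabet:
    reg = _registry(alphabets)
    try:
        return reg[scheme.alphabet]
    except KeyError:
        raise ValueError(f"scheme {scheme.name}: unknown alphabet {scheme.alphabet!r}")


def _grams(alphabet: ReducedAlphabet, n: int) -> list[str]:
    return ["".join(p) for p in itertools.product(alphabet.symbols, repeat=n)]


def attribute_names(scheme: SchemeSpec, alphabets=None) -> list[str]:
    """Canonical (lexicographic-by-declared-order) attribute list of a scheme."""
    ab = _alphabet(scheme, alphabets)
    if scheme.kind == "npeptide":
        return _grams(ab, scheme.n)
    if scheme.kind == "partitioned":
        grams = _grams(ab, scheme.n)
        return [f"s{seg}|{g}" for seg in range(1, scheme.k + 1) for g in grams]
    if scheme.kind == "gapped_dipeptide":
        gap = "x" * scheme.g
        return [f"{a}{gap}{b}" for a in ab.symbols for b in ab.symbols]
    return [f"{c}|{x}" for c in ab.symbols for x in ab.symbols]


def segment_bounds(length: int, k: int) -> list[tuple[int, int]]:
    """Split [0, length) into k contiguous segments, lengths differing by <=1.

    The remainder goes to the leading segments.
    """
    base, rem = divmod(length, k)
    bounds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def _require_length(sequence: str, scheme: SchemeSpec) -> None:
    if len(sequence) < scheme.min_length():
        raise DegenerateInputError(
            f"scheme {scheme.name} needs length >= {scheme.min_length()}, "
            f"got {len(sequence)}"
        )


def iter_matches(
    sequence: str, scheme: SchemeSpec, alphabets=None
) -> Iterator[AttributeMatch]:
    """Yield every attribute occurrence in *sequence* with its footprint.

    For gapped dipeptides only the two anchor residues are in the footprint
    (the intervening residues are wildcards); for partitioned schemes the
    indices are global but the occurrence is confined to its owning segment;
    for windows each occurrence is one (center, pooled neighbor) pair.
    """
    _require_length(sequence, scheme)
    ab = _alphabet(scheme, alphabets)
    enc = ab.encode(sequence)
    L = len(enc)
    if scheme.kind == "npeptide":
        n = scheme.n
        for i in range(L - n + 1):
            yield AttributeMatch(enc[i : i + n], tuple(range(i, i + n)))
    elif scheme.kind == "partitioned":
        n = scheme.n
        for seg, (lo, hi) in enumerate(segment_bounds(L, scheme.k), start=1):
            for i in range(lo, hi - n + 1):
                yield AttributeMatch(f"s{seg}|{enc[i:i + n]}", tuple(range(i, i + n)))
    elif scheme.kind == "gapped_dipeptide":
        gap = "x" * scheme.g
        step = scheme.g + 1
        for i in range(L - step):
            yield AttributeMatch(f"{enc[i]}{gap}{enc[i + step]}", (i, i + step))
    else:  # window
        h = (scheme.l - 1) // 2
        for i in range(L):
            c = enc[i]
            for j in range(max(0, i - h), min(L, i + h + 1)):
                if j != i:
                    yield AttributeMatch(f"{c}|{enc[j]}", (i, j))


def _denominators(sequence: str, scheme: SchemeSpec, alphabets=None) -> dict[str, float]:
    """Per-attribute normalization denominators (constant within a sub-vector)."""
    ab = _alphabet(scheme, alphabets)
    enc = ab.encode(sequence)
    L = len(enc)
    denoms: dict[str, float] = {}
    if scheme.kind == "npeptide":
        d = L - scheme.n + 1
        return {a: d for a in attribute_names(scheme, alphabets)}
    if scheme.kind == "partitioned":
        grams = _grams(ab, scheme.n)
        for seg, (lo, hi) in enumerate(segment_bounds(L, scheme.k), start=1):
            d = hi - lo - scheme.n + 1
            for g in grams:
                denoms[f"s{seg}|{g}"] = d
        return denoms
    if scheme.kind == "gapped_dipeptide":
        d = L - scheme.g - 1
        return {a: d for a in attribute_names(scheme, alphabets)}
    # window: denominator is the pooled-neighbor count of the center type
    h = (scheme.l - 1) // 2
    pool_size: dict[str, int] = {c: 0 for c in ab.symbols}
    for i, c in enumerate(enc):
        pool_size[c] += min(L, i + h + 1) - max(0, i - h) - 1
    for c in ab.symbols:
        for x in ab.symbols:
            denoms[f"{c}|{x}"] = pool_size[c]
    return denoms


def _compose(sequence: str, scheme: SchemeSpec, alphabets=None) -> FeatureVector:
    values = dict.fromkeys(attribute_names(scheme, alphabets), 0.0)
    counts: dict[str, int] = {}
    for m in iter_matches(sequence, scheme, alphabets):
        counts[m.attribute] = counts.get(m.attribute, 0) + 1
    denoms = _denominators(sequence, scheme, alphabets)
    for attr, c in counts.items():
        values[attr] = c / denoms[attr]
    return FeatureVector(scheme=scheme, values=values)


def npeptide_composition(sequence: str, n: int, alphabet: str = "A", alphabets=None) -> FeatureVector:
    return _compose(sequence, SchemeSpec("npeptide", alphabet=alphabet, n=n), alphabets)


def partitioned_composition(
    sequence: str, k: int, n: int = 1, alphabet: str = "A", alphabets=None
) -> FeatureVector:
    return _compose(
        sequence, SchemeSpec("partitioned", alphabet=alphabet, n=n, k=k), alphabets
    )


def gapped_dipeptide_composition(
    sequence: str, g: int, alphabet: str = "A", alphabets=None
) -> FeatureVector:
    return _compose(
        sequence, SchemeSpec("gapped_dipeptide", alphabet=alphabet, g=g), alphabets
    )


def window_composition(sequence: str, l: int, alphabet: str = "A", alphabets=None) -> FeatureVector:
    return _compose(sequence, SchemeSpec("window", alphabet=alphabet, l=l), alphabets)


def compute_features(sequence: str, scheme: SchemeSpec, alphabets=None) -> FeatureVector:
    """Dispatch to the composition matching ``scheme.kind``."""
    return _compose(sequence, scheme, alphabets)


def match_attribute_positions(
    sequence: str, scheme: SchemeSpec, attribute: str, alphabets=None
) -> list[AttributeMatch]:
    """All occurrences of *attribute* in *sequence*, with exact footprints."""
    if attribute not in set(attribute_names(scheme, alphabets)):
        raise UnknownAttributeError(
            f"attribute {attribute!r} does not belong to scheme {scheme.name}"
        )
    return [m for m in iter_matches(sequence, scheme, alphabets) if m.attribute == attribute]


def default_scheme_set() -> list[SchemeSpec]:
    """The default 13-member jury of coding schemes.

    ``{C, X5, X6, X7, D0, D1, D3, D6, H3X5, P3X5, S2X5, W7, W11}`` — global
    composition, three partitioned compositions, four gapped-dipeptide
    schemes, three reduced-alphabet partitioned schemes, two window schemes.
    """
    return [
        SchemeSpec("npeptide", n=1),
        SchemeSpec("partitioned", k=5),
        SchemeSpec("partitioned", k=6),
        SchemeSpec("partitioned", k=7),
        SchemeSpec("gapped_dipeptide", g=0),
        SchemeSpec("gapped_dipeptide", g=1),
        SchemeSpec("gapped_dipeptide", g=3),
        SchemeSpec("gapped_dipeptide", g=6),
        SchemeSpec("partitioned", alphabet="H", n=3, k=5),
        SchemeSpec("partitioned", alphabet="P", n=3, k=5),
        SchemeSpec("partitioned", alphabet="S", n=2, k=5),
        SchemeSpec("window", l=7),
        SchemeSpec("window", l=11),
    ]


@dataclass
class SchemeMatrix:
    """Feature matrix of one scheme over a record list (rows = kept records)."""

    scheme: SchemeSpec
    attribute_order: list[str]
    matrix: np.ndarray
    record_ids: list[str]
    skipped_ids: list[str] = field(default_factory=list)


def build_scheme_matrix(
    records: Iterable[ProteinRecord], scheme: SchemeSpec, alphabets=None
) -> SchemeMatrix:
    """Stack feature vectors row-wise; too-short records are flagged and
    excluded with a warning, never silently zero-filled."""
    order = attribute_names(scheme, alphabets)
    rows, kept, skipped = [], [], []
    for rec in records:
        if len(rec.sequence) < scheme.min_length():
            skipped.append(rec.id)
            continue
        rows.append(_compose(rec.sequence, scheme, alphabets).as_array(order))
        kept.append(rec.id)
    if skipped:
        warnings.warn(
            f"scheme {scheme.name}: {len(skipped)} record(s) shorter than "
            f"{scheme.min_length()} excluded: {skipped[:5]}",
            stacklevel=2,
        )
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, len(order)))
    return SchemeMatrix(scheme, order, matrix, kept, skipped)
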