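"""Independent brute-force oracles and small stubs shared by the tests.

Everything here deliberately avoids the package's own counting/DP code
paths: compositions are recounted by direct enumeration over index tuples,
and alignment scores by exhaustive enumeration of all global alignment
paths.
"""

from __future__ import annotations

import itertools
from math import inf

from Bio.Align import substitution_matrices

from afpid.features import SchemeSpec, segment_bounds
from afpid.seqio import AFP, NONAFP


# ---------------------------------------------------------------------------
# composition count oracles (dicts attribute -> raw occurrence count)


def bf_npeptide_counts(enc: str, n: int, symbols) -> dict[str, int]:
    counts = {}
    for word in ("".join(p) for p in itertools.product(symbols, repeat=n)):
        c = sum(1 for i in range(len(enc) - n + 1) if enc[i : i + n] == word)
        if c:
            counts[word] = c
    return counts


def bf_partitioned_counts(enc: str, k: int, n: int, symbols) -> dict[str, int]:
    counts = {}
    for seg, (lo, hi) in enumerate(segment_bounds(len(enc), k), start=1):
        for word, c in bf_npeptide_counts(enc[lo:hi], n, symbols).items():
            counts[f"s{seg}|{word}"] = c
    return counts


def bf_gapped_counts(enc: str, g: int) -> dict[str, int]:
    counts = {}
    for i in range(len(enc)):
        for j in range(i + 1, len(enc)):
            if j - i == g + 1:
                attr = f"{enc[i]}{'x' * g}{enc[j]}"
                counts[attr] = counts.get(attr, 0) + 1
    return counts


def bf_window_counts(enc: str, l: int) -> dict[str, int]:
    h = (l - 1) // 2
    counts = {}
    for i, c in enumerate(enc):
        for j, x in enumerate(enc):
            if j != i and abs(j - i) <= h:
                attr = f"{c}|{x}"
                counts[attr] = counts.get(attr, 0) + 1
    return counts


def bf_counts(enc: str, scheme: SchemeSpec, symbols) -> dict[str, int]:
    if scheme.kind == "npeptide":
        return bf_npeptide_counts(enc, scheme.n, symbols)
    if scheme.kind == "partitioned":
        return bf_partitioned_counts(enc, scheme.k, scheme.n, symbols)
    if scheme.kind == "gapped_dipeptide":
        return bf_gapped_counts(enc, scheme.g)
    return bf_window_counts(enc, scheme.l)


# ---------------------------------------------------------------------------
# alignment oracle: enumerate every global alignment path


def bf_global_alignment_score(
    a: str, b: str, matrix_name: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0
) -> float:
    """Max score over all global alignments; a gap of length L costs
    open + L * extend.  Exponential -- only for very short strings."""
    sub = substitution_matrices.load(matrix_name)
    best = -inf

    def rec(i: int, j: int, score: float, prev: str):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[a[i], b[j]], "M")
        if i < len(a):  # a[i] against a gap
            cost = gap_extend if prev == "X" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "M")
    return best


# ---------------------------------------------------------------------------
# jury stubs


class StubMember:
    """Jury member with a fixed verdict and a fixed selected-attribute set."""

    def __init__(self, scheme: SchemeSpec, selected=(), verdict: str = NONAFP):
        self.scheme = scheme
        self.attribute_order: list[str] = []
        self._selected = list(selected)
        self._verdict = verdict

    @property
    def selected_attributes(self):
        return list(self._selected)

    def predict(self, X):
        return [self._verdict], None


def signs(labels):
    import numpy as np

    return np.array([1 if lab == AFP else -1 for lab in labels])
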