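"""Global pairwise alignment and sequence-identity (SI) analysis.

Alignment is optimal Needleman-Wunsch with affine gaps (a gap of length L
costs open + L * extend), scored with a named substitution matrix.  SI is
100 * identical columns / alignment length including gap columns by
default; the denominator can be switched to the shorter sequence length.
SI below ~20% is conventionally the "midnight zone" where homology-based
inference is unreliable (documentation constant, not a computation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

MIDNIGHT_ZONE_SI = 20.0


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    si_denominator: str = "alignment"  # or "shorter"

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.si_denominator not in ("alignment", "shorter"):
            raise ValueError("si_denominator must be 'alignment' or 'shorter'")


@dataclass(frozen=True)
class SIRecord:
    query_id: str
    target_id: str
    si: float
    alignment_length: int
    identities: int


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Biopython charges open_gap_score for the first gapped column, so a
    # gap of length L costs open + L * extend under this mapping.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[Align.Alignment, float]:
    """Best global alignment of *a* and *b* plus its percent identity."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    params = params or AlignmentParams()
    alignment = _aligner(params).align(a, b)[0]
    counts = alignment.counts()
    denom = (
        alignment.length
        if params.si_denominator == "alignment"
        else min(len(a), len(b))
    )
    return alignment, 100.0 * counts.identities / denom


def align_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global alignment score (for oracle comparisons)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    return float(_aligner(params or AlignmentParams()).score(a, b))


def best_hit_si(
    query_id: str,
    query: str,
    library: Sequence[tuple[str, str]],
    params: AlignmentParams | None = None,
    exclude_self: bool = False,
) -> SIRecord:
    """Max-SI hit of *query* against a (id, sequence) library.

    Ties break to the first library entry; *exclude_self* skips entries
    whose id equals *query_id*.
    """
    entries = [(i, s) for i, s in library if not (exclude_self and i == query_id)]
    if not entries:
        raise ValueError("library is empty (after self-exclusion)")
    best: SIRecord | None = None
    for target_id, target_seq in entries:
        alignment, si = global_align(query, target_seq, params)
        if best is None or si > best.si:
            best = SIRecord(
                query_id=query_id,
                target_id=target_id,
                si=si,
                alignment_length=alignment.length,
                identities=alignment.counts().identities,
            )
    return best


def si_binned_accuracy(
    si_records: Sequence[SIRecord],
    identified: dict[str, bool],
    bin_edges: Sequence[float] = (0, 20, 40, 60, 80, 100),
) -> list[dict]:
    """Identification rate per SI bin.

    Bins are half-open [lo, hi) except the last, which includes hi.  Every
    record falls in exactly one bin; empty bins are reported with n=0 and
    rate None.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("bin_edges must be increasing with >= 2 values")
    missing = [r.query_id for r in si_records if r.query_id not in identified]
    if missing:
        raise ValueError(f"records without verdicts: {missing[:10]}")
    table = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        members = [
            r
            for r in si_records
            if (lo <= r.si < hi) or (last and r.si == hi)
        ]
        n = len(members)
        n_id = sum(identified[r.query_id] for r in members)
        table.append(
            {
                "si_min": lo,
                "si_max": hi,
                "n": n,
                "identified": n_id,
                "rate": (n_id / n) if n else None,
            }
        )
    return table


def write_si_table(records: Sequence[SIRecord], fh) -> None:
    fh.write("#query\ttarget\tsi\talignment_length\tidentities\n")
    for r in records:
        fh.write(
            f"{r.query_id}\t{r.target_id}\t{r.si:.2f}\t{r.alignment_length}\t{r.identities}\n"
        )
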