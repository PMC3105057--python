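"""Synthetic planted-motif benchmarks and bundled reference fixtures.

Positives are background sequences with short motifs (e.g. the dipeptide
``LT`` or the 2-gap pair ``TxxT``) planted at recorded, non-overlapping
positions; negatives are pure background.  Ground truth is returned so
that feature selection and residue-vote recovery can be tested end to
end, entirely offline.

Also ships small reference tables: the PDB-derived AFP cross-validation
subset listing and the per-organism counts of the independent AFP set,
plus the NTALT worked voting example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .features import SchemeSpec
from .seqio import (
    AFP,
    CANONICAL_RESIDUES,
    NONAFP,
    LabeledDataset,
    ProteinRecord,
    write_fasta,
)


@dataclass(frozen=True)
class MotifSpec:
    """A short planted pattern; ``x`` positions match any residue."""

    pattern: str
    rate_per_100: float = 5.0  # expected occurrences per 100 residues
    jitter: int = 3  # positional noise around regular spacing

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = set(self.pattern) - set(CANONICAL_RESIDUES) - {"x"}
        if bad:
            raise ValueError(f"pattern symbols must be residues or 'x': {bad}")
        if self.rate_per_100 < 0:
            raise ValueError("planting rate must be >= 0")

    @property
    def span(self) -> int:
        return len(self.pattern)

    def anchor_offsets(self) -> list[int]:
        return [i for i, c in enumerate(self.pattern) if c != "x"]

    def scheme_attribute(self) -> tuple[SchemeSpec, str]:
        """The gapped-dipeptide scheme/attribute this motif plants.

        Only two-anchor patterns (``ab``, ``a x..x b``) map onto a single
        attribute; longer anchor sets raise.
        """
        anchors = self.anchor_offsets()
        if len(anchors) != 2 or anchors != [0, self.span - 1]:
            raise ValueError(
                f"pattern {self.pattern!r} is not an anchored two-residue motif"
            )
        g = self.span - 2
        return SchemeSpec("gapped_dipeptide", g=g), self.pattern


@dataclass(frozen=True)
class BenchmarkSpec:
    n_pos: int = 200
    n_neg: int = 200
    min_length: int = 60
    max_length: int = 100
    background: tuple[float, ...] | None = None  # None -> uniform 1/20
    motifs: tuple[MotifSpec, ...] = (MotifSpec("LT"), MotifSpec("TxxT"))
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.background is not None and (
            len(self.background) != 20 or abs(sum(self.background) - 1.0) > 1e-9
        ):
            raise ValueError("background must be 20 frequencies summing to 1")
        for m in self.motifs:
            if m.span > self.max_length:
                raise ValueError(f"motif {m.pattern!r} longer than max_length")


@dataclass(frozen=True)
class PlantedMotif:
    """One planted occurrence, 0-based half-open coordinates."""

    record_id: str
    start: int
    end: int
    pattern: str

    def anchor_positions(self) -> list[int]:
        return [self.start + i for i, c in enumerate(self.pattern) if c != "x"]


@dataclass
class Benchmark:
    dataset: LabeledDataset
    truth: list[PlantedMotif] = field(default_factory=list)
    spec: BenchmarkSpec | None = None


def _background_sequence(rng: np.random.Generator, length: int, probs) -> list[str]:
    idx = rng.choice(20, size=length, p=probs)
    return [CANONICAL_RESIDUES[i] for i in idx]


def _plant(
    seq: list[str],
    motif: MotifSpec,
    rng: np.random.Generator,
    rec_id: str,
    occupied: set[int],
) -> list[PlantedMotif]:
    L = len(seq)
    n_plant = int(round(motif.rate_per_100 * L / 100.0))
    if motif.rate_per_100 > 0:
        n_plant = max(1, n_plant)
    planted: list[PlantedMotif] = []
    if n_plant == 0:
        return planted
    spacing = L / n_plant
    for i in range(n_plant):
        base = int(round(i * spacing + spacing / 2 - motif.span / 2))
        for _ in range(10):  # a few jittered tries, then give up on this slot
            start = base + int(rng.integers(-motif.jitter, motif.jitter + 1))
            start = max(0, min(L - motif.span, start))
            span_idx = range(start, start + motif.span)
            if not occupied.intersection(span_idx):
                for off, c in enumerate(motif.pattern):
                    if c != "x":
                        seq[start + off] = c
                occupied.update(span_idx)
                planted.append(PlantedMotif(rec_id, start, start + motif.span, motif.pattern))
                break
    return planted


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Reproducible planted-motif benchmark with ground-truth positions."""
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.background) if spec.background is not None else np.full(20, 0.05)
    records: list[ProteinRecord] = []
    truth: list[PlantedMotif] = []
    width = max(4, len(str(max(spec.n_pos, spec.n_neg))))
    for i in range(spec.n_pos):
        rec_id = f"pos_{i:0{width}d}"
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = _background_sequence(rng, L, probs)
        occupied: set[int] = set()
        for motif in spec.motifs:
            truth.extend(_plant(seq, motif, rng, rec_id, occupied))
        records.append(ProteinRecord(id=rec_id, sequence="".join(seq), label=AFP))
    for i in range(spec.n_neg):
        rec_id = f"neg_{i:0{width}d}"
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        records.append(
            ProteinRecord(
                id=rec_id,
                sequence="".join(_background_sequence(rng, L, probs)),
                label=NONAFP,
            )
        )
    return Benchmark(dataset=LabeledDataset(records), truth=truth, spec=spec)


def write_benchmark(benchmark: Benchmark, outdir: str | Path, header: str = "") -> None:
    """FASTA + label TSV + BED-like ground-truth TSV (0-based half-open)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(benchmark.dataset.records, outdir / "sequences.fasta")
    with open(outdir / "labels.tsv", "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#id\tlabel\n")
        for rec in benchmark.dataset.records:
            fh.write(f"{rec.id}\t{rec.label}\n")
    with open(outdir / "planted_motifs.tsv", "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#id\tstart\tend\tmotif\n")
        for t in benchmark.truth:
            fh.write(f"{t.record_id}\t{t.start}\t{t.end}\t{t.pattern}\n")


# ---------------------------------------------------------------------------
# bundled fixtures


def worked_example_fixtures() -> dict:
    """The NTALT voting example and the 10-residue vote-map fragment.

    Fixture ``ntalt``: with the dipeptide ``LT`` selected in the 0-gap
    scheme and the pair ``TxxT`` selected in the 2-gap scheme, the residues
    N, T, A, L, T receive votes (0, 1, 0, 1, 2).

    Fixture ``vote_map_fragment``: the fragment QLIPINTALT whose residues
    carry 1-based sequence positions 9..18 in the source chain.
    """
    return {
        "ntalt": {
            "record": ProteinRecord(id="ntalt", sequence="NTALT"),
            "selected": {
                SchemeSpec("gapped_dipeptide", g=0): {"LT"},
                SchemeSpec("gapped_dipeptide", g=2): {"TxxT"},
            },
            "expected_votes": (0, 1, 0, 1, 2),
        },
        "vote_map_fragment": {
            "record": ProteinRecord(id="1msi_fragment", sequence="QLIPINTALT"),
            "first_position": 9,  # 1-based position of the leading Q
        },
    }


def _data_lines(name: str) -> list[str]:
    text = resources.files("afpid").joinpath(f"data/{name}").read_text()
    return [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]


def load_reference_subsets() -> dict[str, int]:
    """PDB id -> cross-validation subset index for the 44 reference AFPs."""
    out: dict[str, int] = {}
    for line in _data_lines("afp_subsets.tsv"):
        subset, _type, pdb_id = line.split("\t")
        if pdb_id in out:
            raise ValueError(f"duplicate PDB id {pdb_id!r} in subset table")
        out[pdb_id] = int(subset)
    return out


def load_organism_counts() -> dict[str, int]:
    """Organism -> number of sequences in the independent AFP dataset."""
    out: dict[str, int] = {}
    for line in _data_lines("afp_organism_counts.tsv"):
        organism, n = line.split("\t")
        out[organism] = int(n)
    return out
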