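"""Canonical human proinsulin and coordinate utilities.

Mature human proinsulin is 86 residues: the insulin B-chain, a dibasic RR
linker, the 31-residue connecting peptide (C-peptide), a dibasic KR linker,
and the insulin A-chain.  Hybrid insulin peptides (HIPs) are fusions of two
proinsulin fragments, so everything downstream needs to slice this sequence,
locate arbitrary peptides within it, and assign regions to spans.

Coordinates are 1-based and inclusive throughout, matching the amino-acid
numbering convention used for mature proinsulin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "PROINSULIN_RESIDUES",
    "PROINSULIN_REGIONS",
    "ProinsulinSequence",
    "SequenceSpan",
    "PeptideFragment",
    "canonical_proinsulin",
    "fragment_kmers",
    "locate_peptide",
    "classify_span",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_B_CHAIN = "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"
_C_PEPTIDE = "EAEDLQVGQVELGGGPGAGSLQPLALEGSLQ"
_A_CHAIN = "GIVEQCCTSICSLYQLENYCN"

#: Mature human proinsulin: B-chain | RR | C-peptide | KR | A-chain.
PROINSULIN_RESIDUES = _B_CHAIN + "RR" + _C_PEPTIDE + "KR" + _A_CHAIN

#: (label, start, end), 1-based inclusive, tiling 1..86.
PROINSULIN_REGIONS = (
    ("B_chain", 1, 30),
    ("dibasic_RR", 31, 32),
    ("C_peptide", 33, 63),
    ("dibasic_KR", 64, 65),
    ("A_chain", 66, 86),
)


@dataclass(frozen=True)
class SequenceSpan:
    """A 1-based inclusive coordinate interval within proinsulin."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span ({self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ProinsulinSequence:
    residues: str = PROINSULIN_RESIDUES
    regions: tuple[tuple[str, int, int], ...] = PROINSULIN_REGIONS

    def __post_init__(self) -> None:
        n = len(self.residues)
        pos = 1
        for label, start, end in self.regions:
            if start != pos or end < start:
                raise ValueError("regions must tile the sequence contiguously")
            pos = end + 1
        if pos != n + 1:
            raise ValueError("regions do not cover the full sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, span: SequenceSpan) -> str:
        if span.end > len(self):
            raise ValueError(f"span {span.as_tuple()} exceeds sequence length {len(self)}")
        return self.residues[span.start - 1 : span.end]

    def region_at(self, position: int) -> str:
        """Region label covering a single 1-based position."""
        for label, start, end in self.regions:
            if start <= position <= end:
                return label
        raise ValueError(f"position {position} outside 1..{len(self)}")


@dataclass(frozen=True)
class PeptideFragment:
    """A proinsulin substring together with its coordinates of origin."""

    sequence: str
    span: SequenceSpan

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.span):
            raise ValueError("fragment sequence length disagrees with its span")

    def __len__(self) -> int:
        return len(self.sequence)


def canonical_proinsulin() -> ProinsulinSequence:
    """The 86-aa mature human proinsulin with its region map."""
    return ProinsulinSequence()


def _validate_alphabet(seq: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad or not seq:
        raise ValueError(
            f"sequence contains non-amino-acid characters {sorted(bad)}"
            if bad
            else "empty sequence"
        )


def fragment_kmers(
    seq: ProinsulinSequence, k: int = 12, step: int = 1
) -> list[PeptideFragment]:
    """All length-``k`` substrings at starts 1, 1+step, ... (overlap k-step).

    The default (k=12, step=1) yields the 75 overlapping 12-mers of
    proinsulin from which candidate HIP fusions are built.
    """
    n = len(seq)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    out = []
    for start in range(1, n - k + 2, step):
        span = SequenceSpan(start, start + k - 1)
        out.append(PeptideFragment(seq.subseq(span), span))
    return out


def locate_peptide(query: str, seq: ProinsulinSequence | None = None) -> list[SequenceSpan]:
    """Every (possibly overlapping) occurrence of ``query`` in proinsulin."""
    if seq is None:
        seq = canonical_proinsulin()
    _validate_alphabet(query)
    spans = []
    start = seq.residues.find(query)
    while start != -1:
        spans.append(SequenceSpan(start + 1, start + len(query)))
        start = seq.residues.find(query, start + 1)
    return spans


def classify_span(
    span: SequenceSpan, seq: ProinsulinSequence | None = None
) -> tuple[str, list[str]]:
    """(majority region label, overlapped labels in sequence order).

    The majority label is the region covering the most residues of the span.
    Ties are broken in favour of C_peptide, then by sequence order — a fixed
    rule for fragments that straddle region boundaries.
    """
    if seq is None:
        seq = canonical_proinsulin()
    if span.end > len(seq):
        raise ValueError(f"span {span.as_tuple()} exceeds sequence length")
    overlapped: list[str] = []
    coverage: dict[str, int] = {}
    for label, start, end in seq.regions:
        ov = min(span.end, end) - max(span.start, start) + 1
        if ov > 0:
            overlapped.append(label)
            coverage[label] = ov
    order = {label: i for i, (label, _, _) in enumerate(seq.regions)}

    def rank(label: str) -> tuple[int, int, int]:
        return (-coverage[label], 0 if label == "C_peptide" else 1, order[label])

    majority = min(coverage, key=rank)
    return majority, overlapped
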