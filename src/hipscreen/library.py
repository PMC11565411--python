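"""Combinatorial HIP library construction.

Every ordered pair of proinsulin k-mers is fused into a 2k-mer, every
junction-spanning window of width ``w`` is extracted as a candidate epitope,
candidates are ranked by a pluggable MHC class II binding predictor
(percentile-rank convention: lower = stronger), the strongest fraction ``q``
is kept, and duplicate sequences are merged.  The pipeline order
(score -> select -> deduplicate) matches the screen design this package
models: duplicates are removed last.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .proinsulin import (
    AMINO_ACIDS,
    PeptideFragment,
    ProinsulinSequence,
    canonical_proinsulin,
    fragment_kmers,
)

__all__ = [
    "FusionPeptide",
    "HipCandidate",
    "BindingScore",
    "LibraryEntry",
    "Library",
    "BindingPredictor",
    "TablePredictor",
    "SurrogatePwmPredictor",
    "ConstantPredictor",
    "LibraryConfig",
    "enumerate_fusions",
    "junction_windows",
    "score_candidates",
    "select_top_fraction",
    "deduplicate",
    "build_library",
    "sequence_id",
    "load_predictor_table",
]


@dataclass(frozen=True)
class FusionPeptide:
    """Ordered fusion of two proinsulin fragments (left + right)."""

    left: PeptideFragment
    right: PeptideFragment

    @property
    def sequence(self) -> str:
        return self.left.sequence + self.right.sequence

    @property
    def junction_index(self) -> int:
        """Position of the last left-fragment residue within the fusion."""
        return len(self.left)


@dataclass(frozen=True)
class BindingScore:
    predictor_id: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("binding score must be finite")


@dataclass(frozen=True)
class HipCandidate:
    """A junction-spanning window of a fusion peptide."""

    sequence: str
    parent: FusionPeptide
    offset: int  # 0-based window start within the parent fusion
    left_len: int
    right_len: int
    score: BindingScore | None = None

    def __post_init__(self) -> None:
        if self.left_len < 1 or self.right_len < 1:
            raise ValueError("candidate must span the junction")
        if self.left_len + self.right_len != len(self.sequence):
            raise ValueError("left_len + right_len must equal window width")
        w = len(self.sequence)
        if self.parent.sequence[self.offset : self.offset + w] != self.sequence:
            raise ValueError("sequence disagrees with parent window")

    def sort_key(self) -> tuple:
        return (
            self.parent.left.span.as_tuple(),
            self.parent.right.span.as_tuple(),
            self.offset,
        )


@dataclass(frozen=True)
class LibraryEntry:
    """One distinct library sequence with its parental provenance."""

    member_id: str
    sequence: str
    provenances: tuple[HipCandidate, ...]
    score: BindingScore | None = None


@dataclass(frozen=True)
class Library:
    entries: tuple[LibraryEntry, ...]
    build_report: Mapping[str, int] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> list[str]:
        return [e.sequence for e in self.entries]

    def member_ids(self) -> list[str]:
        return [e.member_id for e in self.entries]

    def by_id(self) -> dict[str, LibraryEntry]:
        return {e.member_id: e for e in self.entries}


def sequence_id(sequence: str) -> str:
    """Stable member identifier derived from the sequence itself."""
    return "hip_" + hashlib.sha1(sequence.encode()).hexdigest()[:10]


def enumerate_fusions(
    fragments: Sequence[PeptideFragment], allow_self: bool = False
) -> list[FusionPeptide]:
    """All ordered fusions A+B of the given fragments.

    With ``allow_self=False`` (default; each fragment is fused with all
    *other* fragments) pairs with identical spans are excluded.  Order is
    deterministic: by left span, then right span.
    """
    if not fragments:
        raise ValueError("fragments must be non-empty")
    frags = sorted(fragments, key=lambda f: f.span.as_tuple())
    out = []
    for a in frags:
        for b in frags:
            if not allow_self and a.span == b.span:
                continue
            out.append(FusionPeptide(a, b))
    return out


def junction_windows(fusion: FusionPeptide, w: int = 12) -> list[HipCandidate]:
    """Sliding width-``w`` windows of a fusion that cross the junction.

    Windows lying entirely within one parent fragment are native proinsulin
    peptides, not hybrids, and are excluded.  For a 24-mer fusion and w=12
    the surviving offsets are 1..11.
    """
    n = len(fusion.sequence)
    if w > n:
        raise ValueError(f"window width {w} exceeds fusion length {n}")
    if w < 2:
        raise ValueError("window width must be >= 2 to span a junction")
    j = fusion.junction_index
    out = []
    for offset in range(0, n - w + 1):
        left_len = j - offset
        right_len = offset + w - j
        if left_len < 1 or right_len < 1:
            continue
        out.append(
            HipCandidate(
                sequence=fusion.sequence[offset : offset + w],
                parent=fusion,
                offset=offset,
                left_len=left_len,
                right_len=right_len,
            )
        )
    return out


class BindingPredictor:
    """Interface: map a peptide sequence to a rank score (lower = stronger)."""

    predictor_id: str = "abstract"

    def score(self, sequence: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def score_many(self, sequences: Iterable[str]) -> dict[str, float]:
        out = {}
        for s in set(sequences):
            out[s] = self.score(s)
        return out


class TablePredictor(BindingPredictor):
    """Score lookup backed by an externally computed rank table.

    This is the faithful path for predictions exported from an MHC class II
    binding server (percentile ranks, lower = stronger binder).
    """

    def __init__(self, table: Mapping[str, float], predictor_id: str = "table"):
        self.predictor_id = predictor_id
        self._table = dict(table)

    def score(self, sequence: str) -> float:
        try:
            return self._table[sequence]
        except KeyError:
            raise KeyError(f"no score for sequence {sequence!r}") from None

    def score_many(self, sequences: Iterable[str]) -> dict[str, float]:
        seqs = set(sequences)
        missing = sorted(s for s in seqs if s not in self._table)
        if missing:
            raise KeyError(f"predictor table is missing {len(missing)} sequences: {missing[:5]}...")
        return {s: self._table[s] for s in seqs}


def load_predictor_table(path) -> TablePredictor:
    """Read a ``sequence,rank`` CSV whose header comments declare the rank
    direction.  Files that do not state ``# rank: ascending`` (lower =
    stronger) are refused rather than silently misread.
    """
    direction = None
    table: dict[str, float] = {}
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip().lower()
                if body.startswith("rank:"):
                    direction = body.split(":", 1)[1].strip()
                continue
            cols = [c.strip() for c in line.split(",")]
            if not header_seen:
                if cols[:2] != ["sequence", "rank"]:
                    raise ValueError("predictor table must have header 'sequence,rank'")
                header_seen = True
                continue
            table[cols[0]] = float(cols[1])
    if direction != "ascending":
        raise ValueError(
            "predictor table must declare '# rank: ascending' (lower = stronger); refusing file"
        )
    return TablePredictor(table)


# Position weights for a 9-mer binding core, loosely shaped like the HLA-DQ8
# motif (acidic preference at the P9 anchor, aliphatic P1, small P4/P6).
# Deterministic and documented, but NOT a validated predictor: it exists so
# the pipeline runs end-to-end without an external prediction server.
_SURROGATE_WEIGHTS: dict[int, dict[str, float]] = {
    0: {"F": -1.0, "Y": -1.0, "W": -0.8, "L": -0.8, "I": -0.8, "V": -0.6, "M": -0.6},
    3: {"A": -0.4, "S": -0.4, "G": -0.3, "T": -0.3, "D": -0.5, "E": -0.5},
    5: {"G": -0.3, "A": -0.3, "S": -0.3, "P": -0.2},
    8: {"E": -2.0, "D": -1.8, "Q": -0.5, "A": 0.0, "K": 1.0, "R": 1.0},
}


class SurrogatePwmPredictor(BindingPredictor):
    """Deterministic position-weight stand-in for an MHC class II predictor.

    Scores every 9-mer register of the peptide against a fixed weight table
    and reports the best (lowest) core score.  Shorter-than-9 peptides are
    scored on their single full-length register with the trailing weights.
    """

    predictor_id = "surrogate_pwm"

    def score(self, sequence: str) -> float:
        bad = set(sequence) - AMINO_ACIDS
        if bad or not sequence:
            raise ValueError(f"invalid peptide {sequence!r}")
        core = 9
        if len(sequence) < core:
            registers = [sequence]
        else:
            registers = [sequence[i : i + core] for i in range(len(sequence) - core + 1)]
        best = math.inf
        for reg in registers:
            s = 0.0
            for pos, aa in enumerate(reg):
                s += _SURROGATE_WEIGHTS.get(pos, {}).get(aa, 0.2)
            best = min(best, s)
        return best


class ConstantPredictor(BindingPredictor):
    """All sequences score identically (useful for q=1 / oracle tests)."""

    predictor_id = "constant"

    def __init__(self, value: float = 0.0):
        self._value = value

    def score(self, sequence: str) -> float:
        return self._value


def score_candidates(
    candidates: Sequence[HipCandidate], predictor: BindingPredictor
) -> list[HipCandidate]:
    """Attach a BindingScore to every candidate (identical sequences get
    identical scores by construction)."""
    scores = predictor.score_many(c.sequence for c in candidates)
    return [
        replace(c, score=BindingScore(predictor.predictor_id, scores[c.sequence]))
        for c in candidates
    ]


def select_top_fraction(candidates: Sequence[HipCandidate], q: float = 0.21) -> list[HipCandidate]:
    """The floor(q*N) candidates with the lowest (strongest) rank scores.

    Ties at the cut are broken by lexicographic sequence, then by
    (left span, right span, offset), so selection is fully deterministic.
    """
    if not (0 < q <= 1):
        raise ValueError(f"q must be in (0, 1], got {q}")
    unscored = [c for c in candidates if c.score is None]
    if unscored:
        raise ValueError(f"{len(unscored)} candidates are unscored")
    predictor_ids = {c.score.predictor_id for c in candidates}
    if len(predictor_ids) > 1:
        raise ValueError(f"scores from multiple predictors are not comparable: {predictor_ids}")
    n_keep = math.floor(q * len(candidates))
    ordered = sorted(candidates, key=lambda c: (c.score.value, c.sequence, c.sort_key()))
    return ordered[:n_keep]


def deduplicate(candidates: Sequence[HipCandidate]) -> Library:
    """Merge candidates with identical sequences into one library entry each,
    keeping every parental provenance; output sorted lexicographically."""
    by_seq: dict[str, list[HipCandidate]] = {}
    for c in candidates:
        by_seq.setdefault(c.sequence, []).append(c)
    entries = []
    for seq in sorted(by_seq):
        provs = tuple(sorted(by_seq[seq], key=lambda c: c.sort_key()))
        entries.append(
            LibraryEntry(
                member_id=sequence_id(seq),
                sequence=seq,
                provenances=provs,
                score=provs[0].score,
            )
        )
    return Library(entries=tuple(entries))


@dataclass(frozen=True)
class LibraryConfig:
    k: int = 12
    w: int = 12
    q: float = 0.21
    allow_self: bool = False
    dedup_first: bool = False  # sensitivity switch; default keeps dedup last


def build_library(
    config: LibraryConfig,
    predictor: BindingPredictor,
    seq: ProinsulinSequence | None = None,
) -> Library:
    """Full pipeline: fragment -> fuse -> junction windows -> score ->
    top-q selection -> deduplicate.  Emits stage counts in ``build_report``."""
    if seq is None:
        seq = canonical_proinsulin()
    if not (0 < config.q <= 1):
        raise ValueError(f"q must be in (0, 1], got {config.q}")
    fragments = fragment_kmers(seq, k=config.k)
    fusions = enumerate_fusions(fragments, allow_self=config.allow_self)
    candidates: list[HipCandidate] = []
    for fusion in fusions:
        candidates.extend(junction_windows(fusion, w=config.w))
    scored = score_candidates(candidates, predictor)
    if config.dedup_first:
        lib = deduplicate(scored)
        dedup_provs = [p for e in lib.entries for p in e.provenances[:1]]
        selected = select_top_fraction(dedup_provs, q=config.q)
        lib = deduplicate(selected)
    else:
        selected = select_top_fraction(scored, q=config.q)
        lib = deduplicate(selected)
    report = {
        "fragments": len(fragments),
        "fusions": len(fusions),
        "junction_candidates": len(candidates),
        "selected": len(selected),
        "library": len(lib.entries),
    }
    return Library(entries=lib.entries, build_report=report)
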