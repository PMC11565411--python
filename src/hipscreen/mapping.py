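"""Mapping identified HIPs back onto proinsulin.

Each hybrid peptide is a fusion of an N-terminal (left) and a C-terminal
(right) proinsulin fragment.  Given the junction position (known from the
sequenced plasmid, or enumerated when absent) each side is located in
proinsulin and assigned the region (B-chain, dibasic linker, C-peptide,
A-chain) covering the majority of its residues.  The origin summary counts
which regions contribute N- and C-terminal fragments — the analysis that
shows C-peptide dominating HIP formation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .proinsulin import (
    ProinsulinSequence,
    SequenceSpan,
    canonical_proinsulin,
    classify_span,
    locate_peptide,
)

__all__ = [
    "HipAnnotation",
    "annotate_hip",
    "origin_summary",
    "right_align_pfm",
    "pfm_to_frame",
    "hamming_distance",
]


@dataclass(frozen=True)
class SideAnnotation:
    sequence: str
    spans: tuple[SequenceSpan, ...]  # every occurrence in proinsulin
    origins: tuple[str, ...]  # majority region label per span

    @property
    def unambiguous_origin(self) -> str | None:
        labels = set(self.origins)
        return labels.pop() if len(labels) == 1 else None


@dataclass(frozen=True)
class HipAnnotation:
    hip_id: str
    sequence: str
    junction_index: int  # residues on the left side
    left: SideAnnotation
    right: SideAnnotation

    @property
    def ambiguous(self) -> bool:
        return self.left.unambiguous_origin is None or self.right.unambiguous_origin is None


def _annotate_side(fragment: str, seq: ProinsulinSequence, preferred: SequenceSpan | None):
    spans = locate_peptide(fragment, seq)
    if not spans:
        raise ValueError(f"fragment {fragment!r} not found in proinsulin")
    if preferred is not None and preferred in spans:
        spans = [preferred] + [s for s in spans if s != preferred]
    origins = tuple(classify_span(s, seq)[0] for s in spans)
    return SideAnnotation(fragment, tuple(spans), origins)


def annotate_hip(
    hip_sequence: str,
    junction_index: int | None = None,
    seq: ProinsulinSequence | None = None,
    hip_id: str | None = None,
    preferred_spans: tuple[SequenceSpan, SequenceSpan] | None = None,
) -> list[HipAnnotation]:
    """Annotate a HIP's two parental fragments.

    With ``junction_index`` given (residues contributed by the left
    fragment) a single annotation is returned; otherwise every split with
    both sides locatable in proinsulin is reported.  ``preferred_spans``
    (from sequencing provenance) promotes the consistent occurrence to the
    front when a fragment occurs more than once.
    """
    if seq is None:
        seq = canonical_proinsulin()
    if hip_id is None:
        hip_id = hip_sequence
    n = len(hip_sequence)
    if n < 2:
        raise ValueError("a hybrid peptide needs at least two residues")
    if junction_index is not None:
        if not (1 <= junction_index <= n - 1):
            raise ValueError(
                f"junction index {junction_index} leaves an empty side (peptide length {n})"
            )
        splits = [junction_index]
    else:
        splits = list(range(1, n))
    out = []
    for j in splits:
        left_seq, right_seq = hip_sequence[:j], hip_sequence[j:]
        try:
            left = _annotate_side(
                left_seq, seq, preferred_spans[0] if preferred_spans else None
            )
            right = _annotate_side(
                right_seq, seq, preferred_spans[1] if preferred_spans else None
            )
        except ValueError:
            if junction_index is not None:
                raise
            continue
        out.append(
            HipAnnotation(
                hip_id=hip_id,
                sequence=hip_sequence,
                junction_index=j,
                left=left,
                right=right,
            )
        )
    if not out:
        raise ValueError(f"no split of {hip_sequence!r} maps both sides to proinsulin")
    return out


def origin_summary(annotations: Sequence[HipAnnotation]) -> pd.DataFrame:
    """Counts and fractions of N-terminal and C-terminal fragment origins
    per proinsulin region.  Refuses annotations whose origin is ambiguous
    (multiple occurrences in different regions) — resolve those with
    provenance first."""
    if not annotations:
        raise ValueError("no annotations")
    unresolved = [a.hip_id for a in annotations if a.ambiguous]
    if unresolved:
        raise ValueError(f"ambiguous fragment origins for: {unresolved}")
    n = len(annotations)
    n_counts = Counter(a.left.unambiguous_origin for a in annotations)
    c_counts = Counter(a.right.unambiguous_origin for a in annotations)
    regions = sorted(set(n_counts) | set(c_counts))
    return pd.DataFrame(
        {
            "n_terminal_count": [n_counts.get(r, 0) for r in regions],
            "n_terminal_fraction": [n_counts.get(r, 0) / n for r in regions],
            "c_terminal_count": [c_counts.get(r, 0) for r in regions],
            "c_terminal_fraction": [c_counts.get(r, 0) / n for r in regions],
        },
        index=pd.Index(regions, name="region"),
    )


def right_align_pfm(sequences: Sequence[str]) -> dict[int, dict[str, int]]:
    """Position-frequency matrix with sequences aligned on their last
    residue: column 0 is the C-terminus, negative columns extend leftward.
    Each column's counts sum to the number of sequences covering it."""
    if not sequences:
        raise ValueError("no sequences")
    pfm: dict[int, dict[str, int]] = {}
    for s in sequences:
        for i, aa in enumerate(s):
            col = i - (len(s) - 1)
            pfm.setdefault(col, {})
            pfm[col][aa] = pfm[col].get(aa, 0) + 1
    return dict(sorted(pfm.items()))


def pfm_to_frame(pfm: Mapping[int, Mapping[str, int]]) -> pd.DataFrame:
    """Matrix view (rows = alignment columns, columns = residues), suitable
    for TSV export to logo-rendering tools."""
    residues = sorted({aa for col in pfm.values() for aa in col})
    data = {aa: [pfm[c].get(aa, 0) for c in sorted(pfm)] for aa in residues}
    return pd.DataFrame(data, index=pd.Index(sorted(pfm), name="offset"))


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences
    (no implicit alignment)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))
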