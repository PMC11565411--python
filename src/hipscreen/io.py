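"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA is the only sequence format; tabular data is CSV/TSV with documented
headers; ground truth and deconvolution results are JSON.  Every writer
round-trips losslessly through its reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library import Library, LibraryEntry, sequence_id
from .pools import PoolManifest, manifest_from_frame, manifest_to_frame
from .proinsulin import ProinsulinSequence, canonical_proinsulin
from .simulate import ANTIGEN_KINDS, READOUT_COLUMNS, ReactivityTruth

__all__ = [
    "write_proinsulin_fasta",
    "write_region_table",
    "write_library_fasta",
    "write_library_table",
    "read_library_table",
    "write_manifest",
    "read_manifest",
    "parse_readout_table",
    "write_readout_table",
    "write_truth_json",
    "read_truth_json",
    "read_cfse_counts",
    "ClonotypeRecord",
    "filter_tcr_clonotypes",
    "read_clonotype_table",
    "packaged_proinsulin_fasta",
    "packaged_hip_panel",
]


def write_proinsulin_fasta(path, seq: ProinsulinSequence | None = None) -> None:
    if seq is None:
        seq = canonical_proinsulin()
    rec = SeqRecord(Seq(seq.residues), id="proinsulin_human", description="mature human proinsulin (86 aa)")
    SeqIO.write([rec], path, "fasta")


def write_region_table(path, seq: ProinsulinSequence | None = None) -> None:
    """BED-like region TSV; coordinates are 1-based inclusive."""
    if seq is None:
        seq = canonical_proinsulin()
    with open(path, "w") as fh:
        fh.write("# proinsulin regions; start/end are 1-based inclusive\n")
        fh.write("label\tstart\tend\n")
        for label, start, end in seq.regions:
            fh.write(f"{label}\t{start}\t{end}\n")


def write_library_fasta(path, library: Library) -> None:
    records = []
    for e in library.entries:
        p = e.provenances[0]
        desc = (
            f"left={p.parent.left.span.as_tuple()} right={p.parent.right.span.as_tuple()} "
            f"offset={p.offset}"
        )
        records.append(SeqRecord(Seq(e.sequence), id=e.member_id, description=desc))
    SeqIO.write(records, path, "fasta")


def write_library_table(path, library: Library) -> None:
    rows = []
    for e in library.entries:
        p = e.provenances[0]
        rows.append(
            {
                "member_id": e.member_id,
                "sequence": e.sequence,
                "left_start": p.parent.left.span.start,
                "left_end": p.parent.left.span.end,
                "right_start": p.parent.right.span.start,
                "right_end": p.parent.right.span.end,
                "left_len": p.left_len,
                "right_len": p.right_len,
                "score": e.score.value if e.score else "",
                "n_provenances": len(e.provenances),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, manifest: PoolManifest) -> None:
    manifest_to_frame(manifest).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> PoolManifest:
    return manifest_from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


def parse_readout_table(path) -> pd.DataFrame:
    """Read a plate-readout CSV, validating schema and antigen kinds."""
    df = pd.read_csv(path)
    missing = [c for c in READOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"readout table is missing columns: {missing}")
    unknown = set(df["antigen_kind"]) - ANTIGEN_KINDS
    if unknown:
        raise ValueError(f"unknown antigen kinds: {sorted(unknown)}")
    if not pd.api.types.is_numeric_dtype(df["rlu"]):
        raise ValueError("rlu column must be numeric")
    if not pd.api.types.is_integer_dtype(df["replicate"]):
        raise ValueError("replicate column must be integer")
    return df[READOUT_COLUMNS]


def write_readout_table(path, readouts: pd.DataFrame) -> None:
    readouts[READOUT_COLUMNS].to_csv(path, index=False)


def write_truth_json(path, truth: ReactivityTruth) -> None:
    payload = [
        {"avatar": a, "member_id": m, "potency_molar": p}
        for (a, m), p in sorted(truth.entries.items())
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth_json(path) -> ReactivityTruth:
    payload = json.loads(Path(path).read_text())
    return ReactivityTruth(
        entries={(r["avatar"], r["member_id"]): r["potency_molar"] for r in payload}
    )


def read_cfse_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["subject", "group", "antigen", "dim_with", "dim_without"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CFSE counts table is missing columns: {missing}")
    return df


# -- TCR clonotype selection --------------------------------------------------


@dataclass(frozen=True)
class ClonotypeRecord:
    cell_id: str
    trav_genes: tuple[str, ...]
    trbv_genes: tuple[str, ...]
    abundance: int


def filter_tcr_clonotypes(
    records: Sequence[ClonotypeRecord], top_n: int | None = None
) -> list[ClonotypeRecord]:
    """Keep cells with exactly one TRBV and one or two TRAV genes — the
    clonotypes whose TCR chain pairing is unambiguous enough to clone.
    With ``top_n``, keep the most abundant clonotypes (ties by cell id)."""
    kept = [
        r
        for r in records
        if len(r.trbv_genes) == 1 and len(r.trav_genes) in (1, 2)
    ]
    if top_n is not None:
        kept = sorted(kept, key=lambda r: (-r.abundance, r.cell_id))[:top_n]
    return kept


def read_clonotype_table(path) -> list[ClonotypeRecord]:
    """CSV with columns cell_id, trav (semicolon-separated), trbv
    (semicolon-separated), abundance."""
    df = pd.read_csv(path)
    required = ["cell_id", "trav", "trbv", "abundance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clonotype table is missing columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        trav = tuple(g for g in str(row.trav).split(";") if g and g != "nan")
        trbv = tuple(g for g in str(row.trbv).split(";") if g and g != "nan")
        if not trav and not trbv:
            raise ValueError(f"row {i}: no TRAV/TRBV genes parsed")
        try:
            abundance = int(row.abundance)
        except (TypeError, ValueError):
            raise ValueError(f"row {i}: non-integer abundance {row.abundance!r}") from None
        out.append(ClonotypeRecord(str(row.cell_id), trav, trbv, abundance))
    return out


# -- packaged fixtures ---------------------------------------------------------


def packaged_proinsulin_fasta() -> str:
    """Path-like access to the shipped proinsulin FASTA fixture."""
    return str(resources.files("hipscreen.data") / "proinsulin_human.fasta")


def packaged_hip_panel() -> pd.DataFrame:
    """The 13-member HIP panel used for fragment-origin analysis.

    Two members are the published main-text sequences; the remaining 11 are
    synthetic fusions constructed to match the reported aggregate origin
    distribution (see the file header).
    """
    path = resources.files("hipscreen.data") / "synthetic_hip_panel.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")
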