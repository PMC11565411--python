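"""Pool / super-pool design and library-representation QC.

The screen divides the library into fixed-size pools (default 33 members,
giving 136 pools for a 4,488-member library), then groups pools four at a
time into super-pools (34 for 136 pools).  Representation QC works on
transcript-per-million (TPM) abundances computed from sequencing counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import Library

__all__ = [
    "PoolManifest",
    "partition_pools",
    "group_superpools",
    "counts_to_tpm",
    "representation_report",
    "manifest_to_frame",
    "manifest_from_frame",
]


@dataclass(frozen=True)
class PoolManifest:
    """Assignment of library members to pools and pools to super-pools."""

    pool_assignments: Mapping[str, tuple[str, ...]]  # pool id -> member ids
    superpool_assignments: Mapping[str, tuple[str, ...]]  # super-pool id -> pool ids
    pool_size: int
    group_size: int | None = None
    sequences: Mapping[str, str] = field(default_factory=dict)  # member id -> sequence

    @property
    def pool_ids(self) -> list[str]:
        return list(self.pool_assignments)

    @property
    def superpool_ids(self) -> list[str]:
        return list(self.superpool_assignments)

    def members_of_pool(self, pool_id: str) -> tuple[str, ...]:
        return self.pool_assignments[pool_id]

    def members_of_superpool(self, superpool_id: str) -> tuple[str, ...]:
        out: list[str] = []
        for pid in self.superpool_assignments[superpool_id]:
            out.extend(self.pool_assignments[pid])
        return tuple(out)

    def pool_of_member(self, member_id: str) -> str:
        for pid, members in self.pool_assignments.items():
            if member_id in members:
                return pid
        raise KeyError(member_id)

    def superpool_of_pool(self, pool_id: str) -> str:
        for sid, pids in self.superpool_assignments.items():
            if pool_id in pids:
                return sid
        raise KeyError(pool_id)

    def validate_partition(self, member_ids: Sequence[str]) -> None:
        pooled = [m for members in self.pool_assignments.values() for m in members]
        if len(pooled) != len(set(pooled)):
            raise ValueError("pools overlap")
        if set(pooled) != set(member_ids):
            raise ValueError("pools do not cover the library")


def _pool_id(i: int) -> str:
    return f"pool{i + 1:04d}"


def _superpool_id(i: int) -> str:
    return f"sp{i + 1:03d}"


def partition_pools(
    library: Library, pool_size: int = 33, seed: int | None = 0
) -> PoolManifest:
    """Shuffle members with a seeded RNG and chunk into pools of
    ``pool_size`` (the last pool may be short).  ``seed=None`` keeps the
    library's lexicographic order (no shuffle)."""
    if pool_size < 1:
        raise ValueError(f"pool_size must be >= 1, got {pool_size}")
    if len(library) == 0:
        raise ValueError("library is empty")
    ids = library.member_ids()
    if seed is not None:
        rng = np.random.default_rng(seed)
        ids = [ids[i] for i in rng.permutation(len(ids))]
    assignments = {}
    for i in range(0, len(ids), pool_size):
        assignments[_pool_id(i // pool_size)] = tuple(ids[i : i + pool_size])
    sequences = {e.member_id: e.sequence for e in library.entries}
    return PoolManifest(
        pool_assignments=assignments,
        superpool_assignments={},
        pool_size=pool_size,
        sequences=sequences,
    )


def group_superpools(manifest: PoolManifest, group_size: int = 4) -> PoolManifest:
    """Group pools in id order into super-pools of ``group_size`` pools
    (the last super-pool may be short)."""
    if group_size < 1:
        raise ValueError(f"group_size must be >= 1, got {group_size}")
    pids = manifest.pool_ids
    superpools = {}
    for i in range(0, len(pids), group_size):
        superpools[_superpool_id(i // group_size)] = tuple(pids[i : i + group_size])
    return PoolManifest(
        pool_assignments=manifest.pool_assignments,
        superpool_assignments=superpools,
        pool_size=manifest.pool_size,
        group_size=group_size,
        sequences=manifest.sequences,
    )


def counts_to_tpm(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> pd.DataFrame:
    """Length-normalised abundances: tpm_i = (c_i/l_i) / sum_j(c_j/l_j) * 1e6.

    Returns a DataFrame indexed by member id with columns
    ``count, effective_length, tpm``.  All-zero counts yield all-zero TPM.
    """
    missing = sorted(set(counts) - set(lengths))
    if missing:
        raise KeyError(f"missing effective length for ids: {missing[:5]}")
    ids = sorted(counts)
    c = np.asarray([counts[i] for i in ids], dtype=float)
    l = np.asarray([lengths[i] for i in ids], dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(l <= 0):
        raise ValueError("effective lengths must be positive")
    rate = c / l
    total = rate.sum()
    if total == 0:
        import warnings

        warnings.warn("all counts are zero; TPM undefined, reporting zeros")
        tpm = np.zeros_like(rate)
    else:
        tpm = rate / total * 1e6
    return pd.DataFrame(
        {"count": c, "effective_length": l, "tpm": tpm}, index=pd.Index(ids, name="id")
    )


def representation_report(
    table: pd.DataFrame, min_tpm: float = 26.0
) -> tuple[float, list[str]]:
    """(fraction of members with tpm strictly above ``min_tpm``,
    under-represented ids sorted by tpm ascending)."""
    if min_tpm < 0:
        raise ValueError("min_tpm must be >= 0")
    if len(table) == 0:
        raise ValueError("empty abundance table")
    ok = table["tpm"] > min_tpm
    under = table.loc[~ok, "tpm"].sort_values()
    return float(ok.mean()), list(under.index)


def manifest_to_frame(manifest: PoolManifest) -> pd.DataFrame:
    """Flat TSV-ready view: one row per member with pool and super-pool ids."""
    sp_of_pool = {
        pid: sid for sid, pids in manifest.superpool_assignments.items() for pid in pids
    }
    rows = []
    for pid, members in manifest.pool_assignments.items():
        for m in members:
            rows.append(
                {
                    "member_id": m,
                    "sequence": manifest.sequences.get(m, ""),
                    "pool_id": pid,
                    "superpool_id": sp_of_pool.get(pid, ""),
                }
            )
    return pd.DataFrame(rows)


def manifest_from_frame(frame: pd.DataFrame) -> PoolManifest:
    """Inverse of :func:`manifest_to_frame` (lossless round-trip)."""
    pools: dict[str, list[str]] = {}
    superpools: dict[str, list[str]] = {}
    sequences: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        pools.setdefault(row.pool_id, []).append(row.member_id)
        if isinstance(row.sequence, str) and row.sequence:
            sequences[row.member_id] = row.sequence
        sid = getattr(row, "superpool_id", "")
        if isinstance(sid, str) and sid:
            if row.pool_id not in superpools.setdefault(sid, []):
                superpools[sid].append(row.pool_id)
    pool_size = max(len(v) for v in pools.values())
    group_size = max((len(v) for v in superpools.values()), default=None)
    return PoolManifest(
        pool_assignments={k: tuple(v) for k, v in pools.items()},
        superpool_assignments={k: tuple(v) for k, v in superpools.items()},
        pool_size=pool_size,
        group_size=group_size,
        sequences=sequences,
    )
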