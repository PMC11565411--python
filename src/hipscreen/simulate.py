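"""Synthetic screen generator.

Simulates the three-granularity luciferase screen (super-pools, pools,
single colonies), synthetic-peptide dose-response plates, and CFSE
proliferation cohorts against a planted ground truth of TCR-avatar
reactivities.  The generative model:

* a well's luminescence is ``(background + signal) * eps`` with
  multiplicative lognormal noise ``eps ~ LogNormal(0, sigma^2)`` —
  luciferase readouts are positive and heteroscedastic;
* the activation signal follows a Hill curve of the agonist concentration;
  in a pooled well each member is diluted to ``dose / pool_size`` and the
  strongest agonist dominates (the reporter saturates; additive combination
  is available as an option);
* antigen-negative wells (GST-only bacteria, no antigen) carry zero signal.

All randomness flows from explicit integer seeds, so every simulated plate
is exactly reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pools import PoolManifest

__all__ = [
    "ReactivityTruth",
    "NoiseModel",
    "READOUT_COLUMNS",
    "ANTIGEN_KINDS",
    "hill",
    "plant_reactivity",
    "headline_scenario",
    "simulate_plate",
    "draw_colonies",
    "simulate_dose_response",
    "simulate_cfse_cohort",
    "SimulatedScreen",
]

READOUT_COLUMNS = [
    "plate_id",
    "well_id",
    "avatar_id",
    "antigen_id",
    "antigen_kind",
    "replicate",
    "rlu",
]

ANTIGEN_KINDS = {"superpool", "pool", "colony", "peptide", "GST_control", "no_antigen"}


@dataclass(frozen=True)
class ReactivityTruth:
    """Planted ground truth: (avatar, library member) -> EC50 in molar.

    Pairs absent from ``entries`` are non-reactive.
    """

    entries: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (_, _), pot in self.entries.items():
            if not (pot > 0):
                raise ValueError("potencies must be strictly positive")

    def potency(self, avatar_id: str, member_id: str) -> float | None:
        return self.entries.get((avatar_id, member_id))

    def reactive_avatars(self) -> set[str]:
        return {a for a, _ in self.entries}

    def reactive_members(self) -> set[str]:
        return {m for _, m in self.entries}


@dataclass(frozen=True)
class NoiseModel:
    """Generative parameters for luciferase readouts (RLU units)."""

    background_mean: float = 2000.0
    signal_max: float = 50000.0
    lognormal_sigma: float = 0.15
    hill_slope: float = 1.0
    dropout_prob: float = 0.0
    pool_dilution: bool = True
    combine: str = "max"  # or "sum" (saturating)

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")
        if self.signal_max < 0 or self.lognormal_sigma < 0:
            raise ValueError("signal_max and lognormal_sigma must be >= 0")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.combine not in ("max", "sum"):
            raise ValueError("combine must be 'max' or 'sum'")


def hill(conc: float, ec50: float, slope: float = 1.0) -> float:
    """Fractional occupancy ``conc^h / (conc^h + ec50^h)`` (0 at conc=0)."""
    if conc <= 0:
        return 0.0
    return 1.0 / (1.0 + (ec50 / conc) ** slope)


def plant_reactivity(
    avatars: Sequence[str],
    member_ids: Sequence[str],
    planted: Sequence[tuple[str, str, float]],
) -> ReactivityTruth:
    """Build a ReactivityTruth from (avatar, member, potency) triples,
    validating that every planted member exists in the library."""
    members = set(member_ids)
    avset = set(avatars)
    entries = {}
    for avatar, member, potency in planted:
        if member not in members:
            raise KeyError(f"planted sequence {member!r} is not in the library")
        if avatar not in avset:
            raise KeyError(f"planted avatar {avatar!r} is not in the panel")
        entries[(avatar, member)] = potency
    return ReactivityTruth(entries=entries)


# Avatar multiplicities of the headline screen outcome: nine reactive
# avatars recognising 13 distinct library members, with one avatar
# responding to eight members, two to three, one to two and five to one
# (members shared between avatars where the counts require it).
_HEADLINE_PATTERN: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 3, 4, 5, 6, 7),
    (0, 4, 5),
    (5,),
    (6,),
    (6,),
    (8,),
    (9,),
    (10, 11, 12),
    (1, 3),
)


def headline_scenario(
    member_ids: Sequence[str],
    n_avatars: int = 109,
    seed: int = 0,
    potency_range: tuple[float, float] = (20e-9, 20e-6),
) -> tuple[list[str], ReactivityTruth]:
    """The screen's headline ground truth: ``n_avatars`` avatars of which
    nine react, to 13 distinct library members, potencies log-spaced over
    ``potency_range`` (default 20 nM - 20 uM).

    Returns (avatar ids, truth).  Member choice and the identity of the
    reactive avatars are drawn with the given seed.
    """
    if len(member_ids) < 13:
        raise ValueError("need at least 13 library members")
    rng = np.random.default_rng(seed)
    avatars = [f"av{i + 1:03d}" for i in range(n_avatars)]
    reactive = sorted(rng.choice(n_avatars, size=len(_HEADLINE_PATTERN), replace=False))
    chosen = [member_ids[i] for i in sorted(rng.choice(len(member_ids), size=13, replace=False))]
    potencies = np.geomspace(potency_range[0], potency_range[1], 13)
    planted = []
    for av_idx, member_idxs in zip(reactive, _HEADLINE_PATTERN):
        for mi in member_idxs:
            planted.append((avatars[av_idx], chosen[mi], float(potencies[mi])))
    return avatars, plant_reactivity(avatars, member_ids, planted)


def _well_signal(
    truth: ReactivityTruth,
    avatar_id: str,
    members: Sequence[str],
    dose: float,
    noise: NoiseModel,
    dropped: set[str],
) -> float:
    if not members:
        return 0.0
    conc = dose / len(members) if (noise.pool_dilution and len(members) > 1) else dose
    fractions = []
    for m in members:
        if m in dropped:
            continue
        pot = truth.potency(avatar_id, m)
        if pot is not None:
            fractions.append(hill(conc, pot, noise.hill_slope))
    if not fractions:
        return 0.0
    if noise.combine == "max":
        frac = max(fractions)
    else:
        frac = min(sum(fractions), 1.0)
    return noise.signal_max * frac


def _resolve(
    manifest: PoolManifest,
    antigen_kind: str,
    antigen_id: str,
    colony_map: Mapping[str, str] | None,
) -> list[str]:
    if antigen_kind == "superpool":
        return list(manifest.members_of_superpool(antigen_id))
    if antigen_kind == "pool":
        return list(manifest.members_of_pool(antigen_id))
    if antigen_kind == "colony":
        if colony_map is None or antigen_id not in colony_map:
            raise KeyError(f"colony {antigen_id!r} has no member mapping")
        return [colony_map[antigen_id]]
    if antigen_kind == "peptide":
        return [antigen_id]
    if antigen_kind in ("GST_control", "no_antigen"):
        return []
    raise ValueError(f"unresolvable antigen kind {antigen_kind!r}")


def simulate_plate(
    truth: ReactivityTruth,
    manifest: PoolManifest,
    antigen_kind: str,
    antigens: Sequence[str],
    avatar_ids: Sequence[str],
    dose: float,
    noise: NoiseModel,
    replicates: int = 3,
    seed: int = 0,
    colony_map: Mapping[str, str] | None = None,
    control_wells: int = 3,
    plate_prefix: str = "plate",
) -> pd.DataFrame:
    """One simulated plate per avatar: the requested antigens in
    ``replicates`` wells each, plus GST-only and no-antigen control wells.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if antigen_kind not in ANTIGEN_KINDS:
        raise ValueError(f"unknown antigen kind {antigen_kind!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for avatar_id in avatar_ids:
        plate_id = f"{plate_prefix}_{avatar_id}_{antigen_kind}"
        well = 0
        dropped: set[str] = set()
        if noise.dropout_prob > 0:
            all_members = {
                m
                for a in antigens
                for m in _resolve(manifest, antigen_kind, a, colony_map)
            }
            dropped = {m for m in all_members if rng.random() < noise.dropout_prob}
        layout = [(a, antigen_kind, replicates) for a in antigens]
        layout.append(("GST", "GST_control", control_wells))
        layout.append(("none", "no_antigen", control_wells))
        for antigen_id, kind, reps in layout:
            members = _resolve(manifest, kind, antigen_id, colony_map)
            signal = _well_signal(truth, avatar_id, members, dose, noise, dropped)
            for rep in range(1, reps + 1):
                eps = (
                    math.exp(rng.normal(0.0, noise.lognormal_sigma))
                    if noise.lognormal_sigma > 0
                    else 1.0
                )
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well_id": f"w{(well := well + 1):03d}",
                        "avatar_id": avatar_id,
                        "antigen_id": antigen_id,
                        "antigen_kind": kind,
                        "replicate": rep,
                        "rlu": (noise.background_mean + signal) * eps,
                    }
                )
    return pd.DataFrame(rows, columns=READOUT_COLUMNS)


def draw_colonies(
    pool_members: Sequence[str],
    n: int,
    skew: float = math.inf,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Sample ``n`` bacterial colonies from a pool.

    Colony identities follow a Dirichlet-multinomial with symmetric
    concentration ``skew`` per member; ``skew = inf`` is the uniform
    multinomial (every member equally likely).
    """
    if not pool_members:
        raise ValueError("pool is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (skew > 0):
        raise ValueError("skew must be > 0")
    rng = np.random.default_rng(seed)
    k = len(pool_members)
    if math.isinf(skew):
        probs = np.full(k, 1.0 / k)
    else:
        probs = rng.dirichlet(np.full(k, skew))
    draws = rng.choice(k, size=n, p=probs)
    return [(f"colony{i + 1:03d}", pool_members[j]) for i, j in enumerate(draws)]


def simulate_dose_response(
    potency: float | None,
    doses: Sequence[float],
    replicates: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
    avatar_id: str = "avatar",
    antigen_id: str = "peptide",
) -> pd.DataFrame:
    """Synthetic-peptide titration: one row per dose x replicate with
    columns ``avatar_id, antigen_id, dose_molar, replicate, rlu``.
    ``potency=None`` simulates a non-reactive avatar (flat background)."""
    doses = list(doses)
    if len(doses) < 4 or any(d <= 0 for d in doses):
        raise ValueError("need >= 4 strictly positive doses")
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        signal = (
            noise.signal_max * hill(dose, potency, noise.hill_slope)
            if potency is not None
            else 0.0
        )
        for rep in range(1, replicates + 1):
            eps = (
                math.exp(rng.normal(0.0, noise.lognormal_sigma))
                if noise.lognormal_sigma > 0
                else 1.0
            )
            rows.append(
                {
                    "avatar_id": avatar_id,
                    "antigen_id": antigen_id,
                    "dose_molar": dose,
                    "replicate": rep,
                    "rlu": (noise.background_mean + signal) * eps,
                }
            )
    return pd.DataFrame(rows)


def simulate_cfse_cohort(
    group_probs: Mapping[str, float],
    effect_size: float = 10.0,
    lam: float = 20.0,
    n_subjects: int = 10,
    antigens: Sequence[str] = ("antigen",),
    seed: int = 0,
) -> pd.DataFrame:
    """CFSE proliferation cohort: per subject x antigen, counts of divided
    (CFSE-dim) CD4+ cells per 5,000 undivided (CFSE-bright) cells with and
    without antigen.

    Each subject is a responder to each antigen with their group's
    probability; responders divide ``effect_size`` times more with antigen
    than without; counts are Poisson around rate ``lam`` (without antigen).
    """
    for g, p in group_probs.items():
        if not (0 <= p <= 1):
            raise ValueError(f"responder probability for {g!r} outside [0, 1]")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if effect_size <= 0 or lam <= 0:
        raise ValueError("effect_size and lam must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, p in group_probs.items():
        for s in range(1, n_subjects + 1):
            subject = f"{group}_{s:03d}"
            for antigen in antigens:
                responder = rng.random() < p
                cdi_true = effect_size if responder else 1.0
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "antigen": antigen,
                        "dim_with": int(rng.poisson(lam * cdi_true)),
                        "dim_without": int(rng.poisson(lam)),
                        "responder_true": bool(responder),
                    }
                )
    return pd.DataFrame(rows)


def simulate_library_counts(
    member_ids: Sequence[str],
    total_reads: int = 2_000_000,
    concentration: float = 2.5,
    seed: int = 0,
) -> dict[str, int]:
    """Sequencing read counts for a cloned library.

    Member representation is symmetric-Dirichlet (concentration per member;
    smaller = more skewed cloning/amplification bias) and reads are
    multinomial.  The default concentration models a well-made library in
    which the large majority of members stay above the representation QC
    threshold.
    """
    if not member_ids:
        raise ValueError("no members")
    if total_reads < 1 or concentration <= 0:
        raise ValueError("total_reads must be >= 1 and concentration > 0")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(len(member_ids), concentration))
    counts = rng.multinomial(total_reads, probs)
    return {m: int(c) for m, c in zip(member_ids, counts)}


def _id_hash(*parts: str) -> int:
    return zlib.crc32("|".join(parts).encode())


class SimulatedScreen:
    """Stage-addressable readout source backed by the generative model.

    Answers the super-pool / pool / colony queries that staged
    deconvolution issues, deterministically for a given master seed (each
    plate derives its own seed from the master seed and the query).
    """

    def __init__(
        self,
        truth: ReactivityTruth,
        manifest: PoolManifest,
        noise: NoiseModel | None = None,
        dose: float = 2e-3,
        seed: int = 0,
        replicates: tuple[int, int, int] = (3, 3, 2),
    ):
        self.truth = truth
        self.manifest = manifest
        self.noise = noise if noise is not None else NoiseModel()
        self.dose = dose
        self.seed = seed
        self.replicates = replicates

    def _derived_seed(self, *parts: str) -> int:
        ss = np.random.SeedSequence([self.seed, _id_hash(*parts)])
        return int(ss.generate_state(1)[0])

    def superpool_readouts(self, avatar_id: str) -> pd.DataFrame:
        return simulate_plate(
            self.truth,
            self.manifest,
            "superpool",
            self.manifest.superpool_ids,
            [avatar_id],
            self.dose,
            self.noise,
            replicates=self.replicates[0],
            seed=self._derived_seed("stage1", avatar_id),
            plate_prefix="s1",
        )

    def pool_readouts(self, avatar_id: str, superpool_id: str) -> pd.DataFrame:
        pools = list(self.manifest.superpool_assignments[superpool_id])
        sp = simulate_plate(
            self.truth,
            self.manifest,
            "superpool",
            [superpool_id],
            [avatar_id],
            self.dose,
            self.noise,
            replicates=self.replicates[1],
            seed=self._derived_seed("stage2sp", avatar_id, superpool_id),
            plate_prefix="s2",
        )
        pl = simulate_plate(
            self.truth,
            self.manifest,
            "pool",
            pools,
            [avatar_id],
            self.dose,
            self.noise,
            replicates=self.replicates[1],
            seed=self._derived_seed("stage2", avatar_id, superpool_id),
            plate_prefix="s2",
        )
        # one plate per avatar and stage: merge super-pool retest and pools
        pl["plate_id"] = sp["plate_id"].iloc[0]
        return pd.concat([sp, pl], ignore_index=True)

    def colony_readouts(
        self,
        avatar_id: str,
        pool_id: str,
        colonies: Sequence[tuple[str, str]],
        batch: int = 0,
    ) -> pd.DataFrame:
        """Colony plate; ``batch`` distinguishes independent re-screens of
        the same colonies (confirmation runs)."""
        colony_map = {cid: m for cid, m in colonies}
        return simulate_plate(
            self.truth,
            self.manifest,
            "colony",
            [cid for cid, _ in colonies],
            [avatar_id],
            self.dose,
            self.noise,
            replicates=self.replicates[2],
            seed=self._derived_seed("stage3", avatar_id, pool_id, f"b{batch}"),
            colony_map=colony_map,
            plate_prefix=f"s3b{batch}" if batch else "s3",
        )

    def draw_pool_colonies(
        self, pool_id: str, n: int | None, skew: float = math.inf
    ) -> list[tuple[str, str]]:
        """Sample colonies from a pool; ``n=None`` gives exhaustive coverage
        (one colony per member)."""
        members = self.manifest.members_of_pool(pool_id)
        if n is None:
            return [(f"colony{i + 1:03d}", m) for i, m in enumerate(members)]
        return draw_colonies(
            members, n, skew=skew, seed=self._derived_seed("colonies", pool_id)
        )
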