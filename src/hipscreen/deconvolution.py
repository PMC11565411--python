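"""Hit calling and three-stage screen deconvolution.

A well's response is the Delta-luciferase: its RLU minus the mean of the
antigen-negative (GST-only) control wells on the same plate.  An antigen is
positive when its mean replicate delta exceeds ``k`` (default 2) standard
deviations of the control wells; optionally a one-way ANOVA with Dunnett's
many-to-one comparison against the control must also be significant.

Deconvolution narrows a response in three stages: all super-pools, then the
positive super-pools re-tested alongside their component pools (a super-pool
response that fails re-testing is discarded), then single colonies from the
positive pools screened in duplicate.  The identified hybrid peptides are
the members carried by positive colonies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pools import PoolManifest

__all__ = [
    "HitCall",
    "IdentifiedHip",
    "DeconvolutionResult",
    "ScreenPolicy",
    "ReadoutSource",
    "FileReadoutSource",
    "PairedResult",
    "delta_luciferase",
    "call_hits",
    "dunnett_compare",
    "run_deconvolution",
    "paired_comparison",
]


@dataclass(frozen=True)
class HitCall:
    avatar_id: str
    antigen_id: str
    antigen_kind: str
    delta_rlu: float  # mean replicate delta
    threshold: float
    positive: bool
    adjusted_p: float | None = None


@dataclass(frozen=True)
class IdentifiedHip:
    member_id: str
    sequence: str
    superpool_id: str
    pool_id: str
    colony_ids: tuple[str, ...]
    stage_deltas: Mapping[str, float]


@dataclass
class DeconvolutionResult:
    identifications: dict[str, list[IdentifiedHip]] = field(default_factory=dict)

    def positive_avatars(self) -> list[str]:
        return sorted(a for a, hips in self.identifications.items() if hips)

    def distinct_sequences(self) -> set[str]:
        return {h.sequence for hips in self.identifications.values() for h in hips}

    def validate_chains(self, manifest: PoolManifest) -> None:
        """Soundness: every evidence chain is consistent with the manifest."""
        for avatar, hips in self.identifications.items():
            for h in hips:
                if h.member_id not in manifest.members_of_pool(h.pool_id):
                    raise ValueError(f"{avatar}: {h.member_id} not in {h.pool_id}")
                if h.pool_id not in manifest.superpool_assignments[h.superpool_id]:
                    raise ValueError(f"{avatar}: {h.pool_id} not in {h.superpool_id}")

    def to_json(self) -> str:
        payload = {
            avatar: [
                {
                    "member_id": h.member_id,
                    "sequence": h.sequence,
                    "superpool_id": h.superpool_id,
                    "pool_id": h.pool_id,
                    "colony_ids": list(h.colony_ids),
                    "stage_deltas": dict(h.stage_deltas),
                }
                for h in hips
            ]
            for avatar, hips in self.identifications.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def delta_luciferase(
    readouts: pd.DataFrame, control_kind: str = "GST_control"
) -> pd.DataFrame:
    """Per-well delta: RLU minus the mean control RLU within each
    (plate, avatar) stratum.  Control wells' deltas average zero by
    construction."""
    out = []
    for (plate, avatar), grp in readouts.groupby(["plate_id", "avatar_id"], sort=False):
        controls = grp.loc[grp["antigen_kind"] == control_kind, "rlu"]
        if len(controls) < 2:
            raise ValueError(
                f"stratum (plate={plate!r}, avatar={avatar!r}) has "
                f"{len(controls)} {control_kind} wells; need >= 2"
            )
        grp = grp.copy()
        grp["delta"] = grp["rlu"] - controls.mean()
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def _dunnett_max_cdf(t: np.ndarray, k: int, n: int, n0: int, df: int, two_sided: bool) -> np.ndarray:
    """P(max_j T_j <= t) (or max |T_j|) for k balanced many-to-one
    comparisons (group size n, control size n0, pooled df) via quadrature
    over the shared control variate and the chi-distributed scale."""
    rho = n / (n + n0)
    a, b = math.sqrt(rho), math.sqrt(1.0 - rho)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(80)  # weight exp(-x^2/2)
    gh_w = gh_w / math.sqrt(2 * math.pi)
    s_nodes, s_w = np.polynomial.legendre.leggauss(64)
    s_prob = (s_nodes + 1) / 2  # (0,1)
    s_w = s_w / 2
    u = np.sqrt(stats.chi2.ppf(s_prob, df) / df)  # S/sigma quantiles
    t = np.atleast_1d(np.asarray(t, dtype=float))
    # grids: (t, u, x)
    tu = t[:, None, None] * u[None, :, None]
    x = gh_x[None, None, :]
    upper = stats.norm.cdf((tu - a * x) / b)
    if two_sided:
        lower = stats.norm.cdf((-tu - a * x) / b)
        inner = np.clip(upper - lower, 0.0, 1.0) ** k
    else:
        inner = upper**k
    over_x = inner @ gh_w
    return over_x @ s_w


@dataclass(frozen=True)
class DunnettResult:
    statistics: pd.Series  # per antigen t statistic
    adjusted_p: pd.Series  # family-wise adjusted p per antigen
    anova_p: float
    df: int


def dunnett_compare(
    groups: Mapping[str, Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
    alternative: str = "greater",
) -> DunnettResult:
    """One-way ANOVA followed by Dunnett's many-to-one comparisons of every
    group against the control, with family-wise error control.

    Balanced designs (all groups the same size) use an exact quadrature of
    the multivariate-t max statistic; unbalanced designs fall back to
    :func:`scipy.stats.dunnett`.
    """
    if len(groups) < 1:
        raise ValueError("need at least one comparison group")
    names = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in names]
    ctrl = np.asarray(control, dtype=float)
    if any(len(a) < 2 for a in arrs) or len(ctrl) < 2:
        raise ValueError("every group (and the control) needs >= 2 replicates")
    anova_p = float(stats.f_oneway(*arrs, ctrl).pvalue) if len(arrs) >= 1 else 1.0
    if math.isnan(anova_p):  # zero within-group variance
        anova_p = 1.0
    sizes = {len(a) for a in arrs}
    if len(sizes) == 1:
        n = sizes.pop()
        n0 = len(ctrl)
        df = (n - 1) * len(arrs) + (n0 - 1)
        ss = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
        ss += float(((ctrl - ctrl.mean()) ** 2).sum())
        s2 = ss / df
        if s2 <= 0:
            # degenerate (noiseless) data: no sampling variability to test
            t_stats = pd.Series(
                [math.inf if a.mean() > ctrl.mean() else 0.0 for a in arrs], index=names
            )
            p = pd.Series([0.0 if t == math.inf else 1.0 for t in t_stats], index=names)
            return DunnettResult(t_stats, p, anova_p, df)
        se = math.sqrt(s2 * (1.0 / n + 1.0 / n0))
        t_obs = np.array([(a.mean() - ctrl.mean()) / se for a in arrs])
        two_sided = alternative == "two-sided"
        t_eval = np.abs(t_obs) if two_sided else (-t_obs if alternative == "less" else t_obs)
        cdf = _dunnett_max_cdf(t_eval, len(arrs), n, n0, df, two_sided)
        p_adj = np.clip(1.0 - cdf, 0.0, 1.0)
        return DunnettResult(
            pd.Series(t_obs, index=names), pd.Series(p_adj, index=names), anova_p, df
        )
    res = stats.dunnett(*arrs, control=ctrl, alternative=alternative)
    return DunnettResult(
        pd.Series(res.statistic, index=names),
        pd.Series(res.pvalue, index=names),
        anova_p,
        len(ctrl) + sum(len(a) for a in arrs) - len(arrs) - 1,
    )


def call_hits(
    delta_table: pd.DataFrame,
    k: float = 2.0,
    sd_floor: float = 1.0,
    use_dunnett: bool = False,
    alpha: float = 0.05,
    control_kind: str = "GST_control",
    exclude_kinds: frozenset[str] = frozenset({"GST_control", "no_antigen"}),
) -> list[HitCall]:
    """Apply the positivity rule per (plate, avatar) stratum.

    positive <=> mean replicate delta > k * SD(control wells), the SD
    floored at ``sd_floor`` RLU to guard the degenerate zero-noise case;
    with ``use_dunnett`` the antigen must additionally be significant in a
    Dunnett many-to-one comparison at level ``alpha``.
    """
    if sd_floor <= 0:
        raise ValueError("sd_floor must be > 0")
    calls: list[HitCall] = []
    for (_, avatar), grp in delta_table.groupby(["plate_id", "avatar_id"], sort=False):
        controls = grp.loc[grp["antigen_kind"] == control_kind, "delta"]
        if len(controls) < 3:
            raise ValueError(
                f"avatar {avatar!r}: control SD needs >= 3 wells, got {len(controls)}"
            )
        sd = max(float(controls.std(ddof=1)), sd_floor)
        threshold = k * sd
        tests = grp[~grp["antigen_kind"].isin(exclude_kinds)]
        means = tests.groupby("antigen_id", sort=False)["delta"].agg(["mean", "count"])
        kinds = tests.groupby("antigen_id", sort=False)["antigen_kind"].first()
        if (means["count"] < 1).any():
            raise ValueError("every antigen needs at least one replicate")
        passed = means["mean"] > threshold
        adj_p: pd.Series | None = None
        if use_dunnett and passed.any() and float(controls.std(ddof=1)) > sd_floor / 10:
            groups = {
                aid: tests.loc[tests["antigen_id"] == aid, "delta"].to_numpy()
                for aid in means.index
            }
            if all(len(v) >= 2 for v in groups.values()):
                adj_p = dunnett_compare(groups, controls.to_numpy(), alpha=alpha).adjusted_p
        for aid in means.index:
            positive = bool(passed[aid])
            p = float(adj_p[aid]) if adj_p is not None else None
            if use_dunnett and positive and p is not None:
                positive = p < alpha
            calls.append(
                HitCall(
                    avatar_id=avatar,
                    antigen_id=aid,
                    antigen_kind=str(kinds[aid]),
                    delta_rlu=float(means.loc[aid, "mean"]),
                    threshold=threshold,
                    positive=positive,
                    adjusted_p=p,
                )
            )
    return calls


@dataclass(frozen=True)
class ScreenPolicy:
    """Thresholds and sampling policy for a staged screen."""

    k_sd: float = 2.0
    sd_floor: float = 1.0
    use_dunnett: bool = True
    alpha: float = 0.05
    colony_count: int | None = None  # None = exhaustive coverage of the pool
    colony_skew: float = math.inf
    # positive colonies are re-screened on an independent plate and must
    # confirm before their member is reported (every reported hit in the
    # modelled workflow was validated downstream, so a chance single-plate
    # positive is never accepted on its own)
    confirm_colonies: bool = True


class ReadoutSource(Protocol):
    def superpool_readouts(self, avatar_id: str) -> pd.DataFrame: ...

    def pool_readouts(self, avatar_id: str, superpool_id: str) -> pd.DataFrame: ...

    def colony_readouts(
        self,
        avatar_id: str,
        pool_id: str,
        colonies: Sequence[tuple[str, str]],
        batch: int = 0,
    ) -> pd.DataFrame: ...

    def draw_pool_colonies(
        self, pool_id: str, n: int | None, skew: float
    ) -> list[tuple[str, str]]: ...


class FileReadoutSource:
    """Serve pre-recorded readouts (and a colony -> member table) from
    tables, for deconvolving a screen measured outside the simulator."""

    def __init__(self, readouts: pd.DataFrame, colony_table: pd.DataFrame | None = None):
        self.readouts = readouts
        # colony_table columns: colony_id, pool_id, member_id
        self.colony_table = colony_table

    def _select(self, avatar_id: str, kinds: set[str], antigens: set[str] | None = None):
        df = self.readouts[self.readouts["avatar_id"] == avatar_id]
        plates = df.loc[df["antigen_kind"].isin(kinds - {"GST_control", "no_antigen"}), "plate_id"]
        if antigens is not None:
            plates = df.loc[
                df["antigen_kind"].isin(kinds) & df["antigen_id"].isin(antigens), "plate_id"
            ]
        sel = df[df["plate_id"].isin(set(plates))]
        if sel.empty:
            raise KeyError(f"no recorded readouts for avatar {avatar_id!r}, kinds {kinds}")
        return sel.reset_index(drop=True)

    def superpool_readouts(self, avatar_id: str) -> pd.DataFrame:
        return self._select(avatar_id, {"superpool"})

    def pool_readouts(self, avatar_id: str, superpool_id: str) -> pd.DataFrame:
        df = self.readouts[self.readouts["avatar_id"] == avatar_id]
        plates = df.loc[
            (df["antigen_kind"] == "pool") | ((df["antigen_kind"] == "superpool")),
            "plate_id",
        ]
        sel = df[df["plate_id"].isin(set(plates)) & df["plate_id"].str.startswith("s2")]
        if sel.empty:
            raise KeyError(f"no stage-2 readouts for avatar {avatar_id!r}")
        return sel.reset_index(drop=True)

    def colony_readouts(self, avatar_id, pool_id, colonies, batch=0):
        # recorded screens carry a single colony plate; confirmation
        # batches re-serve it (equivalent to confirmation being unavailable)
        df = self.readouts[self.readouts["avatar_id"] == avatar_id]
        wanted = {cid for cid, _ in colonies}
        plates = df.loc[
            (df["antigen_kind"] == "colony") & df["antigen_id"].isin(wanted), "plate_id"
        ]
        sel = df[df["plate_id"].isin(set(plates))]
        if sel.empty:
            raise KeyError(f"no colony readouts for avatar {avatar_id!r}, pool {pool_id!r}")
        return sel.reset_index(drop=True)

    def draw_pool_colonies(self, pool_id, n=None, skew=math.inf):
        if self.colony_table is None:
            raise ValueError("no colony table supplied")
        sub = self.colony_table[self.colony_table["pool_id"] == pool_id]
        return [(r.colony_id, r.member_id) for r in sub.itertuples(index=False)]


def run_deconvolution(
    source: ReadoutSource,
    manifest: PoolManifest,
    avatars: Sequence[str],
    policy: ScreenPolicy | None = None,
) -> DeconvolutionResult:
    """Three-stage deconvolution for every avatar.

    Stage 1 screens all super-pools; stage 2 re-tests each positive
    super-pool alongside its component pools and requires the super-pool to
    confirm; stage 3 screens colonies from the confirmed positive pools and
    reports the members of positive colonies, deduplicated per avatar."""
    if policy is None:
        policy = ScreenPolicy()
    result = DeconvolutionResult()
    for avatar in avatars:
        found: dict[str, IdentifiedHip] = {}
        r1 = delta_luciferase(source.superpool_readouts(avatar))
        hits1 = call_hits(
            r1, k=policy.k_sd, sd_floor=policy.sd_floor,
            use_dunnett=policy.use_dunnett, alpha=policy.alpha,
        )
        for h1 in hits1:
            if not (h1.positive and h1.antigen_kind == "superpool"):
                continue
            sp = h1.antigen_id
            r2 = delta_luciferase(source.pool_readouts(avatar, sp))
            hits2 = call_hits(
                r2, k=policy.k_sd, sd_floor=policy.sd_floor,
                use_dunnett=policy.use_dunnett, alpha=policy.alpha,
            )
            by_antigen = {h.antigen_id: h for h in hits2}
            confirm = by_antigen.get(sp)
            if confirm is None or not confirm.positive:
                continue  # super-pool response failed re-testing
            for h2 in hits2:
                if not (h2.positive and h2.antigen_kind == "pool"):
                    continue
                pool = h2.antigen_id
                if pool not in manifest.superpool_assignments[sp]:
                    raise ValueError(f"readout pool {pool!r} not in super-pool {sp!r}")
                colonies = source.draw_pool_colonies(
                    pool, policy.colony_count, policy.colony_skew
                )
                colony_map = dict(colonies)
                r3 = delta_luciferase(source.colony_readouts(avatar, pool, colonies))
                hits3 = call_hits(
                    r3, k=policy.k_sd, sd_floor=policy.sd_floor,
                    use_dunnett=policy.use_dunnett, alpha=policy.alpha,
                )
                positives3 = [
                    h for h in hits3 if h.positive and h.antigen_kind == "colony"
                ]
                if policy.confirm_colonies and positives3:
                    retest = [(h.antigen_id, colony_map[h.antigen_id]) for h in positives3]
                    rc = delta_luciferase(
                        source.colony_readouts(avatar, pool, retest, batch=1)
                    )
                    confirmed = {
                        h.antigen_id
                        for h in call_hits(
                            rc, k=policy.k_sd, sd_floor=policy.sd_floor,
                            use_dunnett=policy.use_dunnett, alpha=policy.alpha,
                        )
                        if h.positive
                    }
                    positives3 = [h for h in positives3 if h.antigen_id in confirmed]
                for h3 in positives3:
                    member = colony_map[h3.antigen_id]
                    if member in found:
                        prev = found[member]
                        found[member] = IdentifiedHip(
                            member_id=member,
                            sequence=prev.sequence,
                            superpool_id=prev.superpool_id,
                            pool_id=prev.pool_id,
                            colony_ids=tuple(sorted(set(prev.colony_ids) | {h3.antigen_id})),
                            stage_deltas=prev.stage_deltas,
                        )
                    else:
                        found[member] = IdentifiedHip(
                            member_id=member,
                            sequence=manifest.sequences.get(member, member),
                            superpool_id=sp,
                            pool_id=pool,
                            colony_ids=(h3.antigen_id,),
                            stage_deltas={
                                "superpool": h1.delta_rlu,
                                "pool": h2.delta_rlu,
                                "colony": h3.delta_rlu,
                            },
                        )
        result.identifications[avatar] = sorted(found.values(), key=lambda h: h.member_id)
    return result


@dataclass(frozen=True)
class PairedResult:
    mean_difference: float
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


def paired_comparison(
    islet: Sequence[float], spleen: Sequence[float]
) -> PairedResult:
    """Paired t test of islet-extract versus spleen-extract responses.

    Values are paired element-wise (replicate by replicate); the test is a
    two-sided paired Student's t on the within-pair differences.  Constant
    nonzero differences have no sampling variance; the fit is flagged
    degenerate and the limiting p of 0 is reported.
    """
    a = np.asarray(islet, dtype=float)
    b = np.asarray(spleen, dtype=float)
    if a.shape != b.shape:
        raise ValueError("islet and spleen replicate sets must pair one-to-one")
    if len(a) < 2:
        raise ValueError("need >= 2 paired replicates")
    diffs = a - b
    mean_diff = float(diffs.mean())
    if float(diffs.std(ddof=1)) == 0.0:
        if mean_diff == 0.0:
            return PairedResult(0.0, 0.0, 1.0, len(a))
        return PairedResult(mean_diff, math.inf if mean_diff > 0 else -math.inf, 0.0, len(a), True)
    t = stats.ttest_rel(a, b)
    return PairedResult(mean_diff, float(t.statistic), float(t.pvalue), len(a))
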