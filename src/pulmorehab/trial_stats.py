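"""Design and analysis statistics for the three-arm rehabilitation trial.

Covers the trial-design toolbox: the two-sample sample-size formula with
dropout inflation, a Monte-Carlo power check against the analytic
(noncentral-t) power, stratified permuted-block 1:1:1 randomization, a
one-way ANOVA for baseline comparability, and a mixed between-within
(repeated-measures) ANOVA of the V1/V2/V3 outcomes with per-arm change
scores.

Default design assumptions: a 50 m mean 6-minute-walk-distance difference
worth detecting, SD 60 m, two-sided alpha 0.05, 80 % power, 20 % dropout,
three groups — which yields 28 patients per group, 84 in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .regimen import ARMS, Arm

VISITS = ("V1", "V2", "V3")


class DesignParams(BaseModel):
    model_config = {"frozen": True}

    delta: float = Field(default=50.0, gt=0, description="detectable mean difference")
    sd: float = Field(default=60.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    power: float = Field(default=0.80, gt=0, lt=1)
    dropout: float = Field(default=0.20, ge=0, lt=1)
    n_groups: int = Field(default=3, ge=2)


@dataclass(frozen=True)
class SampleSize:
    n_raw: float  # unadjusted analytic n per group, before rounding
    n_per_group: int
    n_total: int


def sample_size(
    params: DesignParams | None = None,
    rounding: Literal["nearest", "ceil"] = "nearest",
) -> SampleSize:
    """Per-group and total sample size for a two-sample mean comparison.

    Uses the normal-approximation formula
    ``n0 = 2 ((z_{1-alpha/2} + z_{power}) sd / delta)^2`` per group, then
    inflates by ``1 / (1 - dropout)`` and rounds.  ``rounding='nearest'``
    (default) rounds the inflated n to the nearest integer;
    ``rounding='ceil'`` takes the ceiling instead, the conservative
    convention.
    """
    params = params or DesignParams()
    z_alpha = stats.norm.ppf(1 - params.alpha / 2)
    z_power = stats.norm.ppf(params.power)
    n0 = 2.0 * ((z_alpha + z_power) * params.sd / params.delta) ** 2
    inflated = n0 / (1.0 - params.dropout)
    if rounding == "nearest":
        n_per_group = int(math.floor(inflated + 0.5))
    elif rounding == "ceil":
        n_per_group = int(math.ceil(inflated))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return SampleSize(n_raw=n0, n_per_group=n_per_group,
                      n_total=n_per_group * params.n_groups)


def analytic_power(n_per_group: int, delta: float, sd: float,
                   alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test (noncentral t)."""
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    df = 2 * n_per_group - 2
    ncp = delta / (sd * math.sqrt(2.0 / n_per_group))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def empirical_power(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo power of the two-sided two-sample t-test.

    Simulates ``reps`` two-arm trials with normal outcomes (true mean
    difference ``delta``, common SD ``sd``) and returns the fraction
    rejected at ``alpha``.  Fully vectorised; reproducible under a fixed
    seed.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    if reps < 1000:
        raise ValueError("use at least 1000 replicates for a stable estimate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(reps, n_per_group))
    b = rng.normal(delta, sd, size=(reps, n_per_group))
    res = stats.ttest_ind(a, b, axis=1)
    return float(np.mean(res.pvalue < alpha))


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

DEFAULT_FEV1_CUT = 50.0
DEFAULT_CAT_CUT = 10.0


def _stratum(fev1: float, cat: float, fev1_cut: float, cat_cut: float) -> str:
    f = "FEV1<{:g}".format(fev1_cut) if fev1 < fev1_cut else f"FEV1>={fev1_cut:g}"
    c = f"CAT<{cat_cut:g}" if cat < cat_cut else f"CAT>={cat_cut:g}"
    return f"{f}|{c}"


class Assignment(BaseModel):
    model_config = {"frozen": True}

    patient_id: str
    arm: Arm
    site: str
    stratum: str
    seed: int


def randomize(
    roster: pd.DataFrame,
    seed: int = 0,
    arms: Sequence[str] = ARMS,
    fev1_cut: float = DEFAULT_FEV1_CUT,
    cat_cut: float = DEFAULT_CAT_CUT,
) -> list[Assignment]:
    """Stratified permuted-block 1:1:1 allocation.

    Within each site x stratum cell (strata: FEV1 %predicted and CAT score
    dichotomised at ``fev1_cut`` / ``cat_cut``), patients are assigned in
    permuted blocks of ``len(arms)`` — one slot per arm per block — so arm
    counts within any cell never differ by more than one.  Deterministic
    under ``seed``.
    """
    required = {"patient_id", "site", "fev1_pct_pred", "cat"}
    missing = required - set(roster.columns)
    if missing:
        raise ValueError(f"roster missing stratification columns: {sorted(missing)}")
    if roster[list(required)].isna().any().any():
        raise ValueError("roster has missing stratification values")
    rng = np.random.default_rng(seed)
    arms = tuple(arms)

    df = roster.copy()
    df["stratum"] = [
        _stratum(f, c, fev1_cut, cat_cut)
        for f, c in zip(df["fev1_pct_pred"], df["cat"])
    ]
    assignments: dict[str, Assignment] = {}
    # Sort cells for a stable draw order, keep roster order within a cell.
    for (site, stratum), cell in df.groupby(["site", "stratum"], sort=True):
        block: list[str] = []
        for pid in cell["patient_id"]:
            if not block:
                block = [arms[i] for i in rng.permutation(len(arms))]
            assignments[pid] = Assignment(
                patient_id=str(pid), arm=block.pop(), site=str(site),
                stratum=stratum, seed=seed,
            )
    return [assignments[pid] for pid in roster["patient_id"]]


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class AnovaResult(BaseModel):
    model_config = {"frozen": True}

    effect: str
    f: float = Field(ge=0)
    df_num: int = Field(gt=0)
    df_den: int = Field(gt=0)
    p: float = Field(ge=0, le=1)
    group_stats: dict[str, dict[str, float]] = {}


def baseline_anova(values_by_group: Mapping[str, Sequence[float]],
                   effect: str = "group") -> AnovaResult:
    """One-way ANOVA comparing a baseline characteristic across arms.

    Classic between/within sums of squares; if the between-group sum of
    squares is numerically zero (identical group means) the F statistic is
    0 and p is 1 rather than an indeterminate 0/0.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if df_w == 0:
        raise ValueError("no residual degrees of freedom")
    ms_within = ss_within / df_w
    scale = max(np.abs(all_vals).max(), 1.0)
    if ss_between <= 1e-12 * scale**2:
        f, p = 0.0, 1.0
    elif ms_within == 0.0:
        raise ValueError("zero within-group variance with nonzero group differences")
    else:
        f = (ss_between / df_b) / ms_within
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        effect=effect, f=float(f), df_num=df_b, df_den=df_w, p=p,
        group_stats={
            str(k): {"mean": float(g.mean()), "sd": float(g.std(ddof=1)),
                     "n": float(g.size)}
            for k, g in groups.items()
        },
    )


@dataclass(frozen=True)
class RmAnovaResult:
    """Mixed between-within ANOVA output plus per-arm change scores."""

    effects: dict[str, AnovaResult]      # keys: group, visit, interaction
    change_scores: pd.DataFrame          # per arm x contrast: mean, sd, n, paired p
    change_anova: dict[str, AnovaResult]  # between-arm ANOVA on each change score
    n_complete: int


def _long_outcomes(outcomes: pd.DataFrame, assignments: pd.DataFrame | None,
                   value: str) -> pd.DataFrame:
    df = outcomes.copy()
    if "arm" not in df.columns:
        if assignments is None:
            raise ValueError("outcomes lack an 'arm' column and no assignments given")
        arm_map = dict(zip(assignments["patient_id"], assignments["arm"]))
        df["arm"] = df["patient_id"].map(arm_map)
    if df["arm"].isna().any():
        raise ValueError("some patients have no arm assignment")
    return df[["patient_id", "arm", "visit", value]].rename(columns={value: "y"})


def rm_anova(
    outcomes: pd.DataFrame,
    value: str = "sixmwt_distance",
    assignments: pd.DataFrame | None = None,
    visits: Sequence[str] = VISITS,
) -> RmAnovaResult:
    """Repeated-measures analysis of visit outcomes across trial arms.

    Restricts to complete cases (patients observed at every visit), runs a
    mixed between-within ANOVA (between factor: arm; within factor: visit)
    and reports the arm, visit and arm x visit effects, per-arm change
    scores (V2-V1, V3-V1) with paired t-tests, and a between-arm one-way
    ANOVA on each change score.
    """
    import pingouin as pg  # deferred: heavy import

    df = _long_outcomes(outcomes, assignments, value)
    df = df[df["visit"].isin(visits)]
    if df["visit"].nunique() < 2:
        raise ValueError("at least two visits are required")
    counts = df.groupby("patient_id")["visit"].nunique()
    complete = counts[counts == len(visits)].index
    df = df[df["patient_id"].isin(complete)]
    per_arm = df.drop_duplicates("patient_id").groupby("arm")["patient_id"].count()
    if (per_arm < 2).any() or per_arm.size < 2:
        raise ValueError("need >=2 complete cases in each of >=2 arms")

    with np.errstate(invalid="ignore", divide="ignore"):
        aov = pg.mixed_anova(data=df, dv="y", within="visit",
                             subject="patient_id", between="arm",
                             correction=False)
    effects = {}
    for _, row in aov.iterrows():
        name = {"arm": "group", "visit": "visit", "Interaction": "interaction"}[
            row["Source"]]
        f = row["F"]
        p = row["p_unc"]
        if not np.isfinite(f):  # zero effect SS on constant data
            f, p = 0.0, 1.0
        arm_stats = {
            str(a): {"mean": float(g["y"].mean()), "sd": float(g["y"].std(ddof=1)),
                     "n": float(g["patient_id"].nunique())}
            for a, g in df.groupby("arm")
        } if name == "group" else {}
        effects[name] = AnovaResult(
            effect=name, f=float(max(f, 0.0)), df_num=int(row["DF1"]),
            df_den=int(row["DF2"]), p=float(np.clip(p, 0.0, 1.0)),
            group_stats=arm_stats,
        )

    wide = df.pivot_table(index=["patient_id", "arm"], columns="visit",
                          values="y").reset_index()
    rows, change_anova = [], {}
    for later in visits[1:]:
        contrast = f"{later}-{visits[0]}"
        wide[contrast] = wide[later] - wide[visits[0]]
        by_arm = {}
        for arm, g in wide.groupby("arm"):
            d = g[contrast].to_numpy()
            tt = stats.ttest_rel(g[later], g[visits[0]])
            rows.append({
                "arm": arm, "contrast": contrast,
                "mean_change": float(d.mean()), "sd_change": float(d.std(ddof=1)),
                "n": int(d.size), "paired_p": float(tt.pvalue),
            })
            by_arm[arm] = d
        change_anova[contrast] = baseline_anova(by_arm, effect=f"arm@{contrast}")
    return RmAnovaResult(
        effects=effects,
        change_scores=pd.DataFrame(rows),
        change_anova=change_anova,
        n_complete=int(wide.shape[0]),
    )
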