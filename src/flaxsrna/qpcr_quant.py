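"""Efficiency-corrected qPCR quantification and the statistics around it.

The quantification model corrects each replicate-averaged threshold cycle
for the measured per-amplicon amplification efficiency E (fraction per
cycle; E = 1 is perfect doubling):

    Cteff      = Ct * log2(1 + E)
    dCteff     = Cteff(target) - mean of Cteff over the reference set
    ddCteff    = dCteff(normal) - dCteff(stress)

so with E = 1 the chain reduces to the classical ddCt.  A higher dCteff
means lower expression; a positive ddCteff means higher expression under
stress.  Standard deviations propagate in quadrature (replicate SD with
n-1 denominator).  Condition-level results are summarized by percentiles
(median, quartiles, extremes) and compared with the exact Mann-Whitney
rank-sum test; miRNA-target co-expression uses Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAX_EFFICIENCY = 1.2
EXACT_MW_CUTOFF = 14  # exact enumeration when n_A + n_B <= this
EXACT_SPEARMAN_CUTOFF = 8


@dataclass
class CtMeasurement:
    sample: str
    condition: str
    transcript: str
    ct_replicates: Sequence[float]
    efficiency: float

    def __post_init__(self) -> None:
        if len(self.ct_replicates) < 1:
            raise ValueError("need at least one Ct replicate")
        if not 0 < self.efficiency <= MAX_EFFICIENCY:
            raise ValueError(f"efficiency must be in (0, {MAX_EFFICIENCY}]")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))

    @property
    def ct_sd(self) -> float:
        if len(self.ct_replicates) < 2:
            return 0.0
        return float(np.std(self.ct_replicates, ddof=1))


@dataclass
class SummaryStats:
    median: float
    q25: float
    q75: float
    min: float
    max: float


def cteff(mean_ct: float, efficiency: float) -> float:
    """Efficiency-corrected threshold cycle: Ct * log2(1 + E)."""
    if not 0 < efficiency <= MAX_EFFICIENCY:
        raise ValueError(f"efficiency must be in (0, {MAX_EFFICIENCY}]")
    if mean_ct < 0:
        raise ValueError("Ct must be non-negative")
    return mean_ct * math.log2(1.0 + efficiency)


def delta_cteff(
    target: tuple[float, float],
    references: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """dCteff of a target against a reference set, with propagated SD.

    Arguments are (cteff, sd) pairs.  References are combined by arithmetic
    mean in Cteff space (geometric mean in quantity space); the SD combines
    in quadrature with the 1/k weight of the reference mean.
    """
    if not references:
        raise ValueError("at least one reference measurement required")
    t, t_sd = target
    k = len(references)
    ref_mean = sum(c for c, _ in references) / k
    ref_var = sum(sd**2 for _, sd in references) / k**2
    return t - ref_mean, math.sqrt(t_sd**2 + ref_var)


def delta_delta_cteff(
    delta_normal: tuple[float, float],
    delta_stress: tuple[float, float],
) -> tuple[float, float]:
    """ddCteff = dCteff(normal) - dCteff(stress), SD in quadrature.

    Positive values mean higher expression under stress (a higher dCteff
    reflects lower expression).
    """
    dn, sn = delta_normal
    ds, ss = delta_stress
    return dn - ds, math.sqrt(sn**2 + ss**2)


def estimate_efficiency(dilution_series: Sequence[tuple[float, float]]) -> float:
    """Standard-curve efficiency from (log10 concentration, Ct) pairs.

    E = 10^(-1/m) - 1 where m is the least-squares slope of Ct against
    log10 concentration; a valid curve has negative slope (Ct rises as
    template dilutes).
    """
    if len(dilution_series) < 3:
        raise ValueError("need at least 3 dilution points")
    x, y = zip(*dilution_series)
    slope = stats.linregress(x, y).slope
    if slope >= 0:
        raise ValueError(f"invalid standard curve: non-negative slope {slope:.3f}")
    return 10 ** (-1.0 / slope) - 1.0


def percentile_summary(values: Sequence[float]) -> SummaryStats:
    """Median, quartiles (linear interpolation, inclusive) and extremes."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value set")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return SummaryStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_cutoff: int = EXACT_MW_CUTOFF,
) -> tuple[float, float]:
    """Mann-Whitney U (for group A) and two-sided p.

    Exact p by full enumeration of rank assignments (midranks for ties)
    when n_A + n_B <= ``exact_cutoff``; otherwise the tie- and
    continuity-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    if na + nb <= exact_cutoff:
        mu = na * nb / 2.0
        dev = abs(u_obs - mu)
        n_extreme = 0
        n_total = 0
        idx = range(na + nb)
        for subset in itertools.combinations(idx, na):
            u = float(ranks[list(subset)].sum() - na * (na + 1) / 2)
            n_total += 1
            if abs(u - mu) >= dev - 1e-9:
                n_extreme += 1
        return u_obs, n_extreme / n_total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_cutoff: int = EXACT_SPEARMAN_CUTOFF,
) -> tuple[float, float]:
    """Spearman rank correlation (Pearson of midranks) and two-sided p.

    Exact permutation p for n <= ``exact_cutoff``; otherwise the
    t-approximation with n-2 degrees of freedom.  Returns (nan, nan) when
    either variable has zero rank variance (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rs = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= exact_cutoff:
        rx_c = rx - rx.mean()
        denom_x = math.sqrt(float(rx_c @ rx_c))
        ry_c = ry - ry.mean()
        denom_y = math.sqrt(float(ry_c @ ry_c))
        n_extreme = 0
        n_total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / (denom_x * denom_y)
            n_total += 1
            if abs(r) >= abs(rs) - 1e-9:
                n_extreme += 1
        return rs, n_extreme / n_total
    t = rs * math.sqrt((n - 2) / max(1e-12, 1.0 - rs**2))
    return rs, float(2 * stats.t.sf(abs(t), df=n - 2))


# --- table-level driver ---------------------------------------------------

CT_COLUMNS = ("sample", "condition", "transcript", "efficiency")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table (TSV/CSV): sample, condition, transcript, ct_rep*, efficiency."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def cteff_table(ct_df: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, transcript): mean Ct, replicate SD, Cteff, Cteff SD."""
    rep_cols = [c for c in ct_df.columns if c.startswith("ct_rep")]
    if not rep_cols:
        raise ValueError("no ct_rep* replicate columns found")
    rows = []
    for _, row in ct_df.iterrows():
        reps = [row[c] for c in rep_cols if pd.notna(row[c])]
        m = CtMeasurement(
            sample=row["sample"],
            condition=row["condition"],
            transcript=row["transcript"],
            ct_replicates=reps,
            efficiency=float(row["efficiency"]),
        )
        scale = math.log2(1.0 + m.efficiency)
        rows.append(
            {
                "sample": m.sample,
                "condition": m.condition,
                "transcript": m.transcript,
                "mean_ct": m.mean_ct,
                "ct_sd": m.ct_sd,
                "cteff": cteff(m.mean_ct, m.efficiency),
                "cteff_sd": m.ct_sd * scale,
            }
        )
    return pd.DataFrame(rows)


def delta_cteff_table(
    cteff_df: pd.DataFrame, target: str, references: Sequence[str]
) -> pd.DataFrame:
    """Per-sample dCteff of one target transcript against the reference set."""
    rows = []
    for sample, group in cteff_df.groupby("sample", sort=True):
        by_transcript = group.set_index("transcript")
        if target not in by_transcript.index:
            continue
        missing = [r for r in references if r not in by_transcript.index]
        if missing:
            raise ValueError(
                f"sample {sample!r}: missing reference measurement(s) {missing}"
            )
        t = by_transcript.loc[target]
        refs = [
            (by_transcript.at[r, "cteff"], by_transcript.at[r, "cteff_sd"])
            for r in references
        ]
        d, sd = delta_cteff((t["cteff"], t["cteff_sd"]), refs)
        rows.append(
            {
                "sample": sample,
                "condition": t["condition"],
                "target": target,
                "delta_cteff": d,
                "delta_sd": sd,
            }
        )
    return pd.DataFrame(rows)


def analyze_targets(
    ct_df: pd.DataFrame,
    targets: Sequence[str],
    references: Sequence[str],
    normal: str = "N",
    stress_conditions: Sequence[str] = ("P", "NPK"),
) -> pd.DataFrame:
    """Full chain per target: condition summaries, ddCteff, Mann-Whitney p.

    ddCteff is computed from condition medians (normal minus stress), with
    the quadrature SD of the two per-condition dCteff SD medians attached.
    """
    ct = cteff_table(ct_df)
    rows = []
    for target in targets:
        deltas = delta_cteff_table(ct, target, references)
        if deltas.empty:
            continue
        per_cond = {
            cond: grp for cond, grp in deltas.groupby("condition", sort=True)
        }
        if normal not in per_cond:
            raise ValueError(f"no measurements for normal condition {normal!r}")
        normal_vals = per_cond[normal]["delta_cteff"].to_numpy()
        s_norm = percentile_summary(normal_vals)
        for stress in stress_conditions:
            if stress not in per_cond:
                continue
            stress_vals = per_cond[stress]["delta_cteff"].to_numpy()
            s_str = percentile_summary(stress_vals)
            dd, dd_sd = delta_delta_cteff(
                (s_norm.median, float(per_cond[normal]["delta_sd"].median())),
                (s_str.median, float(per_cond[stress]["delta_sd"].median())),
            )
            _, p = mann_whitney(normal_vals, stress_vals)
            rows.append(
                {
                    "target": target,
                    "stress": stress,
                    "n_normal": len(normal_vals),
                    "n_stress": len(stress_vals),
                    "median_delta_normal": s_norm.median,
                    "median_delta_stress": s_str.median,
                    "q25_stress": s_str.q25,
                    "q75_stress": s_str.q75,
                    "delta_delta_cteff": dd,
                    "delta_delta_sd": dd_sd,
                    "p_mann_whitney": p,
                }
            )
    return pd.DataFrame(rows)
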