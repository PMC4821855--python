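"""Count-based differential expression between sequencing libraries.

Counts are normalized to reads per million (RPM); expression change between
a stress library and the normal library is the log2 RPM ratio; significance
of a count difference is assessed with the Audic-Claverie test, which under
a flat prior on the common rate gives the posterior-predictive distribution
of the second count y given the first count x:

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

i.e. y | x ~ NegativeBinomial(n = x+1, p = N1/(N1+N2)).  The two-sided
p-value doubles the smaller tail, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .read_processing import TagTable


@dataclass
class ExpressionRecord:
    unit: str  # tag or family name
    count_stress: int
    count_normal: int
    rpm_stress: float
    rpm_normal: float
    fold_change: float
    p_value: float


def to_rpm(count: float, library_total: float) -> float:
    """Reads per million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / library_total * 1e6


def fold_change(rpm_stress: float, rpm_normal: float, pseudocount: float = 1.0) -> float:
    """log2(RPM_stress / RPM_normal); pseudocount applied only on zeros."""
    if rpm_stress < 0 or rpm_normal < 0:
        raise ValueError("RPM values must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if rpm_stress == 0 or rpm_normal == 0:
        return math.log2((rpm_stress + pseudocount) / (rpm_normal + pseudocount))
    return math.log2(rpm_stress / rpm_normal)


def audic_claverie_pmf(y: int, x: int, n1: float, n2: float) -> float:
    """Posterior-predictive point mass p(y | x) for library totals n1, n2."""
    if x < 0 or y < 0 or n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be >= 0 and totals > 0")
    r = n2 / n1
    return float(stats.nbinom.pmf(y, x + 1, 1.0 / (1.0 + r)))


def audic_claverie_p(
    x: int, n1: float, y: int, n2: float, two_sided: bool = True
) -> float:
    """Audic-Claverie significance of observing count ``y`` given ``x``.

    Two-sided doubles the smaller of P(Y <= y) and P(Y >= y) under the
    posterior-predictive negative binomial, capped at 1.  One-sided returns
    the smaller tail itself.
    """
    if x < 0 or y < 0 or n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be >= 0 and totals > 0")
    r = n2 / n1
    p_success = 1.0 / (1.0 + r)
    lower = float(stats.nbinom.cdf(y, x + 1, p_success))
    upper = float(stats.nbinom.sf(y - 1, x + 1, p_success))  # P(Y >= y)
    tail = min(lower, upper)
    if not two_sided:
        return min(1.0, tail)
    return min(1.0, 2.0 * tail)


def de_table(
    table: TagTable,
    stress_lib: str,
    normal_lib: str,
    min_rpm: float = 0.0,
    by_family: pd.Series | None = None,
    pseudocount_reads: float = 1.0,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Differential-expression table for one stress-vs-normal library pair.

    One record per unit (tag, or family when ``by_family`` maps tags to
    family names; family counts are summed before normalization) passing
    ``min_rpm`` in at least one of the two libraries.  The zero-RPM
    pseudocount is the RPM equivalent of ``pseudocount_reads`` reads in the
    smaller library.
    """
    for lib in (stress_lib, normal_lib):
        if lib not in table.libraries:
            raise ValueError(f"library {lib!r} not in table")
    counts = table.counts[[stress_lib, normal_lib]]
    n_stress = int(counts[stress_lib].sum())
    n_normal = int(counts[normal_lib].sum())
    if by_family is not None:
        fam = by_family.reindex(counts.index)
        counts = counts.groupby(fam.dropna()).sum()
    pseudo = to_rpm(pseudocount_reads, min(n_stress, n_normal))
    rows = []
    for unit, row in counts.iterrows():
        cs, cn = int(row[stress_lib]), int(row[normal_lib])
        rs, rn = to_rpm(cs, n_stress), to_rpm(cn, n_normal)
        if max(rs, rn) < min_rpm or (cs == 0 and cn == 0):
            continue
        rows.append(
            {
                "unit": unit,
                "count_stress": cs,
                "count_normal": cn,
                "rpm_stress": rs,
                "rpm_normal": rn,
                "log2fc": fold_change(rs, rn, pseudo),
                "p_ac": audic_claverie_p(cn, n_normal, cs, n_stress, two_sided),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit",
            "count_stress",
            "count_normal",
            "rpm_stress",
            "rpm_normal",
            "log2fc",
            "p_ac",
        ],
    ).set_index("unit")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional extra column; raw p is the default)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    cummin = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        cummin = min(cummin, p[i] * n / (rank_idx + 1))
        adj[i] = cummin
    return adj


def write_de_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="unit")
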