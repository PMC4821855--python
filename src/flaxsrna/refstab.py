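"""Reference-gene stability ranking: BestKeeper-, geNorm- and NormFinder-style.

Three dispersion-based views of the same question — which candidate
transcripts vary least across samples and conditions — plus a consensus:

* BestKeeper: raw-Ct sample SD and CV per candidate, and the Pearson
  correlation of each candidate with the BestKeeper index (the per-sample
  geometric mean Ct over all candidates).  Ranked by ascending SD.
* geNorm: M_j is the mean, over partners k, of the sample SD of the
  pairwise log-ratio log2 q_j - log2 q_k.  The highest-M candidate is
  removed iteratively; the final pair shares rank 1.  Pairwise variations
  V_{n/n+1} track how much the normalization factor changes when an
  (n+1)-th gene is added.
* NormFinder (simplified two-way model): x_ij = sample effect + candidate
  effect + residual; the stability of candidate j is the scaled root sum
  of its squared residuals.  With sample groups, an intergroup term (mean
  absolute group-mean residual) is added.

These are faithful-in-spirit re-implementations of the published
algorithms, not bit-compatible clones of the original spreadsheets/tools.
geNorm and NormFinder expect efficiency-corrected log2 quantities
(``-Cteff`` up to a constant); BestKeeper works on raw Ct, each tool's
native convention.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .qpcr_quant import cteff_table


def bestkeeper(ct_matrix: pd.DataFrame) -> pd.DataFrame:
    """BestKeeper descriptive stability on a samples x candidates Ct matrix.

    Returns per candidate: ``sd`` (cycles, n-1), ``cv`` (percent of mean
    Ct), ``r`` (Pearson vs the geometric-mean index; NaN if degenerate),
    and ``rank`` by ascending SD (ties share the minimum rank).
    """
    if ct_matrix.shape[0] < 3 or ct_matrix.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 candidates")
    if ct_matrix.isna().any().any():
        raise ValueError("missing Ct cells not supported")
    sd = ct_matrix.std(ddof=1)
    cv = 100.0 * sd / ct_matrix.mean()
    index = np.exp(np.log(ct_matrix).mean(axis=1))  # geometric mean per sample
    r = {}
    for cand in ct_matrix.columns:
        col = ct_matrix[cand]
        if col.std(ddof=1) == 0 or index.std(ddof=1) == 0:
            r[cand] = float("nan")
        else:
            r[cand] = float(np.corrcoef(col, index)[0, 1])
    out = pd.DataFrame({"sd": sd, "cv": cv, "r": pd.Series(r)})
    out["rank"] = out["sd"].rank(method="min").astype(int)
    out.index.name = "candidate"
    return out


def genorm_m(log2_q: pd.DataFrame) -> pd.Series:
    """geNorm M value per candidate on a samples x candidates log2 matrix."""
    if log2_q.shape[1] < 2:
        raise ValueError("need >= 2 candidates")
    m = {}
    for j in log2_q.columns:
        sds = [
            (log2_q[j] - log2_q[k]).std(ddof=1)
            for k in log2_q.columns
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm(log2_q: pd.DataFrame) -> pd.DataFrame:
    """Iterative geNorm ranking with pairwise variations.

    Candidates are removed one at a time (highest M first; alphabetical
    tie-break removes the later name) until two remain; those two share
    rank 1 and the next best gets rank 3, matching the usual presentation.
    Output columns: ``M`` (on the full set), ``rank``; the frame carries
    the pairwise variations in ``attrs['pairwise_variation']`` as
    {"V2/3": ...} computed over the best-first ordering.
    """
    m_full = genorm_m(log2_q)
    remaining = list(log2_q.columns)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = genorm_m(log2_q[remaining])
        worst = m.sort_values(kind="stable").index[-1]
        ties = m[m == m[worst]].index
        worst = sorted(ties)[-1]
        exclusion.append(worst)
        remaining.remove(worst)
    order = sorted(remaining) + list(reversed(exclusion))  # best first
    rank = {c: 1 for c in remaining}
    for i, c in enumerate(exclusion[::-1]):
        rank[c] = 3 + i
    out = pd.DataFrame({"M": m_full, "rank": pd.Series(rank)})
    out.index.name = "candidate"

    variations = {}
    for n in range(2, len(order)):
        nf_n = log2_q[order[:n]].mean(axis=1)
        nf_n1 = log2_q[order[: n + 1]].mean(axis=1)
        variations[f"V{n}/{n + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    out.attrs["pairwise_variation"] = variations
    out.attrs["order"] = order
    return out


def normfinder(
    log2_q: pd.DataFrame, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Simplified model-based stability on a samples x candidates log2 matrix.

    Residuals come from the additive two-way decomposition
    ``x_ij - rowmean_i - colmean_j + grandmean``; the stability of
    candidate j is ``sqrt(sum_i r_ij^2 * g / ((n-1)(g-1)))`` with n
    samples and g candidates.  When ``groups`` labels samples, the mean
    absolute group-mean residual of the candidate is added as an
    intergroup-variation term.
    """
    n, g = log2_q.shape
    if n < 2 or g < 2:
        raise ValueError("need >= 2 samples and >= 2 candidates")
    x = log2_q.to_numpy(dtype=float)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    scale = g / ((n - 1) * (g - 1))
    stability = np.sqrt((resid**2).sum(axis=0) * scale)
    out = pd.DataFrame({"stability": stability}, index=log2_q.columns)
    if groups is not None:
        groups = groups.reindex(log2_q.index)
        if groups.isna().any():
            raise ValueError("groups must label every sample")
        resid_df = pd.DataFrame(resid, index=log2_q.index, columns=log2_q.columns)
        intergroup = resid_df.groupby(groups).mean().abs().mean(axis=0)
        out["intergroup"] = intergroup
        out["stability"] = out["stability"] + intergroup
    out["rank"] = out["stability"].rank(method="min").astype(int)
    out.index.name = "candidate"
    return out


def consensus_rank(
    bestkeeper_report: pd.DataFrame,
    genorm_report: pd.DataFrame,
    normfinder_report: pd.DataFrame,
) -> pd.DataFrame:
    """Mean of the three method ranks; ties broken alphabetically."""
    candidates = sorted(bestkeeper_report.index)
    for rep, name in (
        (genorm_report, "geNorm"),
        (normfinder_report, "NormFinder"),
    ):
        if sorted(rep.index) != candidates:
            raise ValueError(f"{name} report has a different candidate set")
    out = pd.DataFrame(
        {
            "bestkeeper_rank": bestkeeper_report["rank"],
            "genorm_rank": genorm_report["rank"],
            "normfinder_rank": normfinder_report["rank"],
        }
    )
    out["mean_rank"] = out.mean(axis=1)
    # alphabetical order first so the stable sort breaks ties alphabetically
    out = out.loc[sorted(out.index)].sort_values("mean_rank", kind="stable")
    out["consensus_rank"] = range(1, len(out) + 1)
    out.index.name = "candidate"
    return out


def log2_quantity_matrix(ct_df: pd.DataFrame, candidates: Sequence[str]) -> pd.DataFrame:
    """Efficiency-corrected log2 quantities (-Cteff) as samples x candidates."""
    ct = cteff_table(ct_df)
    ct = ct[ct["transcript"].isin(candidates)]
    mat = ct.pivot(index="sample", columns="transcript", values="cteff")
    return (-mat)[list(candidates)].sort_index()


def ct_matrix(ct_df: pd.DataFrame, candidates: Sequence[str]) -> pd.DataFrame:
    """Raw mean-Ct matrix (samples x candidates) for BestKeeper."""
    ct = cteff_table(ct_df)
    ct = ct[ct["transcript"].isin(candidates)]
    mat = ct.pivot(index="sample", columns="transcript", values="mean_ct")
    return mat[list(candidates)].sort_index()


def stability_report(
    ct_df: pd.DataFrame,
    candidates: Sequence[str],
    groups_by: str | None = "condition",
) -> pd.DataFrame:
    """Full stability analysis from a long-format Ct table.

    BestKeeper runs on raw mean Ct; geNorm and NormFinder on
    efficiency-corrected log2 quantities.  Returns the per-method metrics
    merged with the consensus ranking.
    """
    candidates = sorted(candidates)
    raw = ct_matrix(ct_df, candidates)
    logq = log2_quantity_matrix(ct_df, candidates)
    groups = None
    if groups_by is not None:
        groups = (
            ct_df.drop_duplicates("sample").set_index("sample")[groups_by].sort_index()
        )
        groups = groups.reindex(logq.index)
    bk = bestkeeper(raw)
    gn = genorm(logq)
    nf = normfinder(logq, groups)
    consensus = consensus_rank(bk, gn, nf)
    report = pd.concat(
        [
            bk.rename(columns=lambda c: f"bk_{c}" if c != "rank" else "bk_rank"),
            gn.rename(columns={"M": "genorm_M", "rank": "genorm_rank"}),
            nf.rename(
                columns=lambda c: {"stability": "nf_stability", "rank": "nf_rank"}.get(c, c)
            ),
            consensus[["mean_rank", "consensus_rank"]],
        ],
        axis=1,
    )
    report.attrs["pairwise_variation"] = gn.attrs.get("pairwise_variation", {})
    return report.sort_values("consensus_rank")


def write_report_tsv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index_label="candidate")
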