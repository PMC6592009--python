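"""CLIP-enrichment ranking of splicing factors.

The core statistic: given M tested events of which K were selected as
differentially spliced, and an RBP bound (per the ExS matrix) to m of the
tested events and to k of the selected ones, the CLIP p-value is the
inclusive upper tail of the hypergeometric distribution,

    p_clip = P(X >= k),  X ~ Hypergeom(M, m, K),

i.e. the one-sided Fisher exact test for over-representation of the RBP's
bound events among the selected set. RBPs are ranked by p_clip ascending;
the candidate list additionally requires the RBP's gene to be
differentially expressed (p_expr < 0.05 and |log2 FC| > 0.58 by default).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exs import ExSMatrix

logger = logging.getLogger(__name__)

COMBINE_METHODS = {"fisher", "stouffer", "irwin_hall", "none"}


def hypergeom_upper_tail(M: int, K: int, m: int, k: int) -> float:
    """Inclusive upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a fixed set of size K and a random
    m-subset drawn from M items. ``k = 0`` gives exactly 1. Computed in a
    numerically stable way (log-space survival function) so that values
    like 1e-300 at M ~ 1e5 are exact to machine precision.

    Parameters follow the enrichment convention: M total events, K
    selected events, m events bound by the RBP, k bound events among the
    selected. By the symmetry of the 2x2 exact test, swapping K and m
    leaves the result unchanged.
    """
    for name, val in (("M", M), ("K", K), ("m", m), ("k", k)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {val}")
    if K > M or m > M:
        raise ValueError(f"margins exceed total: M={M}, K={K}, m={m}")
    if k > min(K, m):
        raise ValueError(f"k={k} exceeds min(K, m)={min(K, m)}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, m, K))


def _hypergeom_upper_tail_vec(
    M: int, K: int, m: np.ndarray, k: np.ndarray
) -> np.ndarray:
    p = stats.hypergeom.sf(k - 1, M, m, K)
    return np.where(k == 0, 1.0, p)


def clip_enrichment(
    exs: ExSMatrix,
    selected: Iterable[str],
    tested: Iterable[str],
) -> pd.DataFrame:
    """Per-RBP contingency counts and CLIP p-values.

    ``selected`` must be a subset of ``tested``, which must be a subset of
    the matrix rows. Returns one row per RBP with columns rbp, M, K, m, k,
    expected (= K*m/M), p_clip and a Benjamini-Hochberg q_clip reported for
    transparency (ranking uses raw p_clip, matching how the method is
    applied).
    """
    selected = list(dict.fromkeys(selected))
    tested = list(dict.fromkeys(tested))
    sel_set, test_set = set(selected), set(tested)
    if not sel_set <= test_set:
        extra = sorted(sel_set - test_set)[:5]
        raise ValueError(f"selected events not among tested: {extra} ...")

    rows_tested = exs.row_index(tested)
    rows_selected = exs.row_index(selected)
    M, K = len(tested), len(selected)
    m = np.asarray(exs.matrix[rows_tested].sum(axis=0)).ravel().astype(int)
    k = np.asarray(exs.matrix[rows_selected].sum(axis=0)).ravel().astype(int)
    p_clip = _hypergeom_upper_tail_vec(M, K, m, k)
    df = pd.DataFrame(
        {
            "rbp": exs.rbp_ids,
            "M": M,
            "K": K,
            "m": m,
            "k": k,
            "expected": K * m / M if M else np.nan,
            "p_clip": p_clip,
        }
    )
    df["q_clip"] = stats.false_discovery_control(df["p_clip"], method="bh")
    return df


def differential_expression_test(
    gene_expr: pd.DataFrame, design: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Two-group differential expression on log2(expr + 1).

    A simple Welch two-sample t-test per gene with log2 fold change
    (condition minus reference) and BH-adjusted q values across genes.
    Zero variance in both groups with equal means yields p = 1.
    """
    design = pd.Series(dict(design))
    ref_cols = design.index[design == "reference"]
    cond_cols = design.index[design == "condition"]
    if len(ref_cols) < 2 or len(cond_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    log_ref = np.log2(gene_expr[ref_cols].to_numpy(float) + 1.0)
    log_cond = np.log2(gene_expr[cond_cols].to_numpy(float) + 1.0)
    lfc = log_cond.mean(axis=1) - log_ref.mean(axis=1)
    p = _welch_p(log_cond, log_ref)
    out = pd.DataFrame(
        {"gene": gene_expr.index, "log2_fc": lfc, "p_expr": p}
    ).reset_index(drop=True)
    out["q_expr"] = stats.false_discovery_control(out["p_expr"], method="bh")
    return out


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test p-values for rows of a vs b.

    Degenerate rows (zero variance in both groups) give p = 1 when the
    means agree and float tiny otherwise.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom2 = va / na + vb / nb
    degenerate = denom2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom2)
        df = denom2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(ma == mb, 1.0, np.finfo(float).tiny), p)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def rank_splicing_factors(
    enr: pd.DataFrame,
    de: pd.DataFrame | None = None,
    p_clip_max: float = 0.05,
    p_expr_max: float = 0.05,
    lfc_min: float = 0.58,
    combine: str = "none",
) -> pd.DataFrame:
    """Rank RBPs by CLIP p-value and flag those passing the expression filter.

    All RBPs receive ``rank_clip`` (1-based, by p_clip ascending, ties by k
    descending then symbol). ``passes_filters`` requires p_clip < p_clip_max,
    p_expr < p_expr_max and |log2_fc| > lfc_min; an RBP with no matching
    gene in the DE table never passes and is flagged by NaN expression
    columns. ``combine`` optionally merges p_clip and p_expr into
    p_combined (fisher, stouffer or irwin_hall; default "none" leaves it
    equal to p_clip, since a knock-down's expression change is informative
    as a filter, not as extra evidence).
    """
    if combine not in COMBINE_METHODS:
        raise ValueError(f"combine must be one of {sorted(COMBINE_METHODS)}")
    df = enr.copy()
    if de is not None:
        de_idx = de.set_index(de["gene"].str.upper())
        df["log2_fc"] = df["rbp"].str.upper().map(de_idx["log2_fc"])
        df["p_expr"] = df["rbp"].str.upper().map(de_idx["p_expr"])
        unmatched = df["p_expr"].isna().sum()
        if unmatched:
            logger.warning(
                "%d RBPs without differential-expression data", unmatched
            )
    else:
        df["log2_fc"] = np.nan
        df["p_expr"] = np.nan

    order = df.sort_values(
        ["p_clip", "k", "rbp"], ascending=[True, False, True]
    ).index
    df.loc[order, "rank_clip"] = np.arange(1, len(df) + 1)
    df["rank_clip"] = df["rank_clip"].astype(int)

    df["passes_filters"] = (
        (df["p_clip"] < p_clip_max)
        & (df["p_expr"] < p_expr_max)
        & (df["log2_fc"].abs() > lfc_min)
    ).fillna(False)

    if combine == "none":
        df["p_combined"] = df["p_clip"]
    else:
        df["p_combined"] = [
            combine_pvalues(pc, pe, combine) if np.isfinite(pe) else np.nan
            for pc, pe in zip(df["p_clip"], df["p_expr"])
        ]
    return df.sort_values("rank_clip").reset_index(drop=True)


def candidate_list(ranking: pd.DataFrame) -> pd.DataFrame:
    """Filter-passing RBPs re-ranked by CLIP p-value (1-based rank column)."""
    cand = (
        ranking[ranking["passes_filters"]]
        .sort_values(["p_clip", "k", "rbp"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    cand["rank_candidates"] = np.arange(1, len(cand) + 1)
    return cand


def combine_pvalues(p_a: float, p_b: float, method: str = "fisher") -> float:
    """Combine two p-values.

    fisher: chi-square(4 df) tail of -2(ln p_a + ln p_b).
    stouffer: normal tail of (z_a + z_b)/sqrt(2), z = Phi^{-1}(1 - p).
    irwin_hall: for s = p_a + p_b, s^2/2 if s <= 1 else 1 - (2 - s)^2/2
        (the distribution of a sum of two independent uniforms).
    none: p_a unchanged.
    """
    if method not in COMBINE_METHODS:
        raise ValueError(f"method must be one of {sorted(COMBINE_METHODS)}")
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    if method == "none":
        return float(p_a)
    if method == "fisher":
        statistic = -2.0 * (np.log(p_a) + np.log(p_b))
        return float(stats.chi2.sf(statistic, df=4))
    if method == "stouffer":
        z = stats.norm.isf(p_a) + stats.norm.isf(p_b)
        return float(stats.norm.sf(z / np.sqrt(2.0)))
    s = p_a + p_b
    if s <= 1.0:
        return float(s * s / 2.0)
    return float(1.0 - (2.0 - s) ** 2 / 2.0)
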