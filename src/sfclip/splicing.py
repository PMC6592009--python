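"""PSI computation, expression filters and differential splicing.

The inclusion level of an event is the Percent Spliced-In,

    PSI = p1 / (p1 + p2),

where p1 and p2 are the expression of the two alternative paths (sums of
transcript abundances over the transcripts carrying each path). Lowly
expressed events — where PSI is noise — are removed by requiring all three
paths (p1, p2, pref) to reach at least the 0.1 quantile of path expression
in at least 75% of samples.

Per-event differential-splicing p-values can be imported from an external
event-level test, or produced by the built-in test: a Welch two-sample
t-test on logit-transformed PSI, gated by a direction check (a genuine
splicing change moves p1 and p2 expression in opposite directions). The
built-in test is a pragmatic stand-in for dedicated event-level statistics,
not a replacement; the import route is the fidelity path.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import SplicingEvent

logger = logging.getLogger(__name__)

#: winsorizing bound for the logit transform; PSI of exactly 0/1 is common
#: at low sequencing depth and would otherwise map to +-inf
LOGIT_EPS = 0.01


@dataclass
class PathExpression:
    """Per-event, per-sample expression of the three event paths.

    Three aligned DataFrames (index = event ids, columns = samples).
    ``pref`` defaults to p1 + p2 when no reference-path transcripts are
    quantified independently.
    """

    p1: pd.DataFrame
    p2: pd.DataFrame
    pref: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("p2", "pref"):
            other = getattr(self, name)
            if not (
                other.index.equals(self.p1.index)
                and other.columns.equals(self.p1.columns)
            ):
                raise ValueError(f"{name} is not aligned with p1")
        for name in ("p1", "p2", "pref"):
            if (getattr(self, name).to_numpy() < 0).any():
                raise ValueError(f"negative values in {name}")

    @property
    def event_ids(self) -> list[str]:
        return list(self.p1.index)

    @property
    def samples(self) -> list[str]:
        return list(self.p1.columns)


def compute_path_expression(
    tx_expr: pd.DataFrame, events: Sequence[SplicingEvent]
) -> PathExpression:
    """Aggregate transcript abundances into per-path event expression.

    p1_expr / p2_expr are sums over the member transcripts of each path;
    pref_expr is the explicit reference-path transcript sum when the event
    defines one, else p1 + p2. Transcripts missing from the table
    contribute 0 (warned once per run); events where neither alternative
    path resolves any transcript are excluded with a warning.
    """
    samples = list(tx_expr.columns)
    known = set(tx_expr.index)
    missing: set[str] = set()
    kept_events: list[str] = []
    p1_rows, p2_rows, pref_rows = [], [], []

    def path_sum(txs: set[str]) -> tuple[np.ndarray, bool]:
        present = [t for t in txs if t in known]
        missing.update(txs - known)
        if not present:
            return np.zeros(len(samples)), False
        return tx_expr.loc[present].to_numpy(float).sum(axis=0), True

    for ev in events:
        v1, ok1 = path_sum(ev.p1_transcripts)
        v2, ok2 = path_sum(ev.p2_transcripts)
        if not ok1 and not ok2:
            logger.warning(
                "%s: no resolvable transcripts on either path; excluded",
                ev.event_id,
            )
            continue
        if ev.pref_transcripts:
            vref, _ = path_sum(ev.pref_transcripts)
        else:
            vref = v1 + v2
        kept_events.append(ev.event_id)
        p1_rows.append(v1)
        p2_rows.append(v2)
        pref_rows.append(vref)

    if missing:
        logger.warning(
            "%d transcripts absent from the expression table (treated as 0)",
            len(missing),
        )
    idx = pd.Index(kept_events, name="event_id")
    return PathExpression(
        p1=pd.DataFrame(p1_rows, index=idx, columns=samples),
        p2=pd.DataFrame(p2_rows, index=idx, columns=samples),
        pref=pd.DataFrame(pref_rows, index=idx, columns=samples),
    )


def compute_psi(pe: PathExpression) -> pd.DataFrame:
    """PSI = p1 / (p1 + p2), NaN where both paths are silent (0/0)."""
    p1 = pe.p1.to_numpy(float)
    p2 = pe.p2.to_numpy(float)
    denom = p1 + p2
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, p1 / denom, np.nan)
    return pd.DataFrame(psi, index=pe.p1.index, columns=pe.p1.columns)


def filter_events_by_expression(
    pe: PathExpression, q: float = 0.1, sample_frac: float = 0.75
) -> set[str]:
    """Keep events whose three paths are all expressed in enough samples.

    Per sample the threshold is the ``q`` quantile (linear interpolation)
    of all path-expression values — p1, p2 and pref pooled over events —
    in that sample. A path passes in a sample if its value >= threshold
    and is positive (a silent path never passes, even when zeros drag the
    quantile itself to 0); an event is kept iff all three paths pass
    together in at least ceil(sample_frac * n_samples) samples.
    """
    p1, p2, pref = (x.to_numpy(float) for x in (pe.p1, pe.p2, pe.pref))
    n_samples = p1.shape[1]
    if n_samples < 1:
        raise ValueError("need >= 1 sample")
    pooled = np.vstack([p1, p2, pref])  # (3*events, samples)
    thresholds = np.quantile(pooled, q, axis=0)  # per sample
    ok = lambda x: (x >= thresholds) & (x > 0)
    all_pass = ok(p1) & ok(p2) & ok(pref)
    needed = math.ceil(sample_frac * n_samples)
    kept = all_pass.sum(axis=1) >= needed
    return set(np.asarray(pe.p1.index)[kept])


def filter_genes_by_expression(
    gene_expr: pd.DataFrame, q: float = 0.25
) -> set[str]:
    """Discard genes below the per-sample ``q`` expression quantile in
    every sample; a gene is kept iff it reaches the quantile (with
    positive expression) in >= 1 sample."""
    values = gene_expr.to_numpy(float)
    thresholds = np.quantile(values, q, axis=0)
    kept = ((values >= thresholds) & (values > 0)).any(axis=1)
    return set(np.asarray(gene_expr.index)[kept])


def differential_splicing_test(
    psi: pd.DataFrame,
    pe: PathExpression,
    design: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Built-in per-event differential-splicing test.

    Welch two-sample t-test (two-sided) on logit(PSI) with PSI winsorized
    to [eps, 1 - eps], eps = 0.01. ``delta_psi`` is reported on the raw
    PSI scale (mean condition minus mean reference). Events are set to
    p = 1 and flagged when: fewer than 2 non-missing PSI values in either
    group ("insufficient"); p1 and p2 expression do not move in opposite
    directions between groups ("direction") — a same-direction change is
    an expression change, not a splicing change; or both groups have zero
    variance with equal means ("degenerate").

    Returns an event-stats table: event_id, delta_psi, p, source
    ("builtin"), flag.
    """
    design = pd.Series(dict(design))
    ref_cols = [s for s in psi.columns if design.get(s) == "reference"]
    cond_cols = [s for s in psi.columns if design.get(s) == "condition"]
    if len(ref_cols) < 2 or len(cond_cols) < 2:
        raise ValueError("need >= 2 samples per group")

    psi_ref = psi[ref_cols].to_numpy(float)
    psi_cond = psi[cond_cols].to_numpy(float)
    n_ref = np.sum(~np.isnan(psi_ref), axis=1)
    n_cond = np.sum(~np.isnan(psi_cond), axis=1)
    insufficient = (n_ref < 2) | (n_cond < 2)

    with np.errstate(invalid="ignore"):
        delta = np.nanmean(psi_cond, axis=1) - np.nanmean(psi_ref, axis=1)
    delta = np.where(n_ref * n_cond > 0, delta, np.nan)

    def logit(x: np.ndarray) -> np.ndarray:
        w = np.clip(x, LOGIT_EPS, 1.0 - LOGIT_EPS)
        return np.log(w) - np.log1p(-w)

    la, lb = logit(psi_cond), logit(psi_ref)
    ma, mb = np.nanmean(la, axis=1), np.nanmean(lb, axis=1)
    va = _nanvar(la)
    vb = _nanvar(lb)
    denom2 = va / np.maximum(n_cond, 1) + vb / np.maximum(n_ref, 1)
    degenerate = denom2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom2)
        dfree = denom2**2 / (
            (va / np.maximum(n_cond, 1)) ** 2 / np.maximum(n_cond - 1, 1)
            + (vb / np.maximum(n_ref, 1)) ** 2 / np.maximum(n_ref - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), dfree)
    p = np.where(
        degenerate, np.where(ma == mb, 1.0, np.finfo(float).tiny), p
    )

    # direction check: mean p1 and p2 expression must shift oppositely
    d1 = (
        pe.p1[cond_cols].to_numpy(float).mean(axis=1)
        - pe.p1[ref_cols].to_numpy(float).mean(axis=1)
    )
    d2 = (
        pe.p2[cond_cols].to_numpy(float).mean(axis=1)
        - pe.p2[ref_cols].to_numpy(float).mean(axis=1)
    )
    wrong_direction = ~(d1 * d2 < 0)

    flag = np.full(len(psi), "", dtype=object)
    flag[degenerate] = "degenerate"
    flag[wrong_direction & (flag == "")] = "direction"
    p = np.where(wrong_direction, 1.0, p)
    flag[insufficient] = "insufficient"
    p = np.where(insufficient, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "event_id": psi.index,
            "delta_psi": delta,
            "p": p,
            "source": "builtin",
            "flag": flag,
        }
    ).reset_index(drop=True)


def _nanvar(x: np.ndarray) -> np.ndarray:
    n = np.sum(~np.isnan(x), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        v = np.nanvar(x, axis=1, ddof=1)
    return np.where(n > 1, v, np.nan)


def import_event_stats(
    path: str | Path, known_event_ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Read an externally computed event-stats TSV (event_id, p[, delta_psi]).

    The imported route lets a dedicated event-level test supply p-values.
    p must lie in (0, 1]; unknown event ids (when a reference set is
    given) are rejected with a listing.
    """
    df = pd.read_csv(path, sep="\t")
    if "event_id" not in df.columns or "p" not in df.columns:
        raise ValueError(f"{path}: need columns event_id and p")
    bad = df[(df["p"] <= 0) | (df["p"] > 1) | df["p"].isna()]
    if len(bad):
        raise ValueError(
            f"{path}: p-values outside (0, 1] for events "
            f"{bad['event_id'].tolist()[:5]}"
        )
    if known_event_ids is not None:
        unknown = sorted(set(df["event_id"]) - set(known_event_ids))
        if unknown:
            raise ValueError(f"{path}: unknown event ids {unknown[:10]}")
    if "delta_psi" not in df.columns:
        df["delta_psi"] = np.nan
    df["source"] = "imported"
    df["flag"] = ""
    return df[["event_id", "delta_psi", "p", "source", "flag"]]


def write_event_stats(stats_df: pd.DataFrame, path: str | Path) -> None:
    stats_df.to_csv(path, sep="\t", index=False)


def merge_event_stats(
    imported: pd.DataFrame, builtin: pd.DataFrame
) -> pd.DataFrame:
    """Combine stats tables, preferring imported rows per event."""
    extra = builtin[~builtin["event_id"].isin(set(imported["event_id"]))]
    return pd.concat([imported, extra], ignore_index=True)


def select_top_events(stats_df: pd.DataFrame, n: int = 1000) -> set[str]:
    """The n most significant events by p-value.

    Boundary ties are broken by larger |delta_psi|, then lexicographic
    event_id; if fewer than n events exist, all are selected.
    """
    ordered = stats_df.assign(_abs=stats_df["delta_psi"].abs().fillna(0.0)).sort_values(
        ["p", "_abs", "event_id"], ascending=[True, False, True]
    )
    return set(ordered["event_id"].head(n))


def select_events_by_p(stats_df: pd.DataFrame, p_threshold: float) -> set[str]:
    """Alternative selection mode: every event with p < threshold."""
    return set(stats_df.loc[stats_df["p"] < p_threshold, "event_id"])
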