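"""Seeded synthetic datasets with a planted knocked-down splicing factor.

The generator emulates the structure the method relies on, at desk scale:
RBP families share binding targets (family members bind the same events
with high probability, others at background rate), one *driver* RBP binds
a set of events whose inclusion level (PSI) shifts between conditions, and
the driver's own gene expression drops in the condition group — the
signature of an siRNA knock-down. Everything lives on one toy chromosome;
the bundle provides exactly the inputs the pipeline consumes (event table,
peak files with metadata, transcript and gene expression, a design) plus
the ground truth needed to score recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clip import ClipPeak
from .events import GenomicInterval, SplicingEvent, write_event_table

#: layout of one simulated cassette event within its genomic slot (offsets
#: from the event base): upstream/downstream constitutive exons form pref,
#: the cassette exon is p1 and the skipping junction region is p2
_PREF_UP = (0, 100)
_P1 = (300, 450)
_P2 = (600, 700)
_PREF_DOWN = (900, 1000)
_EVENT_SPACING = 3000
_PEAK_LEN = 30

_DB_CYCLE = ["POSTAR2", "CLIPdb", "POSTAR2", "DoRiNA", "POSTAR2", "StarBase"]
_TECH_CYCLE = ["eCLIP", "HITS-CLIP", "PAR-CLIP", "iCLIP"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic knock-down dataset."""

    n_events: int = 2000
    n_rbps: int = 30
    n_families: int = 3
    within_family_bind_prob: float = 0.6
    background_bind_prob: float = 0.05
    driver_target_frac: float = 0.1
    delta_psi_effect: float = 0.3
    psi_noise_sd: float = 0.05
    n_samples_per_group: int = 5
    driver_knockdown_log2fc: float = -1.5
    expr_noise_cv: float = 0.1
    decoy_frac: float = 0.0  # fraction of non-driver RBPs co-regulated
    decoy_log2fc: float = -1.0
    n_background_genes: int = 300  # non-RBP genes anchoring the gene filter
    window_nt: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_family_bind_prob", "background_bind_prob",
                     "driver_target_frac", "decoy_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if not (0.0 <= self.delta_psi_effect < 1.0):
            raise ValueError("delta_psi_effect must be in [0, 1)")
        if round(self.driver_target_frac * self.n_events) < 1:
            raise ValueError(
                "infeasible config: driver_target_frac * n_events < 1"
            )


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator."""

    driver_rbp: str
    perturbed_event_ids: set[str]
    family_of: dict[str, int]


@dataclass
class SimulatedDataset:
    """In-memory bundle of every pipeline input plus the ground truth."""

    config: SimulationConfig
    events: list[SplicingEvent]
    peaks: list[ClipPeak]
    peak_metadata: pd.DataFrame
    tx_expr: pd.DataFrame
    gene_expr: pd.DataFrame
    design: pd.Series
    truth: SimulationTruth


def _truncnorm01(rng: np.random.Generator, mean: np.ndarray, sd: float
                 ) -> np.ndarray:
    """Truncated-normal PSI noise on [0, 1] (bounded support)."""
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one deterministic dataset from ``cfg`` (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    n_ev, n_rbp = cfg.n_events, cfg.n_rbps
    event_ids = [f"EV{i:05d}" for i in range(n_ev)]
    rbp_ids = [f"RBP{j:02d}" for j in range(n_rbp)]
    driver = rbp_ids[0]

    # --- events on one toy chromosome ---------------------------------
    bases = 1000 + np.arange(n_ev) * _EVENT_SPACING
    events: list[SplicingEvent] = []
    for i, base in enumerate(bases):
        base = int(base)
        events.append(
            SplicingEvent(
                event_id=event_ids[i],
                gene_id=f"G{i:05d}",
                event_type="cassette",
                p1_intervals=[
                    GenomicInterval("chrS", base + _P1[0], base + _P1[1], "+")
                ],
                p2_intervals=[
                    GenomicInterval("chrS", base + _P2[0], base + _P2[1], "+")
                ],
                pref_intervals=[
                    GenomicInterval("chrS", base + _PREF_UP[0], base + _PREF_UP[1], "+"),
                    GenomicInterval("chrS", base + _PREF_DOWN[0], base + _PREF_DOWN[1], "+"),
                ],
                p1_transcripts={f"{event_ids[i]}.t1"},
                p2_transcripts={f"{event_ids[i]}.t2"},
            )
        )

    # --- family structure and binding ---------------------------------
    rbp_family = {rbp_ids[j]: j % cfg.n_families for j in range(n_rbp)}
    event_family = rng.integers(0, cfg.n_families, size=n_ev)
    fam_vec = np.array([rbp_family[r] for r in rbp_ids])
    prob = np.where(
        event_family[:, None] == fam_vec[None, :],
        cfg.within_family_bind_prob,
        cfg.background_bind_prob,
    )
    bound = rng.random((n_ev, n_rbp)) < prob

    n_perturbed = int(round(cfg.driver_target_frac * n_ev))
    perturbed_idx = np.sort(rng.choice(n_ev, size=n_perturbed, replace=False))
    bound[perturbed_idx, 0] = True  # the driver binds all perturbed events

    # --- peaks: one peak inside the splicing region of each bound event
    ev_idx, rbp_idx = np.nonzero(bound)
    p1_starts = bases[ev_idx] + _P1[0]
    p1_ends = bases[ev_idx] + _P1[1]
    lo = np.maximum(p1_starts - cfg.window_nt + 5, 0)
    hi = p1_ends + cfg.window_nt - _PEAK_LEN - 5
    starts = rng.integers(lo, hi)
    peaks: list[ClipPeak] = []
    meta_rows = []
    for j, rbp in enumerate(rbp_ids):
        db = _DB_CYCLE[j % len(_DB_CYCLE)]
        tech = _TECH_CYCLE[j % len(_TECH_CYCLE)]
        exp_id = f"EXP_{rbp}"
        meta_rows.append(
            (f"{exp_id}.bed", rbp, db, tech, exp_id, "bed6", 0)
        )
    for e, j, s in zip(ev_idx, rbp_idx, starts):
        s = int(s)
        peaks.append(
            ClipPeak(
                rbp=rbp_ids[j],
                experiment_id=f"EXP_{rbp_ids[j]}",
                database=_DB_CYCLE[j % len(_DB_CYCLE)],
                technology=_TECH_CYCLE[j % len(_TECH_CYCLE)],
                interval=GenomicInterval("chrS", s, s + _PEAK_LEN, "+"),
                score=1.0,
            )
        )
    peak_metadata = pd.DataFrame(
        meta_rows,
        columns=["file", "rbp", "database", "technology", "experiment_id",
                 "dialect", "excluded"],
    )

    # --- PSI and transcript expression --------------------------------
    n_s = cfg.n_samples_per_group
    samples = [f"ref{s+1}" for s in range(n_s)] + [f"kd{s+1}" for s in range(n_s)]
    design = pd.Series(
        ["reference"] * n_s + ["condition"] * n_s, index=samples, name="group"
    )

    # baseline inclusion in [0.4, 0.6]; the knock-down shifts perturbed
    # events across 0.5 so both paths stay expressed and the event is not
    # erased by the expression filter it must later pass
    psi0 = rng.uniform(0.3, 0.7, size=n_ev)
    shift_sign = np.where(psi0 <= 0.5, 1.0, -1.0)
    psi_mean = np.tile(psi0[:, None], (1, 2 * n_s))
    cond_cols = np.arange(n_s, 2 * n_s)
    shifted = psi0.copy()
    shifted[perturbed_idx] = np.clip(
        psi0[perturbed_idx] + shift_sign[perturbed_idx] * cfg.delta_psi_effect,
        0.02,
        0.98,
    )
    psi_mean[:, cond_cols] = shifted[:, None]
    psi = _truncnorm01(rng, psi_mean, cfg.psi_noise_sd)

    # event expression spans ~3 orders of magnitude (TPM-like); the
    # relative expression filter then removes genuinely low events rather
    # than events with a skewed path balance
    total = rng.lognormal(np.log(50.0), 0.8, size=n_ev)
    sigma = float(np.sqrt(np.log1p(cfg.expr_noise_cv**2)))
    depth_noise = rng.lognormal(0.0, sigma, size=(n_ev, 2 * n_s))
    tot = total[:, None] * depth_noise
    tx1 = tot * psi
    tx2 = tot * (1.0 - psi)
    tx_rows = np.empty((2 * n_ev, 2 * n_s))
    tx_rows[0::2] = tx1
    tx_rows[1::2] = tx2
    tx_index = [
        t for eid in event_ids for t in (f"{eid}.t1", f"{eid}.t2")
    ]
    tx_expr = pd.DataFrame(tx_rows, index=pd.Index(tx_index, name="transcript"),
                           columns=samples)

    # --- RBP gene expression (knock-down signature) --------------------
    base_expr = rng.lognormal(np.log(100.0), 0.3, size=n_rbp)
    gene_vals = base_expr[:, None] * rng.lognormal(
        0.0, sigma, size=(n_rbp, 2 * n_s)
    )
    gene_vals[0, n_s:] *= 2.0**cfg.driver_knockdown_log2fc
    n_decoys = int(round(cfg.decoy_frac * (n_rbp - 1)))
    if n_decoys:
        decoys = rng.choice(np.arange(1, n_rbp), size=n_decoys, replace=False)
        gene_vals[decoys, n_s:] *= 2.0**cfg.decoy_log2fc
    # background (non-RBP) genes anchor the relative gene-expression
    # filter the way the full transcriptome does in real data; without
    # them the 0.25 quantile would sit inside the RBP genes themselves
    n_bg = cfg.n_background_genes
    bg_base = rng.lognormal(np.log(20.0), 1.2, size=n_bg)
    bg_vals = bg_base[:, None] * rng.lognormal(0.0, sigma, size=(n_bg, 2 * n_s))
    gene_expr = pd.DataFrame(
        np.vstack([gene_vals, bg_vals]),
        index=pd.Index(rbp_ids + [f"BG{i:04d}" for i in range(n_bg)], name="gene"),
        columns=samples,
    )

    truth = SimulationTruth(
        driver_rbp=driver,
        perturbed_event_ids={event_ids[i] for i in perturbed_idx},
        family_of=rbp_family,
    )
    return SimulatedDataset(
        config=cfg,
        events=events,
        peaks=peaks,
        peak_metadata=peak_metadata,
        tx_expr=tx_expr,
        gene_expr=gene_expr,
        design=design,
        truth=truth,
    )


def write_dataset(bundle: SimulatedDataset, out_dir: str | Path) -> None:
    """Emit the bundle as the on-disk formats the pipeline consumes.

    Writes events.tsv, one BED6 peak file per experiment plus
    peak_metadata.tsv, tx_expr.tsv, gene_expr.tsv, design.tsv, truth.json
    and a manifest.json recording the full configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_event_table(bundle.events, out / "events.tsv")

    by_exp: dict[str, list[ClipPeak]] = {}
    for pk in bundle.peaks:
        by_exp.setdefault(pk.experiment_id, []).append(pk)
    for row in bundle.peak_metadata.itertuples(index=False):
        lines = []
        for pk in sorted(
            by_exp.get(row.experiment_id, []), key=lambda p: p.interval
        ):
            iv = pk.interval
            lines.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.experiment_id}\t"
                f"{0 if pk.score is None else pk.score:g}\t{iv.strand}\n"
            )
        (out / row.file).write_text("".join(lines))
    bundle.peak_metadata.to_csv(out / "peak_metadata.tsv", sep="\t", index=False)

    bundle.tx_expr.to_csv(out / "tx_expr.tsv", sep="\t")
    bundle.gene_expr.to_csv(out / "gene_expr.tsv", sep="\t")
    bundle.design.rename("group").to_frame().rename_axis("sample").to_csv(
        out / "design.tsv", sep="\t"
    )
    (out / "truth.json").write_text(
        json.dumps(
            {
                "driver_rbp": bundle.truth.driver_rbp,
                "perturbed_event_ids": sorted(bundle.truth.perturbed_event_ids),
                "family_of": bundle.truth.family_of,
            },
            indent=1,
            sort_keys=True,
        )
    )
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=1, sort_keys=True)
    )


def evaluate_recovery(
    ranking: pd.DataFrame, truth: SimulationTruth
) -> dict[str, object]:
    """Score how well the pipeline recovered the planted driver.

    Returns the driver's CLIP rank over all RBPs, whether it passed the
    expression filters, and its 1-based rank within the candidate list
    (None when it did not pass).
    """
    rows = ranking[ranking["rbp"] == truth.driver_rbp]
    if rows.empty:
        raise ValueError(f"driver {truth.driver_rbp} absent from ranking")
    row = rows.iloc[0]
    passes = bool(row["passes_filters"])
    driver_rank = None
    if passes:
        cands = ranking[ranking["passes_filters"]].sort_values(
            ["p_clip", "k", "rbp"], ascending=[True, False, True]
        )
        driver_rank = int(
            np.nonzero((cands["rbp"] == truth.driver_rbp).to_numpy())[0][0] + 1
        )
    return {
        "driver_rank": driver_rank,
        "driver_passes": passes,
        "driver_rank_clip": int(row["rank_clip"]),
        "driver_p_clip": float(row["p_clip"]),
    }
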