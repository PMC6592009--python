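"""PSI, expression filters, the built-in differential-splicing test and
event selection."""

import math

import numpy as np
import pandas as pd
import pytest

from sfclip import (
    GenomicInterval,
    PathExpression,
    SplicingEvent,
    compute_path_expression,
    compute_psi,
    differential_splicing_test,
    filter_events_by_expression,
    filter_genes_by_expression,
    import_event_stats,
    select_events_by_p,
    select_top_events,
)
from sfclip.splicing import merge_event_stats, write_event_stats


def event(eid, p1_txs, p2_txs):
    return SplicingEvent(
        event_id=eid,
        gene_id=f"G_{eid}",
        event_type="cassette",
        p1_intervals=[GenomicInterval("chr1", 0, 100)],
        p2_intervals=[GenomicInterval("chr1", 200, 300)],
        p1_transcripts=set(p1_txs),
        p2_transcripts=set(p2_txs),
    )


def pe_from_arrays(p1, p2, pref=None, samples=None):
    p1 = np.atleast_2d(np.asarray(p1, float))
    p2 = np.atleast_2d(np.asarray(p2, float))
    samples = samples or [f"s{i}" for i in range(p1.shape[1])]
    idx = pd.Index([f"e{i}" for i in range(p1.shape[0])], name="event_id")
    mk = lambda a: pd.DataFrame(np.atleast_2d(a), index=idx, columns=samples)
    return PathExpression(mk(p1), mk(p2), mk(pref if pref is not None else p1 + p2))


class TestPathExpression:
    def test_sums_over_member_transcripts(self):
        tx = pd.DataFrame(
            {"s1": [3.0, 1.0, 4.0]}, index=["T1", "T2", "T3"]
        )
        pe = compute_path_expression(tx, [event("e1", {"T1", "T2"}, {"T3"})])
        assert pe.p1.loc["e1", "s1"] == 4.0
        assert pe.p2.loc["e1", "s1"] == 4.0
        assert pe.pref.loc["e1", "s1"] == 8.0  # defaults to p1 + p2

    def test_missing_transcript_contributes_zero(self, caplog):
        tx = pd.DataFrame({"s1": [3.0]}, index=["T1"])
        with caplog.at_level("WARNING"):
            pe = compute_path_expression(tx, [event("e1", {"T1"}, {"TX"})])
        assert pe.p2.loc["e1", "s1"] == 0.0
        assert "absent" in caplog.text

    def test_fully_unresolvable_event_excluded(self, caplog):
        tx = pd.DataFrame({"s1": [3.0]}, index=["T1"])
        with caplog.at_level("WARNING"):
            pe = compute_path_expression(
                tx, [event("e1", {"TA"}, {"TB"}), event("e2", {"T1"}, {"TB"})]
            )
        assert pe.event_ids == ["e2"]

    def test_aggregation_matches_brute_force(self, rng):
        txs = [f"T{i}" for i in range(30)]
        tx = pd.DataFrame(
            rng.random((30, 4)) * 10, index=txs,
            columns=[f"s{j}" for j in range(4)],
        )
        events = []
        for i in range(10):
            picked = rng.choice(txs, size=6, replace=False)
            events.append(event(f"e{i}", set(picked[:3]), set(picked[3:])))
        pe = compute_path_expression(tx, events)
        for ev in events:
            expect = sum(tx.loc[t] for t in ev.p1_transcripts)
            assert np.allclose(pe.p1.loc[ev.event_id], expect)


class TestComputePsi:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(0.0, 5.0, 0.0), (3.0, 3.0, 0.5), (5.0, 0.0, 1.0)],
    )
    def test_values(self, p1, p2, expected):
        psi = compute_psi(pe_from_arrays([[p1]], [[p2]]))
        assert psi.iloc[0, 0] == pytest.approx(expected)

    def test_zero_zero_is_missing(self):
        psi = compute_psi(pe_from_arrays([[0.0]], [[0.0]]))
        assert np.isnan(psi.iloc[0, 0])

    def test_label_swap_complements_psi(self, rng):
        p1, p2 = rng.random((5, 4)) + 0.1, rng.random((5, 4)) + 0.1
        a = compute_psi(pe_from_arrays(p1, p2))
        b = compute_psi(pe_from_arrays(p2, p1))
        assert np.allclose(a.to_numpy() + b.to_numpy(), 1.0)


class TestEventFilter:
    def test_silent_event_removed(self):
        p1 = [[0, 0, 0, 0], [10, 10, 10, 10]]
        p2 = [[0, 0, 0, 0], [8, 9, 10, 11]]
        kept = filter_events_by_expression(pe_from_arrays(p1, p2))
        assert kept == {"e1"}

    def test_ceiling_rule(self):
        # 4 samples at sample_frac 0.75 -> need >= 3 passing samples
        assert math.ceil(0.75 * 4) == 3
        p1 = [[10, 10, 10, 0], [10, 10, 0, 0]]
        p2 = [[10, 10, 10, 10], [10, 10, 10, 10]]
        pe = pe_from_arrays(p1, p2)
        kept = filter_events_by_expression(pe, q=0.1, sample_frac=0.75)
        assert kept == {"e0"}

    def test_matches_hand_coded_rule_oracle(self, rng):
        p1 = rng.random((5, 4)) * 20
        p2 = rng.random((5, 4)) * 20
        pref = p1 + p2
        pe = pe_from_arrays(p1, p2, pref)
        q, frac = 0.3, 0.75
        kept = filter_events_by_expression(pe, q=q, sample_frac=frac)
        oracle = set()
        for i in range(5):
            n_ok = 0
            for s in range(4):
                thr = np.quantile(
                    [*p1[:, s], *p2[:, s], *pref[:, s]], q
                )
                if p1[i, s] >= thr and p2[i, s] >= thr and pref[i, s] >= thr:
                    n_ok += 1
            if n_ok >= math.ceil(frac * 4):
                oracle.add(f"e{i}")
        assert kept == oracle

    def test_degenerate_thresholds_keep_everything(self, rng):
        p1 = rng.random((6, 4)) + 0.01
        pe = pe_from_arrays(p1, rng.random((6, 4)) + 0.01)
        assert len(filter_events_by_expression(pe, q=0.0)) == 6
        assert len(filter_events_by_expression(pe, sample_frac=0.0)) == 6


class TestGeneFilter:
    def test_top_gene_kept_bottom_dropped(self):
        expr = pd.DataFrame(
            {"s1": [100.0, 50.0, 10.0, 0.0], "s2": [90.0, 60.0, 12.0, 0.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        kept = filter_genes_by_expression(expr, q=0.25)
        assert "g1" in kept and "g4" not in kept

    def test_matches_rule_oracle(self, rng):
        expr = pd.DataFrame(
            rng.random((8, 3)) * 100,
            index=[f"g{i}" for i in range(8)],
            columns=["s1", "s2", "s3"],
        )
        kept = filter_genes_by_expression(expr, q=0.25)
        thr = expr.quantile(0.25, axis=0)
        oracle = {g for g in expr.index if (expr.loc[g] >= thr).any()}
        assert kept == oracle


def make_groups(n_events, n_per_group, psi_ref, psi_cond, rng, sd=0.05, total=100.0):
    """Path expression for a two-group design from target PSI means."""
    samples = [f"ref{i}" for i in range(n_per_group)] + [
        f"kd{i}" for i in range(n_per_group)
    ]
    psi_mean = np.column_stack(
        [np.tile(psi_ref, (n_per_group, 1)).T, np.tile(psi_cond, (n_per_group, 1)).T]
    )
    psi = np.clip(psi_mean + rng.normal(0, sd, psi_mean.shape), 0.001, 0.999)
    p1 = total * psi
    p2 = total * (1 - psi)
    pe = pe_from_arrays(p1, p2, samples=samples)
    design = pd.Series(
        ["reference"] * n_per_group + ["condition"] * n_per_group, index=samples
    )
    return pe, design


class TestDifferentialSplicingTest:
    def test_identical_groups_p_one(self):
        p1 = np.full((1, 6), 50.0)
        p2 = np.full((1, 6), 50.0)
        pe = pe_from_arrays(p1, p2, samples=[f"s{i}" for i in range(6)])
        design = pd.Series(
            ["reference"] * 3 + ["condition"] * 3, index=pe.samples
        )
        stats = differential_splicing_test(compute_psi(pe), pe, design)
        assert stats["p"].iloc[0] == 1.0
        assert stats["delta_psi"].iloc[0] == 0.0

    def test_planted_shift_power(self):
        """ΔPSI = 0.3 at sd 0.05, n = 5+5 is detected at p < 0.01."""
        rng = np.random.default_rng(11)
        n = 200
        psi_ref = np.full(n, 0.4)
        pe, design = make_groups(n, 5, psi_ref, psi_ref + 0.3, rng)
        stats = differential_splicing_test(compute_psi(pe), pe, design)
        assert (stats["p"] < 0.01).mean() >= 0.95
        assert stats["delta_psi"].mean() == pytest.approx(0.3, abs=0.03)
        assert np.allclose(stats["delta_psi"], 0.3, atol=0.15)

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(12)
        n = 2000
        psi_ref = rng.uniform(0.3, 0.7, n)
        pe, design = make_groups(n, 5, psi_ref, psi_ref, rng)
        stats = differential_splicing_test(compute_psi(pe), pe, design)
        frac = (stats["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_group_relabel_flips_delta_only(self):
        rng = np.random.default_rng(13)
        pe, design = make_groups(50, 4, np.full(50, 0.4), np.full(50, 0.6), rng)
        a = differential_splicing_test(compute_psi(pe), pe, design)
        flipped = design.map(
            {"reference": "condition", "condition": "reference"}
        )
        b = differential_splicing_test(compute_psi(pe), pe, flipped)
        assert np.allclose(a["delta_psi"], -b["delta_psi"])
        assert np.allclose(a["p"], b["p"])

    def test_same_direction_expression_change_flagged(self):
        # both paths double: an expression change, not a splicing change
        samples = [f"s{i}" for i in range(8)]
        p1 = np.array([[10, 11, 10, 11, 20, 21, 20, 21.0]])
        p2 = np.array([[30, 29, 31, 30, 61, 60, 59, 62.0]])
        pe = pe_from_arrays(p1, p2, samples=samples)
        design = pd.Series(["reference"] * 4 + ["condition"] * 4, index=samples)
        stats = differential_splicing_test(compute_psi(pe), pe, design)
        assert stats["flag"].iloc[0] == "direction"
        assert stats["p"].iloc[0] == 1.0

    def test_insufficient_samples_flagged(self):
        samples = [f"s{i}" for i in range(6)]
        # both paths silent in 2 of 3 reference samples -> PSI missing there
        p1 = np.array([[0, 0, 10, 12, 11, 13.0]])
        p2 = np.array([[0, 0, 12, 10, 12, 10.0]])
        pe = pe_from_arrays(p1, p2, samples=samples)
        design = pd.Series(["reference"] * 3 + ["condition"] * 3, index=samples)
        stats = differential_splicing_test(compute_psi(pe), pe, design)
        assert stats["flag"].iloc[0] == "insufficient"
        assert stats["p"].iloc[0] == 1.0


class TestSelection:
    def stats(self, rows):
        return pd.DataFrame(rows, columns=["event_id", "delta_psi", "p"])

    def test_fewer_events_than_n_selects_all(self):
        df = self.stats([(f"e{i}", 0.1, 0.5) for i in range(500)])
        assert len(select_top_events(df, 1000)) == 500

    def test_boundary_tie_broken_by_delta_psi(self):
        df = self.stats(
            [("a", 0.1, 0.01), ("b", 0.5, 0.02), ("c", 0.2, 0.02)]
        )
        assert select_top_events(df, 2) == {"a", "b"}

    def test_matches_sort_oracle(self, rng):
        df = self.stats(
            [(f"e{i}", float(rng.uniform(-1, 1)), float(rng.uniform(0, 1)))
             for i in range(200)]
        )
        got = select_top_events(df, 50)
        ranked = sorted(
            df.itertuples(index=False),
            key=lambda r: (r.p, -abs(r.delta_psi), r.event_id),
        )
        assert got == {r.event_id for r in ranked[:50]}

    def test_p_threshold_mode(self):
        df = self.stats([("a", 0, 0.0005), ("b", 0, 0.5), ("c", 0, 0.0009)])
        assert select_events_by_p(df, 0.001) == {"a", "c"}


class TestImportedStats:
    def test_round_trip_and_merge_precedence(self, tmp_path):
        imported = pd.DataFrame(
            {"event_id": ["e1"], "delta_psi": [0.2], "p": [0.01],
             "source": ["imported"], "flag": [""]}
        )
        path = tmp_path / "stats.tsv"
        write_event_stats(imported, path)
        back = import_event_stats(path, known_event_ids=["e1", "e2"])
        assert back["source"].iloc[0] == "imported"
        builtin = pd.DataFrame(
            {"event_id": ["e1", "e2"], "delta_psi": [0.0, 0.1],
             "p": [0.9, 0.2], "source": "builtin", "flag": ""}
        )
        merged = merge_event_stats(back, builtin).set_index("event_id")
        assert merged.loc["e1", "source"] == "imported"
        assert merged.loc["e1", "p"] == 0.01
        assert merged.loc["e2", "source"] == "builtin"

    def test_p_zero_rejected(self, tmp_path):
        path = tmp_path / "stats.tsv"
        path.write_text("event_id\tp\ne1\t0.0\n")
        with pytest.raises(ValueError, match="0, 1"):
            import_event_stats(path)

    def test_unknown_event_rejected(self, tmp_path):
        path = tmp_path / "stats.tsv"
        path.write_text("event_id\tp\neX\t0.5\n")
        with pytest.raises(ValueError, match="unknown"):
            import_event_stats(path, known_event_ids=["e1"])
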