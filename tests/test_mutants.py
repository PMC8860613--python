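"""DMT calling, methyltransferase contributions, overlap and density bias."""

import itertools

import numpy as np
import pandas as pd
import pytest

from telosubmeth import (
    SampleProfile,
    call_dmts,
    contribution,
    density_bias_test,
    overlap_analysis,
)


def _tiles(levels, end_id="1L", width=40, start=71, **extra):
    """Build a tile table from a dict of column -> list."""
    n = len(next(iter(levels.values())))
    base = {
        "end_id": [end_id] * n,
        "start": [start + i * width for i in range(n)],
        "end": [start + (i + 1) * width - 1 for i in range(n)],
    }
    base.update(levels)
    base.update(extra)
    df = pd.DataFrame(base)
    for col in ("CGm", "CHGm", "CHHm"):
        if col not in df.columns:
            df[col] = np.nan
    return df


class TestCallDmts:
    def test_chg_threshold_arithmetic(self):
        wt = _tiles({"CHGm": [40.0]})
        mut = _tiles({"CHGm": [22.0]})
        calls = call_dmts(wt, {"m": mut})
        row = calls[(calls.context == "CHG")].iloc[0]
        assert row.labelled and row.is_dmt  # delta 18 >= 15

    def test_low_wt_not_labelled(self):
        wt = _tiles({"CGm": [18.0]})
        mut = _tiles({"CGm": [0.0]})
        calls = call_dmts(wt, {"m": mut})
        row = calls[calls.context == "CG"].iloc[0]
        assert not row.labelled and not row.is_dmt

    @pytest.mark.parametrize(
        "ctx,thr", [("CG", 20.0), ("CHG", 15.0), ("CHH", 10.0)]
    )
    def test_exact_threshold_is_called(self, ctx, thr):
        wt = _tiles({ctx + "m": [50.0]})
        mut = _tiles({ctx + "m": [50.0 - thr]})
        calls = call_dmts(wt, {"m": mut})
        assert calls[calls.context == ctx].iloc[0].is_dmt

    def test_interval_mismatch_errors(self):
        wt = _tiles({"CGm": [50.0, 40.0]})
        mut = _tiles({"CGm": [10.0, 10.0]}, start=111)
        with pytest.raises(ValueError, match="intervals"):
            call_dmts(wt, {"m": mut})

    def test_dmt_monotonicity(self):
        """Lowering a mutant tile level never un-calls a DMT."""
        rng = np.random.default_rng(13)
        wt = _tiles({"CHHm": rng.uniform(0, 100, 30)})
        mut_levels = rng.uniform(0, 100, 30)
        calls1 = call_dmts(wt, {"m": _tiles({"CHHm": mut_levels})})
        calls2 = call_dmts(wt, {"m": _tiles({"CHHm": mut_levels - 5.0})})
        before = calls1[calls1.context == "CHH"].is_dmt.to_numpy()
        after = calls2[calls2.context == "CHH"].is_dmt.to_numpy()
        assert (after | ~before).all()

    def test_relative_mode(self):
        wt = _tiles({"CGm": [30.0]})
        mut = _tiles({"CGm": [20.0]})  # 10 points = 33% relative
        assert not call_dmts(wt, {"m": mut}).iloc[0].is_dmt
        rel = call_dmts(wt, {"m": mut}, relative=True)
        assert rel[rel.context == "CG"].iloc[0].is_dmt


def _profile_from_levels(genotype, levels, context="CHH", subcontext="CCH"):
    rows = [
        ("1L", 100 + i, "+", context, subcontext, 0, 1, lv)
        for i, lv in enumerate(levels)
    ]
    return SampleProfile(genotype, pd.DataFrame(
        rows, columns=["end_id", "pos", "strand", "context", "subcontext",
                       "meth", "total", "level"]))


class TestContribution:
    def test_formula(self):
        wt = _profile_from_levels("WT", [50.0] * 10)
        mut = _profile_from_levels("drm2", [20.0] * 10)
        c = contribution(wt, mut, "CHH")
        assert c.value == pytest.approx(60.0)

    def test_identity_gives_zero(self):
        wt = _profile_from_levels("WT", [37.0] * 5)
        mut = _profile_from_levels("drm2", [37.0] * 5)
        assert contribution(wt, mut, "CHH").value == pytest.approx(0.0)

    def test_zero_wt_is_undefined(self):
        wt = _profile_from_levels("WT", [0.0] * 5)
        mut = _profile_from_levels("drm2", [0.0] * 5)
        c = contribution(wt, mut, "CHH")
        assert not c.defined

    def test_gain_is_negative_and_clipped(self):
        wt = _profile_from_levels("WT", [10.0] * 5)
        mut = _profile_from_levels("drm2", [40.0] * 5)
        c = contribution(wt, mut, "CHH")
        assert c.raw_value == pytest.approx(-300.0)
        assert c.value == -100.0

    def test_subcontext_scope(self):
        wt = _profile_from_levels("WT", [50.0] * 5, subcontext="CCH")
        mut = _profile_from_levels("drm2", [10.0] * 5, subcontext="CCH")
        c = contribution(wt, mut, "CCH")
        assert c.value == pytest.approx(80.0)

    def test_recovers_planted_activity_loss(self, default_truth):
        """A mutant retaining 15% of CHH activity loses 85% of WT
        methylation; the estimate lands within 5 points at 20x."""
        from telosubmeth import generate_end, simulate_methylome
        import dataclasses

        activity = {g: dict(a) for g, a in default_truth.activity.items()}
        activity["mutX"] = {s: 1.0 for s in activity["WT"]}
        for s in ("CAH", "CTH", "CCH"):
            activity["mutX"][s] = 0.15
        truth = dataclasses.replace(default_truth, activity=activity, seed=23)
        syn = generate_end(truth)
        wt, _ = simulate_methylome(syn, "WT", seed=1001)
        mut, _ = simulate_methylome(syn, "mutX", seed=1002)
        c = contribution(wt, mut, "CHH", interval=(71, truth.extent))
        assert c.n_sites >= 300
        assert c.value == pytest.approx(85.0, abs=5.0)


class TestOverlapAnalysis:
    def _fixture_calls(self, seed=31, n=30):
        rng = np.random.default_rng(seed)
        rows = []
        flags = {}
        for g in ("met1", "drm2", "cmt2"):
            flags[g] = rng.random(n) < 0.5
        for i in range(n):
            for g in ("met1", "drm2", "cmt2"):
                rows.append({
                    "end_id": "1L", "start": 71 + 40 * i, "end": 110 + 40 * i,
                    "context": "CHH", "genotype": g,
                    "wt_level": 50.0, "mut_level": 10.0,
                    "labelled": True, "delta": 40.0,
                    "is_dmt": bool(flags[g][i]),
                })
        return pd.DataFrame(rows), flags, n

    def test_counts_match_set_algebra(self):
        calls, flags, n = self._fixture_calls()
        out = overlap_analysis(calls)
        for g, f in flags.items():
            assert out["percent"].loc["CHH", g] == pytest.approx(100 * f.sum() / n)
        inter = out["intersections"]["CHH"]
        for r in (1, 2, 3):
            for combo in itertools.combinations(sorted(flags), r):
                expect = np.ones(n, dtype=bool)
                for g in combo:
                    expect &= flags[g]
                assert inter["&".join(combo)] == expect.sum()

    def test_single_genotype_dmts(self):
        calls, flags, n = self._fixture_calls()
        only = calls.copy()
        only.loc[only.genotype != "met1", "is_dmt"] = False
        only.loc[only.genotype == "met1", "is_dmt"] = True
        out = overlap_analysis(only)
        assert out["percent"].loc["CHH", "met1"] == 100.0
        assert out["percent"].loc["CHH", "drm2"] == 0.0
        assert out["intersections"]["CHH"]["drm2&met1"] == 0

    def test_percentages_bounded_and_intersection_smallest(self):
        calls, _, _ = self._fixture_calls(seed=5)
        out = overlap_analysis(calls)
        pct = out["percent"].loc["CHH"]
        assert (pct <= 100).all() and (pct >= 0).all()
        inter = out["intersections"]["CHH"]
        all_three = inter["cmt2&drm2&met1"]
        for g in ("met1", "drm2", "cmt2"):
            assert all_three <= inter[g]


class TestDensityBias:
    def _calls_and_tiles(self, rng, n, shift):
        dens = rng.normal(50, 5, n)
        is_dmt = np.zeros(n, dtype=bool)
        is_dmt[: n // 2] = True
        dens[is_dmt] += shift
        tiles = _tiles({"CHGm": [50.0] * n}, CGd=dens)
        rows = [{
            "end_id": "1L", "start": 71 + 40 * i, "end": 110 + 40 * i,
            "context": "CHG", "genotype": "met1",
            "wt_level": 50.0, "mut_level": 10.0,
            "labelled": True, "delta": 40.0, "is_dmt": bool(is_dmt[i]),
        } for i in range(n)]
        return pd.DataFrame(rows), tiles

    def test_null_calibration(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            calls, tiles = self._calls_and_tiles(rng, 40, shift=0.0)
            res = density_bias_test(calls, tiles, "CGd", "CHG", "met1")
            if res.test.p_two_sided < 0.05:
                hits += 1
        assert hits <= 10

    def test_planted_bias_detected(self):
        rng = np.random.default_rng(1)
        calls, tiles = self._calls_and_tiles(rng, 40, shift=15.0)  # 3 SD
        res = density_bias_test(calls, tiles, "CGd", "CHG", "met1")
        assert res.test.p_two_sided < 0.01
        assert res.mean_dmt > res.mean_non_dmt

    def test_small_groups_flagged(self):
        rng = np.random.default_rng(2)
        calls, tiles = self._calls_and_tiles(rng, 6, shift=0.0)
        res = density_bias_test(calls, tiles, "CGd", "CHG", "met1")
        assert res is not None
        assert res.small_n
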