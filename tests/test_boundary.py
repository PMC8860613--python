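"""Boundary tiling, repeat-position methylation and telomeric-read calls."""

import numpy as np
import pytest
from scipy import stats as sps

from telosubmeth import (
    SyntheticTruth,
    boundary_tiles,
    classify_telomeric_reads,
    generate_end,
    repeat_position_methylation,
    scan_repeats,
    simulate_methylome,
    simulate_reads,
)


class TestBoundaryTiles:
    def test_two_tel_and_eighteen_subtel_tiles(self, cohort):
        syn, profiles, _ = cohort
        tiles = boundary_tiles(profiles["WT"], syn.end)
        assert len(tiles) == 20
        assert (tiles.zone == "Tel").sum() == 2
        assert (tiles.zone == "Subtel").sum() == 18
        assert list(tiles.loc[tiles.zone == "Tel", "end"]) == [35, 70]

    def test_planted_drop_is_detected(self):
        """Telomeric CHH decays toward the terminus; pooling the boundary
        tiles of six simulated ends (as for a six-ended genome), the Tel
        tiles sit significantly below the Subtel tiles at 20x coverage."""
        tel, sub = [], []
        for seed in range(6):
            truth = SyntheticTruth(seed=100 + seed)
            syn = generate_end(truth)
            profile, _ = simulate_methylome(syn, "WT")
            tiles = boundary_tiles(profile, syn.end)
            tel.extend(tiles.loc[tiles.zone == "Tel", "CHHm"].dropna())
            sub.extend(tiles.loc[tiles.zone == "Subtel", "CHHm"].dropna())
        assert np.mean(tel) < np.mean(sub)
        p = sps.mannwhitneyu(tel, sub, alternative="two-sided").pvalue
        assert p < 0.01

    def test_flat_methylation_gives_no_significant_difference(self):
        """With the boundary decay switched off (flat surface into the
        telomere block) the Tel/Subtel comparison is null."""
        flat_plateau = {"CG": 85.0, "CAG": 50.0, "CTG": 50.0, "CCG": 25.0,
                        "CAH": 15.0, "CTH": 15.0, "CCH": 15.0}
        false_hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            truth = SyntheticTruth(seed=seed, boundary_decay=1e9,
                                   its_chh_boost=1.0, plateau=flat_plateau)
            syn = generate_end(truth)
            profile, _ = simulate_methylome(syn, "WT")
            tiles = boundary_tiles(profile, syn.end)
            tel = tiles.loc[tiles.zone == "Tel", "CHHm"].dropna()
            sub = tiles.loc[tiles.zone == "Subtel", "CHHm"].dropna()
            p = sps.mannwhitneyu(tel, sub, alternative="two-sided").pvalue
            if p < 0.05:
                false_hits += 1
        assert false_hits <= 10  # alpha=0.05, >=90% of seeds null


class TestRepeatPositionMethylation:
    def test_recovers_planted_per_position_probabilities(self):
        """Units methylated at (5%, 10%, 40%) per cytosine position are
        recovered within 3 points at 30x over >= 50 units."""
        rng = np.random.default_rng(21)
        n_units, cov, probs = 60, 30, (0.05, 0.10, 0.40)
        seq = "CCCTAAA" * n_units
        import pandas as pd

        from telosubmeth import SampleProfile
        from telosubmeth.reference import ChromosomeEnd

        end = ChromosomeEnd(id="z", side="left", residues=seq + "GATTACA")
        rows = []
        for u in range(n_units):
            for k in range(3):
                pos = 7 * u + k + 1
                meth = rng.binomial(cov, probs[k])
                rows.append(("z", pos, "+", "CHH", "CCH" if k < 2 else "CTH",
                             meth, cov, 100.0 * meth / cov))
        profile = SampleProfile("WT", pd.DataFrame(
            rows, columns=["end_id", "pos", "strand", "context", "subcontext",
                           "meth", "total", "level"]))
        hits = scan_repeats(end)
        prof = repeat_position_methylation(profile, hits, zone="Subtel")
        assert prof.n_units >= 50
        for est, true in zip(prof.levels, probs):
            assert est == pytest.approx(100 * true, abs=3.0)

    def test_single_unit_profile(self):
        import pandas as pd

        from telosubmeth import SampleProfile
        from telosubmeth.reference import ChromosomeEnd

        end = ChromosomeEnd(id="z", side="left", residues="CCCTAAA" + "GATTACA")
        rows = [("z", p, "+", "CHH", "CCH", m, 10, 10.0 * m)
                for p, m in [(1, 0), (2, 0), (3, 10)]]
        profile = SampleProfile("WT", pd.DataFrame(
            rows, columns=["end_id", "pos", "strand", "context", "subcontext",
                           "meth", "total", "level"]))
        prof = repeat_position_methylation(profile, scan_repeats(end))
        assert prof.levels == (0.0, 0.0, 100.0)

    def test_no_qualifying_units_gives_nan(self):
        import pandas as pd

        from telosubmeth import SampleProfile
        from telosubmeth.reference import ChromosomeEnd

        end = ChromosomeEnd(id="z", side="left", residues="CCCTAAAGATTACA")
        profile = SampleProfile("WT", pd.DataFrame(
            columns=["end_id", "pos", "strand", "context", "subcontext",
                     "meth", "total", "level"]))
        prof = repeat_position_methylation(profile, scan_repeats(end))
        assert prof.n_units == 0
        assert all(np.isnan(v) for v in prof.levels)

    def test_third_cytosine_most_methylated_in_its(self, cohort):
        """The generator's subcontext plateaus make the third unit cytosine
        (a CTH site) more methylated than the first two (CCH sites)."""
        syn, profiles, _ = cohort
        hits = [h for h in scan_repeats(syn.end)
                if syn.its_interval[0] <= h.position <= syn.its_interval[1]]
        prof = repeat_position_methylation(profiles["WT"], hits, zone="ITS")
        assert prof.n_units >= 5
        assert prof.levels[2] > prof.levels[0]
        assert prof.levels[2] > prof.levels[1]


class TestClassifyTelomericReads:
    def test_constructed_example(self):
        rs = classify_telomeric_reads(["TTTTAAATTTTAAACTTTAAA"], min_units=3)
        assert rs.n_reads == 1
        assert rs.n_Y_positions == 9
        assert rs.n_methylated == 1
        assert rs.fraction_methylated == pytest.approx(100 / 9)

    def test_pattern_break_rejected(self):
        rs = classify_telomeric_reads(["TTTTAAAGGTTAAA"], min_units=1)
        assert rs.n_reads == 0

    def test_g_rich_counted_separately(self):
        rs = classify_telomeric_reads(["TTTAGGG" * 5], min_units=3)
        assert rs.n_reads == 0
        assert rs.n_g_rich == 1
        assert rs.n_Y_positions == 0

    def test_min_units_gate(self):
        read = "TTTTAAA" * 3  # 3 complete units
        assert classify_telomeric_reads([read], min_units=3).n_reads == 1
        assert classify_telomeric_reads([read], min_units=4).n_reads == 0

    def test_non_acgt_read_skipped(self):
        rs = classify_telomeric_reads(["TTTTAAAXTTTAAA"], min_units=1)
        assert rs.n_reads == 0
        assert rs.n_skipped == 1

    def test_phase_invariance(self):
        """Rotating a telomeric read by whole units preserves the call and
        the methylation count."""
        base = "CTTTAAA" * 6
        r0 = classify_telomeric_reads([base], min_units=4)
        r7 = classify_telomeric_reads([base[7:] + base[:7]], min_units=4)
        assert r0.n_reads == r7.n_reads == 1
        assert r0.n_methylated == r7.n_methylated

    def test_partial_edge_units_count_y_positions(self):
        # 2 trailing Y bases of a fourth, incomplete unit
        read = "TTTTAAA" * 4 + "TT"
        rs = classify_telomeric_reads([read], min_units=4)
        assert rs.n_reads == 1
        assert rs.n_Y_positions == 14

    def test_simulated_unmethylated_reads_recover_nonconversion(self):
        """Inner-telomere reads from an unmethylated surface read back the
        injected non-conversion rate."""
        truth = SyntheticTruth(
            seed=17, plateau={s: 0.0 for s in
                              ("CG", "CAG", "CTG", "CCG", "CAH", "CTH", "CCH")}
        )
        syn = generate_end(truth)
        reads, _ = simulate_reads(syn, n_reads=10_000, read_len=100)
        rs = classify_telomeric_reads(reads, min_units=4)
        assert rs.n_reads > 2000
        assert rs.fraction_methylated == pytest.approx(0.8, abs=0.2)
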