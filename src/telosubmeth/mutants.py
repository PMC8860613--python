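"""Differential methylation between wild type and methyltransferase mutants.

Tiles carrying at least 20% wild-type methylation in a context are
*labelled* for that context; only labelled tiles enter the differential
analysis.  A labelled tile is a differentially methylated tile (DMT) for a
mutant when the mutant's level is lower than the wild type's by at least 20
percentage points for CG, 15 for CHG, or 10 for CHH.  The *contribution*
of a methyltransferase to a methylation type is the percentage of wild-type
methylation that disappears in the corresponding mutant,
100 x (m_WT - m_mut) / m_WT.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome import SampleProfile
from .stats import GatedTestResult, gated_two_sample_test

LABEL_MIN = 20.0
DMT_THRESHOLDS = {"CG": 20.0, "CHG": 15.0, "CHH": 10.0}
CONTEXTS = ("CG", "CHG", "CHH")


def call_dmts(
    wt_tiles: pd.DataFrame,
    mutant_tiles: Mapping[str, pd.DataFrame],
    *,
    label_min: float = LABEL_MIN,
    thresholds: Mapping[str, float] = DMT_THRESHOLDS,
    relative: bool = False,
) -> pd.DataFrame:
    """Call differentially methylated tiles per context and genotype.

    All tile tables must share identical (end_id, start, end) intervals.
    Returns a long DataFrame with one row per tile x context x genotype:
    wt_level, mut_level, labelled, delta and is_dmt.  With ``relative``
    the thresholds are read as percent of the wild-type level instead of
    absolute percentage points.
    """
    key = ["end_id", "start", "end"]
    wt = wt_tiles.sort_values(key).reset_index(drop=True)
    rows = []
    for genotype, mt in mutant_tiles.items():
        mt = mt.sort_values(key).reset_index(drop=True)
        if not wt[key].equals(mt[key]):
            raise ValueError(f"{genotype}: tile intervals do not match the WT tiling")
        for ctx in CONTEXTS:
            col = ctx + "m"
            wl = wt[col].to_numpy(dtype=float)
            ml = mt[col].to_numpy(dtype=float)
            labelled = ~np.isnan(wl) & (wl >= label_min)
            delta = wl - ml
            if relative:
                with np.errstate(divide="ignore", invalid="ignore"):
                    effective = 100.0 * delta / wl
            else:
                effective = delta
            is_dmt = labelled & ~np.isnan(ml) & (effective >= thresholds[ctx])
            for i in range(len(wt)):
                rows.append(
                    {
                        "end_id": wt.end_id.iloc[i],
                        "start": int(wt.start.iloc[i]),
                        "end": int(wt.end.iloc[i]),
                        "context": ctx,
                        "genotype": genotype,
                        "wt_level": wl[i],
                        "mut_level": ml[i],
                        "labelled": bool(labelled[i]),
                        "delta": delta[i],
                        "is_dmt": bool(is_dmt[i]),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class ContributionEstimate:
    """Percent of wild-type methylation lost in a mutant."""

    genotype: str
    context: str
    scope: str
    value: float  # clipped to [-100, 100] for reporting
    raw_value: float
    m_wt: float
    m_mut: float
    n_sites: int
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def contribution(
    wt: SampleProfile,
    mut: SampleProfile,
    context: str,
    *,
    scope: str = "all",
    end_id: str | None = None,
    interval: tuple[int, int] | None = None,
) -> ContributionEstimate:
    """Contribution of a methyltransferase to one methylation type.

    ``context`` may be a context (CG/CHG/CHH) or a subcontext (e.g. CCH).
    ``scope`` is a free label: one end (pass ``end_id``), all ends, or a
    reference locus (pass ``end_id`` + ``interval`` delimiting the locus).
    The mean is the unweighted mean of per-cytosine level percentages.
    """
    kw = dict(end_id=end_id, interval=interval)
    if context in ("CG", "CHG", "CHH"):
        wt_levels = wt.levels(context=context, **kw)
        mut_levels = mut.levels(context=context, **kw)
    else:
        wt_levels = wt.levels(subcontext=context, **kw)
        mut_levels = mut.levels(subcontext=context, **kw)
    n = len(wt_levels)
    if n == 0:
        return ContributionEstimate(
            mut.genotype, context, scope, np.nan, np.nan, np.nan, np.nan, 0,
            undefined_reason="no covered WT sites in scope",
        )
    m_wt = float(wt_levels.mean())
    m_mut = float(mut_levels.mean()) if len(mut_levels) else np.nan
    if m_wt == 0:
        return ContributionEstimate(
            mut.genotype, context, scope, np.nan, np.nan, m_wt, m_mut, n,
            undefined_reason="WT methylation is zero in scope",
        )
    raw = 100.0 * (m_wt - m_mut) / m_wt
    return ContributionEstimate(
        genotype=mut.genotype,
        context=context,
        scope=scope,
        value=float(np.clip(raw, -100.0, 100.0)),
        raw_value=raw,
        m_wt=m_wt,
        m_mut=m_mut,
        n_sites=n,
    )


def overlap_analysis(dmt_calls: pd.DataFrame) -> dict:
    """Overlap of methyltransferase influence across labelled tiles.

    Returns a dict with:

    ``percent``
        context x genotype table: percent of that context's labelled tiles
        that are DMTs in the genotype.
    ``co_occurrence``
        per context, a genotype x genotype matrix: of the tiles DMT for
        the row genotype, the percent also DMT for the column genotype.
    ``intersections``
        per context, counts of every genotype-combination of DMT status.
    """
    key = ["end_id", "start", "end"]
    genotypes = sorted(dmt_calls.genotype.unique())
    percent = {}
    co = {}
    inter = {}
    for ctx, sub in dmt_calls.groupby("context"):
        wide = sub.pivot_table(
            index=key, columns="genotype", values="is_dmt", aggfunc="first"
        ).astype(bool)
        labelled = sub.pivot_table(
            index=key, columns="genotype", values="labelled", aggfunc="first"
        ).astype(bool)
        lab_mask = labelled.any(axis=1)
        wide = wide[lab_mask]
        n_lab = int(lab_mask.sum())
        percent[ctx] = {
            g: (100.0 * wide[g].sum() / n_lab if n_lab else np.nan) for g in genotypes
        }
        mat = pd.DataFrame(index=genotypes, columns=genotypes, dtype=float)
        for g in genotypes:
            base = wide[wide[g]]
            for h in genotypes:
                mat.loc[g, h] = 100.0 * base[h].sum() / len(base) if len(base) else np.nan
        co[ctx] = mat
        counts = {}
        for r in range(1, len(genotypes) + 1):
            for combo in combinations(genotypes, r):
                mask = np.ones(len(wide), dtype=bool)
                for g in combo:
                    mask &= wide[g].to_numpy()
                counts["&".join(combo)] = int(mask.sum())
        inter[ctx] = counts
    return {
        "percent": pd.DataFrame(percent).T,  # context rows, genotype cols
        "co_occurrence": co,
        "intersections": inter,
    }


def expected_tile_levels(
    truth_table: pd.DataFrame,
    tiles: pd.DataFrame,
    non_conversion: float = 0.0,
) -> pd.DataFrame:
    """Noise-free per-tile context levels implied by planted probabilities.

    The expected observed level of a cytosine is
    100 x (p_true + (1 - p_true) * eps); a tile's expected context level is
    the unweighted mean over its sites, mirroring the observed estimator.
    """
    tt = truth_table.copy()
    tt["level"] = 100.0 * (tt.p_true + (1 - tt.p_true) * non_conversion)
    rows = []
    for r in tiles[["end_id", "start", "end"]].itertuples(index=False):
        sub = tt[(tt.end_id == r.end_id) & (tt.pos >= r.start) & (tt.pos <= r.end)]
        row = {"end_id": r.end_id, "start": r.start, "end": r.end}
        for ctx in CONTEXTS:
            vals = sub.loc[sub.context == ctx, "level"]
            row[ctx + "m"] = vals.mean() if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def dmt_truth_metrics(
    dmt_calls: pd.DataFrame,
    syn,
    truth_tables: Mapping[str, pd.DataFrame],
    label_min: float = LABEL_MIN,
    thresholds: Mapping[str, float] = DMT_THRESHOLDS,
) -> dict:
    """Precision/recall of observed DMT calls against generator truth.

    Truth DMT status is computed by applying the same labelling and
    threshold rules to the noise-free expected tile levels.
    """
    key = ["end_id", "start", "end"]
    tiles = dmt_calls[key].drop_duplicates().reset_index(drop=True)
    eps = syn.truth.non_conversion
    wt_true = expected_tile_levels(truth_tables["WT"], tiles, eps)
    true_calls = call_dmts(
        wt_true,
        {
            g: expected_tile_levels(tt, tiles, eps)
            for g, tt in truth_tables.items()
            if g != "WT"
        },
        label_min=label_min,
        thresholds=thresholds,
    )
    merged = dmt_calls.merge(
        true_calls[key + ["context", "genotype", "is_dmt", "labelled"]],
        on=key + ["context", "genotype"],
        suffixes=("", "_true"),
    )
    # judge only tiles labelled under truth AND observation: the labelling
    # gate itself is part of the procedure, not of the planted signal
    m = merged[merged.labelled & merged.labelled_true]
    tp = int((m.is_dmt & m.is_dmt_true).sum())
    fp = int((m.is_dmt & ~m.is_dmt_true).sum())
    fn = int((~m.is_dmt & m.is_dmt_true).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision, "recall": recall, "n_judged": len(m),
    }


@dataclass
class DensityBiasResult:
    genotype: str
    context: str
    density_key: str
    test: GatedTestResult
    mean_dmt: float
    mean_non_dmt: float
    n_dmt: int
    n_non_dmt: int
    small_n: bool


def density_bias_test(
    dmt_calls: pd.DataFrame,
    tiles: pd.DataFrame,
    density_key: str,
    context: str,
    genotype: str,
    *,
    small_n_below: int = 8,
) -> DensityBiasResult | None:
    """Does a mutant preferentially affect tiles of high/low site density?

    Compares ``density_key`` (e.g. ``CGd``) between DMT and non-DMT
    labelled tiles of one context for one genotype, using the
    normality-gated two-sample test.  Returns None when either group has
    fewer than 3 tiles (degenerate); sets ``small_n`` when either group is
    smaller than ``small_n_below``.
    """
    key = ["end_id", "start", "end"]
    sub = dmt_calls[
        (dmt_calls.context == context)
        & (dmt_calls.genotype == genotype)
        & dmt_calls.labelled
    ]
    merged = sub.merge(tiles[key + [density_key]], on=key, how="left")
    a = merged.loc[merged.is_dmt, density_key].dropna()
    b = merged.loc[~merged.is_dmt, density_key].dropna()
    if len(a) < 3 or len(b) < 3:
        return None
    test = gated_two_sample_test(a, b)
    return DensityBiasResult(
        genotype=genotype,
        context=context,
        density_key=density_key,
        test=test,
        mean_dmt=float(a.mean()),
        mean_non_dmt=float(b.mean()),
        n_dmt=len(a),
        n_non_dmt=len(b),
        small_n=min(len(a), len(b)) < small_n_below,
    )
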