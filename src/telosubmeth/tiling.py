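"""Fixed-width tiling of methylation profiles.

Subtelomeric sequences are windowed into consecutive tiles (40 bp for the
main analysis, 35 bp at the boundary).  A tile's level in a context is the
unweighted mean of the per-cytosine level percentages of the covered
cytosines of that context on both strands; site counts come from the
reference and do not depend on coverage.  Densities are sites per kbp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import SampleProfile, iter_cytosines
from .reference import ChromosomeEnd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
SUBCONTEXTS = ("CG", "CAG", "CTG", "CCG", "CAH", "CTH", "CCH")

#: tile-table level columns, e.g. CGm = percent CG methylation in the tile
LEVEL_COLUMNS = [c + "m" for c in CONTEXTS] + [s + "m" for s in SUBCONTEXTS[1:]]
#: site-count columns (CAG_CTG pools the two symmetric CHG subcontexts)
SITE_COLUMNS = ["CG_sites", "CHG_sites", "CHH_sites", "CAG_CTG_sites", "CCG_sites"]
DENSITY_COLUMNS = ["CGd", "CHGd", "CHHd", "CAG_CTGd", "CCGd"]


@dataclass
class MethylationExtent:
    """Inward border of subtelomeric methylation for one end."""

    end_id: str
    border_position: int  # region coordinate of the last retained CG site
    overridden: bool = False


def reference_sites(end: ChromosomeEnd) -> pd.DataFrame:
    """All classifiable cytosines of an end (both strands) with contexts."""
    rows = list(iter_cytosines(end))
    df = pd.DataFrame(rows, columns=["pos", "strand", "context", "subcontext"])
    df.insert(0, "end_id", end.id)
    return df


def make_tiles(
    profile: SampleProfile | None,
    end: ChromosomeEnd,
    start: int = 71,
    stop: int | None = None,
    width: int = 40,
    *,
    its_intervals: Sequence[tuple[int, int]] = (),
) -> pd.DataFrame:
    """Window an end into consecutive fixed-width tiles.

    Tiles are ``[start, start+width-1], [start+width, ...]``; a trailing
    partial tile is dropped so the tiled span is an exact multiple of
    ``width``.  Returns one row per tile with level, site-count and density
    columns; levels are NaN where no covered site of the context exists.
    ``profile`` may be None to tile the reference alone (sites/densities).
    """
    if width < 7:
        raise ValueError("width must be >= 7")
    if stop is None:
        stop = len(end.residues)
    if start > stop:
        raise ValueError("start must be <= stop")
    n_tiles = (stop - start + 1) // width
    sites = reference_sites(end)
    records = None
    if profile is not None:
        records = profile.records[profile.records.end_id == end.id]
    rows = []
    for k in range(n_tiles):
        lo = start + k * width
        hi = lo + width - 1
        row: dict = {"end_id": end.id, "start": lo, "end": hi}
        tile_sites = sites[(sites.pos >= lo) & (sites.pos <= hi)]
        ctx_counts = tile_sites.context.value_counts()
        sub_counts = tile_sites.subcontext.value_counts()
        row["CG_sites"] = int(ctx_counts.get("CG", 0))
        row["CHG_sites"] = int(ctx_counts.get("CHG", 0))
        row["CHH_sites"] = int(ctx_counts.get("CHH", 0))
        row["CAG_CTG_sites"] = int(sub_counts.get("CAG", 0) + sub_counts.get("CTG", 0))
        row["CCG_sites"] = int(sub_counts.get("CCG", 0))
        for name, n in zip(DENSITY_COLUMNS, SITE_COLUMNS):
            row[name] = row[n] * 1000.0 / width
        if records is not None:
            tr = records[(records.pos >= lo) & (records.pos <= hi)]
            for ctx in CONTEXTS:
                vals = tr.loc[tr.context == ctx, "level"]
                row[ctx + "m"] = vals.mean() if len(vals) else np.nan
                row["n_" + ctx] = len(vals)
            for sub in SUBCONTEXTS[1:]:
                vals = tr.loc[tr.subcontext == sub, "level"]
                row[sub + "m"] = vals.mean() if len(vals) else np.nan
        row["in_its"] = any(lo <= b and a <= hi for a, b in its_intervals)
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_extent(
    tiles: pd.DataFrame,
    end: ChromosomeEnd,
    min_level: float = 20.0,
    window: int = 5,
    *,
    override: int | None = None,
) -> MethylationExtent:
    """Delimit the inward extent of subtelomeric methylation.

    Heuristic: walk the ordered tiles for the first run of ``window``
    consecutive tiles that are below ``min_level`` in *every* context; the
    border tile is the last tile before that run with CG methylation of at
    least ``min_level``, and the border position is the last CG site inside
    it.  Without such a dead run the last qualifying tile overall is used.
    An explicit per-end ``override`` wins and is logged.
    """
    if override is not None:
        logger.info("%s: methylation border overridden to %d", end.id, override)
        return MethylationExtent(end.id, border_position=int(override), overridden=True)
    tiles = tiles.sort_values("start").reset_index(drop=True)
    level_cols = [c for c in ("CGm", "CHGm", "CHHm") if c in tiles.columns]
    below = (tiles[level_cols].fillna(0.0) < min_level).all(axis=1).to_numpy()
    qual = (tiles["CGm"].fillna(0.0) >= min_level).to_numpy()
    dead_start = None
    for i in range(len(tiles) - window + 1):
        if below[i : i + window].all():
            dead_start = i
            break
    idx = np.nonzero(qual[:dead_start] if dead_start is not None else qual)[0]
    if len(idx) == 0:
        warnings.warn(f"{end.id}: no tile reaches CGm >= {min_level}; extent set to 71")
        return MethylationExtent(end.id, border_position=71)
    border_tile = tiles.iloc[idx[-1]]
    sites = reference_sites(end)
    cg = sites[
        (sites.context == "CG")
        & (sites.pos >= border_tile.start)
        & (sites.pos <= border_tile.end)
    ]
    border = int(cg.pos.max()) if len(cg) else int(border_tile.end)
    return MethylationExtent(end.id, border_position=border)


DEFAULT_CORRELATION_PAIRS = [
    ("CGm", "CHGm"),
    ("CGm", "CHHm"),
    ("CHGm", "CHHm"),
    ("CGm", "CGd"),
    ("CHGm", "CHGd"),
    ("CHGm", "CAG_CTGd"),
    ("CHGm", "CCGd"),
]


def profile_correlations(
    tiles: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
) -> pd.DataFrame:
    """Pearson correlations between tile-level columns.

    Returns one row per pair with r, the two-sided p-value and n (complete
    cases); pairs with fewer than 3 complete cases yield NaN, not an error.
    """
    rows = []
    for x, y in pairs:
        if x in tiles.columns and y in tiles.columns:
            sub = tiles[[x, y]].dropna()
        else:
            sub = pd.DataFrame(columns=[x, y])
        if len(sub) >= 3:
            r, p = stats.pearsonr(sub[x], sub[y])
        else:
            r, p = np.nan, np.nan
        rows.append({"x": x, "y": y, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def write_bedgraph(
    tiles: pd.DataFrame, column: str, path: str | Path
) -> Path:
    """One bedGraph line per tile for the named level/density column."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in tiles.itertuples(index=False):
            val = getattr(r, column)
            if pd.isna(val):
                continue
            fh.write(f"{r.end_id}\t{r.start - 1}\t{r.end}\t{val:.6g}\n")
    return path
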