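"""Per-cytosine bisulfite methylation calls: parsing, context assignment,
coordinate mapping and replicate merging.

Methylation context is defined by the two bases 3' of the cytosine *on its
own strand*: CG, CHG or CHH with H in {A, C, T}.  Subcontexts split the H
base (CAG/CTG/CCG for CHG; CAH/CTH/CCH for CHH).  Contexts stated in call
files are never trusted — they are re-derived from the reference, because
callers disagree near edges and on the strand convention.

A sample's calls live in a :class:`SampleProfile`, a genotype label plus a
pandas DataFrame with one row per (end_id, position, strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference import ChromosomeEnd

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "met1", "cmt3", "suvh456", "drm2", "cmt2")

#: columns of the per-cytosine record table
RECORD_COLUMNS = [
    "end_id",
    "pos",
    "strand",
    "context",
    "subcontext",
    "meth",
    "total",
    "level",
]

_H = set("ACT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class EdgeUndefinedContext(ValueError):
    """Fewer than two bases exist 3' of the cytosine; context is undefined."""


def classify_context(
    residues: str, position: int, strand: str
) -> tuple[str, str]:
    """Classify the methylation context of a cytosine.

    Parameters
    ----------
    residues
        Forward (C-rich) region strand of the end.
    position
        1-based region coordinate of the cytosine.
    strand
        ``"+"`` for a C on the forward strand, ``"-"`` for a C on the
        reverse strand (a G in ``residues``).

    Returns
    -------
    (context, subcontext)
        e.g. ``("CHG", "CAG")`` or ``("CHH", "CTH")``.
    """
    i = position - 1
    if strand == "+":
        if residues[i] != "C":
            raise ValueError(f"base at {position}+ is {residues[i]}, not C")
        if i + 2 >= len(residues):
            raise EdgeUndefinedContext(f"position {position}+: <2 downstream bases")
        b1, b2 = residues[i + 1], residues[i + 2]
    elif strand == "-":
        if residues[i] != "G":
            raise ValueError(f"base at {position}- is {residues[i]}, not C (G on forward)")
        if i - 2 < 0:
            raise EdgeUndefinedContext(f"position {position}-: <2 downstream bases")
        b1, b2 = _COMP[residues[i - 1]], _COMP[residues[i - 2]]
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if b1 == "G":
        return "CG", "CG"
    if b1 in _H and b2 == "G":
        return "CHG", f"C{b1}G"
    if b1 in _H and b2 in _H:
        return "CHH", f"C{b1}H"
    raise EdgeUndefinedContext(f"position {position}{strand}: ambiguous base (N) downstream")


def iter_cytosines(end: ChromosomeEnd):
    """Yield (pos, strand, context, subcontext) for every classifiable
    cytosine of an end, both strands."""
    res = end.residues
    for i, base in enumerate(res):
        pos = i + 1
        if base == "C":
            strand = "+"
        elif base == "G":
            strand = "-"
        else:
            continue
        try:
            context, sub = classify_context(res, pos, strand)
        except EdgeUndefinedContext:
            continue
        yield pos, strand, context, sub


@dataclass
class SampleProfile:
    """A genotype-labelled methylome over one or more chromosome ends."""

    genotype: str
    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")

    def levels(
        self,
        context: str | None = None,
        subcontext: str | None = None,
        end_id: str | None = None,
        interval: tuple[int, int] | None = None,
    ) -> pd.Series:
        """Per-cytosine level percentages after optional filtering."""
        df = self.records
        if end_id is not None:
            df = df[df.end_id == end_id]
        if context is not None:
            df = df[df.context == context]
        if subcontext is not None:
            df = df[df.subcontext == subcontext]
        if interval is not None:
            df = df[(df.pos >= interval[0]) & (df.pos <= interval[1])]
        return df.level


def _records_frame(rows: list) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["meth"] = df["meth"].astype(np.int64)
    df["total"] = df["total"].astype(np.int64)
    df["level"] = df["level"].astype(float)
    return df


def read_calls(
    path: str | Path,
    dialect: str,
    ref: Mapping[str, ChromosomeEnd],
    *,
    genotype: str = "WT",
    coords: str = "region",
    min_cov: int = 1,
) -> SampleProfile:
    """Parse a per-cytosine call file into a :class:`SampleProfile`.

    Dialects
    --------
    ``CGmap``
        7 tab-separated columns: contig, nucleotide (C/G), position,
        context, subcontext, methylated count, total count.
    ``bismark_cov``
        6 columns: contig, start, end, methylation percent, count
        methylated, count unmethylated.  Strand is inferred from the
        reference base.

    ``coords="region"`` means positions refer to the written (oriented,
    truncated) reference; ``coords="input"`` means they refer to the
    original input FASTA and are mapped through each end's source_offset —
    for right arms the coordinate is flipped and the strand swapped.

    Contexts are re-derived from the reference; file-stated contexts that
    disagree are counted and logged, never propagated.
    """
    if dialect not in ("CGmap", "bismark_cov"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows = []
    n_mismatch = 0
    n_edge = 0
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if dialect == "CGmap":
                    contig, nuc, pos_s, file_ctx, _sub, meth_s, total_s = f[:7]
                    pos = int(pos_s)
                    strand = "+" if nuc == "C" else "-"
                    meth, total = int(meth_s), int(total_s)
                else:
                    contig, pos_s, _end_s, _pct, meth_s, unmeth_s = f[:6]
                    pos = int(pos_s)
                    meth, unmeth = int(meth_s), int(unmeth_s)
                    total = meth + unmeth
                    file_ctx = None
                    strand = None
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {dialect} line") from exc
            if contig not in ref:
                unknown.add(contig)
                continue
            end = ref[contig]
            if coords == "input":
                pos = end.input_to_region(pos)
                if end.source_offset.get("strand_flipped", False) and strand is not None:
                    strand = "-" if strand == "+" else "+"
            if pos < 1 or pos > len(end.residues):
                continue  # trimmed-away telomeric repeats
            base = end.residues[pos - 1]
            if strand is None:
                strand = "+" if base == "C" else "-"
            if (strand == "+" and base != "C") or (strand == "-" and base != "G"):
                raise ValueError(
                    f"{path}:{lineno}: position {pos}{strand} on {contig} is not a "
                    f"cytosine in the reference (base {base})"
                )
            try:
                context, sub = classify_context(end.residues, pos, strand)
            except EdgeUndefinedContext:
                n_edge += 1
                continue
            if file_ctx not in (None, "", context):
                n_mismatch += 1
            if total < min_cov or total < 1:
                continue
            rows.append(
                (contig, pos, strand, context, sub, meth, total, 100.0 * meth / total)
            )
    if unknown:
        raise ValueError(f"{path}: unknown contigs not in reference: {sorted(unknown)}")
    if n_mismatch:
        logger.warning("%s: %d file-stated contexts overridden by reference", path, n_mismatch)
    if n_edge:
        logger.info("%s: %d edge-undefined cytosines skipped", path, n_edge)
    return SampleProfile(genotype=genotype, records=_records_frame(rows), provenance=[str(path)])


def write_calls(profile: SampleProfile, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a profile's records as the internal TSV, CGmap, or bismark-cov."""
    path = Path(path)
    df = profile.records.sort_values(["end_id", "pos", "strand"])
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            if dialect == "tsv":
                fh.write(
                    f"{r.end_id}\t{r.pos}\t{r.strand}\t{r.context}\t{r.subcontext}"
                    f"\t{r.meth}\t{r.total}\n"
                )
            elif dialect == "CGmap":
                nuc = "C" if r.strand == "+" else "G"
                fh.write(
                    f"{r.end_id}\t{nuc}\t{r.pos}\t{r.context}\t{r.subcontext}"
                    f"\t{r.meth}\t{r.total}\n"
                )
            elif dialect == "bismark_cov":
                unmeth = r.total - r.meth
                pct = 100.0 * r.meth / r.total
                fh.write(
                    f"{r.end_id}\t{r.pos}\t{r.pos}\t{pct:.6g}\t{r.meth}\t{unmeth}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    return path


def merge_profiles(
    profiles: list[SampleProfile], mode: str = "pool_counts"
) -> SampleProfile:
    """Combine replicate profiles of one genotype.

    ``pool_counts`` sums methylated/total read counts per cytosine and
    re-derives the level; ``mean_levels`` averages the per-cytosine level
    percentages, unweighted, over the profiles covering that cytosine.
    """
    if not profiles:
        raise ValueError("no profiles to merge")
    genotypes = {p.genotype for p in profiles}
    if len(genotypes) != 1:
        raise ValueError(f"cannot merge profiles of different genotypes: {sorted(genotypes)}")
    if mode not in ("pool_counts", "mean_levels"):
        raise ValueError(f"unknown merge mode {mode!r}")
    cat = pd.concat([p.records for p in profiles], ignore_index=True)
    keys = ["end_id", "pos", "strand", "context", "subcontext"]
    grouped = cat.groupby(keys, as_index=False, sort=True).agg(
        meth=("meth", "sum"), total=("total", "sum"), level_mean=("level", "mean")
    )
    if mode == "pool_counts":
        grouped["level"] = 100.0 * grouped["meth"] / grouped["total"]
    else:
        grouped["level"] = grouped["level_mean"]
    grouped = grouped.drop(columns="level_mean")[RECORD_COLUMNS]
    prov = [x for p in profiles for x in p.provenance]
    return SampleProfile(genotype=profiles[0].genotype, records=grouped, provenance=prov)
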