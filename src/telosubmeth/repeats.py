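"""Degenerate telomeric-repeat variants, repeat scanning and ITS annotation.

An interstitial telomeric sequence (ITS) is an internal array of perfect
telomeric repeats interspersed with *degenerate* repeats — 7-mers one
mismatch away from the canonical unit — all sharing one head-to-tail
orientation.  The two canonical units (CCCTAAA and its reverse complement
TTTAGGG) differ at every position, so each yields 21 single-mismatch
variants and the two variant sets are disjoint: 42 variants in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .reference import C_RICH_UNIT, G_RICH_UNIT, ChromosomeEnd, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class RepeatVariant:
    """A 7-mer at Hamming distance exactly 1 from a canonical unit."""

    sequence: str
    orientation: str  # "C-rich" | "G-rich"
    mismatch_position: int  # 1-7
    substituted_base: str


@dataclass
class RepeatHit:
    """One non-overlapping 7-mer match in a scanned sequence."""

    position: int  # 1-based region coordinate of the first base
    kind: str  # "perfect" | "degenerate"
    orientation: str
    variant: RepeatVariant | None = None  # None for perfect hits
    chain_id: int = 0

    @property
    def sequence(self) -> str:
        if self.variant is not None:
            return self.variant.sequence
        return C_RICH_UNIT if self.orientation == "C-rich" else G_RICH_UNIT


@dataclass
class ITSAnnotation:
    """A chained run of same-orientation repeat hits forming one ITS."""

    interval: tuple[int, int]  # closed, 1-based
    hits: list[RepeatHit] = field(default_factory=list)

    @property
    def n_perfect(self) -> int:
        return sum(h.kind == "perfect" for h in self.hits)

    @property
    def n_degenerate(self) -> int:
        return sum(h.kind == "degenerate" for h in self.hits)

    @property
    def variant_types(self) -> set[str]:
        return {h.variant.sequence for h in self.hits if h.variant is not None}

    @property
    def orientation(self) -> str:
        return self.hits[0].orientation


def enumerate_variants(
    unit: str = C_RICH_UNIT, both_orientations: bool = True
) -> set[RepeatVariant]:
    """Enumerate all single-mismatch variants of a repeat unit.

    Each of the 7 positions can be substituted by 3 other bases, giving 21
    variants per orientation; with ``both_orientations`` the reverse
    complement contributes another 21 (disjoint when the unit and its
    reverse complement differ at every position, as CCCTAAA/TTTAGGG do).
    """
    unit = unit.upper()
    if len(unit) != 7 or any(b not in _BASES for b in unit):
        raise ValueError(f"unit must be a 7-mer over ACGT, got {unit!r}")
    variants: set[RepeatVariant] = set()
    units = [(unit, "C-rich")]
    if both_orientations:
        units.append((reverse_complement(unit), "G-rich"))
    for u, orientation in units:
        for pos in range(7):
            for base in _BASES:
                if base == u[pos]:
                    continue
                var = u[:pos] + base + u[pos + 1 :]
                variants.add(
                    RepeatVariant(
                        sequence=var,
                        orientation=orientation,
                        mismatch_position=pos + 1,
                        substituted_base=base,
                    )
                )
    return variants


def _index_variants(variants: Iterable[RepeatVariant]) -> dict[str, RepeatVariant]:
    # at equal sequence prefer the lowest mismatch_position (deterministic)
    index: dict[str, RepeatVariant] = {}
    for v in sorted(variants, key=lambda v: (v.sequence, v.mismatch_position)):
        index.setdefault(v.sequence, v)
    return index


def scan_repeats(
    end: ChromosomeEnd | str,
    variants: Iterable[RepeatVariant] | None = None,
    max_gap: int = 21,
) -> list[RepeatHit]:
    """Greedy left-to-right tiling of non-overlapping repeat hits.

    At each offset a perfect canonical match is preferred over a degenerate
    one; a hit consumes 7 bases.  Hits separated by more than ``max_gap``
    intervening bases, or differing in orientation, start a new chain
    (``chain_id``); chains are what :func:`call_its` groups into ITSs.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    seq = end.residues if isinstance(end, ChromosomeEnd) else end.upper()
    if variants is None:
        variants = enumerate_variants()
    vindex = _index_variants(variants)
    canonicals = {C_RICH_UNIT: "C-rich", G_RICH_UNIT: "G-rich"}
    hits: list[RepeatHit] = []
    chain = 0
    i = 0
    n = len(seq)
    while i <= n - 7:
        kmer = seq[i : i + 7]
        hit = None
        if kmer in canonicals:
            hit = RepeatHit(position=i + 1, kind="perfect", orientation=canonicals[kmer])
        elif kmer in vindex:
            v = vindex[kmer]
            hit = RepeatHit(
                position=i + 1, kind="degenerate", orientation=v.orientation, variant=v
            )
        if hit is None:
            i += 1
            continue
        if hits:
            prev = hits[-1]
            gap = hit.position - (prev.position + 7)
            if gap > max_gap or hit.orientation != prev.orientation:
                chain += 1
        hit.chain_id = chain
        hits.append(hit)
        i += 7
    return hits


def call_its(
    hits: Sequence[RepeatHit],
    min_hits: int = 3,
    max_gap: int = 21,
    *,
    exclude_span: tuple[int, int] | None = None,
) -> list[ITSAnnotation]:
    """Chain repeat hits into ITS annotations.

    Same-orientation hits with inter-hit gaps of at most ``max_gap`` bases
    form a chain; chains of at least ``min_hits`` hits become ITSs.  When
    ``exclude_span`` is given (the retained telomere block), hits inside it
    are dropped first so ITS intervals never overlap the telomere.
    """
    kept = [h for h in hits]
    if exclude_span is not None:
        lo, hi = exclude_span
        kept = [h for h in kept if not (h.position >= lo and h.position + 6 <= hi)]
    kept.sort(key=lambda h: h.position)
    chains: list[list[RepeatHit]] = []
    for h in kept:
        if (
            chains
            and h.orientation == chains[-1][-1].orientation
            and h.position - (chains[-1][-1].position + 7) <= max_gap
        ):
            chains[-1].append(h)
        else:
            chains.append([h])
    return [
        ITSAnnotation(interval=(c[0].position, c[-1].position + 6), hits=c)
        for c in chains
        if len(c) >= min_hits
    ]


def write_bed(
    items: Sequence[RepeatHit] | Sequence[ITSAnnotation],
    path: str | Path,
    end_id: str,
) -> Path:
    """Write hits or ITS intervals as BED (0-based half-open on conversion)."""
    path = Path(path)
    with open(path, "w") as fh:
        for it in items:
            if isinstance(it, RepeatHit):
                name = f"{it.kind}:{it.sequence}"
                fh.write(f"{end_id}\t{it.position - 1}\t{it.position + 6}\t{name}\n")
            else:
                lo, hi = it.interval
                name = f"ITS:{it.n_perfect}p+{it.n_degenerate}d"
                fh.write(f"{end_id}\t{lo - 1}\t{hi}\t{name}\n")
    return path
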