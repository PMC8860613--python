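"""Telomere-truncated, orientation-normalized chromosome-end references.

Plant telomeres are long arrays of the perfect CCCTAAA repeat on the C-rich
strand.  For bisulfite mapping at the telomere-subtelomere boundary the
terminal array is trimmed so that every end retains exactly ``keep`` perfect
repeats (70 bp by default): reads arising from deep inside telomeres then
fail to align, and only boundary-spanning reads cover the retained block.

All coordinates downstream of this module are *region coordinates*: 1-based,
closed intervals, position 1 at the outermost chromosome base, increasing
inward.  Right chromosome arms are reverse-complemented on construction so
that the C-rich telomeric strand is always the forward region strand.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: canonical C-rich telomeric repeat unit (plant type)
C_RICH_UNIT = "CCCTAAA"
#: canonical G-rich unit, reverse complement of the C-rich unit
G_RICH_UNIT = "TTTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NoCanonicalTelomereError(ValueError):
    """The outermost perfect-repeat run is shorter than the required minimum."""

    def __init__(self, observed_run: int, min_run: int):
        self.observed_run = observed_run
        self.min_run = min_run
        super().__init__(
            f"no canonical telomere: outermost perfect-repeat run has "
            f"{observed_run} copies, need >= {min_run}"
        )


@dataclass
class ChromosomeEnd:
    """Oriented chromosome-end sequence in distance-from-terminus coordinates.

    Attributes
    ----------
    id
        End label, e.g. ``"1L"`` or ``"5R"``.
    side
        ``"left"`` or ``"right"`` chromosome arm.
    residues
        Bases of the C-rich forward region strand; index 0 is region
        position 1 (the chromosome terminus).
    telomere_span
        Closed 1-based interval of the retained perfect-repeat block,
        ``(1, 7 * keep)``, or ``None`` for raw ends.
    source_offset
        Mapping back to input-FASTA coordinates: number of trimmed repeats,
        input length, and whether the input strand was flipped.
    """

    id: str
    side: str
    residues: str
    telomere_span: tuple[int, int] | None = None
    source_offset: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def region_to_input(self, pos: int) -> int:
        """Map a region coordinate back to the coordinate of the input FASTA."""
        removed_bp = 7 * self.source_offset.get("repeats_removed", 0)
        input_len = self.source_offset.get("input_length", len(self.residues))
        if self.source_offset.get("strand_flipped", False):
            return input_len - (pos + removed_bp) + 1
        return pos + removed_bp

    def input_to_region(self, pos: int) -> int:
        removed_bp = 7 * self.source_offset.get("repeats_removed", 0)
        input_len = self.source_offset.get("input_length", len(self.residues))
        if self.source_offset.get("strand_flipped", False):
            return input_len - pos + 1 - removed_bp
        return pos - removed_bp


def find_perfect_repeat_runs(seq: str, unit: str = C_RICH_UNIT) -> list[tuple[int, int]]:
    """Find maximal tandem runs of a perfect repeat unit.

    Runs are maximal head-to-tail chains of exact copies, found by a single
    greedy left-to-right pass (equivalent to ``re.finditer`` of ``(unit)+``).
    Ns never match, so a run always terminates at an N.

    Parameters
    ----------
    seq
        Sequence to scan (A/C/G/T/N).
    unit
        Repeat unit, length 7.

    Returns
    -------
    list of (start, count)
        1-based start position and number of tandem copies of each run.
        Returned runs never overlap.
    """
    if not seq:
        raise ValueError("empty input sequence")
    if len(unit) != 7:
        raise ValueError(f"repeat unit must be 7 bp, got {len(unit)}")
    seq = seq.upper()
    unit = unit.upper()
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i <= n - 7:
        if seq[i : i + 7] == unit:
            count = 1
            j = i + 7
            while seq[j : j + 7] == unit:
                count += 1
                j += 7
            runs.append((i + 1, count))
            i = j
        else:
            i += 1
    return runs


def orient(seq: str, side: str) -> str:
    """Return the sequence in region orientation (C-rich strand forward).

    Left arms are already terminus-first; right arms are supplied G-rich /
    terminus-last and are reverse-complemented.  Applying the transform twice
    for a right arm returns the original input.
    """
    if side == "left":
        return seq.upper()
    if side == "right":
        return reverse_complement(seq.upper())
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def truncate_telomere(
    seq: str,
    side: str = "left",
    *,
    id: str = "end",
    min_run: int = 10,
    keep: int = 10,
    unit: str = C_RICH_UNIT,
) -> ChromosomeEnd:
    """Trim the terminal perfect-repeat array down to exactly ``keep`` units.

    The input must carry, at its outermost extent after orientation
    normalization, a perfect telomeric run of at least ``min_run`` copies
    (default 10, i.e. a run long enough that no interstitial locus mimics
    it).  The returned end starts with exactly ``keep`` C-rich repeats
    followed by the unmodified inward sequence.

    Raises
    ------
    NoCanonicalTelomereError
        If the outermost run has fewer than ``min_run`` copies.
    """
    if keep > min_run:
        raise ValueError("keep cannot exceed min_run")
    oriented = orient(seq, side)
    runs = find_perfect_repeat_runs(oriented, unit)
    outer = next((r for r in runs if r[0] == 1), None)
    observed = outer[1] if outer else 0
    if observed < min_run:
        raise NoCanonicalTelomereError(observed, min_run)
    start, count = outer
    removed = count - keep
    residues = unit * keep + oriented[7 * count :]
    return ChromosomeEnd(
        id=id,
        side=side,
        residues=residues,
        telomere_span=(1, 7 * keep),
        source_offset={
            "repeats_removed": removed,
            "input_length": len(seq),
            "strand_flipped": side == "right",
        },
    )


def write_reference(
    ends: Iterable[ChromosomeEnd], path: str | Path, *, sidecar: bool = True
) -> Path:
    """Write oriented ends as a 60-column FASTA plus a JSON sidecar.

    The sidecar records telomere_span and source_offset per record so that
    call files aligned to the written reference can be mapped back to input
    coordinates.
    """
    ends = list(ends)
    ids = [e.id for e in ends]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate end ids: {sorted(ids)}")
    if not ends:
        warnings.warn("writing an empty reference (no ends supplied)")
    path = Path(path)
    records = [
        SeqRecord(Seq(e.residues), id=e.id, description="") for e in ends
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    if sidecar:
        meta = {
            e.id: {
                "side": e.side,
                "length": len(e.residues),
                "telomere_span": list(e.telomere_span) if e.telomere_span else None,
                "source_offset": e.source_offset,
            }
            for e in ends
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
    return path


def read_reference(path: str | Path) -> dict[str, ChromosomeEnd]:
    """Read a reference written by :func:`write_reference` (sidecar required
    to restore spans/offsets; without it ends are loaded as raw left arms)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    ends = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = meta.get(rec.id, {})
        span = m.get("telomere_span")
        ends[rec.id] = ChromosomeEnd(
            id=rec.id,
            side=m.get("side", "left"),
            residues=str(rec.seq),
            telomere_span=tuple(span) if span else None,
            source_offset=m.get("source_offset", {}),
        )
    return ends


def refuse_unassembled(end_id: str) -> None:
    """The rDNA-bearing arms (2L, 4L) are not assembled through their
    telomeres and cannot be represented; refuse them explicitly."""
    if end_id.upper() in ("2L", "4L"):
        raise ValueError(
            f"{end_id}: this arm carries unassembled rDNA arrays and has no "
            "canonical telomere-subtelomere boundary; it cannot be built"
        )
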