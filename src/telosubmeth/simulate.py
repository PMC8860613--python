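"""Synthetic chromosome ends, methylomes and bisulfite reads with known truth.

The generator emulates the architecture of a plant chromosome end: a
telomere of perfect CCCTAAA repeats, an abutting interstitial telomeric
sequence (ITS) of perfect units randomly degenerated to single-mismatch
variants, and a unique subtelomere.  On top of the sequence it lays a
methylation surface per subcontext: a plateau over the methylated
subtelomeric domain, a progressive decay across the telomere block, a hard
stop at the inward extent L, and a CHH boost inside the ITS.  Genotypes
act multiplicatively through a retained-activity matrix, so a knockout's
*contribution* (percent of wild-type methylation lost) equals
100 x (1 - activity) by construction.

Observed data are drawn per cytosine: coverage ~ Poisson(lambda) resampled
to be >= 1, methylated reads ~ Binomial(cov, p_true + (1 - p_true) * eps)
where eps is the bisulfite non-conversion rate.  All randomness flows from
one seeded generator, so a seed fixes every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .methylome import RECORD_COLUMNS, SampleProfile, iter_cytosines
from .reference import C_RICH_UNIT, ChromosomeEnd
from .repeats import enumerate_variants

SUBCONTEXTS = ("CG", "CAG", "CTG", "CCG", "CAH", "CTH", "CCH")

#: retained-activity fraction per (genotype, subcontext); WT is all ones.
#: Presets emulate the division of labour among the plant methyltransferases:
#: MET1 maintains CG (and is required for CCG), CMT3 with SUVH4/5/6 maintain
#: CAG/CTG, DRM2 performs most CHH and essentially all CCH, CMT2 has a mild
#: CHH role.  Values are presets, not measurements.
DEFAULT_ACTIVITY: dict[str, dict[str, float]] = {
    "WT": {s: 1.0 for s in SUBCONTEXTS},
    "met1": {"CG": 0.02, "CAG": 0.85, "CTG": 0.85, "CCG": 0.15,
             "CAH": 0.60, "CTH": 0.60, "CCH": 0.60},
    "cmt3": {"CG": 0.97, "CAG": 0.15, "CTG": 0.15, "CCG": 0.50,
             "CAH": 0.85, "CTH": 0.85, "CCH": 0.85},
    "suvh456": {"CG": 0.85, "CAG": 0.20, "CTG": 0.20, "CCG": 0.50,
                "CAH": 0.80, "CTH": 0.80, "CCH": 0.80},
    "drm2": {"CG": 0.98, "CAG": 0.85, "CTG": 0.85, "CCG": 0.70,
             "CAH": 0.35, "CTH": 0.35, "CCH": 0.05},
    "cmt2": {"CG": 0.99, "CAG": 0.95, "CTG": 0.95, "CCG": 0.95,
             "CAH": 0.70, "CTH": 0.70, "CCH": 0.70},
}

#: plateau methylation (percent) per subcontext in the wild type; CCG lower
#: than CAG/CTG and CTH above CCH, mirroring the subcontext biases of plant
#: heterochromatin.
DEFAULT_PLATEAU: dict[str, float] = {
    "CG": 85.0, "CAG": 50.0, "CTG": 50.0, "CCG": 25.0,
    "CAH": 16.0, "CTH": 18.0, "CCH": 12.0,
}


@dataclass
class SyntheticTruth:
    """Generator parameters: the study conditions for every synthetic run.

    Defaults describe an Arabidopsis-like chromosome end: a 40-repeat telomere,
    a 400-bp ITS with 40% degenerate units, a 3-kbp subtelomere whose
    methylation extends 1.5 kbp, 20x Poisson coverage and a 0.8% bisulfite
    non-conversion rate.
    """

    telomere_repeats: int = 40
    its_length: int = 400  # bp, rounded down to whole 7-mers
    degenerate_fraction: float = 0.4
    subtelomere_length: int = 3000  # bp of unique sequence after the ITS
    gc_content: float = 0.36  # of the unique subtelomere (AT-rich genome)
    plateau: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PLATEAU))
    extent: int = 1500  # L: methylated domain reaches this region coordinate
    boundary_decay: float = 25.0  # bp; e-folding of the decay across the telomere
    its_chh_boost: float = 2.0  # multiplies CHH p_true inside the ITS
    activity: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(a) for g, a in DEFAULT_ACTIVITY.items()}
    )
    coverage: float = 20.0  # Poisson lambda
    non_conversion: float = 0.008  # eps
    seed: int = 0

    def __post_init__(self):
        for g, row in self.activity.items():
            bad = [s for s, v in row.items() if not 0.0 <= v <= 1.0]
            if bad:
                raise ValueError(f"activity[{g}] outside [0,1] for {bad}")
        if not all(abs(v - 1.0) < 1e-12 for v in self.activity.get("WT", {}).values()):
            raise ValueError("WT activity row must be all 1")
        if self.extent > 70 + self.its_length + self.subtelomere_length:
            raise ValueError("extent exceeds the synthetic end length")

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=seed)


@dataclass
class SyntheticEnd:
    """A generated end plus its planted ground-truth annotations."""

    end: ChromosomeEnd
    truth: SyntheticTruth
    its_interval: tuple[int, int]  # region coords after truncation to 10 repeats
    raw_sequence: str  # untruncated input sequence (telomere_repeats units)


def generate_end(truth: SyntheticTruth, end_id: str = "synL") -> SyntheticEnd:
    """Generate a chromosome-end sequence with planted telomere and ITS.

    The raw sequence is ``telomere_repeats`` perfect CCCTAAA units, an ITS
    of whole units each independently degenerated with probability
    ``degenerate_fraction`` (single-mismatch variants, same orientation),
    then random unique sequence.  The returned ChromosomeEnd is already
    truncated to the canonical 10-repeat (70 bp) telomere block, and the
    planted ITS interval is reported in those final region coordinates.
    """
    rng = np.random.default_rng(truth.seed)
    variants = sorted(
        {v.sequence for v in enumerate_variants(C_RICH_UNIT, both_orientations=False)}
    )
    n_units = truth.its_length // 7
    its_units = []
    for _ in range(n_units):
        if rng.random() < truth.degenerate_fraction:
            its_units.append(variants[rng.integers(len(variants))])
        else:
            its_units.append(C_RICH_UNIT)
    its_seq = "".join(its_units)
    sub = "".join(
        rng.choice(
            np.array(list("ACGT")),
            p=[
                (1 - truth.gc_content) / 2,
                truth.gc_content / 2,
                truth.gc_content / 2,
                (1 - truth.gc_content) / 2,
            ],
            size=truth.subtelomere_length,
        )
    )
    raw = C_RICH_UNIT * truth.telomere_repeats + its_seq + sub
    from .reference import truncate_telomere

    end = truncate_telomere(raw, side="left", id=end_id)
    # Leading perfect ITS units are indistinguishable from telomeric repeats
    # and are absorbed into the terminal run, hence trimmed; the planted ITS
    # therefore starts with its first degenerate unit, at position 71.
    lead_perfect = 0
    for u in its_units:
        if u == C_RICH_UNIT:
            lead_perfect += 1
        else:
            break
    its_start = 71
    its_end = 70 + 7 * (n_units - lead_perfect)
    return SyntheticEnd(
        end=end, truth=truth, its_interval=(its_start, its_end), raw_sequence=raw
    )


def true_probability(
    syn: SyntheticEnd, pos: int, subcontext: str, genotype: str = "WT"
) -> float:
    """Planted methylation probability of a cytosine (before noise)."""
    truth = syn.truth
    if pos > truth.extent:
        return 0.0
    base = truth.plateau[subcontext] / 100.0
    if pos <= 70:
        # progressive decay across the telomere block toward the terminus
        base *= float(np.exp(-(71 - pos) / truth.boundary_decay))
    if subcontext in ("CAH", "CTH", "CCH"):
        a, b = syn.its_interval
        if a <= pos <= b:
            base *= truth.its_chh_boost
    base *= truth.activity[genotype][subcontext]
    return float(min(base, 1.0))


def truth_table(syn: SyntheticEnd, genotype: str = "WT") -> pd.DataFrame:
    """Per-cytosine planted probabilities for one genotype."""
    rows = [
        (syn.end.id, pos, strand, context, sub,
         true_probability(syn, pos, sub, genotype))
        for pos, strand, context, sub in iter_cytosines(syn.end)
    ]
    return pd.DataFrame(
        rows, columns=["end_id", "pos", "strand", "context", "subcontext", "p_true"]
    )


def simulate_methylome(
    syn: SyntheticEnd, genotype: str = "WT", *, seed: int | None = None
) -> tuple[SampleProfile, pd.DataFrame]:
    """Draw an observed methylome for one genotype.

    Returns the observed :class:`SampleProfile` and the truth table of
    planted per-cytosine probabilities.
    """
    truth = syn.truth
    if genotype not in truth.activity:
        raise ValueError(f"unknown genotype {genotype!r}")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    tt = truth_table(syn, genotype)
    n = len(tt)
    cov = rng.poisson(truth.coverage, size=n)
    while (cov == 0).any():  # enforce >= 1 read by resampling zeros
        zeros = cov == 0
        cov[zeros] = rng.poisson(truth.coverage, size=int(zeros.sum()))
    p_obs = tt.p_true.to_numpy() + (1 - tt.p_true.to_numpy()) * truth.non_conversion
    meth = rng.binomial(cov, p_obs)
    records = tt.drop(columns="p_true").copy()
    records["meth"] = meth
    records["total"] = cov
    records["level"] = 100.0 * meth / cov
    records = records[RECORD_COLUMNS]
    return SampleProfile(genotype=genotype, records=records, provenance=["synthetic"]), tt


def simulate_cohort(
    truth: SyntheticTruth, genotypes=None, *, end_id: str = "synL"
) -> tuple[SyntheticEnd, dict[str, SampleProfile], dict[str, pd.DataFrame]]:
    """One end, one observed methylome per genotype (distinct substreams)."""
    if genotypes is None:
        genotypes = list(truth.activity)
    syn = generate_end(truth, end_id=end_id)
    profiles, truths = {}, {}
    for i, g in enumerate(genotypes):
        profiles[g], truths[g] = simulate_methylome(syn, g, seed=truth.seed + 101 + i)
    return syn, profiles, truths


def simulate_reads(
    syn: SyntheticEnd,
    n_reads: int,
    read_len: int = 100,
    *,
    genotype: str = "WT",
    telomere_extension: int = 2000,
    seed: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Simulate C-rich-strand bisulfite reads across a virtually extended end.

    The telomere is extended outward by ``telomere_extension`` bp of perfect
    repeats (virtual coordinates <= 0 carry zero true methylation beyond
    the boundary decay), so reads lying fully inside the telomere exist and
    exercise the (YYYTAAA)n classifier.  Each C in a read is emitted as C
    with probability p_true + (1 - p_true) * eps, else as T.

    Returns the read sequences and a truth table with per-read Y-position
    and methylated counts.
    """
    truth = syn.truth
    ext = (telomere_extension // 7) * 7
    template = C_RICH_UNIT * (ext // 7) + syn.end.residues
    if read_len > len(template):
        raise ValueError("read_len exceeds the (extended) end length")
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    # planted probability by template index (region pos = idx - ext + 1)
    sub_by_pos = {pos: sub for pos, strand, _, sub in iter_cytosines(syn.end) if strand == "+"}
    p_by_idx = np.zeros(len(template))
    for idx, base in enumerate(template):
        if base != "C":
            continue
        region_pos = idx - ext + 1
        if region_pos >= 1:
            sub = sub_by_pos.get(region_pos)
            p_by_idx[idx] = (
                true_probability(syn, region_pos, sub, genotype) if sub else 0.0
            )
        else:
            # virtual telomere interior: unmethylated (decay has vanished)
            p_by_idx[idx] = 0.0
    starts = rng.integers(0, len(template) - read_len + 1, size=n_reads)
    reads: list[str] = []
    rows = []
    for ridx, s in enumerate(starts):
        frag = template[s : s + read_len]
        out = []
        n_c = n_meth = 0
        for k, base in enumerate(frag):
            if base == "C":
                n_c += 1
                p = p_by_idx[s + k] + (1 - p_by_idx[s + k]) * truth.non_conversion
                if rng.random() < p:
                    out.append("C")
                    n_meth += 1
                else:
                    out.append("T")
            else:
                out.append(base)
        reads.append("".join(out))
        rows.append({"read": ridx, "start": int(s) - ext + 1, "n_C": n_c, "n_meth": n_meth})
    return reads, pd.DataFrame(rows)


def write_fastq(reads: list[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i}\n{r}\n+\n{'I' * len(r)}\n")
    return path
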