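"""End-to-end orchestration: reference (or simulation) -> ITS annotation ->
call import -> tiling -> boundary -> differential analysis -> statistics.

A run is driven by one declarative config (dict or YAML).  Every threshold
actually used is logged, all outputs are written under one directory, and a
manifest with SHA-256 checksums makes reruns byte-verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import boundary as boundary_mod
from . import mutants as mutants_mod
from . import stats as stats_mod
from .methylome import merge_profiles, read_calls, write_calls
from .reference import read_reference, truncate_telomere, write_reference
from .repeats import call_its, scan_repeats, write_bed
from .simulate import SyntheticTruth, simulate_cohort, simulate_reads, write_fastq
from .tiling import estimate_extent, make_tiles, profile_correlations, write_bedgraph

logger = logging.getLogger(__name__)

DEFAULTS = {
    "tile_width": 40,
    "boundary_width": 35,
    "boundary_span": 700,
    "label_min": 20.0,
    "dmt_thresholds": {"CG": 20.0, "CHG": 15.0, "CHH": 10.0},
    "extent_min_level": 20.0,
    "extent_window": 5,
    "its_max_gap": 21,
    "its_min_hits": 3,
    "min_units": 4,
    "seed": 0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    merged = {**DEFAULTS, **(cfg or {})}
    if "simulate" not in merged:
        if "reference" not in merged:
            raise ValueError("config needs either 'simulate' or 'reference'")
        if not Path(merged["reference"]).exists():
            raise ValueError(f"reference not found: {merged['reference']}")
        for genotype, paths in merged.get("samples", {}).items():
            for p in [paths] if isinstance(paths, str) else paths:
                if not Path(p).exists():
                    raise ValueError(f"sample file for {genotype} not found: {p}")
    for ctx, thr in merged["dmt_thresholds"].items():
        if thr <= 0:
            raise ValueError(f"DMT threshold for {ctx} must be positive")
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return the run report.

    The report carries per-stage summaries and, for simulated runs, the
    differential-call precision/recall against generator truth.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "telosubmeth_out"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in config.items() if k != "samples"}}
    outputs: list[Path] = []

    stage = "reference"
    try:
        if "simulate" in config:
            sim_cfg = dict(config["simulate"] or {})
            sim_cfg.setdefault("seed", config["seed"])
            truth = SyntheticTruth(**sim_cfg)
            syn, profiles, truths = simulate_cohort(truth)
            ends = {syn.end.id: syn.end}
            outputs.append(write_reference(ends.values(), out / "reference.fa"))
            outputs.append(outputs[-1].with_suffix(".fa.json"))
            for g, p in profiles.items():
                outputs.append(write_calls(p, out / f"{g}.cgmap", dialect="CGmap"))
            reads, _ = simulate_reads(syn, n_reads=config.get("n_reads", 5000))
            outputs.append(write_fastq(reads, out / "reads.fastq"))
            wt = profiles["WT"]
            mutant_profiles = {g: p for g, p in profiles.items() if g != "WT"}
        else:
            ends = read_reference(config["reference"])
            profiles = {}
            for genotype, paths in config.get("samples", {}).items():
                paths = [paths] if isinstance(paths, str) else paths
                parts = [
                    read_calls(p, config.get("dialect", "CGmap"), ends, genotype=genotype)
                    for p in paths
                ]
                profiles[genotype] = (
                    parts[0] if len(parts) == 1
                    else merge_profiles(parts, config.get("merge_mode", "pool_counts"))
                )
            wt = profiles.get("WT")
            mutant_profiles = {g: p for g, p in profiles.items() if g != "WT"}
            syn = None
            reads = None
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "scan-its"
    try:
        its_by_end = {}
        for end in ends.values():
            hits = scan_repeats(end, max_gap=config["its_max_gap"])
            its = call_its(
                hits,
                min_hits=config["its_min_hits"],
                max_gap=config["its_max_gap"],
                exclude_span=end.telomere_span,
            )
            its_by_end[end.id] = its
            outputs.append(write_bed(its, out / f"{end.id}.its.bed", end.id))
        report["its"] = {
            eid: [list(a.interval) for a in anns] for eid, anns in its_by_end.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "profile"
    try:
        tiles_by_genotype: dict[str, pd.DataFrame] = {}
        extents = {}
        for end in ends.values():
            its_iv = [a.interval for a in its_by_end[end.id]]
            for g, p in profiles.items():
                t = make_tiles(
                    p, end, start=71, width=config["tile_width"], its_intervals=its_iv
                )
                tiles_by_genotype[g] = (
                    t if g not in tiles_by_genotype
                    else pd.concat([tiles_by_genotype[g], t], ignore_index=True)
                )
            if wt is not None:
                wt_t = make_tiles(wt, end, start=71, width=config["tile_width"])
                extents[end.id] = estimate_extent(
                    wt_t, end,
                    min_level=config["extent_min_level"],
                    window=config["extent_window"],
                ).border_position
        for g, t in tiles_by_genotype.items():
            t.to_csv(out / f"{g}.tiles.tsv", sep="\t", index=False)
            outputs.append(out / f"{g}.tiles.tsv")
        if "WT" in tiles_by_genotype:
            for col in ("CGm", "CHGm", "CHHm"):
                outputs.append(
                    write_bedgraph(tiles_by_genotype["WT"], col, out / f"WT.{col}.bedgraph")
                )
            corr = profile_correlations(tiles_by_genotype["WT"])
            corr.to_csv(out / "WT.correlations.tsv", sep="\t", index=False)
            outputs.append(out / "WT.correlations.tsv")
        report["extent"] = extents
        logger.info("extent borders: %s", extents)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "boundary"
    try:
        if wt is not None:
            bt_all = []
            for end in ends.values():
                bt = boundary_mod.boundary_tiles(
                    wt, end, span=config["boundary_span"], width=config["boundary_width"]
                )
                bt_all.append(bt)
            bt = pd.concat(bt_all, ignore_index=True)
            bt.to_csv(out / "boundary.tiles.tsv", sep="\t", index=False)
            outputs.append(out / "boundary.tiles.tsv")
            report["boundary"] = {
                "tel_tiles": int((bt.zone == "Tel").sum()),
                "subtel_tiles": int((bt.zone == "Subtel").sum()),
            }
        if reads is not None:
            rs = boundary_mod.classify_telomeric_reads(reads, min_units=config["min_units"])
            report["telomeric_reads"] = {
                "n_reads": rs.n_reads,
                "fraction_methylated": rs.fraction_methylated,
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "compare"
    try:
        if wt is not None and mutant_profiles:
            dmt = mutants_mod.call_dmts(
                tiles_by_genotype["WT"],
                {g: tiles_by_genotype[g] for g in mutant_profiles},
                label_min=config["label_min"],
                thresholds=config["dmt_thresholds"],
            )
            dmt.to_csv(out / "dmt_calls.tsv", sep="\t", index=False)
            outputs.append(out / "dmt_calls.tsv")
            overlap = mutants_mod.overlap_analysis(dmt)
            overlap["percent"].to_csv(out / "overlap_percent.tsv", sep="\t")
            outputs.append(out / "overlap_percent.tsv")
            contribs = []
            for g, mp in mutant_profiles.items():
                for ctx in ("CHG", "CHH"):
                    c = mutants_mod.contribution(wt, mp, ctx, scope="all")
                    contribs.append(
                        {"genotype": g, "context": ctx, "value": c.value, "n": c.n_sites}
                    )
            pd.DataFrame(contribs).to_csv(out / "contributions.tsv", sep="\t", index=False)
            outputs.append(out / "contributions.tsv")
            report["contributions"] = contribs
            if syn is not None:
                report["dmt_vs_truth"] = _dmt_truth_metrics(dmt, syn, truths, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "stats"
    try:
        if len(profiles) >= 3:
            tree = stats_mod.cluster_genotypes(list(profiles.values()))
            (out / "clustering.nwk").write_text(tree.to_newick() + "\n")
            outputs.append(out / "clustering.nwk")
            report["cluster_groups"] = [sorted(g) for g in tree.groups(3)]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    manifest = {
        str(p.relative_to(out)): _sha256(p) for p in outputs if p.exists()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _dmt_truth_metrics(dmt: pd.DataFrame, syn, truths, config) -> dict:
    """Precision/recall of DMT calls against the generator's planted truth."""
    from .mutants import dmt_truth_metrics

    return dmt_truth_metrics(dmt, syn, truths, config["label_min"], config["dmt_thresholds"])
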