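"""End-to-end pipeline: simulate/load traces -> call -> QC -> profile -> stats -> report.

A run is described by a YAML (or dict) config and writes its artifacts -- trace
fixtures, ground truth, profile TSV, per-CpG statistics TSV, lollipop SVG,
optional BED and concordance summary -- into one output directory together
with a run log recording the package version, seed, thresholds and every
per-trace QC decision.  Config validation happens before any computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .quantify import LocusProfile, QuantConfig, profile_locus
from .reference import (
    FORWARD,
    ORIENTATIONS,
    ConfigurationError,
    GenomicAnchor,
    ReferenceLocus,
    load_loci,
)
from .report import export_profile, export_profile_bed, render_lollipop
from .simulate import SimulationDesign, simulate_experiment, simulate_pyro
from .stats import compare_profile, concordance, fraction_significant
from .traceio import read_trace_json, write_trace_json

logger = logging.getLogger(__name__)

_THRESHOLD_KEYS = {
    "homogeneity_threshold", "signal_floor_frac", "conversion_threshold",
    "identity_floor", "match", "mismatch", "gap",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    locus: ReferenceLocus
    seed: int
    quant: QuantConfig
    simulation: Optional[dict]
    trace_paths: list[Path]
    samples: dict[str, str]
    stats: dict
    pyro: Optional[dict]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        return cls.from_dict(raw, base=base)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a mapping")
        locus = _parse_locus(raw.get("locus"), base)
        seed = int(raw.get("seed", 0))
        thresholds = raw.get("thresholds") or {}
        unknown = set(thresholds) - _THRESHOLD_KEYS
        if unknown:
            raise ConfigurationError(f"unknown threshold keys: {sorted(unknown)}")
        quant = QuantConfig(**thresholds)
        simulation = raw.get("simulation")
        trace_paths = [base / p for p in (raw.get("traces") or [])]
        samples = {str(k): str(v) for k, v in (raw.get("samples") or {}).items()}
        if (simulation is None) == (not trace_paths):
            raise ConfigurationError(
                "config must provide exactly one of 'simulation' or 'traces'"
            )
        if trace_paths and not samples:
            raise ConfigurationError("'traces' mode requires a 'samples' sample->group map")
        stats = {"mode": "overall", "control": "control", "alpha": 0.05}
        stats.update(raw.get("stats") or {})
        if stats["mode"] not in {"overall", "pooled", "pairwise", "none"}:
            raise ConfigurationError(f"unknown stats mode {stats['mode']!r}")
        groups = (
            set((simulation or {}).get("group_effects", {"control": 0.0}))
            if simulation
            else set(samples.values())
        )
        if stats["mode"] in {"pooled", "pairwise"} and stats["control"] not in groups:
            raise ConfigurationError(
                f"stats control group {stats['control']!r} is not a defined group "
                f"(defined: {sorted(groups)})"
            )
        if simulation and samples:
            undefined = set(samples.values()) - groups
            if undefined:
                raise ConfigurationError(f"samples reference undefined groups: {sorted(undefined)}")
        pyro = raw.get("pyro")
        if pyro is not None and simulation is None:
            raise ConfigurationError("'pyro' simulation requires 'simulation' mode")
        return cls(locus, seed, quant, simulation, trace_paths, samples, stats, pyro)

    def build_design(self) -> SimulationDesign:
        sim = dict(self.simulation or {})
        orientation = sim.pop("orientation", FORWARD)
        if orientation not in ORIENTATIONS:
            raise ConfigurationError(f"unknown orientation {orientation!r}")
        sim.setdefault("group_effects", {"control": 0.0})
        sim.pop("seed", None)
        return SimulationDesign(
            locus=self.locus, orientation=orientation, seed=self.seed, **sim
        )


def _parse_locus(raw: Optional[dict], base: Path) -> ReferenceLocus:
    if not raw:
        raise ConfigurationError("config needs a 'locus' section")
    if "fasta" in raw:
        loci = load_loci(base / raw["fasta"], base / raw["locus_config"])
        name = raw.get("name")
        if name is None and len(loci) == 1:
            return next(iter(loci.values()))
        if name not in loci:
            raise ConfigurationError(f"locus {name!r} not found in FASTA")
        return loci[name]
    anchor = None
    if raw.get("chrom") is not None:
        anchor = GenomicAnchor(str(raw["chrom"]), int(raw["genomic_start"]))
    return ReferenceLocus(
        name=str(raw.get("name", "locus")),
        sequence=str(raw["sequence"]),
        tss_offset=int(raw["tss_offset"]),
        genomic_anchor=anchor,
    )


def run_pipeline(config: RunConfig | dict | str | Path, outdir: str | Path) -> dict:
    """Execute the full pipeline and write artifacts under ``outdir``.

    Returns a summary dict with artifact paths and headline numbers.  Any
    stage failure raises PipelineError tagged with the stage; the run log then
    ends with a FAILED line so partial artifacts are flagged.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pkg_logger = logging.getLogger("bstrace")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger.addHandler(handler)
    old_level = pkg_logger.level
    pkg_logger.setLevel(logging.INFO)

    summary: dict = {"outdir": str(outdir), "version": __version__, "seed": config.seed}
    stage = "setup"
    try:
        logger.info("bstrace %s: seed=%d locus=%s", __version__, config.seed, config.locus.name)
        logger.info("thresholds: %s", config.quant)

        stage = "traces"
        truth = None
        if config.simulation is not None:
            design = config.build_design()
            traces, truth, sample_table = simulate_experiment(design)
            groups = dict(sample_table.itertuples(index=False))
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            tracedir = outdir / "traces"
            tracedir.mkdir(exist_ok=True)
            for tr in traces:
                write_trace_json(tr, tracedir / f"{tr.sample_id}.json")
            logger.info("simulated %d traces (%d groups)", len(traces), truth["group"].nunique())
        else:
            traces = [read_trace_json(p) for p in config.trace_paths]
            groups = config.samples
            missing = [t.sample_id for t in traces if t.sample_id not in groups]
            if missing:
                raise ConfigurationError(f"traces without a group assignment: {missing}")

        stage = "profile"
        profile = profile_locus(traces, config.locus, config.quant, groups=groups)

        stage = "stats"
        if config.stats["mode"] != "none":
            table = compare_profile(
                profile,
                mode=config.stats["mode"],
                control=config.stats["control"],
                alpha=float(config.stats["alpha"]),
            )
            table.to_csv(outdir / "stats.tsv", sep="\t")
            try:
                summary["fraction_significant"] = fraction_significant(
                    table, alpha=float(config.stats["alpha"])
                )
            except Exception:
                summary["fraction_significant"] = None
            logger.info("fraction significant: %s", summary["fraction_significant"])

        stage = "concordance"
        if config.pyro is not None and truth is not None:
            pyro = simulate_pyro(
                truth,
                measurement_sd=float(config.pyro.get("measurement_sd", 0.0)),
                seed=config.seed + 1,
            )
            pyro.to_csv(outdir / "pyro.tsv", sep="\t", index=False)
            merged = _pair_profile_with_truth(profile, pyro)
            res = concordance(merged["trace_percent"], merged["percent_methylation"])
            summary["concordance"] = {
                "n": res.n, "slope": res.slope, "intercept": res.intercept,
                "r_squared": res.r_squared, "assessable": res.assessable,
            }
            logger.info("concordance: %s", summary["concordance"])

        stage = "report"
        export_profile(profile, outdir / "profile.tsv")
        svg = render_lollipop(profile)
        (outdir / "lollipop.svg").write_text(svg)
        if isinstance(profile.locus, ReferenceLocus) and profile.locus.genomic_anchor:
            export_profile_bed(profile, outdir / "cpg_sites.bed")
        logger.info("artifacts written to %s", outdir)
        summary["profile_samples"] = profile.samples
        return summary
    except Exception as exc:
        logger.error("FAILED at stage %s: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        pkg_logger.removeHandler(handler)
        handler.close()
        pkg_logger.setLevel(old_level)


def _pair_profile_with_truth(profile: LocusProfile, pyro: pd.DataFrame) -> pd.DataFrame:
    """Pair per-(group, CpG) mean trace estimates with pyro percentages."""
    long = profile.proportions.copy()
    long.columns = [profile.groups.get(s, "all") for s in long.columns]
    means = (
        long.T.groupby(level=0).mean().T.reset_index()
        .melt(id_vars="tss_relative", var_name="group", value_name="trace_proportion")
    )
    means["trace_percent"] = 100.0 * means["trace_proportion"]
    return means.merge(
        pyro, left_on=["tss_relative", "group"], right_on=["cpg_tss_relative", "group"]
    ).dropna(subset=["trace_percent", "percent_methylation"])
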