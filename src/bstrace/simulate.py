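"""Synthetic electropherograms with known per-CpG methylation ground truth.

The forward model emulates direct (non-cloned) bisulphite Sanger sequencing of
a PCR-amplified mixed molecule population: at every read position each of the
four dye channels carries a Gaussian-shaped peak whose amplitude is
proportional to the fraction of molecules carrying that base.  At a CpG the
C/T (forward read) or G/A (reverse read) amplitudes split according to the
bulk methylation proportion; every non-CpG reference cytosine reads as fully
converted (T forward / A reverse) unless it is drawn as a conversion failure.
Peaks are truncated at half the base spacing so neighbouring bases do not
bleed into each other's measurement window, which makes peak-height ratios
exactly proportional to population fractions in the noiseless limit.

Group designs (e.g. control vs. knockdown with per-group per-CpG methylation
offsets) and biological replicates are generated from a single seeded RNG, so
an experiment is bit-reproducible from its design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .reference import (
    FORWARD,
    REVERSE,
    ConfigurationError,
    ConvertedTemplate,
    ReferenceLocus,
    convert_reference,
)
from .traceio import CHANNEL_ORDER, TraceRecord

logger = logging.getLogger(__name__)


@dataclass
class SimulationDesign:
    """Parameters of a simulated bisulphite sequencing experiment.

    ``true_methylation`` gives the baseline per-CpG methylated fraction of the
    population; ``group_effects`` adds a per-group offset (scalar, or one
    value per CpG).  Effective proportions are clipped to [0, 1] with a logged
    warning.  ``conversion_failure_rate`` is the per-position probability that
    a non-CpG cytosine escapes conversion; ``noise_sd`` is additive Gaussian
    channel noise on the same scale as ``amplitude`` (the height of a pure
    single-base peak).
    """

    locus: ReferenceLocus
    true_methylation: Sequence[float]
    conversion_failure_rate: float = 0.0
    noise_sd: float = 0.0
    peak_sd: float = 2.5
    spacing: int = 12
    amplitude: float = 100.0
    n_replicates: int = 3
    group_effects: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"control": 0.0}
    )
    orientation: str = FORWARD
    seed: int = 0

    def __post_init__(self) -> None:
        n_cpg = len(self.locus.cpg_sites)
        if n_cpg == 0:
            raise ConfigurationError(f"locus {self.locus.name!r} has no CpG sites")
        tm = np.asarray(self.true_methylation, dtype=float)
        if tm.ndim == 0:
            tm = np.full(n_cpg, float(tm))
        if tm.shape != (n_cpg,):
            raise ConfigurationError(
                f"true_methylation needs one value per CpG site ({n_cpg}), got {tm.shape}"
            )
        if ((tm < 0) | (tm > 1)).any():
            raise ConfigurationError("true_methylation values must lie in [0, 1]")
        self.true_methylation = tm
        if not 0 <= self.conversion_failure_rate < 1:
            raise ConfigurationError("conversion_failure_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 1 or not self.group_effects:
            raise ConfigurationError("need >= 1 group and >= 1 replicate")
        if self.spacing < 4 * self.peak_sd:
            logger.warning(
                "spacing %s < 4*peak_sd (%s): peaks may merge", self.spacing, 4 * self.peak_sd
            )

    def group_proportions(self, group: str) -> np.ndarray:
        """Effective per-CpG proportions for a group, clipped to [0, 1]."""
        if group not in self.group_effects:
            raise ConfigurationError(f"group {group!r} not in design")
        eff = np.broadcast_to(
            np.asarray(self.group_effects[group], dtype=float), self.true_methylation.shape
        )
        raw = self.true_methylation + eff
        clipped = np.clip(raw, 0.0, 1.0)
        if not np.array_equal(raw, clipped):
            logger.warning(
                "group %r: %d effective proportions clipped to [0, 1]",
                group,
                int((raw != clipped).sum()),
            )
        return clipped


def _render_trace(
    template: ConvertedTemplate,
    site_fractions: dict[int, dict[str, float]],
    design: SimulationDesign,
    rng: np.random.Generator,
    sample_id: str,
) -> TraceRecord:
    """Render channels from per-read-position base fractions."""
    n = len(template.expected_bases)
    spacing, sd, amp = design.spacing, design.peak_sd, design.amplitude
    length = spacing * (n + 1)
    centers = spacing * (np.arange(n) + 1)
    x = np.arange(length, dtype=float)
    channels = {b: np.zeros(length) for b in CHANNEL_ORDER}
    half = spacing / 2.0
    for i, center in enumerate(centers):
        lo = max(0, int(np.ceil(center - half + 1e-9)))
        hi = min(length, int(np.floor(center + half - 1e-9)) + 1)
        window = x[lo:hi]
        shape = np.exp(-0.5 * ((window - center) / sd) ** 2)
        for base, frac in site_fractions[i].items():
            if frac > 0:
                channels[base][lo:hi] += amp * frac * shape
    if design.noise_sd > 0:
        for b in CHANNEL_ORDER:
            channels[b] = np.clip(
                channels[b] + rng.normal(0.0, design.noise_sd, length), 0.0, None
            )
    stacked = np.stack([channels[b][centers] for b in CHANNEL_ORDER])
    called = "".join(CHANNEL_ORDER[j] for j in stacked.argmax(axis=0))
    return TraceRecord(
        sample_id=sample_id,
        orientation=template.orientation,
        channels=channels,
        peak_positions=centers,
        called_bases=called,
        source="simulated",
    )


def simulate_trace(
    design: SimulationDesign,
    sample_id: str = "sample",
    group: str | None = None,
    rng: Optional[np.random.Generator] = None,
) -> TraceRecord:
    """Simulate one chromatogram for one sample of one group."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if group is None:
        group = next(iter(design.group_effects))
    proportions = design.group_proportions(group)
    template = convert_reference(design.locus, design.orientation)
    sites = design.locus.cpg_sites

    meth_base, unmeth_base = ("C", "T") if design.orientation == FORWARD else ("G", "A")
    cpg_read_pos = {template.read_position(s): m for s, m in zip(sites, proportions)}
    failure_pos = {
        p
        for p in template.nonCpG_c_read_positions
        if design.conversion_failure_rate > 0
        and rng.random() < design.conversion_failure_rate
    }

    fractions: dict[int, dict[str, float]] = {}
    for i, base in enumerate(template.expected_bases):
        if i in cpg_read_pos:
            m = cpg_read_pos[i]
            fractions[i] = {meth_base: m, unmeth_base: 1.0 - m}
        elif i in failure_pos:
            fractions[i] = {meth_base: 1.0}  # unconverted C reads as C (fwd) / G (rev)
        elif base in ("Y", "R"):  # pragma: no cover - guarded by template invariants
            raise AssertionError("ambiguity code outside CpG position")
        else:
            fractions[i] = {base: 1.0}
    return _render_trace(template, fractions, design, rng, sample_id)


def simulate_experiment(
    design: SimulationDesign,
) -> tuple[list[TraceRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate all (group, replicate) traces of a design.

    Returns the traces, a ground-truth table of effective per-CpG proportions
    per group, and a sample table mapping sample_id to group.
    """
    rng = np.random.default_rng(design.seed)
    sites = design.locus.cpg_sites
    traces: list[TraceRecord] = []
    truth_rows = []
    sample_rows = []
    for group in design.group_effects:
        proportions = design.group_proportions(group)
        for s, p in zip(sites, proportions):
            truth_rows.append(
                {
                    "locus": design.locus.name,
                    "group": group,
                    "cpg_tss_relative": s.tss_relative,
                    "proportion": float(p),
                }
            )
        for rep in range(1, design.n_replicates + 1):
            sample_id = f"{group}_rep{rep}"
            traces.append(simulate_trace(design, sample_id, group, rng=rng))
            sample_rows.append({"sample_id": sample_id, "group": group})
    return traces, pd.DataFrame(truth_rows), pd.DataFrame(sample_rows)


def simulate_pyro(
    truth: pd.DataFrame, measurement_sd: float, seed: int
) -> pd.DataFrame:
    """Simulate a pyrosequencing percent-methylation table from ground truth.

    ``truth`` needs a ``proportion`` column in [0, 1]; the result carries the
    same identifying columns plus ``percent_methylation`` = 100*proportion +
    Gaussian measurement noise, clipped to [0, 100].
    """
    if measurement_sd < 0:
        raise ConfigurationError("measurement_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = truth.copy()
    values = 100.0 * out["proportion"].to_numpy(dtype=float)
    if measurement_sd > 0:
        values = values + rng.normal(0.0, measurement_sd, len(values))
    out["percent_methylation"] = np.clip(values, 0.0, 100.0)
    bad = (out["percent_methylation"] < 0) | (out["percent_methylation"] > 100)
    assert not bad.any()
    return out.drop(columns=["proportion"])
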