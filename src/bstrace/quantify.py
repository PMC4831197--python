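"""Per-CpG methylation calling from chromatogram peak heights.

The procedure mirrors how direct bisulphite Sanger traces are read by eye:
the called read is globally aligned to the in-silico converted reference
(with Y/R ambiguity codes matching either allele at CpG positions), then at
each mapped CpG the heights of the two relevant dye peaks are measured -- C
vs. T on a forward read, G vs. A on a reverse read.  A single peak means a
homogeneous population (proportion 0 or 1); two peaks mean a mixed population
whose methylated fraction is the methylated-channel height over the summed
heights.  Proportions are ranked into five intervals (0-0.2, 0.2-0.4,
0.4-0.6, 0.6-0.8, 0.8-1].  Non-CpG reference cytosines, which must read fully
converted, provide a per-trace bisulphite conversion-efficiency QC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .reference import (
    FORWARD,
    ConvertedTemplate,
    CpGSite,
    ReferenceLocus,
    convert_reference,
)
from .traceio import TraceRecord

logger = logging.getLogger(__name__)

#: call status codes
OK = "ok"
UNCOVERED = "uncovered"
LOW_SIGNAL = "low_signal"


class TraceRejectedError(ValueError):
    """Trace failed alignment identity or another per-trace QC gate."""


class EmptyProfileError(ValueError):
    """No trace of a locus survived QC."""


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds of the calling procedure.

    homogeneity_threshold: minor/major peak ratio below which the position is
        treated as a single peak (homogeneous population).
    signal_floor_frac: fraction of the trace's median called-peak height below
        which both relevant channels count as absent (call fails QC).
    conversion_threshold: minimum conversion efficiency for a trace to pass.
    identity_floor: minimum alignment identity before a trace is rejected.
    match/mismatch/gap: global alignment scores; Y/R ambiguity scores as match.
    """

    homogeneity_threshold: float = 0.10
    signal_floor_frac: float = 0.05
    conversion_threshold: float = 0.95
    identity_floor: float = 0.80
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass
class AlignmentMap:
    """Monotone mapping between read and template positions."""

    read_to_template: dict[int, int]
    template_to_read: dict[int, int]
    score: float
    gap_count: int
    identity: float


@dataclass
class MethylationCall:
    cpg_site: CpGSite
    proportion: Optional[float]
    level: Optional[int]
    homogeneous: bool
    peak_heights: tuple[float, float]  # (methylated channel, unmethylated channel)
    qc_pass: bool
    status: str = OK


@dataclass
class ConversionQC:
    n_positions: int
    n_converted: int
    efficiency: Optional[float]
    threshold: float
    assessable: bool

    @property
    def qc_pass(self) -> Optional[bool]:
        if not self.assessable:
            return None
        return self.efficiency >= self.threshold


@dataclass
class TraceCalls:
    """All per-CpG calls of one trace plus its trace-level QC."""

    sample_id: str
    orientation: str
    calls: list[MethylationCall]
    conversion: ConversionQC
    alignment: AlignmentMap


@dataclass
class LocusProfile:
    """CpG-by-sample methylation matrix for one locus.

    Rows are CpG sites in TSS-relative order; columns are samples.  Missing
    calls are NaN, never dropped.  ``stats`` (per-CpG p-values/flags) is
    attached by the group-comparison step.
    """

    locus: ReferenceLocus | str  # a bare name when rebuilt from a TSV export
    proportions: pd.DataFrame  # index: tss_relative, columns: sample ids
    levels: pd.DataFrame
    status: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    stats: Optional[pd.DataFrame] = None

    @property
    def name(self) -> str:
        return self.locus if isinstance(self.locus, str) else self.locus.name

    @property
    def positions(self) -> list[int]:
        return list(self.proportions.index)

    @property
    def samples(self) -> list[str]:
        return list(self.proportions.columns)


# ---------------------------------------------------------------------------
# Alignment

_ALPHABET = "ACGTYRN"


def _build_aligner(config: QuantConfig) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = config.mismatch
    for a in "ACGT":
        matrix[a, a] = config.match
    for b in "CT":  # forward CpG allele
        matrix["Y", b] = matrix[b, "Y"] = config.match
    for b in "GA":  # reverse CpG allele
        matrix["R", b] = matrix[b, "R"] = config.match
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = config.gap
    aligner.extend_gap_score = config.gap
    return aligner


def align_read(
    trace: TraceRecord,
    template: ConvertedTemplate,
    config: QuantConfig = QuantConfig(),
) -> AlignmentMap:
    """Globally align a trace's called bases to the converted template.

    Y matches C or T and R matches G or A at full match score.  Traces whose
    identity (full-match columns over template length) falls below
    ``config.identity_floor`` are rejected.
    """
    if trace.orientation != template.orientation:
        raise TraceRejectedError(
            f"trace {trace.sample_id!r} orientation {trace.orientation!r} does not "
            f"match template orientation {template.orientation!r}"
        )
    read = "".join(b if b in _ALPHABET else "N" for b in trace.called_bases.upper())
    aligner = _build_aligner(config)
    alignment = aligner.align(template.expected_bases, read)[0]
    t2r: dict[int, int] = {}
    r2t: dict[int, int] = {}
    matches = 0
    for (t0, t1), (r0, r1) in zip(*alignment.aligned):
        for dt in range(t1 - t0):
            t, r = t0 + dt, r0 + dt
            t2r[t] = r
            r2t[r] = t
            if _is_match(template.expected_bases[t], read[r]):
                matches += 1
    n_template = len(template.expected_bases)
    identity = matches / n_template if n_template else 0.0
    gap_count = (n_template - len(t2r)) + (len(read) - len(r2t))
    if identity < config.identity_floor:
        raise TraceRejectedError(
            f"trace {trace.sample_id!r}: alignment identity {identity:.3f} below "
            f"floor {config.identity_floor}"
        )
    return AlignmentMap(
        read_to_template=r2t,
        template_to_read=t2r,
        score=float(alignment.score),
        gap_count=gap_count,
        identity=identity,
    )


def _is_match(template_base: str, read_base: str) -> bool:
    if template_base == "Y":
        return read_base in "CT"
    if template_base == "R":
        return read_base in "GA"
    return template_base == read_base


# ---------------------------------------------------------------------------
# Peak measurement and calling


def _estimate_spacing(trace: TraceRecord) -> int:
    if len(trace.peak_positions) < 2:
        return 12
    return int(np.median(np.diff(trace.peak_positions)))


def peak_height(trace: TraceRecord, read_index: int, channel: str) -> float:
    """Maximum channel intensity within a half-spacing window around a peak."""
    center = int(trace.peak_positions[read_index])
    half = max(1, _estimate_spacing(trace) // 2 - 1)
    sig = trace.channels[channel]
    lo, hi = max(0, center - half), min(len(sig), center + half + 1)
    return float(sig[lo:hi].max())


def _median_peak_height(trace: TraceRecord) -> float:
    heights = [
        max(trace.channels[b][p] for b in trace.channels)
        for p in trace.peak_positions
    ]
    return float(np.median(heights)) if heights else 0.0


def bin_level(proportion: float) -> int:
    """Five-interval rank of a methylation proportion.

    Contiguous half-open bins (0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 0.8],
    (0.8, 1] with 0 assigned to bin 1: level 1 covers [0, 0.2], level 5
    covers (0.8, 1].
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    if proportion <= 0.0:
        return 1
    return min(5, int(math.floor(proportion * 5.0 - 1e-9)) + 1)


def call_site(
    trace: TraceRecord,
    amap: AlignmentMap,
    site: CpGSite,
    template: ConvertedTemplate,
    config: QuantConfig = QuantConfig(),
) -> MethylationCall:
    """Estimate the methylated fraction at one CpG from peak heights.

    Forward reads compare the C (methylated) and T (unmethylated) channels;
    reverse reads compare G and A.  A minor peak below the homogeneity
    threshold yields a homogeneous call (proportion exactly 0 or 1); otherwise
    the proportion is h_meth / (h_meth + h_unmeth).
    """
    template_pos = template.read_position(site)
    read_index = amap.template_to_read.get(template_pos)
    if read_index is None:
        return MethylationCall(site, None, None, False, (0.0, 0.0), False, UNCOVERED)
    meth_ch, unmeth_ch = ("C", "T") if template.orientation == FORWARD else ("G", "A")
    h_meth = peak_height(trace, read_index, meth_ch)
    h_unmeth = peak_height(trace, read_index, unmeth_ch)
    floor = config.signal_floor_frac * _median_peak_height(trace)
    if h_meth < floor and h_unmeth < floor:
        return MethylationCall(site, None, None, False, (h_meth, h_unmeth), False, LOW_SIGNAL)
    major, minor = max(h_meth, h_unmeth), min(h_meth, h_unmeth)
    if minor < config.homogeneity_threshold * major:
        proportion = 1.0 if h_meth >= h_unmeth else 0.0
        homogeneous = True
    else:
        proportion = h_meth / (h_meth + h_unmeth)
        homogeneous = False
    return MethylationCall(
        site, proportion, bin_level(proportion), homogeneous, (h_meth, h_unmeth), True, OK
    )


def conversion_qc(
    trace: TraceRecord,
    template: ConvertedTemplate,
    amap: AlignmentMap,
    config: QuantConfig = QuantConfig(),
) -> ConversionQC:
    """Score bisulphite conversion from non-CpG reference cytosines.

    A mapped position counts as converted iff the unconverted channel (C on
    forward reads, G on reverse) stays below the single-peak minor threshold
    relative to the converted channel (T / A).  With no non-CpG cytosines in
    the template the QC is not assessable.
    """
    unconv_ch, conv_ch = ("C", "T") if template.orientation == FORWARD else ("G", "A")
    n = 0
    n_converted = 0
    for template_pos in template.nonCpG_c_read_positions:
        read_index = amap.template_to_read.get(template_pos)
        if read_index is None:
            continue
        n += 1
        h_unconv = peak_height(trace, read_index, unconv_ch)
        h_conv = peak_height(trace, read_index, conv_ch)
        if h_unconv < config.homogeneity_threshold * max(h_conv, 1e-12):
            n_converted += 1
    if n == 0:
        return ConversionQC(0, 0, None, config.conversion_threshold, assessable=False)
    return ConversionQC(
        n, n_converted, n_converted / n, config.conversion_threshold, assessable=True
    )


def call_trace(
    trace: TraceRecord,
    locus: ReferenceLocus,
    config: QuantConfig = QuantConfig(),
) -> TraceCalls:
    """Align one trace and call every CpG site of the locus."""
    template = convert_reference(locus, trace.orientation)
    amap = align_read(trace, template, config)
    conv = conversion_qc(trace, template, amap, config)
    calls = [call_site(trace, amap, site, template, config) for site in locus.cpg_sites]
    return TraceCalls(trace.sample_id, trace.orientation, calls, conv, amap)


def profile_locus(
    traces: Sequence[TraceRecord],
    locus: ReferenceLocus,
    config: QuantConfig = QuantConfig(),
    groups: Optional[dict[str, str]] = None,
    enforce_conversion_qc: bool = True,
) -> LocusProfile:
    """Build the CpG-by-replicate methylation matrix for one locus.

    Traces failing alignment or (if enforced) conversion QC are excluded with
    a logged reason; uncovered or low-signal sites stay as missing cells.
    Raises EmptyProfileError when no trace survives.
    """
    sites = locus.cpg_sites
    index = pd.Index([s.tss_relative for s in sites], name="tss_relative")
    prop_cols: dict[str, list[float]] = {}
    level_cols: dict[str, list[float]] = {}
    status_cols: dict[str, list[str]] = {}
    for trace in traces:
        try:
            result = call_trace(trace, locus, config)
        except TraceRejectedError as exc:
            logger.warning("excluding trace %r: %s", trace.sample_id, exc)
            continue
        if enforce_conversion_qc and result.conversion.qc_pass is False:
            logger.warning(
                "excluding trace %r: conversion efficiency %.3f below threshold %.3f",
                trace.sample_id,
                result.conversion.efficiency,
                config.conversion_threshold,
            )
            continue
        prop_cols[trace.sample_id] = [
            c.proportion if c.proportion is not None else np.nan for c in result.calls
        ]
        level_cols[trace.sample_id] = [
            c.level if c.level is not None else np.nan for c in result.calls
        ]
        status_cols[trace.sample_id] = [c.status for c in result.calls]
    if not prop_cols:
        raise EmptyProfileError(f"no trace of locus {locus.name!r} passed QC")
    groups = groups or {}
    return LocusProfile(
        locus=locus,
        proportions=pd.DataFrame(prop_cols, index=index),
        levels=pd.DataFrame(level_cols, index=index),
        status=pd.DataFrame(status_cols, index=index),
        groups={s: groups.get(s, "all") for s in prop_cols},
    )
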