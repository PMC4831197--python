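"""Lollipop rendering and tabular export of locus methylation profiles.

The lollipop plot is the field's standard display: a grid of circles, one
column per CpG ordered by TSS-relative position, one row per sample, with the
fill drawn from a five-step gradient keyed to the methylation level (1 =
unmethylated, 5 = fully methylated).  Missing calls are drawn as crossed open
circles and per-CpG significance is marked with an asterisk above the column.
The SVG is assembled as plain text so identical profiles render to
byte-identical documents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .quantify import LocusProfile
from .reference import ConfigurationError, ReferenceLocus, cpg_sites_to_bed, write_bed

#: default five-step monochrome gradient, levels 1..5
DEFAULT_PALETTE = ("#ffffff", "#bfbfbf", "#808080", "#404040", "#000000")


@dataclass(frozen=True)
class LollipopStyle:
    palette: tuple[str, ...] = DEFAULT_PALETTE
    cell: int = 28  # grid pitch in px
    radius: int = 10
    label_width: int = 130
    top_margin: int = 46
    bottom_margin: int = 64
    font: str = "monospace"

    def __post_init__(self) -> None:
        if len(self.palette) != 5:
            raise ConfigurationError("palette must have exactly 5 colours")


def render_lollipop(profile: LocusProfile, style: LollipopStyle = LollipopStyle()) -> str:
    """Render a locus profile as an SVG lollipop grid (deterministic text)."""
    if profile.proportions.empty or not profile.samples:
        raise ValueError("cannot render an empty profile")
    positions = profile.positions
    samples = sorted(profile.samples, key=lambda s: (profile.groups.get(s, ""), s))
    n_cols, n_rows = len(positions), len(samples)
    width = style.label_width + style.cell * n_cols + 140
    height = style.top_margin + style.cell * n_rows + style.bottom_margin

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<text x="{style.label_width}" y="18" font-family="{style.font}" '
        f'font-size="14" font-weight="bold">{_esc(profile.name)}</text>',
    ]

    significant = _significance_flags(profile)
    for j, pos in enumerate(positions):
        cx = style.label_width + style.cell * j + style.cell // 2
        if significant.get(pos, False):
            parts.append(
                f'<text x="{cx}" y="{style.top_margin - 6}" text-anchor="middle" '
                f'font-family="{style.font}" font-size="13">*</text>'
            )
        ly = style.top_margin + style.cell * n_rows + 12
        parts.append(
            f'<text x="{cx}" y="{ly}" text-anchor="end" font-family="{style.font}" '
            f'font-size="10" transform="rotate(-60 {cx} {ly})">{pos:+d}</text>'
        )

    for i, sample in enumerate(samples):
        cy = style.top_margin + style.cell * i + style.cell // 2
        group = profile.groups.get(sample, "")
        label = f"{sample} [{group}]" if group else sample
        parts.append(
            f'<text x="{style.label_width - 8}" y="{cy + 4}" text-anchor="end" '
            f'font-family="{style.font}" font-size="11">{_esc(label)}</text>'
        )
        for j, pos in enumerate(positions):
            cx = style.label_width + style.cell * j + style.cell // 2
            level = profile.levels.loc[pos, sample]
            if isinstance(level, float) and math.isnan(level):
                r = style.radius
                parts.append(
                    f'<circle cx="{cx}" cy="{cy}" r="{r}" fill="none" '
                    f'stroke="#888888" stroke-dasharray="2,2"/>'
                    f'<line x1="{cx - r}" y1="{cy - r}" x2="{cx + r}" y2="{cy + r}" '
                    f'stroke="#888888"/>'
                )
            else:
                fill = style.palette[int(level) - 1]
                parts.append(
                    f'<circle cx="{cx}" cy="{cy}" r="{style.radius}" fill="{fill}" '
                    f'stroke="#000000"/>'
                )

    # legend: the five intervals
    lx = style.label_width + style.cell * n_cols + 24
    parts.append(
        f'<text x="{lx}" y="{style.top_margin - 6}" font-family="{style.font}" '
        f'font-size="10">methylation</text>'
    )
    bounds = ("0-0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", "0.8-1")
    for lvl in range(1, 6):
        cy = style.top_margin + 16 * (lvl - 1) + 8
        parts.append(
            f'<circle cx="{lx + 8}" cy="{cy}" r="6" fill="{style.palette[lvl - 1]}" '
            f'stroke="#000000"/>'
            f'<text x="{lx + 20}" y="{cy + 4}" font-family="{style.font}" '
            f'font-size="10">{bounds[lvl - 1]}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _significance_flags(profile: LocusProfile) -> dict[int, bool]:
    if profile.stats is None:
        return {}
    flags: dict[int, bool] = {}
    for pos, row in profile.stats.iterrows():
        flags[pos] = flags.get(pos, False) or bool(row.get("significant", False))
    return flags


def _esc(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


# ---------------------------------------------------------------------------
# Tabular export

_COLUMNS = [
    "locus", "tss_relative", "sample", "group",
    "proportion", "level", "qc", "p_value", "significant",
]


def export_profile(profile: LocusProfile, path: str | Path) -> pd.DataFrame:
    """Write a locus profile as a long-format TSV (proportions at 4 decimals)."""
    stats = profile.stats
    rows = []
    for pos in profile.positions:
        p_value = np.nan
        significant = False
        if stats is not None and pos in stats.index:
            srow = stats.loc[[pos]].iloc[0]
            p_value = srow["p_value"]
            significant = bool(srow["significant"])
        for sample in profile.samples:
            prop = profile.proportions.loc[pos, sample]
            level = profile.levels.loc[pos, sample]
            rows.append(
                {
                    "locus": profile.name,
                    "tss_relative": pos,
                    "sample": sample,
                    "group": profile.groups.get(sample, "all"),
                    "proportion": "" if math.isnan(prop) else f"{prop:.4f}",
                    "level": "" if (isinstance(level, float) and math.isnan(level)) else int(level),
                    "qc": profile.status.loc[pos, sample],
                    "p_value": "" if math.isnan(p_value) else f"{p_value:.6g}",
                    "significant": int(significant),
                }
            )
    table = pd.DataFrame(rows, columns=_COLUMNS)
    table.to_csv(path, sep="\t", index=False)
    return table


def import_profile(path: str | Path) -> LocusProfile:
    """Rebuild a LocusProfile (matrices + groups + flags) from an exported TSV."""
    raw = pd.read_csv(path, sep="\t", dtype={"qc": str})
    if list(raw.columns) != _COLUMNS:
        raise ValueError(f"unexpected profile TSV columns: {list(raw.columns)}")
    loci = raw["locus"].unique()
    if len(loci) != 1:
        raise ValueError("profile TSV must contain exactly one locus")
    proportions = raw.pivot(index="tss_relative", columns="sample", values="proportion")
    levels = raw.pivot(index="tss_relative", columns="sample", values="level")
    status = raw.pivot(index="tss_relative", columns="sample", values="qc")
    order = raw["sample"].unique()  # keep export column order
    groups = dict(raw[["sample", "group"]].drop_duplicates().itertuples(index=False))
    stats = None
    per_site = raw.drop_duplicates("tss_relative").set_index("tss_relative")
    if per_site["p_value"].notna().any():
        stats = per_site[["p_value", "significant"]].copy()
        stats["significant"] = stats["significant"].astype(bool)
    return LocusProfile(
        locus=str(loci[0]),
        proportions=proportions[order].astype(float),
        levels=levels[order].astype(float),
        status=status[order],
        groups=groups,
        stats=stats,
    )


def export_profile_bed(profile: LocusProfile, path: str | Path) -> None:
    """BED export of CpG positions with the per-site median level as score.

    Requires the profile to carry a ReferenceLocus with a genomic anchor.
    """
    if not isinstance(profile.locus, ReferenceLocus):
        raise ConfigurationError("BED export needs the reference locus, not a bare name")
    scores = [
        int(v) if not math.isnan(v) else 0
        for v in profile.levels.median(axis=1).to_numpy()
    ]
    write_bed(cpg_sites_to_bed(profile.locus, scores), path)
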