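"""Reference loci, CpG enumeration and in-silico bisulphite conversion.

Direct bisulphite Sanger sequencing reads the PCR product of converted DNA.
On the top strand every unmethylated cytosine has become thymine while
5-methylcytosines remain cytosines, so with a forward sequencing primer a CpG
cytosine is read as a C/T mixture; with a reverse primer the read is the
reverse complement of the converted top strand and the same site is read as a
G/A mixture.  This module builds the *expected* read for either primer
orientation, with IUPAC ambiguity codes (Y = C/T, R = G/A) at CpG-derived
positions, and enumerates CpG sites in TSS-relative coordinates.

Coordinates are 0-based; ``tss_relative = locus_position - tss_offset`` so the
first base at/downstream of the TSS is 0 and upstream positions are negative.
Only the top-strand CpG cytosine is profiled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

FORWARD = "forward-primer"
REVERSE = "reverse-primer"
ORIENTATIONS = (FORWARD, REVERSE)

_COMPLEMENT = str.maketrans("ACGTYR", "TGCARY")


class InputFormatError(ValueError):
    """Raised when a reference sequence or config does not meet its contract."""


class ConfigurationError(ValueError):
    """Raised for invalid run/locus configuration values."""


@dataclass(frozen=True)
class GenomicAnchor:
    """Genomic placement of a locus, for BED export."""

    chrom: str
    start: int  # 0-based genomic position of locus base 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InputFormatError("genomic anchor start must be >= 0")


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide, addressed by the position of its cytosine."""

    locus_position: int
    tss_relative: int
    context: str = "CG"


@dataclass(frozen=True)
class ReferenceLocus:
    """A locus sequence with an annotated transcription start site."""

    name: str
    sequence: str
    tss_offset: int
    genomic_anchor: Optional[GenomicAnchor] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGT")
        if bad:
            raise InputFormatError(
                f"locus {self.name!r}: sequence contains non-ACGT characters "
                f"{sorted(bad)} (ambiguity codes are rejected at load)"
            )
        if not 0 <= self.tss_offset <= len(seq):
            raise InputFormatError(
                f"locus {self.name!r}: tss_offset {self.tss_offset} outside "
                f"[0, {len(seq)}]"
            )

    @property
    def cpg_sites(self) -> tuple[CpGSite, ...]:
        return enumerate_cpg_sites(self)


@dataclass(frozen=True)
class ConvertedTemplate:
    """Expected read of fully converted, PCR-amplified DNA for one primer.

    ``expected_bases`` is over {A,C,G,T,Y,R}: Y marks a forward-read CpG
    cytosine (C if methylated, T if not), R the same site seen from the
    reverse primer (G if methylated, A if not).  ``cpg_read_positions`` maps
    each CpG site (by its locus position) to its position in the read;
    ``nonCpG_c_read_positions`` are the read positions of non-CpG reference
    cytosines, which should read T (forward) / A (reverse) when conversion is
    complete -- these drive the conversion QC.
    """

    locus_name: str
    orientation: str
    expected_bases: str
    cpg_read_positions: Mapping[int, int]
    nonCpG_c_read_positions: tuple[int, ...] = field(default=())

    def read_position(self, site: CpGSite) -> int:
        return self.cpg_read_positions[site.locus_position]


def enumerate_cpg_sites(locus: ReferenceLocus) -> tuple[CpGSite, ...]:
    """All CpG dinucleotides of a locus, ordered by position.

    Each site is addressed by the 0-based position of the C; ``tss_relative``
    is the signed distance to the TSS (negative = upstream).
    """
    seq = locus.sequence
    sites = []
    pos = seq.find("CG")
    while pos != -1:
        sites.append(CpGSite(pos, pos - locus.tss_offset))
        pos = seq.find("CG", pos + 1)
    return tuple(sites)


def convert_reference(locus: ReferenceLocus, orientation: str) -> ConvertedTemplate:
    """Expected base sequence after complete bisulphite conversion and PCR.

    Forward: every non-CpG C becomes T, every CpG C becomes Y.  Reverse: the
    read is the reverse complement of the converted top strand, so CpG-derived
    positions carry R and all other former-C complements become A.
    """
    if orientation not in ORIENTATIONS:
        raise ConfigurationError(
            f"unknown orientation {orientation!r}; expected one of {ORIENTATIONS}"
        )
    seq = locus.sequence
    n = len(seq)
    cpg_positions = {s.locus_position for s in enumerate_cpg_sites(locus)}
    forward = []
    non_cpg_c = []
    for i, base in enumerate(seq):
        if base == "C":
            if i in cpg_positions:
                forward.append("Y")
            else:
                forward.append("T")
                non_cpg_c.append(i)
        else:
            forward.append(base)
    fwd = "".join(forward)
    if orientation == FORWARD:
        return ConvertedTemplate(
            locus_name=locus.name,
            orientation=FORWARD,
            expected_bases=fwd,
            cpg_read_positions={p: p for p in sorted(cpg_positions)},
            nonCpG_c_read_positions=tuple(non_cpg_c),
        )
    rev = fwd.translate(_COMPLEMENT)[::-1]
    return ConvertedTemplate(
        locus_name=locus.name,
        orientation=REVERSE,
        expected_bases=rev,
        cpg_read_positions={p: n - 1 - p for p in sorted(cpg_positions)},
        nonCpG_c_read_positions=tuple(n - 1 - p for p in reversed(non_cpg_c)),
    )


# ---------------------------------------------------------------------------
# IO: FASTA + locus config, BED export


def load_loci(fasta_path: str | Path, config_path: str | Path) -> dict[str, ReferenceLocus]:
    """Load loci from a FASTA file and a TSV/YAML locus-config table.

    The config supplies per-locus ``tss_offset`` and optionally
    ``chrom``/``genomic_start``.  TSV needs columns ``name`` and
    ``tss_offset``; YAML is a mapping name -> {tss_offset, chrom, genomic_start}.
    """
    config = _read_locus_config(Path(config_path))
    loci: dict[str, ReferenceLocus] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in config:
            raise ConfigurationError(f"locus {rec.id!r} missing from locus config")
        entry = config[rec.id]
        anchor = None
        if entry.get("chrom") is not None:
            anchor = GenomicAnchor(str(entry["chrom"]), int(entry["genomic_start"]))
        loci[rec.id] = ReferenceLocus(
            name=rec.id,
            sequence=str(rec.seq),
            tss_offset=int(entry["tss_offset"]),
            genomic_anchor=anchor,
        )
    missing = set(config) - set(loci)
    if missing:
        raise ConfigurationError(f"config names loci absent from FASTA: {sorted(missing)}")
    return loci


def _read_locus_config(path: Path) -> dict[str, dict]:
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("YAML locus config must be a mapping of name -> fields")
        return {str(k): dict(v or {}) for k, v in raw.items()}
    out: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise ConfigurationError("TSV locus config needs a 'name' column")
        for row in reader:
            out[row["name"]] = {
                "tss_offset": int(row["tss_offset"]),
                "chrom": row.get("chrom") or None,
                "genomic_start": int(row["genomic_start"]) if row.get("genomic_start") else None,
            }
    return out


def cpg_sites_to_bed(
    locus: ReferenceLocus, scores: Optional[Sequence[int]] = None
) -> list[tuple[str, int, int, str, int]]:
    """CpG site coordinates as 0-based half-open BED rows.

    Requires a genomic anchor.  ``scores`` (one per site, e.g. methylation
    level) fills the BED score column; defaults to 0.
    """
    if locus.genomic_anchor is None:
        raise ConfigurationError(
            f"locus {locus.name!r} has no genomic anchor; BED export unsupported"
        )
    sites = enumerate_cpg_sites(locus)
    if scores is None:
        scores = [0] * len(sites)
    if len(scores) != len(sites):
        raise ConfigurationError("one BED score per CpG site required")
    anchor = locus.genomic_anchor
    return [
        (
            anchor.chrom,
            anchor.start + s.locus_position,
            anchor.start + s.locus_position + 1,
            f"{locus.name}_CpG_{s.tss_relative:+d}",
            int(score),
        )
        for s, score in zip(sites, scores)
    ]


def write_bed(rows: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
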