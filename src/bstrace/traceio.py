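"""Chromatogram trace records and their on-disk formats.

Two sources are supported: real ABIF (.ab1) chromatograms read through
Biopython, and a plain-JSON trace dialect used for simulated fixtures so that
the whole pipeline can be exercised without binary files.  The JSON dialect is

    {"schema": "bstrace-trace/1", "sample_id": ..., "orientation": ...,
     "channels": {"A": [...], "C": [...], "G": [...], "T": [...]},
     "peak_positions": [...], "called_bases": "...", "source": ...}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import ORIENTATIONS, ConfigurationError, InputFormatError

TRACE_SCHEMA = "bstrace-trace/1"
CHANNEL_ORDER = ("A", "C", "G", "T")


@dataclass
class TraceRecord:
    """A four-channel chromatogram with called bases and peak positions."""

    sample_id: str
    orientation: str
    channels: dict[str, np.ndarray]
    peak_positions: np.ndarray
    called_bases: str
    source: str = "simulated"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if set(self.channels) != set(CHANNEL_ORDER):
            raise InputFormatError("channels must be exactly A, C, G, T")
        self.channels = {b: np.asarray(self.channels[b], dtype=float) for b in CHANNEL_ORDER}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise InputFormatError("all four channel arrays must share one length")
        if any((v < 0).any() for v in self.channels.values()):
            raise InputFormatError("channel intensities must be non-negative")
        self.peak_positions = np.asarray(self.peak_positions, dtype=int)
        n = lengths.pop()
        if len(self.peak_positions):
            if (np.diff(self.peak_positions) <= 0).any():
                raise InputFormatError("peak_positions must be strictly increasing")
            if self.peak_positions[0] < 0 or self.peak_positions[-1] >= n:
                raise InputFormatError("peak_positions outside signal range")
        if len(self.called_bases) != len(self.peak_positions):
            raise InputFormatError("called_bases and peak_positions lengths differ")

    def __len__(self) -> int:
        return len(self.called_bases)


def write_trace_json(trace: TraceRecord, path: str | Path) -> None:
    payload = {
        "schema": TRACE_SCHEMA,
        "sample_id": trace.sample_id,
        "orientation": trace.orientation,
        "channels": {b: [round(float(x), 6) for x in trace.channels[b]] for b in CHANNEL_ORDER},
        "peak_positions": [int(p) for p in trace.peak_positions],
        "called_bases": trace.called_bases,
        "source": trace.source,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, separators=(",", ":"), sort_keys=True)
        fh.write("\n")


def read_trace_json(path: str | Path) -> TraceRecord:
    with open(path) as fh:
        payload = json.load(fh)
    schema = payload.get("schema")
    if schema != TRACE_SCHEMA:
        raise InputFormatError(f"unsupported trace schema {schema!r}")
    return TraceRecord(
        sample_id=payload["sample_id"],
        orientation=payload["orientation"],
        channels={b: payload["channels"][b] for b in CHANNEL_ORDER},
        peak_positions=payload["peak_positions"],
        called_bases=payload["called_bases"],
        source=payload.get("source", "simulated"),
    )


def read_abif(path: str | Path, orientation: str, sample_id: str | None = None) -> TraceRecord:
    """Read an ABIF (.ab1) chromatogram into a TraceRecord.

    Channel-to-base assignment follows the instrument's filter wheel order
    (FWO_ tag) over the raw DATA9-12 analyzed channels; peak positions come
    from PLOC and called bases from PBAS.
    """
    from Bio import SeqIO

    record = SeqIO.read(str(path), "abi")
    raw = record.annotations["abif_raw"]
    fwo = raw["FWO_1"]
    if isinstance(fwo, bytes):
        fwo = fwo.decode()
    data_tags = ["DATA9", "DATA10", "DATA11", "DATA12"]
    channels = {}
    for base, tag in zip(fwo, data_tags):
        channels[base] = np.asarray(raw[tag], dtype=float)
    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    called = str(record.seq)
    return TraceRecord(
        sample_id=sample_id or record.id or Path(path).stem,
        orientation=orientation,
        channels=channels,
        peak_positions=np.asarray(ploc, dtype=int),
        called_bases=called,
        source="abif",
    )
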