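import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bstrace as b

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


# 10 CpG sites plus 10 non-CpG cytosines (for conversion QC) over 70 bp, TSS
# in the middle: a desk-scale stand-in for a promoter amplicon.
PROMOTER_SEQ = "TCACGTT" * 10


@pytest.fixture
def locus10():
    return b.ReferenceLocus("promoter", PROMOTER_SEQ, tss_offset=35)


@pytest.fixture
def locus3():
    # three CpGs, a few non-CpG Cs for conversion QC
    return b.ReferenceLocus("small", "TTCACGTTCGATTCACGTT", tss_offset=4)


@pytest.fixture
def knockdown_config():
    """Control vs. two knockdown groups, +0.4 methylation at 7 of 10 CpGs."""

    def make(seed: int, noise_sd: float = 2.0) -> dict:
        effect = [0.4] * 7 + [0.0] * 3
        return {
            "seed": seed,
            "locus": {"name": "promoter", "sequence": PROMOTER_SEQ, "tss_offset": 25},
            "simulation": {
                "true_methylation": 0.2,
                "noise_sd": noise_sd,
                "n_replicates": 3,
                "group_effects": {"control": 0.0, "sh1": effect, "sh4": effect},
            },
            "stats": {"mode": "pooled", "control": "control", "alpha": 0.05},
        }

    return make


def make_flat_trace(heights_by_channel, orientation=b.FORWARD, spacing=12):
    """Build a TraceRecord from explicit per-base channel peak heights.

    ``heights_by_channel`` is a list (one entry per base) of {channel: height}.
    Peaks are rectangles of the given height, so the measured height equals
    the specified one exactly.
    """
    n = len(heights_by_channel)
    length = spacing * (n + 1)
    channels = {c: np.zeros(length) for c in "ACGT"}
    centers = spacing * (np.arange(n) + 1)
    called = []
    for i, heights in enumerate(heights_by_channel):
        for ch, h in heights.items():
            channels[ch][centers[i]] = h
        called.append(max(heights, key=heights.get) if heights else "N")
    return b.TraceRecord(
        sample_id="manual",
        orientation=orientation,
        channels=channels,
        peak_positions=centers,
        called_bases="".join(called),
    )
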