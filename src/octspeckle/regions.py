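"""Region vocabulary shared by the simulator, feature extraction and classifiers.

The six region types correspond to the materials of a tissue-mimicking
phantom used for OCT lymphography/neurography development: air above the
sample, the deep low-SNR noise floor, dyed water (lymph analog) inside a
PTFE micro-tube, a transparent solid rod (nerve analog, e.g. fishing line),
the semi-transparent PTFE tube wall (vessel-wall analog), and the scattering
Intralipid-gelatin background (tissue analog).
"""

from __future__ import annotations

from enum import IntEnum

__all__ = ["Region", "UNASSIGNED", "REGION_SHORT_NAMES"]

#: Label value for voxels not assigned to any region (never produced by the
#: phantom generator, which labels every voxel, but reserved for user maps).
UNASSIGNED = -1


class Region(IntEnum):
    """Integer labels for the six phantom region types."""

    AIR = 0
    NOISE = 1
    DYED_WATER = 2
    TRANSPARENT_SOLID = 3
    SEMI_TRANSPARENT_SOLID = 4
    INTRALIPID = 5


#: Conventional short names (as used in figures/tables of OCT phantom work).
REGION_SHORT_NAMES = {
    Region.AIR: "Ar",
    Region.NOISE: "No",
    Region.DYED_WATER: "dW",
    Region.TRANSPARENT_SOLID: "tS",
    Region.SEMI_TRANSPARENT_SOLID: "stS",
    Region.INTRALIPID: "IL",
}
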