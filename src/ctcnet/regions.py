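"""Region-of-interest definitions for the a-priori networks.

The primary network is the bilateral cerebello-thalamo-cortical (CTC)
circuit: cerebellar Crus I/II, thalamus, dorsolateral prefrontal cortex
(DLPFC), and precuneus, left and right.  A bilateral language network
(Brodmann areas 40, 44, 45) with comparatively low glucocorticoid-receptor
density serves as a control comparison.

Region identity here is purely a label: the package consumes already
extracted ROI time courses and never touches voxel data.
"""

from __future__ import annotations

CTC_REGIONS: list[str] = [
    "cerebellum_L",
    "cerebellum_R",
    "thalamus_L",
    "thalamus_R",
    "dlpfc_L",
    "dlpfc_R",
    "precuneus_L",
    "precuneus_R",
]

LANGUAGE_REGIONS: list[str] = [
    "ba40_L",
    "ba40_R",
    "ba44_L",
    "ba44_R",
    "ba45_L",
    "ba45_R",
]

#: Anatomical module partition of the CTC network (node -> module).
CTC_PARTITION: dict[str, str] = {
    "cerebellum_L": "cerebellar",
    "cerebellum_R": "cerebellar",
    "thalamus_L": "thalamic",
    "thalamus_R": "thalamic",
    "dlpfc_L": "frontal",
    "dlpfc_R": "frontal",
    "precuneus_L": "parietal",
    "precuneus_R": "parietal",
}

#: Alternative partition by hemisphere, for left/right subnetwork analyses.
HEMISPHERE_PARTITION: dict[str, str] = {
    r: ("left" if r.endswith("_L") else "right") for r in CTC_REGIONS
}

LANGUAGE_PARTITION: dict[str, str] = {
    "ba40_L": "parietal",
    "ba40_R": "parietal",
    "ba44_L": "frontal",
    "ba44_R": "frontal",
    "ba45_L": "frontal",
    "ba45_R": "frontal",
}

NETWORKS: dict[str, dict] = {
    "ctc": {"regions": CTC_REGIONS, "partition": CTC_PARTITION},
    "language": {"regions": LANGUAGE_REGIONS, "partition": LANGUAGE_PARTITION},
}
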