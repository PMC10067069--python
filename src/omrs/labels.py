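"""Tissue class labels and the integer mask convention shared by all modules.

Masks are single-channel uint8 rasters.  The four classifier classes occupy
0–3 in a fixed order (which is also the probability-vector order and the
argmax tie-break order); 255 marks annotated technical artifacts that are
excluded from patch labelling.
"""

from __future__ import annotations

BACKGROUND = 0
CONNECTIVE = 1
NONDYS_EPI = 2
TUMOR_EPI = 3
ARTIFACT_EXCLUDE = 255

#: Fixed class order: probability vectors, confusion matrices and argmax
#: tie-breaking all follow this order.
CLASS_ORDER = (BACKGROUND, CONNECTIVE, NONDYS_EPI, TUMOR_EPI)

CLASS_NAMES = {
    BACKGROUND: "background",
    CONNECTIVE: "connective",
    NONDYS_EPI: "nondys_epi",
    TUMOR_EPI: "tumor_epi",
    ARTIFACT_EXCLUDE: "artifact",
}

NAME_TO_CLASS = {v: k for k, v in CLASS_NAMES.items()}

#: The two classes collapsed into "epithelium" when analysing OL slides.
EPITHELIUM_CLASSES = (NONDYS_EPI, TUMOR_EPI)

#: Heatmap rendering palette: yellow tumor epithelium, green nondysplastic
#: epithelium, blue connective tissue, purple white background.
PALETTE = {
    TUMOR_EPI: (235, 200, 40),
    NONDYS_EPI: (70, 170, 80),
    CONNECTIVE: (70, 110, 205),
    BACKGROUND: (140, 80, 175),
}

#: Grey used for heatmap cells outside every class (e.g. masked-out cells).
PALETTE_ABSENT = (220, 220, 220)
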