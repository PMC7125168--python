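"""Region labels for the 90-region Automated Anatomical Labelling (AAL) atlas.

The 90 cerebral regions (45 bilateral pairs, cerebellum excluded) in the
standard AAL ordering — left/right interleaved — using the dotted naming
convention common in connectomics reports (e.g. ``Frontal.Mid.R``).
"""

from __future__ import annotations

_BILATERAL = [
    "Precentral",
    "Frontal.Sup",
    "Frontal.Sup.Orb",
    "Frontal.Mid",
    "Frontal.Mid.Orb",
    "Frontal.Inf.Oper",
    "Frontal.Inf.Tri",
    "Frontal.Inf.Orb",
    "Rolandic.Oper",
    "Supp.Motor.Area",
    "Olfactory",
    "Frontal.Sup.Medial",
    "Frontal.Med.Orb",
    "Rectus",
    "Insula",
    "Cingulum.Ant",
    "Cingulum.Mid",
    "Cingulum.Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital.Sup",
    "Occipital.Mid",
    "Occipital.Inf",
    "Fusiform",
    "Postcentral",
    "Parietal.Sup",
    "Parietal.Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral.Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal.Sup",
    "Temporal.Pole.Sup",
    "Temporal.Mid",
    "Temporal.Pole.Mid",
    "Temporal.Inf",
]

#: The 90 AAL region labels, left/right interleaved (odd = left, even = right).
AAL90_REGIONS: tuple[str, ...] = tuple(
    f"{base}.{side}" for base in _BILATERAL for side in ("L", "R")
)

assert len(AAL90_REGIONS) == 90
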