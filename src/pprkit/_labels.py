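"""Region label sets for the 86-region Desikan-Killiany-style parcellation.

68 cortical labels (34 per hemisphere) plus 18 subcortical labels
(9 per hemisphere). Labels use a uniform ``{lh,rh}_{structure}`` scheme.
"""

from __future__ import annotations

_DK_CORTICAL = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
]

_SUBCORTICAL = [
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "ventraldc",
    "cerebellum",
]


def dk86_labels() -> list[str]:
    """Ordered 86-region label list: cortical lh, cortical rh, subcortical lh/rh."""
    labels = [f"lh_{r}" for r in _DK_CORTICAL]
    labels += [f"rh_{r}" for r in _DK_CORTICAL]
    for r in _SUBCORTICAL:
        labels += [f"lh_{r}", f"rh_{r}"]
    return labels


def generic_labels(n: int) -> list[str]:
    """Placeholder labels region_000 ... region_{n-1} for non-atlas graphs."""
    width = max(3, len(str(n - 1)))
    return [f"region_{i:0{width}d}" for i in range(n)]
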