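"""AAL parcellation labels and hemisphere/lobe bookkeeping.

The atlas splits the gray matter into 45 anatomical regions per hemisphere
(90 regions in total).  Throughout the package regions are ordered with the
two hemispheres interleaved (``PreCG.L, PreCG.R, SFGdor.L, ...``), so the
homotopic partner of region ``2i`` is region ``2i + 1``.
"""

from __future__ import annotations

#: 45 region abbreviations, grouped by lobe in atlas order.
AAL_BASE: tuple[str, ...] = (
    # frontal (16)
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBmed", "REC", "ACG", "MCG",
    # parietal (8)
    "PCG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    # temporal (10)
    "HIP", "PHG", "AMYG", "FFG", "HES", "STG", "TPOsup", "MTG", "TPOmid", "ITG",
    # occipital (6)
    "CAL", "CUN", "LING", "SOG", "MOG", "IOG",
    # subcortical (5)
    "CAU", "PUT", "PAL", "INS", "THA",
)

#: lobe name -> number of base regions, in the order of AAL_BASE.
LOBE_SIZES: tuple[tuple[str, int], ...] = (
    ("frontal", 16),
    ("parietal", 8),
    ("temporal", 10),
    ("occipital", 6),
    ("subcortical", 5),
)

HEMISPHERES = ("L", "R")


def region_labels(n_regions: int = 90) -> list[str]:
    """Region column labels, hemispheres interleaved (``PreCG.L, PreCG.R, ...``).

    ``n_regions`` must be even and at most 90; smaller (down-scaled) parcellations
    take the first ``n_regions // 2`` base regions.
    """
    if n_regions % 2 != 0 or not 2 <= n_regions <= 2 * len(AAL_BASE):
        raise ValueError(f"n_regions must be even and in [2, 90], got {n_regions}")
    return [f"{base}.{h}" for base in AAL_BASE[: n_regions // 2] for h in HEMISPHERES]


def homotopic_pairs(n_regions: int = 90) -> list[tuple[int, int]]:
    """Index pairs of left/right homologues under the interleaved ordering."""
    return [(2 * i, 2 * i + 1) for i in range(n_regions // 2)]


def lobe_blocks(n_regions: int = 90) -> dict[str, list[int]]:
    """Map lobe name -> full-region indices (both hemispheres) within n_regions."""
    blocks: dict[str, list[int]] = {}
    start = 0
    for lobe, size in LOBE_SIZES:
        idx = [
            2 * b + h
            for b in range(start, start + size)
            for h in (0, 1)
            if 2 * b + h < n_regions
        ]
        if idx:
            blocks[lobe] = idx
        start += size
    return blocks
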