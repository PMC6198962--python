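"""Bundled reference chlorotype frequency tables for the Big-Bracted
dogwood collections (wild *Cornus florida*, *C. florida* cultivars,
*C. kousa* cultivars, and a mixed group of other *Cornus* species), as
published for the 4-site and 12-site panels, plus reconstruction of
per-sample datasets from those printed percentages.

Percentages are the printed integer values; group sizes are the
collection sizes they refer to. ``reconstructed_dataset`` turns a
percentage column back into individuals via half-up rounding with
largest-remainder correction, which is the closest integer realisation
of a table printed at integer precision.
"""

from __future__ import annotations

import pandas as pd

from .panel import FOUR_SITE_PANEL, GroupedDataset, TWELVE_SITE_PANEL
from .simulate import reconstruct_counts_from_percentages

__all__ = [
    "GROUP_SIZES",
    "FOUR_SITE_PERCENT",
    "TWELVE_SITE_PERCENT",
    "reconstructed_dataset",
    "four_site_node_frequencies",
]

GROUP_SIZES = {
    "wild_florida": 225,
    "florida_cultivars": 91,
    "kousa_cultivars": 109,
    "other_cornus": 32,
}

#: 4-site chlorotype frequencies (%) per collection. Dashes in the source
#: table are zeros here. Wild-florida percentages sum to 96 and the
#: cultivar columns to 99/100 because the source prints integers.
FOUR_SITE_PERCENT: dict[str, dict[str, float]] = {
    "wild_florida": {"0001": 1, "0011": 17, "0101": 46, "0111": 24, "1100": 1, "1110": 7},
    "florida_cultivars": {"0011": 1, "0101": 13, "0111": 82, "1110": 3},
    "kousa_cultivars": {"1110": 100},
    "other_cornus": {"0111": 6, "1101": 66, "1111": 28},
}

#: 12-site chlorotype frequencies (%); determined only for the two
#: cultivar collections.
TWELVE_SITE_PERCENT: dict[str, dict[str, float]] = {
    "florida_cultivars": {
        "001100111111": 1,
        "010100111111": 12,
        "010101111111": 1,
        "011100011111": 1,
        "011100111101": 1,
        "011100111111": 80,
        "111010111111": 3,
    },
    "kousa_cultivars": {
        "111010000000": 2,
        "111010000111": 1,
        "111011000000": 51,
        "111011000001": 19,
        "111011001010": 1,
        "111011010000": 13,
        "111011010001": 10,
        "111011110000": 2,
        "111011111111": 1,
    },
}

_TABLES = {"4-site": (FOUR_SITE_PERCENT, FOUR_SITE_PANEL), "12-site": (TWELVE_SITE_PERCENT, TWELVE_SITE_PANEL)}


def reconstructed_dataset(
    panel_name: str = "12-site",
    groups: tuple[str, ...] = ("florida_cultivars", "kousa_cultivars"),
) -> GroupedDataset:
    """Per-sample :class:`GroupedDataset` reconstructed from the printed
    percentage tables: ``round(pct * n / 100)`` copies of each chlorotype
    per group (largest-remainder corrected when rounding does not hit the
    group size exactly)."""
    table, _ = _TABLES[panel_name]
    samples: list[tuple[str, str, str]] = []
    for group in groups:
        pct = table[group]
        n = GROUP_SIZES[group]
        counts, _corrected = reconstruct_counts_from_percentages(list(pct.values()), n)
        i = 0
        for chlorotype, c in zip(pct, counts):
            for _ in range(c):
                samples.append((f"{group}_{i:04d}", group, chlorotype))
                i += 1
    return GroupedDataset(samples, list(groups))


def four_site_node_frequencies() -> dict[str, int]:
    """Total reconstructed count of every 4-site chlorotype across all
    four collections (node sizes for the 4-site network).

    Plain half-up rounding per cell, no forcing to the group size: the
    wild-collection percentages sum to 96, and the unreported remainder
    is left out rather than redistributed."""
    totals: dict[str, int] = {}
    for group, pct in FOUR_SITE_PERCENT.items():
        n = GROUP_SIZES[group]
        for chlorotype, p in pct.items():
            totals[chlorotype] = totals.get(chlorotype, 0) + int(p * n / 100.0 + 0.5)
    return dict(sorted(totals.items()))


def contingency_table(dataset: GroupedDataset) -> pd.DataFrame:
    """Chlorotype x group count table of a dataset (resolved samples)."""
    kept = [s for s in dataset.samples if "?" not in s[2]]
    types = sorted({c for _, _, c in kept})
    tab = pd.DataFrame(0, index=types, columns=dataset.groups, dtype=int)
    for _, g, c in kept:
        tab.loc[c, g] += 1
    return tab
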