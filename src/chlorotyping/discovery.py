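"""CAPS site discovery: panel extension from aligned region sequences.

A nucleotide substitution is *analytically informative* when it creates
or abolishes a restriction site: per enzyme, each ungapped sequence is
scanned for recognition sites and the hit positions are projected onto
alignment coordinates (a motif interrupted by an alignment gap is still
scanned on the real molecule and projected by its first base's column).
Every alignment coordinate at which site presence differs between at
least one pair of samples becomes a candidate diagnostic site carrying
the sample bipartition it induces. Indel columns are reported separately
and are not used as diagnostic sites by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .enzymes import Enzyme, scan_recognition_sites
from .io import column_map, ungap
from .panel import ChlorotypePanel, DiagnosticSite

__all__ = [
    "PolymorphicColumn",
    "CandidateSite",
    "find_polymorphic_columns",
    "discover_informative_digests",
    "select_minimal_panel",
    "variable_site_proportion",
]


@dataclass(frozen=True)
class PolymorphicColumn:
    column: int
    symbols: tuple[str, ...]       # distinct non-gap symbols observed
    has_gap: bool                  # indel column


@dataclass(frozen=True)
class CandidateSite:
    """A discovered diagnostic site and the presence partition it induces
    (one '0'/'1' per sample, in input order)."""

    region_id: str
    enzyme: str
    alignment_column: int
    partition: str

    def as_diagnostic_site(self) -> DiagnosticSite:
        return DiagnosticSite(self.region_id, self.enzyme, alignment_column=self.alignment_column)

    def splits(self, i: int, j: int) -> bool:
        return self.partition[i] != self.partition[j]


def _check_aligned(alignment: Mapping[str, str]) -> int:
    widths = {len(s) for s in alignment.values()}
    if len(widths) != 1:
        raise ValueError(f"ragged alignment: widths {sorted(widths)}")
    return widths.pop()


def find_polymorphic_columns(alignment: Mapping[str, str]) -> list[PolymorphicColumn]:
    """Columns with >=2 distinct non-gap symbols, plus indel flags."""
    if len(alignment) < 2:
        raise ValueError("alignment needs at least two sequences")
    width = _check_aligned(alignment)
    rows = [s.upper() for s in alignment.values()]
    out = []
    for col in range(width):
        symbols = {r[col] for r in rows}
        has_gap = "-" in symbols
        residues = tuple(sorted(symbols - {"-", "N"}))
        if len(residues) >= 2:
            out.append(PolymorphicColumn(col, residues, has_gap))
    return out


def discover_informative_digests(
    alignment: Mapping[str, str],
    catalog: Mapping[str, Enzyme] | Sequence[Enzyme],
    region_id: str = "region",
    exclude: ChlorotypePanel | Sequence[DiagnosticSite] = (),
    n_policy: str = "conservative",
) -> list[CandidateSite]:
    """Alignment coordinates where recognition-site presence differs
    between samples, for every enzyme of the catalog.

    ``exclude`` removes already-used panel positions: a site with a known
    alignment column excludes that exact (region, enzyme, column); a
    site without one excludes every column of that (region, enzyme).
    """
    _check_aligned(alignment)
    enzymes = list(catalog.values()) if isinstance(catalog, Mapping) else list(catalog)
    if not enzymes:
        raise ValueError("empty enzyme catalog")
    sample_ids = list(alignment)

    excl_sites = exclude.sites if isinstance(exclude, ChlorotypePanel) else tuple(exclude)
    excluded_exact = {
        (s.region_id, s.enzyme, s.alignment_column)
        for s in excl_sites
        if s.alignment_column is not None
    }
    excluded_enzyme = {
        (s.region_id, s.enzyme) for s in excl_sites if s.alignment_column is None
    }

    found: list[CandidateSite] = []
    for enzyme in enzymes:
        if (region_id, enzyme.name) in excluded_enzyme:
            continue
        start_cols: dict[str, set[int]] = {}
        for sid in sample_ids:
            row = alignment[sid].upper()
            cols = column_map(row)
            start_cols[sid] = {
                cols[h.position]
                for h in scan_recognition_sites(ungap(row), enzyme, n_policy)
            }
        all_cols = sorted(set().union(*start_cols.values())) if start_cols else []
        for col in all_cols:
            if (region_id, enzyme.name, col) in excluded_exact:
                continue
            presence = "".join("1" if col in start_cols[sid] else "0" for sid in sample_ids)
            if "0" in presence and "1" in presence:
                found.append(CandidateSite(region_id, enzyme.name, col, presence))
    found.sort(key=lambda s: (s.region_id, s.enzyme, s.alignment_column))
    return found


def select_minimal_panel(
    sites: Sequence[CandidateSite], n_samples: int, name: str = "minimal"
) -> ChlorotypePanel:
    """Greedy set cover: repeatedly add the site splitting the most
    still-unsplit distinguishable sample pairs, until every pair the full
    site set distinguishes is split. Ties break lexicographically by
    (region, enzyme, column)."""
    pairs = [(i, j) for i in range(n_samples) for j in range(i + 1, n_samples)]
    target = {p for p in pairs if any(s.splits(*p) for s in sites)}
    chosen: list[CandidateSite] = []
    remaining = set(target)
    pool = sorted(sites, key=lambda s: (s.region_id, s.enzyme, s.alignment_column))
    while remaining:
        # pool is lexicographically sorted, so a strict improvement rule
        # implements the (region, enzyme, column) tie-break
        best, best_gain = None, -1
        for s in pool:
            gain_count = sum(s.splits(*p) for p in remaining)
            if gain_count > best_gain:
                best, best_gain = s, gain_count
        if best is None or best_gain <= 0:
            break
        gain = {p for p in remaining if best.splits(*p)}
        chosen.append(best)
        pool.remove(best)
        remaining -= gain
    return ChlorotypePanel(name, tuple(s.as_diagnostic_site() for s in chosen))


def variable_site_proportion(alignment: Mapping[str, str]) -> tuple[float, int]:
    """(percentage of polymorphic columns, alignment length)."""
    width = _check_aligned(alignment)
    if width == 0:
        raise ValueError("empty alignment")
    n_var = len(find_polymorphic_columns(alignment))
    return 100.0 * n_var / width, width
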