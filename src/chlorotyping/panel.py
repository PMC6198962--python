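"""Chlorotype panels and typing: digests -> ordered binary strings.

A *chlorotype* is the ordered string of restriction-digest outcomes over
a panel of region x enzyme diagnostic sites: ``1`` for a digested PCR
product, ``0`` for no digestion, a lower-case letter for a novel/complex
fragment pattern, and ``?`` for an inconclusive call. The shipped
4-site panel is, in order, cpDNA01dAcuI, cpDNA02dTaqI, cpDNA02dTsp45I,
cpDNA03dSwaI; the 12-site panel appends cpDNA01dHpy188I, cpDNA01dMseI,
cpDNA01dMspI, cpDNA01dTaqI, cpDNA02dHpy188I, cpDNA03dAluI, cpDNA03dApoI,
cpDNA03dMmeI. On the 4-site panel the named types are H1="0101",
H2="0011", H3="1110", H4="0111".
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enzymes import Enzyme, scan_recognition_sites
from .io import column_map, ungap

__all__ = [
    "DiagnosticSite",
    "ChlorotypePanel",
    "DigestCall",
    "GroupedDataset",
    "FrequencyTable",
    "FOUR_SITE_PANEL",
    "TWELVE_SITE_PANEL",
    "HAPLOTYPE_ALIASES",
    "call_digest_state",
    "encode_chlorotype",
    "type_alignments",
    "tabulate_frequencies",
    "read_digest_table",
    "write_digest_table",
]

#: Named 4-site chlorotypes of wild flowering dogwood.
HAPLOTYPE_ALIASES = {"H1": "0101", "H2": "0011", "H3": "1110", "H4": "0111"}

_NOVEL_SYMBOLS = string.ascii_lowercase
_VALID_CALLS = frozenset("01?") | set(_NOVEL_SYMBOLS)


@dataclass(frozen=True)
class DiagnosticSite:
    """One panel position: a region x enzyme digest, optionally anchored
    to a 0-based column of the region's reference alignment."""

    region_id: str
    enzyme: str
    panel_index: int = 0
    alignment_column: int | None = None

    @property
    def key(self) -> str:
        return f"{self.region_id}d{self.enzyme}"


@dataclass(frozen=True)
class ChlorotypePanel:
    name: str
    sites: tuple[DiagnosticSite, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sites",
            tuple(replace(s, panel_index=i) for i, s in enumerate(self.sites)),
        )

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def keys(self) -> list[str]:
        return [s.key for s in self.sites]


def _panel(name: str, pairs: Sequence[tuple[str, str]]) -> ChlorotypePanel:
    return ChlorotypePanel(name, tuple(DiagnosticSite(r, e) for r, e in pairs))


FOUR_SITE_PANEL = _panel(
    "4-site",
    [("cpDNA01", "AcuI"), ("cpDNA02", "TaqI"), ("cpDNA02", "Tsp45I"), ("cpDNA03", "SwaI")],
)

TWELVE_SITE_PANEL = _panel(
    "12-site",
    [
        ("cpDNA01", "AcuI"),
        ("cpDNA02", "TaqI"),
        ("cpDNA02", "Tsp45I"),
        ("cpDNA03", "SwaI"),
        ("cpDNA01", "Hpy188I"),
        ("cpDNA01", "MseI"),
        ("cpDNA01", "MspI"),
        ("cpDNA01", "TaqI"),
        ("cpDNA02", "Hpy188I"),
        ("cpDNA03", "AluI"),
        ("cpDNA03", "ApoI"),
        ("cpDNA03", "MmeI"),
    ],
)


@dataclass(frozen=True)
class DigestCall:
    sample_id: str
    region_id: str
    enzyme: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in _VALID_CALLS:
            raise ValueError(f"invalid digest state {self.state!r}")


@dataclass
class GroupedDataset:
    """Samples with group labels and chlorotype strings."""

    samples: list[tuple[str, str, str]]  # (sample_id, group, chlorotype)
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            seen: dict[str, None] = {}
            for _, g, _ in self.samples:
                seen.setdefault(g)
            self.groups = list(seen)
        missing = {g for _, g, _ in self.samples} - set(self.groups)
        if missing:
            raise ValueError(f"samples reference undeclared groups: {sorted(missing)}")
        lengths = {len(c) for _, _, c in self.samples}
        if len(lengths) > 1:
            raise ValueError(f"heterogeneous chlorotype lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.samples)

    def complete(self) -> "GroupedDataset":
        """Samples whose chlorotype contains no ``?`` (used by all statistics)."""
        kept = [s for s in self.samples if "?" not in s[2]]
        return GroupedDataset(kept, [g for g in self.groups if any(s[1] == g for s in kept)])

    def chlorotypes(self) -> list[str]:
        return [c for _, _, c in self.samples]

    def labels(self) -> list[str]:
        return [g for _, g, _ in self.samples]


# ---------------------------------------------------------------------------
# Typing from aligned sequences


def _hit_column_intervals(aligned: str, enzyme: Enzyme, n_policy: str) -> list[tuple[int, int]]:
    """Recognition-site footprints of one aligned row, as closed column
    intervals. Scanning happens on the ungapped molecule; a motif that an
    alignment gap interrupts is still a real site and is projected back
    through the row's own gap pattern."""
    seq = ungap(aligned)
    cols = column_map(aligned)
    m = len(enzyme.recognition)
    return [
        (cols[h.position], cols[h.position + m - 1])
        for h in scan_recognition_sites(seq, enzyme, n_policy)
    ]


class _NovelSymbols:
    """Assign ``a, b, c, ...`` to unseen fragment patterns, stable in order
    of first appearance."""

    def __init__(self) -> None:
        self._bysite: dict[str, dict[frozenset[int], str]] = {}

    def get(self, site_key: str, pattern: frozenset[int]) -> str:
        table = self._bysite.setdefault(site_key, {})
        if pattern not in table:
            if len(table) >= len(_NOVEL_SYMBOLS):
                raise ValueError(f"too many novel patterns at {site_key}")
            table[pattern] = _NOVEL_SYMBOLS[len(table)]
        return table[pattern]


def call_digest_state(
    aligned_sample: str,
    site: DiagnosticSite,
    reference_alignment: Mapping[str, str],
    catalog: Mapping[str, Enzyme],
    sample_id: str = "",
    n_policy: str = "conservative",
    _symbols: _NovelSymbols | None = None,
) -> DigestCall:
    """Call one diagnostic site for one aligned sample row.

    ``1`` if a recognition-site footprint of the enzyme spans the
    diagnostic column; ``?`` if the sample is gapped or ambiguous at the
    column; ``0`` if the site is absent and the sample's remaining site
    set for the enzyme matches a reference pattern; otherwise a novel
    lower-case symbol.
    """
    if site.alignment_column is None:
        raise ValueError(f"site {site.key} has no alignment column; cannot type from sequences")
    enzyme = catalog[site.enzyme]
    col = site.alignment_column
    if not 0 <= col < len(aligned_sample):
        raise ValueError(f"column {col} outside alignment of width {len(aligned_sample)}")

    intervals = _hit_column_intervals(aligned_sample, enzyme, n_policy)
    if any(a <= col <= b for a, b in intervals):
        return DigestCall(sample_id, site.region_id, site.enzyme, "1")
    if aligned_sample[col] in "-N":
        return DigestCall(sample_id, site.region_id, site.enzyme, "?")

    rest = frozenset(a for a, b in intervals if not a <= col <= b)
    reference_rest = {
        frozenset(
            a
            for a, b in _hit_column_intervals(ref, enzyme, n_policy)
            if not a <= col <= b
        )
        for ref in reference_alignment.values()
    }
    if rest in reference_rest:
        return DigestCall(sample_id, site.region_id, site.enzyme, "0")
    symbols = _symbols if _symbols is not None else _NovelSymbols()
    return DigestCall(sample_id, site.region_id, site.enzyme, symbols.get(site.key, rest))


def encode_chlorotype(
    calls: Iterable[DigestCall], panel: ChlorotypePanel, sample_id: str = ""
) -> str:
    """Concatenate digest states in panel order; missing positions -> ``?``."""
    states: dict[str, str] = {}
    for call in calls:
        key = f"{call.region_id}d{call.enzyme}"
        if key in states and states[key] != call.state:
            raise ValueError(
                f"conflicting calls for sample {sample_id or call.sample_id!r} at {key}: "
                f"{states[key]!r} vs {call.state!r}"
            )
        states[key] = call.state
    return "".join(states.get(key, "?") for key in panel.keys)


def type_alignments(
    alignments: Mapping[str, Mapping[str, str]],
    panel: ChlorotypePanel,
    catalog: Mapping[str, Enzyme],
    groups: Mapping[str, str] | None = None,
    reference_ids: Sequence[str] | None = None,
    n_policy: str = "conservative",
) -> GroupedDataset:
    """Type every sample of ``alignments`` (``{region_id: {sample_id: row}}``)
    on ``panel`` and assemble a :class:`GroupedDataset`.

    Reference fragment patterns are taken from ``reference_ids`` (default:
    all samples), so a sample whose site set matches no reference pattern
    receives a novel symbol.
    """
    sample_ids: list[str] = []
    for rows in alignments.values():
        for sid in rows:
            if sid not in sample_ids:
                sample_ids.append(sid)

    symbols = _NovelSymbols()
    calls: dict[str, list[DigestCall]] = {sid: [] for sid in sample_ids}
    for site in panel.sites:
        rows = alignments.get(site.region_id)
        if rows is None:
            continue
        widths = {len(r) for r in rows.values()}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment for region {site.region_id}")
        reference = (
            rows if reference_ids is None else {k: rows[k] for k in reference_ids if k in rows}
        )
        for sid, row in rows.items():
            calls[sid].append(
                call_digest_state(
                    row, site, reference, catalog, sample_id=sid, n_policy=n_policy,
                    _symbols=symbols,
                )
            )

    samples = [
        (sid, groups.get(sid, "all") if groups else "all", encode_chlorotype(calls[sid], panel, sid))
        for sid in sample_ids
    ]
    return GroupedDataset(samples)


# ---------------------------------------------------------------------------
# Frequency tables


@dataclass
class FrequencyTable:
    """Per-group chlorotype counts and percentages.

    ``percent`` holds full precision; ``percent_rounded`` the integer
    display form. Samples containing ``?`` are excluded from both and
    counted in ``excluded``.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    percent_rounded: pd.DataFrame
    excluded: dict[str, int]

    def distinct_types(self, group: str) -> int:
        return int((self.counts[group] > 0).sum())


def tabulate_frequencies(dataset: GroupedDataset) -> FrequencyTable:
    if not dataset.samples:
        raise ValueError("empty dataset")
    excluded = {g: 0 for g in dataset.groups}
    for _, g, c in dataset.samples:
        if "?" in c:
            excluded[g] += 1
    kept = [s for s in dataset.samples if "?" not in s[2]]
    for g in dataset.groups:
        if not any(s[1] == g for s in kept):
            raise ValueError(f"group {g!r} has no resolved chlorotypes")
    types = sorted({c for _, _, c in kept})
    counts = pd.DataFrame(0, index=types, columns=dataset.groups, dtype=int)
    for _, g, c in kept:
        counts.loc[c, g] += 1
    percent = 100.0 * counts / counts.sum(axis=0)
    return FrequencyTable(counts, percent, percent.round(0).astype(int), excluded)


# ---------------------------------------------------------------------------
# Digest-call tables (TSV mirroring the lab scoring sheets)


def read_digest_table(
    path: str | Path, panel: ChlorotypePanel | None = None
) -> tuple[GroupedDataset, ChlorotypePanel]:
    """Read a per-sample digest-call TSV.

    Layout: columns ``sample_id``, ``group``, then one column per
    region x enzyme written ``<region>d<enzyme>`` in panel order. When a
    panel is supplied the file's columns are reordered to it; otherwise
    the file's column order defines the panel.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"digest table must have columns {sorted(required)}")
    site_cols = [c for c in df.columns if c not in required]
    file_sites = []
    for col in site_cols:
        region, _, enzyme = col.partition("d")
        if not enzyme:
            raise ValueError(f"column {col!r} is not of the form <region>d<enzyme>")
        file_sites.append(DiagnosticSite(region, enzyme))
    if panel is None:
        panel = ChlorotypePanel("from-file", tuple(file_sites))
        order = site_cols
    else:
        by_key = {f"{s.region_id}d{s.enzyme}": c for s, c in zip(file_sites, site_cols)}
        missing = [k for k in panel.keys if k not in by_key]
        if missing:
            raise ValueError(f"digest table lacks panel columns: {missing}")
        order = [by_key[k] for k in panel.keys]

    samples = []
    for i, row in df.iterrows():
        states = []
        for col in order:
            s = row[col]
            if s not in _VALID_CALLS:
                raise ValueError(f"unknown symbol {s!r} at row {i + 1}, column {col!r}")
            states.append(s)
        samples.append((row["sample_id"], row["group"], "".join(states)))
    return GroupedDataset(samples), panel


def write_digest_table(path: str | Path, dataset: GroupedDataset, panel: ChlorotypePanel) -> None:
    rows = [
        {"sample_id": sid, "group": g, **dict(zip(panel.keys, chlorotype))}
        for sid, g, chlorotype in dataset.samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "group", *panel.keys]).to_csv(
        path, sep="\t", index=False
    )
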