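"""Synthetic chlorotyping data with exactly controlled digest states.

The generator emulates the study design the analyses assume: a few
haplotype classes over three amplified chloroplast regions, differing by
point substitutions placed inside enzyme recognition sites, collected
into groups at specified chlorotype frequencies, with an optional rate
of inconclusive calls. Region lengths default to the alignment sizes of
the three cpDNA non-coding regions (1667/986/907 columns).

Sequences are built on one shared random backbone per region, so
haplotypes differ only at the diagnostic loci: the recognition motif of
the site's enzyme is present at the locus iff the haplotype's target
symbol is ``1``. Placement is verified by scanning and the backbone is
redrawn on collision (bounded retries), so digest states are controlled
exactly. Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .amplify import Region
from .enzymes import Enzyme, default_catalog, scan_recognition_sites
from .io import write_sequences
from .panel import ChlorotypePanel, DiagnosticSite, FOUR_SITE_PANEL, GroupedDataset

__all__ = [
    "SyntheticSpec",
    "HaplotypeSequences",
    "generate_haplotype_sequences",
    "generate_sample_collection",
    "reconstruct_counts_from_percentages",
]

DEFAULT_REGION_LENGTHS = [("cpDNA01", 1667), ("cpDNA02", 986), ("cpDNA03", 907)]

_BASES = "ACGT"


@dataclass
class SyntheticSpec:
    """Study-condition description for the generators."""

    haplotypes: list[tuple[str, str]]  # (name, target chlorotype)
    groups: list[tuple[str, int, dict[str, float]]]  # (label, size, hap freqs)
    panel: ChlorotypePanel = FOUR_SITE_PANEL
    regions: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_REGION_LENGTHS))
    missing_rate: float = 0.0
    seed: int = 0
    primer_length: int = 20

    def __post_init__(self) -> None:
        width = len(self.panel)
        for name, target in self.haplotypes:
            if len(target) != width:
                raise ValueError(
                    f"haplotype {name!r}: target length {len(target)} != panel size {width}"
                )
        names = [n for n, _ in self.haplotypes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate haplotype names")
        for label, size, freqs in self.groups:
            if size <= 0:
                raise ValueError(f"group {label!r}: size must be positive")
            unknown = set(freqs) - set(names)
            if unknown:
                raise ValueError(f"group {label!r}: unknown haplotypes {sorted(unknown)}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"group {label!r}: frequencies must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        region_ids = {r for r, _ in self.regions}
        needed = {s.region_id for s in self.panel.sites}
        if not needed <= region_ids:
            raise ValueError(f"panel regions missing from spec: {sorted(needed - region_ids)}")


@dataclass
class HaplotypeSequences:
    """Generated templates plus everything needed to type them back."""

    templates: dict[str, dict[str, str]]       # haplotype -> region -> template
    regions: dict[str, Region]                 # region -> primers/length
    panel: ChlorotypePanel                     # sites with alignment columns filled
    diagnostic_columns: dict[str, int]         # site key -> amplicon column

    def region_alignments(self) -> dict[str, dict[str, str]]:
        """Per-region 'alignments' (equal-length templates; no indels are
        simulated, so templates align column-for-column)."""
        out: dict[str, dict[str, str]] = {}
        for hap, by_region in self.templates.items():
            for region_id, seq in by_region.items():
                out.setdefault(region_id, {})[hap] = seq
        return out


def _concretize(motif: str, rng: np.random.Generator) -> str:
    from .enzymes import IUPAC

    return "".join(ch if ch in _BASES else rng.choice(sorted(IUPAC[ch])) for ch in motif)


def _spans_column(seq: str, enzyme: Enzyme, col: int) -> bool:
    m = len(enzyme.recognition)
    return any(h.position <= col <= h.position + m - 1 for h in scan_recognition_sites(seq, enzyme))


def _break_motif(instance: str, enzyme: Enzyme, rng: np.random.Generator) -> list[str]:
    """Candidate one-substitution variants of a concrete motif instance
    that no longer match the (possibly degenerate) motif."""
    from .enzymes import IUPAC

    out = []
    order = rng.permutation(len(instance))
    for pos in order:
        allowed = IUPAC[enzyme.recognition[pos]]
        for base in _BASES:
            if base != instance[pos] and base not in allowed:
                out.append(instance[:pos] + base + instance[pos + 1 :])
    return out


def generate_haplotype_sequences(
    spec: SyntheticSpec, catalog: Mapping[str, Enzyme] | None = None
) -> HaplotypeSequences:
    """Build per-haplotype, per-region templates realising the target
    chlorotypes (see module docstring)."""
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(spec.seed)
    panel_sites = spec.panel.sites
    by_region: dict[str, list[DiagnosticSite]] = {}
    for s in panel_sites:
        by_region.setdefault(s.region_id, []).append(s)

    region_enzymes = {
        rid: [catalog[s.enzyme] for s in sites] for rid, sites in by_region.items()
    }
    hap_names = [n for n, _ in spec.haplotypes]
    targets = dict(spec.haplotypes)

    templates: dict[str, dict[str, str]] = {n: {} for n in hap_names}
    regions: dict[str, Region] = {}
    diagnostic_columns: dict[str, int] = {}

    for region_id, length in spec.regions:
        sites = by_region.get(region_id, [])
        enzymes = [catalog[s.enzyme] for s in sites]
        max_motif = max((len(e.recognition) for e in enzymes), default=4)
        margin = max_motif + 10
        interior = length - 2 * spec.primer_length
        if sites and interior < (len(sites) + 1) * (max_motif + 2 * margin):
            raise ValueError(f"region {region_id}: length {length} too short for {len(sites)} sites")

        fwd = "".join(rng.choice(list(_BASES), spec.primer_length))
        rev_rc = "".join(rng.choice(list(_BASES), spec.primer_length))
        loci = [
            spec.primer_length + margin + k * (interior - 2 * margin) // max(len(sites), 1)
            for k in range(len(sites))
        ]

        for _attempt in range(200):
            backbone = fwd + "".join(rng.choice(list(_BASES), interior)) + rev_rc
            instances = [_concretize(e.recognition, rng) for e in enzymes]
            broken = [
                next(iter(_break_motif(inst, e, rng)), None)
                for inst, e in zip(instances, enzymes)
            ]
            if any(b is None for b in broken):
                continue
            built: dict[str, str] = {}
            ok = True
            for hap in hap_names:
                seq = list(backbone)
                for k, site in enumerate(sites):
                    piece = instances[k] if targets[hap][site.panel_index] == "1" else broken[k]
                    seq[loci[k] : loci[k] + len(piece)] = piece
                s = "".join(seq)
                for k, site in enumerate(sites):
                    want = targets[hap][site.panel_index] == "1"
                    if _spans_column(s, region_enzymes[region_id][k], loci[k]) != want:
                        ok = False
                        break
                if not ok:
                    break
                built[hap] = s
            if ok:
                break
        else:
            raise RuntimeError(f"region {region_id}: motif placement kept colliding")

        for hap in hap_names:
            templates[hap][region_id] = built[hap]
        total_len = spec.primer_length * 2 + interior
        regions[region_id] = Region(
            region_id,
            forward_primer=fwd,
            reverse_primer=_revcomp(rev_rc),
            expected_length_range=(total_len, total_len),
        )
        for k, site in enumerate(sites):
            diagnostic_columns[site.key] = loci[k]

    placed = tuple(
        DiagnosticSite(s.region_id, s.enzyme, alignment_column=diagnostic_columns.get(s.key))
        for s in panel_sites
    )
    return HaplotypeSequences(
        templates, regions, ChlorotypePanel(spec.panel.name, placed), diagnostic_columns
    )


def _revcomp(seq: str) -> str:
    from .enzymes import reverse_complement

    return reverse_complement(seq)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconstruct_counts_from_percentages(
    percentages: Sequence[float], n: int
) -> tuple[list[int], bool]:
    """Integer counts from printed percentages of a group of size ``n``.

    Per entry, ``round(pct * n / 100)``; if the rounded counts do not sum
    to ``n`` a largest-remainder correction is applied and flagged.
    Returns ``(counts, corrected)`` with input order preserved.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if any(p < 0 for p in percentages):
        raise ValueError("negative percentage")
    quotas = [p * n / 100.0 for p in percentages]
    counts = [_round_half_up(q) for q in quotas]
    corrected = False
    diff = n - sum(counts)
    if diff != 0:
        corrected = True
        remainders = sorted(
            range(len(counts)), key=lambda i: (quotas[i] - counts[i]), reverse=diff > 0
        )
        step = 1 if diff > 0 else -1
        i = 0
        while diff != 0 and i < 10 * len(counts):
            j = remainders[i % len(counts)]
            if counts[j] + step >= 0:
                counts[j] += step
                diff -= step
            i += 1
        if diff != 0:
            raise ValueError("cannot reconcile counts with group size")
    return counts, corrected


def generate_sample_collection(
    spec: SyntheticSpec,
    mode: str = "exact",
) -> tuple[GroupedDataset, dict[str, str]]:
    """Draw a grouped sample collection from the spec's frequencies.

    ``exact`` mode materialises ``round(freq * size)`` copies of each
    haplotype (an inconsistent spec is an error); ``multinomial`` mode
    draws counts from the frequency vector. ``?`` symbols are injected
    per call at ``missing_rate``. Returns the dataset plus the
    sample -> haplotype assignment (for sequence emission).
    """
    rng = np.random.default_rng(spec.seed + 1)
    targets = dict(spec.haplotypes)
    samples: list[tuple[str, str, str]] = []
    assignment: dict[str, str] = {}
    for label, size, freqs in spec.groups:
        names = list(freqs)
        if mode == "exact":
            counts = [_round_half_up(freqs[h] * size) for h in names]
            if sum(counts) != size:
                raise ValueError(
                    f"group {label!r}: frequencies x size give {sum(counts)} samples, not {size}"
                )
        elif mode == "multinomial":
            counts = list(rng.multinomial(size, [freqs[h] for h in names]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        i = 0
        for hap, c in zip(names, counts):
            for _ in range(c):
                sid = f"{label}_{i:04d}"
                i += 1
                chlorotype = targets[hap]
                if spec.missing_rate > 0:
                    chlorotype = "".join(
                        "?" if rng.random() < spec.missing_rate else ch for ch in chlorotype
                    )
                samples.append((sid, label, chlorotype))
                assignment[sid] = hap
    dataset = GroupedDataset(samples, [label for label, _, _ in spec.groups])
    return dataset, assignment


def write_collection_fasta(
    outdir: str | Path,
    dataset: GroupedDataset,
    assignment: Mapping[str, str],
    haplotype_sequences: HaplotypeSequences,
) -> list[Path]:
    """Emit one multi-FASTA per region for a generated collection."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for region_id in haplotype_sequences.regions:
        records = {
            sid: haplotype_sequences.templates[assignment[sid]][region_id]
            for sid, _, _ in dataset.samples
        }
        path = outdir / f"{region_id}.fasta"
        write_sequences(path, records)
        paths.append(path)
    return paths
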