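"""Restriction enzymes: IUPAC motif matching, site scanning, virtual digestion.

Coordinates are 0-based, half-open, on the top strand of the scanned
sequence. A recognition-site hit is the interval
``[position, position + len(motif))``; a cut coordinate is
``position + cut_offset`` for top-strand hits. For hits of a
non-palindromic motif found on the bottom strand the cut is mirrored,
``position + len(motif) - cut_offset``.

The default policy is a *conservative digest*: ``N`` in the template
matches no motif character, so a miscalled base can never invent a
restriction site. Pass ``n_policy="permissive"`` to let template ``N``
match anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import yaml

__all__ = [
    "Enzyme",
    "SiteHit",
    "iupac_match",
    "reverse_complement",
    "scan_recognition_sites",
    "digest_fragments",
    "default_catalog",
    "load_catalog",
]

# IUPAC nucleotide ambiguity codes -> set of concrete bases.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(motif_char: str, base: str, n_policy: str = "conservative") -> bool:
    """Does a template ``base`` satisfy a single IUPAC ``motif_char``?

    Template ``N`` matches nothing under the default conservative policy
    and everything under ``n_policy="permissive"``.
    """
    try:
        allowed = IUPAC[motif_char]
    except KeyError:
        raise ValueError(f"not an IUPAC code: {motif_char!r}") from None
    if base == "N":
        return n_policy == "permissive"
    if base not in "ACGT":
        raise ValueError(f"not a template base: {base!r}")
    return base in allowed


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme defined by its recognition motif.

    ``cut_offset`` is measured from the motif start on the top strand and
    may exceed the motif length for Type IIS downstream cutters (e.g.
    AcuI CTGAAG(16/14)); cut coordinates are clamped to the sequence when
    digesting.
    """

    name: str
    recognition: str
    cut_offset: int
    palindromic: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition motif")
        bad = set(self.recognition) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)}")
        if self.cut_offset < 0:
            raise ValueError(f"{self.name}: negative cut offset")
        # Palindromy is a property of the motif; recompute rather than trust.
        object.__setattr__(
            self, "palindromic", reverse_complement(self.recognition) == self.recognition
        )


@dataclass(frozen=True, order=True)
class SiteHit:
    """One recognition-site match: ``[position, position+len(motif))``."""

    position: int
    strand: str
    enzyme: str


def _matches_at(seq: str, motif: str, pos: int, n_policy: str) -> bool:
    for k, mc in enumerate(motif):
        base = seq[pos + k]
        if base == "N":
            if n_policy != "permissive":
                return False
            continue
        if base not in IUPAC[mc]:
            return False
    return True


def _scan_one_strand(seq: str, motif: str, n_policy: str) -> Iterator[int]:
    m = len(motif)
    for pos in range(len(seq) - m + 1):
        if _matches_at(seq, motif, pos, n_policy):
            yield pos


def scan_recognition_sites(
    sequence: str, enzyme: Enzyme, n_policy: str = "conservative"
) -> list[SiteHit]:
    """All motif matches on the top strand, plus bottom-strand matches for
    non-palindromic enzymes (reported at their top-strand footprint with
    strand ``-``). Sorted by position."""
    seq = sequence.upper()
    if "-" in seq:
        raise ValueError("sequence contains gaps; ungap before scanning")
    hits = [
        SiteHit(pos, "+", enzyme.name)
        for pos in _scan_one_strand(seq, enzyme.recognition, n_policy)
    ]
    if not enzyme.palindromic:
        rc_motif = reverse_complement(enzyme.recognition)
        plus = {h.position for h in hits}
        hits.extend(
            SiteHit(pos, "-", enzyme.name)
            for pos in _scan_one_strand(seq, rc_motif, n_policy)
            if pos not in plus
        )
    hits.sort()
    return hits


def cut_coordinates(sequence: str, enzyme: Enzyme, n_policy: str = "conservative") -> list[int]:
    """Distinct interior cut coordinates, clamped to the sequence bounds."""
    L = len(sequence)
    m = len(enzyme.recognition)
    coords = set()
    for hit in scan_recognition_sites(sequence, enzyme, n_policy):
        if hit.strand == "+":
            c = hit.position + enzyme.cut_offset
        else:
            c = hit.position + m - enzyme.cut_offset
        coords.add(min(max(c, 0), L))
    return sorted(c for c in coords if 0 < c < L)


def digest_fragments(
    sequence: str, enzyme: Enzyme, n_policy: str = "conservative"
) -> list[int]:
    """Fragment lengths (bp) of a complete digest, sorted ascending.

    Fragment lengths always sum to the sequence length; an uncut
    sequence yields the single fragment ``[L]``.
    """
    L = len(sequence)
    cuts = cut_coordinates(sequence, enzyme, n_policy)
    bounds = [0, *cuts, L]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


# Public REBASE recognition data for the shipped panel enzymes. The caret in
# the comment marks the top-strand cut encoded by cut_offset.
_DEFAULT_CATALOG_SPEC = [
    ("AcuI", "CTGAAG", 22),    # CTGAAG(16/14), Type IIS downstream cutter
    ("AluI", "AGCT", 2),       # AG^CT
    ("ApoI", "RAATTY", 1),     # R^AATTY
    ("Hpy188I", "TCNGA", 3),   # TCN^GA
    ("MmeI", "TCCRAC", 26),    # TCCRAC(20/18), Type IIS downstream cutter
    ("MseI", "TTAA", 1),       # T^TAA
    ("MspI", "CCGG", 1),       # C^CGG
    ("SwaI", "ATTTAAAT", 4),   # ATTT^AAAT
    ("TaqI", "TCGA", 1),       # T^CGA
    ("Tsp45I", "GTSAC", 0),    # ^GTSAC
]


def default_catalog() -> dict[str, Enzyme]:
    """The ten panel enzymes with public REBASE motifs, keyed by name."""
    return {name: Enzyme(name, motif, off) for name, motif, off in _DEFAULT_CATALOG_SPEC}


def load_catalog(path: str | Path) -> dict[str, Enzyme]:
    """Load an enzyme catalog from YAML.

    Layout::

        enzymes:
          - name: TaqI
            recognition: TCGA
            cut_offset: 1
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries: Iterable[dict] = doc["enzymes"] if isinstance(doc, dict) else doc
    catalog: dict[str, Enzyme] = {}
    for entry in entries:
        enz = Enzyme(entry["name"], entry["recognition"].upper(), int(entry["cut_offset"]))
        if enz.name in catalog:
            raise ValueError(f"duplicate enzyme {enz.name!r} in catalog")
        catalog[enz.name] = enz
    return catalog
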