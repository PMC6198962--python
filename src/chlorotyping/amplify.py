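"""Virtual PCR: extract the amplicon a primer pair would produce.

Primer matching is Hamming-only (no indels) with a configurable mismatch
budget, defaulting to one mismatch — near-exact matching is all routine
amplification requires. The amplicon runs from the start of the best
forward-primer footprint through the end of the reverse complement of
the best reverse-primer footprint, inclusive of both, and is reported
oriented with the forward primer at the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .enzymes import IUPAC, reverse_complement

__all__ = ["Region", "Amplicon", "PrimerNotFoundError", "extract_amplicon"]


@dataclass(frozen=True)
class Region:
    """A PCR-targeted locus: primer pair plus the expected product size."""

    id: str
    forward_primer: str
    reverse_primer: str
    expected_length_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError(f"region {self.id}: empty primer")
        if self.expected_length_range is not None:
            lo, hi = self.expected_length_range
            if not (0 < lo <= hi):
                raise ValueError(f"region {self.id}: bad length range {lo}..{hi}")


@dataclass(frozen=True)
class Amplicon:
    sample_id: str
    region_id: str
    sequence: str
    strand: str = "+"
    length_warning: bool = field(default=False)


class PrimerNotFoundError(ValueError):
    def __init__(self, primer: str, max_mismatch: int):
        self.primer = primer
        super().__init__(
            f"primer-not-found: {primer!r} has no match within {max_mismatch} mismatch(es)"
        )


def _mismatches(window: str, primer: str, budget: int) -> int:
    n = 0
    for base, code in zip(window, primer):
        if base == "N" or base not in IUPAC[code]:
            n += 1
            if n > budget:
                return n
    return n


def _best_match(template: str, primer: str, budget: int) -> tuple[int, int] | None:
    """(position, mismatches) of the leftmost best Hamming match, or None."""
    m = len(primer)
    best: tuple[int, int] | None = None
    for pos in range(len(template) - m + 1):
        mm = _mismatches(template[pos : pos + m], primer, budget)
        if mm <= budget and (best is None or mm < best[1]):
            best = (pos, mm)
            if mm == 0:
                break
    return best


def extract_amplicon(
    template: str,
    region: Region,
    sample_id: str = "",
    max_mismatch: int = 1,
) -> Amplicon:
    """Extract the virtual PCR product of ``region`` from ``template``.

    Both template orientations are tried; the reported amplicon always
    starts with the forward-primer footprint. A product length outside
    the region's expected range sets ``length_warning`` rather than
    raising. A template that is itself the amplicon (primers at both
    ends) is returned unchanged.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    template = template.upper().replace("-", "")
    fwd = region.forward_primer.upper()
    rev_rc = reverse_complement(region.reverse_primer.upper())

    candidates = []
    for strand, seq in (("+", template), ("-", reverse_complement(template))):
        f = _best_match(seq, fwd, max_mismatch)
        if f is None:
            continue
        # reverse primer footprint must lie downstream of the forward one
        tail_at = f[0] + len(fwd)
        r = _best_match(seq[tail_at:], rev_rc, max_mismatch)
        if r is None:
            continue
        end = tail_at + r[0] + len(rev_rc)
        candidates.append((f[1] + r[1], strand, seq[f[0] : end]))

    if not candidates:
        # name the primer that failed, preferring the forward one
        for strand, seq in (("+", template), ("-", reverse_complement(template))):
            if _best_match(seq, fwd, max_mismatch) is not None:
                raise PrimerNotFoundError(region.reverse_primer, max_mismatch)
        raise PrimerNotFoundError(region.forward_primer, max_mismatch)

    _, strand, product = min(candidates, key=lambda c: c[0])
    warn = False
    if region.expected_length_range is not None:
        lo, hi = region.expected_length_range
        warn = not (lo <= len(product) <= hi)
    return Amplicon(sample_id, region.id, product, strand, warn)
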