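# Methods

## The chlorotyping model

A *chlorotype* is a haplotype of the chloroplast genome read out through
PCR-RFLP (CAPS) markers: three non-coding cpDNA regions (the
*trnQ–rps16* spacer, the *ndhF–rpl32* spacer, and the *rps16* intron,
called cpDNA01/02/03 throughout) are PCR-amplified and each product is
cut with a set of restriction enzymes. Because point substitutions in
these fast-evolving regions create or abolish recognition sites, the
digest outcomes classify individuals. A chlorotype is the ordered string
of outcomes over a fixed panel of region × enzyme *diagnostic sites*:
`1` = digested, `0` = not digested, a lower-case letter for a fragment
pattern that matches no reference pattern, `?` = inconclusive.

Two panels ship with the package. The 4-site panel is, in order,
cpDNA01·AcuI, cpDNA02·TaqI, cpDNA02·Tsp45I, cpDNA03·SwaI, with the named
types H1=`0101`, H2=`0011`, H3=`1110`, H4=`0111`. The 12-site panel
appends cpDNA01·Hpy188I, cpDNA01·MseI, cpDNA01·MspI, cpDNA01·TaqI,
cpDNA02·Hpy188I, cpDNA03·AluI, cpDNA03·ApoI, cpDNA03·MmeI. Both orders
are overridable with a custom panel file.

## In-silico digestion

Enzyme recognition motifs are IUPAC strings from public REBASE data
(overridable in a YAML catalog). Coordinates are 0-based, half-open, on
the top strand. Non-palindromic motifs (AcuI, MmeI) are scanned on both
strands; a bottom-strand hit counts as a site, with the cut mirrored to
`position + len(motif) − cut_offset`. Type IIS downstream cutters (AcuI
CTGAAG(16/14), MmeI TCCRAC(20/18)) have cut coordinates clamped to the
sequence bounds; presence of the recognition motif, not the cut
position, drives chlorotype calls.

An `N` in the template matches no motif character under the default
*conservative digest* policy: a miscalled base must not invent a
restriction site. A permissive policy is available per call.

Virtual PCR finds the best Hamming match (no indels) of each primer,
with a default budget of one mismatch per primer — the assays this
emulates amplify routinely, so near-exact matching suffices. A product
outside the region's expected size range is flagged, not rejected.

## Calling digest states from alignments

Typing from sequences consumes pre-aligned region FASTAs (alignment
construction is out of scope). For each diagnostic site the sample's
ungapped molecule is scanned and hit footprints are projected through
the row's own gap pattern onto alignment columns — digestion happens on
real molecules, not on alignments, so a motif interrupted by an
alignment gap is still a site. The call is `1` if a footprint spans the
diagnostic column; `?` if the sample is gapped/ambiguous there; `0` if
the site is absent and the sample's remaining site set for that enzyme
matches a reference pattern; otherwise a novel symbol (`a`, `b`, … in
order of first appearance, stable for a fixed input order).

## Site discovery and panel selection

A substitution is *analytically informative* when recognition-site
presence at an alignment coordinate differs between samples — the unit
of discovery is the restriction change, not the raw SNP, because one SNP
can affect overlapping motifs of several enzymes. Indel columns are
reported but not used as diagnostic sites by default. Panel selection is
greedy set cover over sample pairs (add the site splitting the most
still-unsplit pairs; ties break lexicographically by region, enzyme,
column), which separates every pair the full candidate set separates.

## Statistics

**Pearson χ²** on chlorotype × group count tables: expected counts from
the marginals, zero-marginal rows/columns dropped with a warning,
expected counts below 5 flagged but not collapsed (the tables this
mirrors are sparse, and the test is reported plainly).

**AMOVA.** With `d²(i,j)` the squared inter-individual distance,

    SSD_total  = (1/N) Σ_{i<j} d²
    SSD_within = Σ_g (1/n_g) Σ_{i<j∈g} d²
    SSD_among  = SSD_total − SSD_within

with df `G−1` among and `N−G` within, `σ²_within = MS_within`,
`σ²_among = (MS_among − MS_within)/n₀`, `n₀ = (N − Σn_g²/N)/(G−1)`.
The default squared distance is the Hamming count of differing panel
positions — identical to squared Euclidean distance on 0/1 site vectors,
the natural choice for genotype-agreement data; novel symbols count as
distinct from both `0` and `1`. A per-site Nei distance (−ln of the
fraction of matching positions) is available as a configuration choice.
Negative variance components are floored at zero for percentage
reporting and flagged, mirroring common AMOVA practice. Significance is
a Monte-Carlo permutation test (default 999 label permutations, matching
the study design this reproduces; seed required for reproducibility):
p = (1 + #{σ²_among* ≥ observed}) / (n_perm + 1). Per-group shares of
SSD_within are reported as percentages summing to 100.

Samples containing `?` are excluded from χ²/AMOVA/networks but retained
(and counted) in frequency reports. Percentages are displayed rounded to
integers with full precision kept internally.

The implementation was cross-checked against the canonical R
implementation of the same estimator during development; the shipped
test suite instead carries an independent explicit double-loop oracle so
it runs without R.

## Networks

Chlorotype networks are minimum spanning networks (MSN): Kruskal
processed by weight class with all component-bridging edges of a class
added before the components merge, so every tied alternative connection
is retained. Weight classes are formed with an absolute tie tolerance of
1e-9 (integer Hamming weights tie exactly; Nei weights need the
tolerance). Pairs at infinite Nei distance (no matching positions) are
excluded rather than given an invented weight. Nodes carry chlorotype
frequencies and per-group composition; exports are GraphML plus TSV edge
and node tables.

Eigenvector centrality is the principal eigenvector of the edge-affinity
matrix, computed by power iteration (relative tolerance 1e-10, with a
diagonal shift so bipartite adjacency spectra cannot make the iteration
oscillate) and normalised to a maximum of 1. The affinity transformation
is a configuration choice — `1/weight` by default, `max−weight`
optionally — since distance-to-strength conversions in this area are
conventions, not derivations; zero-weight edges receive the largest
finite affinity. Disconnected networks are scored per component with a
warning.

## Synthetic data

The generator emulates the study conditions the analyses assume: K
haplotype classes over three regions (default lengths 1667/986/907, the
alignment sizes of the three cpDNA regions), group collections drawn at
specified chlorotype frequencies (exact counts by default; multinomial
for distributional tests), and `?` injection at a configurable rate.
Sequences are one shared random backbone per region with primer
footprints at the ends; haplotypes differ only at diagnostic loci, where
the enzyme's motif (a concrete instantiation of its IUPAC pattern) is
planted iff the target symbol is `1`, or carries a single disabling
substitution otherwise. Placement is verified by rescanning and the
backbone is redrawn on collision (bounded retries), so
encode(generate(spec)) is the identity on the targets for every seed.

What the generator does *not* emulate: indels, recombination, mutation
processes, sequencing error and alignment artefacts. Passing round-trip
tests therefore demonstrate the internal consistency of the
digest→encode→analyse chain, not robustness to real-world alignment
noise; the `?`/novel-symbol paths are exercised separately.

Printed percentage tables are turned back into per-sample datasets by
half-up rounding of `pct·n/100` with a largest-remainder correction
(flagged) when the rounded counts miss the group size — the closest
integer realisation of a table printed at integer precision.

## Numerical and design notes

- Frequency-table percentages per group sum to 100 (full precision);
  the integer display column can drift by ±rounding.
- AMOVA on all-identical individuals reports an undefined partition with
  a flag instead of raising.
- The variance-component estimator is not invariant under exact
  duplication of every individual (duplication adds zero-distance pairs
  and deflates the within-group mean squared distance); the test suite
  asserts sample-order and relabelling invariance, SSD additivity, and
  permutation-p uniformity instead.
- Statistical property tests use deliberately modest problem sizes —
  e.g. parameter recovery with two groups of 200 over 50 seeds, and
  permutation-uniformity at 199 permutations × 200 replicates — chosen
  to keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- dCAPS design, thermodynamic PCR simulation and gel-image simulation
  are out of scope.
- Hierarchical (three-level) AMOVA is not implemented.
- Typing from sequences requires diagnostic sites anchored to alignment
  columns; the shipped panels carry region × enzyme identities only, so
  sequence-based typing needs a panel file with columns (the synthetic
  generator produces one automatically).
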