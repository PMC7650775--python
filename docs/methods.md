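# Methods

This note documents the models, algorithms, defaults and known limitations
of baculokit, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and circular topology

Internally every interval is 0-based half-open; files use the standard
1-based inclusive convention (GenBank, GFF3). A feature spanning the origin
of a circular genome is one logical feature whose `end` exceeds the genome
length (`start < end` always holds); on disk it becomes a GenBank `join` or
two GFF3 CDS lines sharing one `ID`. This keeps interval arithmetic
unambiguous while emitting standard-compliant files, and makes the
granulin-anchored linearization (rotating the genome so a chosen start codon
occupies positions 1–3) an exact, invertible operation. `N` bases are
accepted on input but excluded from GC content and never matched by motif
patterns.

## ORF prediction

The caller enumerates ATG→stop frames of at least `min_codons = 50` sense
codons (stop excluded from the count and the translation, so a "144 aa"
protein is an ORF of 144 codons plus stop) on both strands, scanning the
doubled sequence so origin-crossing frames are found; an ORF may occupy at
most one full circumference. Candidates sharing a genomic stop codon
collapse to the one with the most upstream start — the common
viral-annotation convention. "Minimal overlap" is operationalized as greedy
longest-first selection with a `max_overlap = 30` bp tolerance (ties:
smaller start, then plus strand); both knobs are exposed because the
gene-finder heuristics behind published annotations are not reproducible
exactly. The caller uses no coding-potential statistics, so a spurious
≥50-codon frame in non-coding sequence or antisense to a real gene is
reported when it fits; on synthetic genomes this occasionally (≈1% of
implants over seeded replicates) displaces a short genuine ORF that it
overlaps. Genome summaries report GC over unambiguous bases and coding
density as the union of CDS intervals (overlaps counted once).

## Promoter screen

Three IUPAC patterns are scanned in the `window = 180` nt upstream of each
start codon on the coding strand, with positions reported relative to the A
of the initiation codon (A = 0, upstream negative): `TATAW` + `CAKT`
(early), `TAATWAA` (*lef*-type TATA-like), `DTAAG` (late). The early class
requires the CAKT to begin 25–35 nt downstream of the TATAW; the spacing is
measured start-to-start by default (the anchor convention is not fixed by
common usage; a switch selects end-to-start). The window is a pure distance
window: it is not truncated at the upstream gene boundary, and it wraps
across the origin on circular genomes. A late element beginning within
15 nt of the start codon sets `proximal_late`. The frequently quoted
"−60 nt on average" position of the late element is reported as a summary
statistic, never applied as a filter.

## Repeat discovery

**Direct repeats (tandem).** For each candidate unit length d in
[10, 200] bp the sequence is compared against itself at lag d; windows of
length d with identity ≥ 0.8 mark adjacent copies and contiguous runs merge
into arrays (≥ 1.8 copies). Overlapping calls at different d keep the higher
score (copies × identity × unit length, ties to the smaller unit). The
thresholds are permissive by design — on random sequence they admit short
two-copy calls (a ~20-mer with ≥80% lag identity arises by chance every few
hundred bp), which is why the negative-control property is stated at the
stricter copies ≥ 3, identity ≥ 0.9 setting, where random 5-kb sequence is
clean. Arrays spanning the origin are not searched.

**Homologous repeat regions.** Seed-and-extend: exact 12-mer seeds in both
orientations (k-mers occurring > 30 times are skipped as low-complexity),
ungapped x-drop extension scored +1/−1 with drop 8. Gapped extension was
deliberately omitted: hr units diverge by substitutions, and an alignment
engine would buy nothing at this scale. Each extended match is an exact
affine map between unit coordinate frames (x → x + d forward, x → c − x
reverse), so all units of a cluster are projected into one reference frame;
unit boundaries are then trimmed to the majority-support span and tightened
by consensus agreement (smoothed column agreement ≥ 0.75 — well above the
~0.45 agreement random columns show against a majority-vote consensus).
Units abutting the sequence ends are clipped with `N` padding so their
columns stay in register. A cluster qualifies as an hr with ≥ 2 units of
≥ 40 bp at ≥ 0.7 identity to the consensus; purely tandem same-orientation
arrays are left to the dr finder (that adjacency-vs-dispersal split is how
the two locus types are used in granulovirus genome descriptions). The
palindromic core is the longest perfect palindrome (≥ 8 bp) in a gap
between opposite-orientation neighbour units; every reported core equals its
own reverse complement by construction. Cruciform potential is reported
structurally (core + arms); folding free energies are out of scope because
published values depend on an RNA parameter set applied to DNA. Exact unit
edges are not a guarantee of the method — unit count, orientation pattern,
consensus length and core are; on generator replicates at the default
fidelity (2% per-copy mutation) the recovered unit edges land within a few
bp of the implants.

**Palindromes.** Maximal even-length reverse-complement palindromes by
centre expansion; the outermost pair of a reported span always matches, so
the mismatch budget (default 0) is interior-only. Odd `min_len` is rejected
— a perfect biological palindrome pairs around a central axis.

## Gene content, homologs, parity

Protein alignment is BLOSUM62 with affine gaps (open −11, extend −1) via
Biopython's PairwiseAligner; identity is computed over aligned
residue–residue columns. Classification assigns each ORF the best panel
gene meeting three thresholds: identity ≥ 0.25, coverage ≥ 0.5 (aligned
span over the better-covered sequence), and raw score ≥ 60. The score floor
plays the role a BLAST e-value cutoff played in the original searches:
identity-over-aligned-columns is inflated for short local hits, and
measured on shuffled/random decoys the 25%/50% gates alone pass ~4–7% of
them (decoy scores p95 ≈ 49) while genuine remote homologs (~30% identity
over 150 aa) score ≥ ~117. ORFs with no qualifying hit are *unique*. The
panel fixture transcribes the published gene-content table: 38 core, 16
lepidopteran-conserved, 20 other, 5 unique entries. Two published
inconsistencies are surfaced rather than resolved: the abstract-level count
of 18 lepidopteran-conserved genes versus the table's 16 (the fixture
follows the table), and the orf85/orf105 naming conflict (*iap-1/iap-2* in
the table versus *iap-6/iap-5* in the text; the fixture records the table
name with the text name as an alias).

Homologs between two genomes are one-to-one reciprocal best hits under the
same alignment and thresholds. The parity plot is the scatter of homolog
ordinal positions; its collinearity score is the longest monotone chain of
index pairs divided by the number of pairs, maximized over circular
rotations of either genome and (optionally) reflection — an
artifact-defined score, since published parity analyses show plots without
a statistic. Note the chain may thread single members of an inverted block,
so a 5-of-15 inversion scores 11/15, not 10/15.

Whole-genome identity between related genomes is *estimated* by symmetrized
canonical k-mer containment (k = 17, odd to avoid self-reverse-complement
k-mers); it is a fast surrogate with its own scale, not a reproduction of
global-alignment identity values.

## Distances, demarcation, trees

K2P distances use the closed form d = −½ ln[(1 − 2P − Q)√(1 − 2Q)] with
uniform rates; sites gapped or ambiguous in either member of a pair are
excluded for that pair only (pairwise deletion; ambiguity codes are treated
like gaps). Saturation (either logarithm argument ≤ 0) yields an undefined
marker (NaN), never an exception; undefined distances force an
*inconclusive* demarcation verdict and are a hard error for tree building.
The demarcation rule is applied strictly in its published direction:
*distinct species* iff every supplied gene distance exceeds 0.05
substitutions/site. A lower "same species" bound (a second threshold some
criteria use) is intentionally not applied, because the source analysis
states only the upper rule; equality at 0.05 therefore falls on the
*same species* side.

Trees are neighbor joining with negative branch lengths clamped to zero and
the deficit moved to the sister branch (preserving the joined pair's
distance); ties in the Q-criterion break deterministically by index. NJ is
a desk-scale surrogate for the minimum-evolution and maximum-likelihood
searches used in large published analyses; topology claims about real taxa
are integration-level expectations requiring external genomes, not unit
guarantees. On additive matrices NJ reproduces the generating tree exactly;
on simulated 8-taxon data at moderate divergence it recovers the topology
in ≥ 95% of seeded replicates. Bootstrap (site resampling, bipartition
counts) is available and off by default. Concatenation of per-gene
alignments records per-gene column offsets and refuses missing taxa by
name.

## Synthetic data

The generator is the package's stand-in for real sequencing data, and its
defaults are the study-like conditions: 37.18% GC background, ≥50-codon
ORFs on both strands (70% plus-strand), an hr of five 104-bp units with two
reverse-oriented copies flanking the perfect core `GTAAACGTTTAC`, an AT
tandem dr, and promoter implants whose late-element offsets centre near
−60 nt. Implant probabilities per ORF (early 0.3, lef 0.3, late 0.6) are a
realistic mix chosen once; spacings follow the promoter model above. ORF
interiors are drawn codon-wise excluding stops at the background
composition; an in-frame TAA is written immediately 5′ of each start codon
so the implant is provably the longest ORF for its stop; promoter windows
are rejection-sampled free of accidental motif matches before implantation,
and the core's immediate neighbours are rejected if they would extend the
palindrome. Packing is checked before any sequence is emitted; generation
is byte-deterministic under the mandatory seed.

Divergence follows a per-site independent two-parameter (Kimura-type)
process parameterized so the *expected* K2P distance equals `d_true`
exactly and the expected transition:transversion count ratio equals
`kappa`; no indels, no rate heterogeneity (matching the uniform-rates
distance model). Genome-pair divergence keeps every ORF open — start and
stop codons are preserved and substitutions creating in-frame stops revert
— a slight, documented departure from site independence that keeps homolog
truth well-defined. Optional block plans translocate or invert contiguous
runs of ORFs, cutting midway through intergenic gaps, with the homolog
truth composed accordingly.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: codon-usage and amphipathic constraints inside genes,
overlapping genes, promoter elements shared between divergently transcribed
neighbours, nested or degenerate repeat families, indel evolution, and
assembly artefacts. Real-genome behaviour is exercised separately by the
deposited-record reproduction test, which requires the GenBank file.

## Numerical and scale choices

Problem sizes in the default test run were chosen to keep the whole suite
in tens of seconds while leaving estimator checks well-powered: 20-kb
synthetic genomes, 50 generator replicates for repeat recovery, 10-kb
sequences for distance-bias checks (|bias| < 0.01), 2-kb sequences × 100
replicates for 8-taxon topology recovery. The acceptance script regenerates
its own inputs from the `--seed` argument; all randomness in package code
flows through explicitly passed seeds or NumPy `Generator` objects.
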