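# Methods

## Coordinate model

All coordinates are 1-based and fully inclusive on the heavy strand of a
circular molecule, so a gene at 1–1542 is 1542 bp. Conversions to
half-open or 0-based systems happen only at format boundaries (GenBank
I/O through Biopython). Origin-spanning features are written `start > end`
and are supported throughout the native gene-table path; in GenBank input
they would arrive as `join()` compound locations, which the reader
deliberately rejects — supporting them would complicate the parser for a
case the native format already covers, so it is a documented limitation
rather than a silent misparse.

Intergenic spacers are `start_next − end_prev − 1` for consecutive
features in start order, reported on the upstream gene's row; negative
values are overlaps and are never "resolved" — overlapping mitochondrial
genes (atp8/atp6, nad4/nad4l and several tRNA pairs) are real. On a
circular annotation the wrap-around pair (last gene back to the first)
closes the list, which yields the telescoping identity

    Σ gene lengths + Σ spacers (overlaps negative) = genome length,

asserted for every synthesized genome and on 1,000 random layouts in the
test suite.

Where a published annotation table's printed gene-length column disagrees
with its own coordinate ranges (seven rows do in the packaged reference),
coordinates are authoritative: every computation derives lengths from
coordinates, and `refdata.length_discrepancies()` surfaces both values
side by side instead of hiding the conflict. Likewise the reference
strand census follows the per-gene table (23 heavy / 14 light of 37
stranded genes).

## Composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C), computed on raw
counts; the ratios are scale-invariant so percentage inputs give the same
value. A + T = 0 (or G + C = 0) yields NaN — undefined, never zero.
Ambiguous residues (N) are excluded from all denominators and tallied
separately.

Per-region profiles concatenate all features of one class in annotation
order and profile the concatenation. Two conventions matter and both are
explicit:

* **Orientation.** Published per-region tables rarely state which strand
  they used. The default here is coding orientation for PCG/tRNA/rRNA
  and heavy-strand orientation for the control region and the whole
  genome, with an `orient` flag to force either; sign-flipped skews in
  some published comparative rows suggest inconsistent strand handling in
  public records, so both conventions are first-class.
* **Overlaps.** Bases inside two genes count once per gene, because
  published region sizes equal sums of gene lengths, not union
  footprints.

Reporting precision follows the conventions of mitogenome descriptions —
percentages to 1 decimal, skews to 3 decimals, RSCU to 2 — using decimal
half-up rounding of full-precision internals (banker's rounding would
disagree with published tables on exact halves). Raw values stay
available (`--raw`).

## Codon usage

Codons are read on the coding strand from each PCG's annotated start;
per-gene lists are pooled over all PCGs. A gene whose length is not a
codon multiple ends in a 1–2 bp remainder — the incomplete stop codon
completed to UAA by post-transcriptional polyadenylation — which is
reported per gene and excluded from counts; no padding is inferred. This
convention is exactly self-consistent with the packaged reference data:
3722 pooled codons × 3 plus the single 1 bp remainder equals the summed
coordinate-derived PCG lengths.

RSCU divides each codon's count by its synonymous family's mean count, so
Σ RSCU over a family equals the family size. The default genetic code is
translation table 5 (via Biopython's codon tables); the stop family
(UAA/UAG) is retained in the table because annotated complete stops are
part of the pooled counts, with `--exclude-stops` as a sensitivity
switch. The test suite confirms the reference RSCU values are reproduced
*only* under the table-5 family structure (8-codon Ser, AUA → Met,
UGA → Trp) and fail under the standard nuclear code.

Terminal classification reports the first codon verbatim (flagging
non-ATN/GTG starts), and calls the stop complete only when the final full
codon is in the stop set; otherwise the remainder is the incomplete stop.

## Gene order

Orders are circular signed sequences; equality is rotation-invariant
(lexicographically minimal rotation as canonical key) while reflection is
a distinct order. Anchoring rotates a chosen gene to the front (default
cox1, the conventional display anchor); an L-strand anchor reflects and
sign-flips the whole order so the anchor reads forward. Gene-name
synonyms (nd4l/nad4L, cob/cytb, 16S/rrnL, D-loop/CR...) are normalized
before comparison. The control region participates as an
orientation-free element and its adjacencies count.

Unsigned breakpoints compare unordered, orientation-free neighbour pairs;
signed breakpoints keep order and orientation with reading-direction
symmetry ((x+, y+) ≡ (y−, x−)). Event detection is deliberately minimal:
greedy application of the adjacent swap or single-gene translocation that
most reduces the unsigned breakpoint count, stopping when no move helps;
whatever remains is reported as `unexplained` with the genes involved.
This is not a rearrangement-distance solver (no DCJ, no inversion
distance) — it is sized to the biological cases at hand, single tRNA
exchanges between close relatives, and validated against a brute-force
adjacency oracle on random permutations.

## Synthetic genomes

The generator produces (sequence, annotation, truth record) triples that
emulate a palaemonid-like mitogenome while making every analysis output
predictable:

* **PCGs are planted at codon level, not base level.** Each gene gets its
  planned start codon, interior codons dealt from the configured pool
  after a seeded shuffle, and its planned stop — truncated to "T"/"TA"
  for incomplete stops. Codon-count and RSCU recovery are therefore exact
  identities, not statistical checks. The pool is validated up front:
  terminals must be available and the leftover pool must exactly fill the
  interior demand implied by gene lengths, otherwise the config is
  rejected before any output.
* **tRNA/rRNA/CR bodies are i.i.d. draws** from per-region target base
  compositions on the coding strand (reverse-complemented into the genome
  for L-strand genes), so measured region composition converges to the
  target at multinomial rate; tests check 3σ bounds for the region
  lengths used. Intergenic gaps draw from the CR (non-coding) profile.
* **Overlaps are realized by sharing.** PCGs are written first and are
  hard constraints; unconstrained regions adopt whatever bases a PCG
  already fixed under them. An overlap between two PCGs is attempted
  literally and rejected on any disagreeing shared base.

The default layout mirrors the reference gene sequence, strands, and
coordinate-derived lengths on a 15,955 bp circle, with two adjustments:
the two 7 bp overlaps between consecutive PCG pairs (atp8/atp6,
nad4/nad4l) are flattened to abutting, since frame-shifted shared bases
cannot in general be satisfied by an exactly planted codon pool, and the
control region is shortened by the same 14 bp so the circle length is
unchanged. The two single-base PCG overlaps (atp6/cox3, nad6/cytb) are
kept: there the shared base is the upstream TAA's final A, which is also
the downstream ATG's initial A, so the constraint holds by construction.
Default region compositions are the reference per-region values (CR
84.8% AT, the most AT-rich region), the default codon pool is the
reference codon-count vector, and the default terminal plan follows the
reference per-gene start/stop codons including the cytb single-T stop.

All randomness flows through one `numpy.random.default_rng(seed)`; the
seed is recorded in the truth record and identical seeds give
byte-identical FASTA and gene-table output. No global random state is
touched.

Rearrangement edits (adjacent swap, single-gene move) act on the layout
with spacer slots kept positional, so gene lengths are preserved, the
circle length is conserved, and a double swap is the identity.

**What the generator does not emulate:** sequencing error, assembly
artifacts, real tRNA secondary structure, codon autocorrelation along a
gene (interior codons are exchangeable), and base-level overlap between
two coding frames. Passing tests therefore demonstrate correctness of the
bookkeeping and statistics on idealized data, not robustness to
annotation error in real records.

## Problem sizes

The test suite and acceptance script run on the packaged desk-scale
inputs (one 38-feature annotation, 64-codon table, 60 composition rows,
11 gene orders), one ~16 kb synthesized genome per seed, 1,000 random
layouts for the conservation property, and 120 random 4–10-label
permutations for the breakpoint oracle — a few seconds end to end on one
CPU.
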