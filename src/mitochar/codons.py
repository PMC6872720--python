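"""Codon extraction, terminal-codon classification, and RSCU.

Relative synonymous codon usage (RSCU) is a codon's observed count divided
by the mean count of its synonymous family; within a family the values
average 1, and codons with RSCU > 1 are used more often than expected under
uniform synonymous usage.  The default genetic code is the invertebrate
mitochondrial code (NCBI translation table 5: AGA/AGG -> Ser, ATA -> Met,
TGA -> Trp, stops TAA/TAG), under which serine has an 8-codon family and
the stop signal a 2-codon family.  Stop codons are kept in the table as
their own family because complete annotated stops are part of the coding
sequence totals.

Mitochondrial PCGs frequently end on an incomplete stop (a trailing T or
TA completed to UAA by polyadenylation); such 1-2 bp remainders are
reported separately and never counted as codons.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .annotation import AnnotationError, GeneFeature, GenomeSequence, MitoAnnotation, extract_sequence
from .composition import round_half_up

_BASES = "TCAG"
_ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table with stops mapped to ``'*'``."""

    id: int
    name: str
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(_ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 unambiguous codons")

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(
            id=table_id,
            name=table.names[0],
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
        )

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino-acid symbol -> codons (DNA alphabet)."""
        fams: dict[str, list[str]] = {}
        for codon in _ALL_CODONS:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(codons) for aa, codons in fams.items()}

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")


INVERTEBRATE_MITO = GeneticCode.from_table_id(5)


@dataclass
class CodonExtraction:
    """Pooled codon counts over PCGs plus per-gene incomplete remainders."""

    counts: Counter
    remainders: dict[str, str] = field(default_factory=dict)
    skipped_ambiguous: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def gene_codons(feature: GeneFeature, genome: GenomeSequence) -> tuple[list[str], str]:
    """Codons of one PCG read on the coding strand, plus the 1-2 bp tail."""
    seq = extract_sequence(feature, genome, orient="coding")
    if len(seq) < 3:
        raise AnnotationError(f"PCG {feature.name!r} is shorter than one codon")
    n_full = len(seq) // 3
    codons = [seq[i * 3 : i * 3 + 3] for i in range(n_full)]
    return codons, seq[n_full * 3 :]


def extract_codons(annotation: MitoAnnotation, genome: GenomeSequence) -> CodonExtraction:
    """Pool codons over all PCGs from their annotated starts.

    Codons containing N are skipped and tallied in ``skipped_ambiguous``;
    trailing 1-2 bp remainders (incomplete stops) are excluded from counts
    and reported per gene.
    """
    result = CodonExtraction(counts=Counter())
    pcgs = annotation.of_category("PCG")
    if not pcgs:
        raise AnnotationError("annotation has no PCG features")
    for f in pcgs:
        codons, tail = gene_codons(f, genome)
        for codon in codons:
            if "N" in codon:
                result.skipped_ambiguous += 1
            else:
                result.counts[codon] += 1
        if tail:
            result.remainders[f.name] = tail
    return result


@dataclass(frozen=True)
class TerminalClassification:
    start_codon: str
    stop_codon: str
    complete: bool
    canonical_start: bool  # ATN or GTG


def classify_terminals(
    feature: GeneFeature, genome: GenomeSequence, code: GeneticCode = INVERTEBRATE_MITO
) -> TerminalClassification:
    """Report a PCG's first codon and its (possibly incomplete) terminator.

    The stop is the final full codon when the gene length is a codon
    multiple; otherwise the 1-2 bp tail is reported as an incomplete stop.
    Unusual codons are reported, never rejected.
    """
    codons, tail = gene_codons(feature, genome)
    start = codons[0]
    if tail:
        stop, complete = tail, False
    else:
        stop = codons[-1]
        complete = stop in code.stop_codons
    canonical = (start.startswith("AT") and len(start) == 3) or start == "GTG"
    return TerminalClassification(start, stop, complete, canonical)


@dataclass
class CodonUsageTable:
    """Per-codon counts and RSCU grouped by synonymous family.

    Codons are held in the DNA alphabet; rendered outputs use RNA (U).
    Families with zero total get NaN RSCU.
    """

    counts: dict[str, int]
    rscu: dict[str, float]
    aa: dict[str, str]
    code: GeneticCode

    def rscu_rounded(self, codon: str) -> float:
        return round_half_up(self.rscu[to_dna(codon)], 2)

    def preferred(self) -> set[str]:
        return preferred_codons(self)

    def to_rows(self) -> list[dict]:
        """Table rows (RNA codons) ordered by amino acid then codon."""
        preferred = self.preferred()
        rows = []
        for aa, codons in sorted(self.code.families().items()):
            for codon in codons:
                rows.append(
                    {
                        "codon": to_rna(codon),
                        "aa": aa,
                        "count": self.counts.get(codon, 0),
                        "rscu": round_half_up(self.rscu[codon], 2),
                        "preferred": codon in preferred,
                    }
                )
        return rows


def rscu(
    counts: dict[str, int] | Counter,
    code: GeneticCode = INVERTEBRATE_MITO,
    include_stops: bool = True,
) -> CodonUsageTable:
    """RSCU_i = count_i / (family total / family size), per synonymous family.

    ``counts`` may use DNA (T) or RNA (U) codons.  ``include_stops=False``
    drops the stop family from the table (a sensitivity switch; the default
    keeps it, as complete stops are part of the extracted codon pool).
    """
    normalized: Counter = Counter()
    for codon, n in counts.items():
        dna = to_dna(codon)
        if dna not in code.codon_to_aa:
            raise AnnotationError(f"codon {codon!r} is not a valid unambiguous codon")
        if n < 0:
            raise AnnotationError(f"negative count for codon {codon!r}")
        normalized[dna] += int(n)
    table_counts: dict[str, int] = {}
    table_rscu: dict[str, float] = {}
    table_aa: dict[str, str] = {}
    for aa, codons in code.families().items():
        if aa == "*" and not include_stops:
            continue
        total = sum(normalized.get(c, 0) for c in codons)
        mean = total / len(codons)
        for c in codons:
            table_counts[c] = normalized.get(c, 0)
            table_aa[c] = aa
            table_rscu[c] = normalized.get(c, 0) / mean if total > 0 else math.nan
    return CodonUsageTable(counts=table_counts, rscu=table_rscu, aa=table_aa, code=code)


def preferred_codons(table: CodonUsageTable) -> set[str]:
    """Per family, the codon(s) with maximal RSCU (ties all returned)."""
    out: set[str] = set()
    for aa, codons in table.code.families().items():
        present = [c for c in codons if c in table.rscu and not math.isnan(table.rscu[c])]
        if not present:
            continue
        best = max(table.rscu[c] for c in present)
        out.update(c for c in present if table.rscu[c] == best)
    return out


def family_ties(table: CodonUsageTable) -> set[str]:
    """Amino-acid symbols whose maximal-RSCU codon is not unique."""
    ties: set[str] = set()
    preferred = preferred_codons(table)
    for aa, codons in table.code.families().items():
        winners = [c for c in codons if c in preferred]
        if len(winners) > 1:
            ties.add(aa)
    return ties
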