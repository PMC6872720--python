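"""Domain types and circular-coordinate arithmetic for annotated mitogenomes.

A metazoan mitochondrial genome is a circular molecule of roughly 14-18 kb
carrying 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one AT-rich
control region (CR).  This module holds the annotation model every other
stage consumes: 1-based fully-inclusive coordinates on the heavy strand,
with origin-spanning features expressed as ``start > end``.

Strand vocabulary is ``H``/``L`` internally (heavy/light), serialized as
``+``/``-`` in the tab-separated gene table and as ``complement()`` in
GenBank flat files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR")

_STRAND_TO_TSV = {"H": "+", "L": "-", None: "."}
_TSV_TO_STRAND = {"+": "H", "-": "L", ".": None, "": None}


class AnnotationError(ValueError):
    """Invalid annotation input (bad coordinates, duplicate names, ...)."""


class UnsupportedLocationError(AnnotationError):
    """GenBank location form we deliberately do not parse (join/order)."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a circular genome.

    ``start``/``end`` are 1-based inclusive heavy-strand positions; an
    origin-spanning feature has ``end < start``.  ``strand`` is ``H`` or
    ``L`` (``None`` for the control region, which has no transcription
    polarity in this model).
    """

    name: str
    category: str
    start: int
    end: int
    strand: str | None = "H"
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"unknown category {self.category!r} for gene {self.name!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.strand not in ("H", "L", None):
            raise AnnotationError(f"strand must be H, L or None, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(
                f"gene {self.name!r}: coordinates must be >= 1 (got {self.start}..{self.end})"
            )

    @property
    def spans_origin(self) -> bool:
        return self.end < self.start


def gene_length(feature: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length``.

    ``end >= start`` is the plain inclusive span; ``end < start`` wraps
    through the origin.
    """
    if feature.end >= feature.start:
        return feature.end - feature.start + 1
    return genome_length - feature.start + 1 + feature.end


@dataclass
class MitoAnnotation:
    """Ordered set of :class:`GeneFeature` on one circular genome."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise AnnotationError(f"genome_length must be positive, got {self.genome_length}")
        if not self.features:
            raise AnnotationError("annotation must contain at least one feature")
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise AnnotationError(f"duplicate gene name {f.name!r}")
            seen.add(f.name)
            for pos, label in ((f.start, "start"), (f.end, "end")):
                if not 1 <= pos <= self.genome_length:
                    raise AnnotationError(
                        f"gene {f.name!r}: {label} {pos} outside [1, {self.genome_length}]"
                    )
            if not self.circular and f.spans_origin:
                raise AnnotationError(
                    f"gene {f.name!r} spans the origin but the annotation is not circular"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def of_category(self, category: str) -> list[GeneFeature]:
        if category not in CATEGORIES:
            raise AnnotationError(f"unknown category {category!r}")
        return [f for f in self.features if f.category == category]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for f in self.features:
            counts[f.category] += 1
        return counts

    def strand_counts(self) -> dict[str, int]:
        """Number of stranded genes on H and on L (CR has no strand)."""
        counts = {"H": 0, "L": 0}
        for f in self.features:
            if f.strand is not None:
                counts[f.strand] += 1
        return counts

    def length_of(self, name: str) -> int:
        return gene_length(self.get(name), self.genome_length)

    def replace_features(self, features: Iterable[GeneFeature]) -> "MitoAnnotation":
        return MitoAnnotation(self.genome_length, list(features), self.circular)


def spacer_lengths(annotation: MitoAnnotation) -> list[tuple[str, int]]:
    """Intergenic spacer after each feature, in start order.

    For consecutive features ``prev``/``next`` the spacer is
    ``start_next - end_prev - 1``; negative values are overlaps.  The value
    is reported on ``prev``'s row.  A circular annotation closes the list
    with the wrap-around pair (last feature back to the first, through the
    origin); a linear one omits it.
    """
    feats = annotation.features
    if len(feats) < 2:
        raise AnnotationError("spacer_lengths needs at least two features")
    L = annotation.genome_length

    def linear_end(f: GeneFeature) -> int:
        # Origin-spanning features extend past L on the unrolled axis.
        return f.end if f.end >= f.start else f.end + L

    out: list[tuple[str, int]] = []
    for prev, nxt in zip(feats, feats[1:]):
        out.append((prev.name, nxt.start - linear_end(prev) - 1))
    if annotation.circular:
        last, first = feats[-1], feats[0]
        out.append((last.name, first.start + L - linear_end(last) - 1))
    return out


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """Heavy-strand residues, 5'->3', over the alphabet {A,C,G,T,N}."""

    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise AnnotationError(f"invalid residues {sorted(bad)}; expected A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice with circular wrap when ``end < start``."""
        n = len(self.residues)
        if not (1 <= start <= n and 1 <= end <= n):
            raise AnnotationError(f"slice {start}..{end} outside [1, {n}]")
        if end >= start:
            return self.residues[start - 1 : end]
        return self.residues[start - 1 :] + self.residues[:end]


def extract_sequence(
    feature: GeneFeature, genome: GenomeSequence, orient: str = "coding"
) -> str:
    """Residues of a feature in genome (heavy-strand) or coding orientation.

    Coding orientation reverse-complements L-strand features; H-strand and
    unstranded features are identical in both orientations.
    """
    if orient not in ("genome", "coding"):
        raise AnnotationError(f"orient must be 'genome' or 'coding', got {orient!r}")
    s = genome.slice(feature.start, feature.end)
    if orient == "coding" and feature.strand == "L":
        s = reverse_complement(s)
    return s


# ---------------------------------------------------------------------------
# Gene table (TSV) I/O

_TABLE_COLUMNS = (
    "name",
    "category",
    "start",
    "end",
    "strand",
    "anticodon",
    "start_codon",
    "stop_codon",
)


def read_gene_table(path: str | Path) -> MitoAnnotation:
    """Read the native tab-separated gene table.

    Format: a pragma line ``#genome_length=<int>``, a header line, then one
    row per gene with columns ``name category start end strand [anticodon]
    [start_codon] [stop_codon]`` (trailing cells may be empty or absent).
    """
    text = Path(path).read_text()
    genome_length: int | None = None
    rows: list[GeneFeature] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("#genome_length="):
                genome_length = int(line.split("=", 1)[1])
            continue
        cells = line.split("\t")
        if not header_seen:
            if cells[0] != "name":
                raise AnnotationError(f"line {lineno}: expected header starting with 'name'")
            header_seen = True
            continue
        cells += [""] * (len(_TABLE_COLUMNS) - len(cells))
        name, category, start, end, strand, anticodon, start_codon, stop_codon = cells[:8]
        rows.append(
            GeneFeature(
                name=name,
                category=category,
                start=int(start),
                end=int(end),
                strand=_strand_from_tsv(strand, name),
                anticodon=anticodon or None,
                start_codon=start_codon or None,
                stop_codon=stop_codon or None,
            )
        )
    if genome_length is None:
        raise AnnotationError("missing '#genome_length=' pragma line")
    if not rows:
        raise AnnotationError("gene table contains no feature rows")
    return MitoAnnotation(genome_length=genome_length, features=rows)


def _strand_from_tsv(cell: str, name: str) -> str | None:
    try:
        return _TSV_TO_STRAND[cell]
    except KeyError:
        raise AnnotationError(f"gene {name!r}: strand must be '+', '-' or '.', got {cell!r}")


def write_gene_table(annotation: MitoAnnotation, path: str | Path) -> None:
    lines = [f"#genome_length={annotation.genome_length}", "\t".join(_TABLE_COLUMNS)]
    for f in annotation.features:
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.category,
                    str(f.start),
                    str(f.end),
                    _STRAND_TO_TSV[f.strand],
                    f.anticodon or "",
                    f.start_codon or "",
                    f.stop_codon or "",
                ]
            ).rstrip("\t")
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA I/O (single record)


def read_fasta(path: str | Path) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(f"expected exactly one FASTA record, found {len(records)}")
    return GenomeSequence(str(records[0].seq).upper())


def write_fasta(genome: GenomeSequence, path: str | Path, name: str = "genome") -> None:
    record = SeqRecord(Seq(genome.residues), id=name, description="")
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "fasta")


# ---------------------------------------------------------------------------
# GenBank flat-file I/O (single record)

_GENBANK_FEATURE_TYPES = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "CR",
    "misc_feature": "CR",
}
_CATEGORY_TO_GENBANK = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}


def read_genbank(path: str | Path) -> tuple[MitoAnnotation, GenomeSequence]:
    """Read a single-record GenBank flat file.

    CDS/tRNA/rRNA features map to PCG/tRNA/rRNA; D-loop and misc_feature
    map to CR.  ``complement()`` locations become strand L.  Compound
    ``join()``/``order()`` locations (e.g. a tRNA spanning the origin) are
    rejected: origin-spanning features are supported only in the native
    gene table.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise AnnotationError(f"expected exactly one GenBank record, found {len(records)}")
    rec = records[0]
    genome = GenomeSequence(str(rec.seq).upper())
    feats: list[GeneFeature] = []
    for sf in rec.features:
        category = _GENBANK_FEATURE_TYPES.get(sf.type)
        if category is None:
            continue
        if not isinstance(sf.location, SimpleLocation):
            raise UnsupportedLocationError(
                f"{sf.type} feature has a compound location {sf.location}; "
                "join()/order() locations are not supported"
            )
        name = _first_qualifier(sf, "gene") or _first_qualifier(sf, "product")
        if name is None:
            name = f"{sf.type}_{int(sf.location.start) + 1}"
        strand: str | None
        if category == "CR":
            strand = None
        else:
            strand = "L" if sf.location.strand == -1 else "H"
        feats.append(
            GeneFeature(
                name=name,
                category=category,
                start=int(sf.location.start) + 1,  # 0-based half-open -> 1-based inclusive
                end=int(sf.location.end),
                strand=strand,
                anticodon=_first_qualifier(sf, "anticodon_seq"),
                start_codon=_first_qualifier(sf, "start_codon"),
                stop_codon=_first_qualifier(sf, "stop_codon"),
            )
        )
    if not feats:
        raise AnnotationError("GenBank record contains no CDS/tRNA/rRNA/D-loop features")
    annotation = MitoAnnotation(genome_length=len(genome), features=feats)
    return annotation, genome


def _first_qualifier(sf: SeqFeature, key: str) -> str | None:
    values = sf.qualifiers.get(key)
    return values[0] if values else None


def write_genbank(
    annotation: MitoAnnotation,
    genome: GenomeSequence,
    path: str | Path,
    name: str = "genome",
) -> None:
    if len(genome) != annotation.genome_length:
        raise AnnotationError(
            f"sequence length {len(genome)} != annotation genome_length "
            f"{annotation.genome_length}"
        )
    rec = SeqRecord(Seq(genome.residues), id=name, name=name[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if annotation.circular else "linear"
    for f in annotation.features:
        if f.spans_origin:
            raise UnsupportedLocationError(
                f"gene {f.name!r} spans the origin; GenBank output does not emit join()"
            )
        qualifiers: dict[str, list[str]] = {"gene": [f.name]}
        for key, value in (
            ("anticodon_seq", f.anticodon),
            ("start_codon", f.start_codon),
            ("stop_codon", f.stop_codon),
        ):
            if value:
                qualifiers[key] = [value]
        loc = SimpleLocation(f.start - 1, f.end, strand=-1 if f.strand == "L" else 1)
        rec.features.append(SeqFeature(loc, type=_CATEGORY_TO_GENBANK[f.category], qualifiers=qualifiers))
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")
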