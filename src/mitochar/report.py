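"""Whole-genome summary report: gene geometry, per-region composition,
and the codon-usage table, serializable to JSON and TSV with identical
values."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

from .annotation import (
    AnnotationError,
    GenomeSequence,
    MitoAnnotation,
    gene_length,
    spacer_lengths,
)
from .codons import GeneticCode, INVERTEBRATE_MITO, classify_terminals, extract_codons, rscu
from .composition import REGIONS, region_composition, round_half_up


@dataclass
class SummaryReport:
    gene_rows: list[dict[str, Any]]
    composition_rows: list[dict[str, Any]]
    codon_rows: list[dict[str, Any]]
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "genes": self.gene_rows,
                "composition": self.composition_rows,
                "codons": self.codon_rows,
            },
            indent=2,
            allow_nan=True,
        )

    def to_tsv(self) -> str:
        """Three sections with the same values as the JSON form."""
        blocks = []
        for title, rows in (
            ("genes", self.gene_rows),
            ("composition", self.composition_rows),
            ("codons", self.codon_rows),
        ):
            if not rows:
                blocks.append(f"## {title}\n(unavailable)")
                continue
            cols = list(dict.fromkeys(c for row in rows for c in row))
            lines = [f"## {title}", "\t".join(cols)]
            for row in rows:
                lines.append("\t".join(_cell(row.get(c)) for c in cols))
            blocks.append("\n".join(lines))
        return "\n\n".join(blocks) + "\n"


def _cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return "nan"
        return repr(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def summarize(
    annotation: MitoAnnotation,
    genome: GenomeSequence | None = None,
    code: GeneticCode = INVERTEBRATE_MITO,
    raw: bool = False,
) -> SummaryReport:
    """Aggregate all per-genome analyses into one report.

    Without a sequence only the gene-geometry section is populated;
    composition and codon sections are left empty.  ``raw=True`` keeps full
    float precision instead of the reporting precision (1 d.p.
    percentages, 3 d.p. skews, 2 d.p. RSCU).
    """
    spacers = dict(spacer_lengths(annotation)) if len(annotation) >= 2 else {}
    gene_rows = []
    for f in annotation.features:
        row: dict[str, Any] = {
            "name": f.name,
            "category": f.category,
            "start": f.start,
            "end": f.end,
            "length": gene_length(f, annotation.genome_length),
            "strand": f.strand or ".",
            "start_codon": f.start_codon,
            "stop_codon": f.stop_codon,
            "spacer_after": spacers.get(f.name),
        }
        if genome is not None and f.category == "PCG":
            terminals = classify_terminals(f, genome, code)
            row["start_codon"] = terminals.start_codon
            row["stop_codon"] = terminals.stop_codon
            row["stop_complete"] = terminals.complete
            row["canonical_start"] = terminals.canonical_start
        gene_rows.append(row)

    composition_rows: list[dict[str, Any]] = []
    codon_rows: list[dict[str, Any]] = []
    if genome is not None:
        present = {c for c, n in annotation.category_counts().items() if n > 0}
        for region in ("whole",) + tuple(r for r in REGIONS if r != "whole"):
            if region != "whole" and region not in present:
                continue
            profile = region_composition(annotation, genome, region)
            if raw:
                values = {
                    "pct_a": profile.pct_a,
                    "pct_g": profile.pct_g,
                    "pct_t": profile.pct_t,
                    "pct_c": profile.pct_c,
                    "at_content": profile.at_content,
                    "at_skew": profile.at_skew,
                    "gc_skew": profile.gc_skew,
                }
            else:
                values = profile.rounded()
            composition_rows.append({"region": region, "size_bp": profile.length, **values})
        table = rscu(extract_codons(annotation, genome).counts, code)
        codon_rows = table.to_rows()
        if raw:
            from .codons import to_dna

            for row in codon_rows:
                row["rscu"] = table.rscu[to_dna(row["codon"])]

    return SummaryReport(
        gene_rows=gene_rows,
        composition_rows=composition_rows,
        codon_rows=codon_rows,
        metadata={
            "genome_length": annotation.genome_length,
            "circular": annotation.circular,
            "n_features": len(annotation),
            "genetic_code": code.id,
            "sequence_available": genome is not None,
        },
    )
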