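"""Packaged reference tables for the Palaemonetes sinensis mitogenome study.

These are the published desk-scale inputs of the analysis: the annotation
table (gene coordinates, strands, terminal codons) of the P. sinensis
mitogenome (GenBank MH880828), its codon-usage table, and the per-region
composition rows reported across 12 Palaemoninae mitogenome records.  They
serve as ground truth for recomputation — skews from percentages, RSCU from
counts, geometry from coordinates — without requiring any download.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .annotation import MitoAnnotation, gene_length, read_gene_table
from .order import GeneOrder, linearize_order

#: Gene lengths as printed in the published annotation table.  Several rows
#: disagree with their own coordinate ranges; coordinates are authoritative
#: and :func:`length_discrepancies` surfaces both values.
PRINTED_GENE_LENGTHS = {
    "cox1": 1542, "trnL2": 63, "cox2": 675, "trnK": 69, "trnD": 65,
    "atp8": 159, "atp6": 663, "cox3": 783, "trnG": 65, "nad3": 345,
    "trnA": 61, "trnR": 64, "trnN": 65, "trnS1": 67, "trnE": 68,
    "trnF": 64, "nad5": 1725, "trnH": 64, "nad4": 1335, "nad4l": 264,
    "trnP": 66, "trnT": 64, "nad6": 525, "cytb": 1134, "trnS2": 68,
    "nad1": 942, "trnL1": 66, "rrnL": 1298, "trnV": 65, "rrnS": 790,
    "CR": 1159, "trnI": 67, "trnQ": 68, "trnM": 65, "nad2": 942,
    "trnW": 66, "trnC": 63, "trnY": 65,
}

#: The 11 Palaemoninae taxa compared for gene order: 7 share the conserved
#: arrangement, the 4 Macrobrachium carry the trnT/trnP translocation.
CONSERVED_ORDER_TAXA = (
    "Palaemonetes_sinensis",
    "Palaemon_serenus",
    "Palaemon_gravieri",
    "Palaemon_capensis",
    "Exopalaemon_annandalei",
    "Exopalaemon_modestus",
    "Exopalaemon_carinicauda",
)
MACROBRACHIUM_TAXA = (
    "Macrobrachium_bullatum",
    "Macrobrachium_lanchesteri",
    "Macrobrachium_nipponense",
    "Macrobrachium_rosenbergii",
)


def _data_text(filename: str) -> str:
    return resources.files("mitochar.data").joinpath(filename).read_text()


def reference_annotation() -> MitoAnnotation:
    """The 38-feature P. sinensis annotation (15,955 bp circle)."""
    with resources.as_file(resources.files("mitochar.data") / "psinensis_genes.tsv") as p:
        return read_gene_table(p)


def reference_codon_table() -> pd.DataFrame:
    """Published codon table: codon (RNA), amino acid, count, printed RSCU."""
    return pd.read_csv(io.StringIO(_data_text("psinensis_codon_counts.tsv")), sep="\t")


def reference_codon_counts() -> dict[str, int]:
    df = reference_codon_table()
    return dict(zip(df["codon"], df["count"].astype(int)))


def composition_table() -> pd.DataFrame:
    """Published per-region composition rows for 12 Palaemoninae records.

    Columns: species, accession, region (whole/PCG/tRNA/rRNA/CR), size_bp,
    pct_a/g/t/c, pct_at, at_skew, gc_skew — percentages to one decimal and
    skews to three, exactly as printed.
    """
    return pd.read_csv(io.StringIO(_data_text("palaemoninae_composition.tsv")), sep="\t")


def length_discrepancies(
    annotation: MitoAnnotation | None = None,
    printed: dict[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Genes whose coordinate-derived length differs from the printed length.

    Returns ``(name, coordinate_length, printed_length)`` tuples; the
    coordinate value is the one all computations use.
    """
    annotation = annotation or reference_annotation()
    printed = printed or PRINTED_GENE_LENGTHS
    out = []
    for f in annotation.features:
        if f.name in printed:
            coord = gene_length(f, annotation.genome_length)
            if coord != printed[f.name]:
                out.append((f.name, coord, printed[f.name]))
    return out


def _swap_adjacent_labels(order: GeneOrder, first: str, second: str) -> GeneOrder:
    labels = list(order.labels)
    signs = list(order.signs)
    i, j = labels.index(first), labels.index(second)
    n = len(labels)
    if (i + 1) % n != j and (j + 1) % n != i:
        raise ValueError(f"{first} and {second} are not adjacent")
    labels[i], labels[j] = labels[j], labels[i]
    signs[i], signs[j] = signs[j], signs[i]
    return GeneOrder(tuple(labels), tuple(signs), anchor=order.anchor)


def palaemoninae_orders(anchor: str = "cox1") -> dict[str, GeneOrder]:
    """The 11 taxon gene orders used for the rearrangement comparison.

    The seven conserved taxa carry the P. sinensis arrangement
    (...nad4l, trnP, trnT, nad6...); the four Macrobrachium carry the
    trnP/trnT exchange (...nad4l, trnT, trnP, nad6...).
    """
    conserved = linearize_order(reference_annotation(), anchor=anchor)
    swapped = _swap_adjacent_labels(conserved, "trnP", "trnT")
    orders: dict[str, GeneOrder] = {}
    for taxon in CONSERVED_ORDER_TAXA:
        orders[taxon] = conserved
    for taxon in MACROBRACHIUM_TAXA:
        orders[taxon] = swapped
    return orders
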