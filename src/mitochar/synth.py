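"""Seeded generator of annotated circular mitogenomes with planted truth.

The generator emulates what sequencing and assembly would deliver — a
circular ~16 kb genome with 13 PCGs, 22 tRNAs, 2 rRNAs and a control
region — but with every analysis target planted by construction:

* PCG bodies are exact arrangements of a planted codon pool (start and
  stop codons per a terminal plan, interior codons dealt from the pool
  after seeded shuffling), so codon counts and RSCU are recovered exactly,
  not statistically.
* tRNA/rRNA/CR bodies are i.i.d. draws from per-region target base
  compositions on the coding strand, so composition is recovered to
  multinomial sampling error.
* Incomplete stop codons are realized by truncation (a terminal "T" or
  "TA"), and gene overlaps by sharing bases: PCGs are written first and
  unconstrained regions adopt whatever bases already lie under them.
  Overlaps between two PCGs are attempted literally and rejected if the
  two planted sequences disagree on any shared base.

The default layout mirrors the P. sinensis gene sequence, strands, and
coordinate-derived lengths on a 15,955 bp circle (see docs/methods.md for
the two spacer adjustments it makes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import refdata
from .annotation import (
    AnnotationError,
    GeneFeature,
    GenomeSequence,
    MitoAnnotation,
    gene_length,
    reverse_complement,
    spacer_lengths,
)
from .codons import to_dna, to_rna
from .order import GeneOrder, linearize_order

_ACGT = np.array(list("ACGT"))


class InfeasibleConfigError(ValueError):
    """The requested genome cannot be constructed (inconsistent lengths,
    unsatisfiable overlap, codon pool mismatch)."""


@dataclass(frozen=True)
class LayoutEntry:
    """One gene slot: name, category, length in bp, strand, and the spacer
    (possibly negative = overlap) between this gene and the next one around
    the circle.  The last entry's spacer closes the circle."""

    name: str
    category: str
    length: int
    strand: str | None
    spacer_after: int = 0


@dataclass(frozen=True)
class TerminalPlan:
    """Planned start codon and stop for one PCG; a 1-2 bp stop is an
    incomplete terminator realized by truncation."""

    start_codon: str
    stop_codon: str

    @property
    def complete(self) -> bool:
        return len(self.stop_codon) == 3


@dataclass(frozen=True)
class SwapAdjacent:
    first: str
    second: str


@dataclass(frozen=True)
class MoveGene:
    name: str
    after: str


OrderEdit = SwapAdjacent | MoveGene


@dataclass
class SynthesisConfig:
    layout: list[LayoutEntry]
    region_composition: dict[str, dict[str, float]]
    codon_counts: dict[str, int]
    terminal_plan: dict[str, TerminalPlan]
    order_edits: list[OrderEdit] = field(default_factory=list)
    seed: int = 0


@dataclass
class TruthRecord:
    """Everything needed to predict every analysis output exactly."""

    codon_counts: dict[str, int]  # RNA alphabet, pooled over PCGs
    region_composition: dict[str, dict[str, float]]
    remainders: dict[str, str]  # per-gene incomplete-stop tails
    order: GeneOrder
    events: list[OrderEdit]
    seed: int
    genome_length: int


# Default per-region base-composition targets (percent, coding strand):
# AT-rich values typical of a palaemonid mitogenome; CR is the most
# AT-biased region, and intergenic gaps are drawn like CR (non-coding).
DEFAULT_REGION_COMPOSITION = {
    "tRNA": {"A": 34.4, "G": 15.2, "T": 30.4, "C": 20.0},
    "rRNA": {"A": 38.9, "G": 9.1, "T": 34.6, "C": 17.4},
    "CR": {"A": 46.7, "G": 6.5, "T": 38.1, "C": 8.7},
    "intergenic": {"A": 46.7, "G": 6.5, "T": 38.1, "C": 8.7},
}


def palaemonid_default_layout() -> list[LayoutEntry]:
    """The 38-slot default layout on a 15,955 bp circle.

    Gene names, categories, strands, and coordinate-derived lengths follow
    the reference annotation.  Two multi-base overlaps between consecutive
    PCG pairs (atp8/atp6 and nad4/nad4l, -7 bp each) are flattened to 0 —
    planted codon pools cannot generally satisfy frame-shifted shared
    bases — and the control region is shortened by the same 14 bp so the
    circle length is unchanged.  Single-base PCG overlaps (atp6/cox3,
    nad6/cytb) are kept: the shared base is the upstream TAA's final A and
    the downstream ATG's initial A.
    """
    ann = refdata.reference_annotation()
    spacers = dict_spacers = dict(spacer_lengths(ann))
    entries = []
    for f in ann.features:
        length = gene_length(f, ann.genome_length)
        spacer = spacers[f.name]
        if f.name in ("atp8", "nad4"):
            spacer = 0
        if f.name == "CR":
            length -= 14
        entries.append(LayoutEntry(f.name, f.category, length, f.strand, spacer))
    return entries


def default_terminal_plan() -> dict[str, TerminalPlan]:
    ann = refdata.reference_annotation()
    return {
        f.name: TerminalPlan(f.start_codon, f.stop_codon)
        for f in ann.of_category("PCG")
    }


def default_config(seed: int = 0, order_edits: Sequence[OrderEdit] = ()) -> SynthesisConfig:
    """Study-condition defaults: reference layout, published codon counts,
    reference terminal plan, per-region composition targets."""
    return SynthesisConfig(
        layout=palaemonid_default_layout(),
        region_composition={k: dict(v) for k, v in DEFAULT_REGION_COMPOSITION.items()},
        codon_counts=refdata.reference_codon_counts(),
        terminal_plan=default_terminal_plan(),
        order_edits=list(order_edits),
        seed=seed,
    )


def layout_to_annotation(layout: Sequence[LayoutEntry], first_start: int = 1) -> MitoAnnotation:
    """Place layout slots around the circle; the circle length is
    sum(length + spacer) and must come out positive."""
    genome_length = sum(e.length + e.spacer_after for e in layout)
    if genome_length < max((e.length for e in layout), default=1):
        raise InfeasibleConfigError(
            f"layout closes a circle of {genome_length} bp, shorter than its longest gene"
        )
    feats = []
    pos = first_start
    for e in layout:
        if e.length < 1:
            raise InfeasibleConfigError(f"gene {e.name!r} has non-positive length {e.length}")
        start = (pos - 1) % genome_length + 1
        end = (pos + e.length - 2) % genome_length + 1
        feats.append(GeneFeature(e.name, e.category, start, end, e.strand))
        pos += e.length + e.spacer_after
    return MitoAnnotation(genome_length=genome_length, features=feats)


def _validate_config(cfg: SynthesisConfig) -> None:
    for region, comp in cfg.region_composition.items():
        total = sum(comp.get(b, 0.0) for b in "ACGT")
        if abs(total - 100.0) > 1e-6:
            raise InfeasibleConfigError(
                f"region {region!r} composition sums to {total}, expected 100"
            )
    names = [e.name for e in cfg.layout]
    if len(set(names)) != len(names):
        raise InfeasibleConfigError("duplicate gene names in layout")
    n = len(cfg.layout)
    for i, e in enumerate(cfg.layout):
        if e.spacer_after < 0:
            nxt = cfg.layout[(i + 1) % n]
            if -e.spacer_after >= min(e.length, nxt.length):
                raise InfeasibleConfigError(
                    f"overlap of {-e.spacer_after} bp between {e.name} and {nxt.name} "
                    "is not shorter than both genes"
                )
    for e in cfg.layout:
        if e.category == "PCG" and e.name not in cfg.terminal_plan:
            raise InfeasibleConfigError(f"PCG {e.name!r} has no terminal plan")


def _codon_budget(cfg: SynthesisConfig) -> tuple[Counter, dict[str, int]]:
    """Remove planned terminals from the pool; return (interior pool,
    per-gene interior codon demand)."""
    pool: Counter = Counter()
    for codon, n in cfg.codon_counts.items():
        pool[to_dna(codon)] += int(n)
    demand: dict[str, int] = {}
    for e in cfg.layout:
        if e.category != "PCG":
            continue
        plan = cfg.terminal_plan[e.name]
        r = e.length % 3
        if plan.complete and r != 0:
            raise InfeasibleConfigError(
                f"{e.name}: length {e.length} is not a codon multiple but the plan "
                f"stop {plan.stop_codon!r} is complete"
            )
        if not plan.complete and r != len(plan.stop_codon):
            raise InfeasibleConfigError(
                f"{e.name}: incomplete stop {plan.stop_codon!r} does not match the "
                f"{r} bp tail implied by length {e.length}"
            )
        n_codons = e.length // 3
        n_terminal = 2 if plan.complete else 1
        if n_codons < n_terminal:
            raise InfeasibleConfigError(f"{e.name}: too short for its terminal plan")
        for terminal in ([plan.start_codon, plan.stop_codon] if plan.complete else [plan.start_codon]):
            t = to_dna(terminal)
            if pool[t] <= 0:
                raise InfeasibleConfigError(
                    f"codon pool exhausted: no {terminal} left for {e.name}'s terminals"
                )
            pool[t] -= 1
        demand[e.name] = n_codons - n_terminal
    total_demand = sum(demand.values())
    remaining = sum(pool.values())
    if total_demand != remaining:
        raise InfeasibleConfigError(
            f"codon pool size mismatch: layout needs {total_demand} interior codons, "
            f"pool holds {remaining} after terminals"
        )
    return pool, demand


def _region_probs(comp: dict[str, float]) -> np.ndarray:
    return np.array([comp.get(b, 0.0) for b in "ACGT"]) / 100.0


def synthesize(cfg: SynthesisConfig) -> tuple[GenomeSequence, MitoAnnotation, TruthRecord]:
    """Build (sequence, annotation, truth record); deterministic in the seed."""
    _validate_config(cfg)
    layout = list(cfg.layout)
    for edit in cfg.order_edits:
        layout = edit_layout(layout, edit)
    annotation = layout_to_annotation(layout)
    L = annotation.genome_length
    rng = np.random.default_rng(cfg.seed)

    pool, demand = _codon_budget(replace(cfg, layout=layout))
    interior = [c for codon, n in sorted(pool.items()) for c in [codon] * n]
    rng.shuffle(interior)

    buf: list[str | None] = [None] * L
    remainders: dict[str, str] = {}

    def write(start: int, residues: str, gene: str, allow_shared: bool) -> None:
        for k, base in enumerate(residues):
            idx = (start - 1 + k) % L
            if buf[idx] is None:
                buf[idx] = base
            elif not allow_shared and buf[idx] != base:
                raise InfeasibleConfigError(
                    f"overlap conflict at position {idx + 1} while writing {gene}: "
                    f"{buf[idx]} already placed, {base} required"
                )

    # Pass 1: PCGs carry hard base constraints; conflicts between two PCG
    # frames are rejected rather than resolved.
    cursor = 0
    for e in layout:
        if e.category != "PCG":
            continue
        plan = cfg.terminal_plan[e.name]
        n_int = demand[e.name]
        body = interior[cursor : cursor + n_int]
        cursor += n_int
        coding = to_dna(plan.start_codon) + "".join(body) + to_dna(plan.stop_codon)
        if len(coding) != e.length:
            raise InfeasibleConfigError(f"{e.name}: assembled {len(coding)} bp != {e.length}")
        if not plan.complete:
            remainders[e.name] = to_dna(plan.stop_codon)
        f = annotation.get(e.name)
        strandwise = reverse_complement(coding) if e.strand == "L" else coding
        write(f.start, strandwise, e.name, allow_shared=False)

    # Passes 2-3: unconstrained regions draw i.i.d. bases on the coding
    # strand and adopt any base a PCG already fixed under them.
    for category in ("tRNA", "rRNA", "CR"):
        comp = cfg.region_composition.get(category)
        if comp is None:
            comp = DEFAULT_REGION_COMPOSITION[category]
        probs = _region_probs(comp)
        for e in layout:
            if e.category != category:
                continue
            coding = "".join(rng.choice(_ACGT, size=e.length, p=probs))
            strandwise = reverse_complement(coding) if e.strand == "L" else coding
            f = annotation.get(e.name)
            write(f.start, strandwise, e.name, allow_shared=True)

    # Pass 4: leftover intergenic gaps.
    gaps = [i for i, b in enumerate(buf) if b is None]
    if gaps:
        probs = _region_probs(
            cfg.region_composition.get("intergenic", DEFAULT_REGION_COMPOSITION["intergenic"])
        )
        filler = rng.choice(_ACGT, size=len(gaps), p=probs)
        for i, base in zip(gaps, filler):
            buf[i] = base

    genome = GenomeSequence("".join(buf))  # type: ignore[arg-type]
    truth = TruthRecord(
        codon_counts={to_rna(c): int(n) for c, n in sorted(Counter(_planted_codons(cfg, layout)).items())},
        region_composition={k: dict(v) for k, v in cfg.region_composition.items()},
        remainders=remainders,
        order=linearize_order(annotation, anchor=layout[0].name, normalize=False),
        events=list(cfg.order_edits),
        seed=cfg.seed,
        genome_length=L,
    )
    return genome, annotation, truth


def _planted_codons(cfg: SynthesisConfig, layout: Sequence[LayoutEntry]) -> Iterable[str]:
    """The codon multiset actually placed: the configured pool minus any
    incomplete stops (truncated codons never count)."""
    pool: Counter = Counter()
    for codon, n in cfg.codon_counts.items():
        pool[to_dna(codon)] += int(n)
    return [c for codon, n in pool.items() for c in [codon] * n]


def edit_layout(layout: Sequence[LayoutEntry], edit: OrderEdit) -> list[LayoutEntry]:
    """Apply one rearrangement to a layout; spacer slots stay positional so
    the circle length is conserved and edits are involutions."""
    names = [e.name for e in layout]
    out = list(layout)
    if isinstance(edit, SwapAdjacent):
        try:
            i, j = names.index(edit.first), names.index(edit.second)
        except ValueError as exc:
            raise AnnotationError(f"unknown gene in edit: {exc}")
        if abs(i - j) != 1:
            raise AnnotationError(
                f"{edit.first} and {edit.second} are not adjacent in the layout"
            )
        si, sj = out[i].spacer_after, out[j].spacer_after
        out[i], out[j] = out[j], out[i]
        out[i] = replace(out[i], spacer_after=si)
        out[j] = replace(out[j], spacer_after=sj)
        return out
    if isinstance(edit, MoveGene):
        try:
            i = names.index(edit.name)
        except ValueError:
            raise AnnotationError(f"unknown gene in edit: {edit.name!r}")
        entry = out.pop(i)
        rest_names = [e.name for e in out]
        try:
            j = rest_names.index(edit.after)
        except ValueError:
            raise AnnotationError(f"unknown anchor gene in edit: {edit.after!r}")
        out.insert(j + 1, entry)
        return out
    raise AnnotationError(f"unknown edit type {type(edit).__name__}")


def annotation_to_layout(annotation: MitoAnnotation) -> list[LayoutEntry]:
    spacers = dict(spacer_lengths(annotation))
    return [
        LayoutEntry(
            f.name,
            f.category,
            gene_length(f, annotation.genome_length),
            f.strand,
            spacers[f.name],
        )
        for f in annotation.features
    ]


def apply_order_edit(annotation: MitoAnnotation, edit: OrderEdit) -> MitoAnnotation:
    """Rearrange an annotation: gene lengths are preserved, coordinates are
    recomputed from the first feature's start, and the circle still closes.
    Non-coordinate feature metadata (anticodons, terminal codons) travels
    with each gene."""
    layout = edit_layout(annotation_to_layout(annotation), edit)
    rebuilt = layout_to_annotation(layout, first_start=annotation.features[0].start)
    feats = [
        replace(annotation.get(f.name), start=f.start, end=f.end)
        for f in rebuilt.features
    ]
    return rebuilt.replace_features(feats)
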