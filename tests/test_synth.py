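"""Synthetic-mitogenome generator: planted truth must be recoverable."""

import math

import numpy as np
import pytest

from mitochar import synth
from mitochar.annotation import (
    AnnotationError,
    gene_length,
    spacer_lengths,
    write_fasta,
    write_gene_table,
)
from mitochar.codons import extract_codons, to_rna
from mitochar.composition import region_composition
from mitochar.order import compare_orders, linearize_order
from mitochar.synth import (
    InfeasibleConfigError,
    LayoutEntry,
    MoveGene,
    SwapAdjacent,
    apply_order_edit,
    default_config,
    layout_to_annotation,
    synthesize,
)


class TestDefaultSynthesis:
    def test_layout_realizes_study_conditions(self, default_synthesis):
        _, annotation, truth = default_synthesis
        assert annotation.genome_length == 15955
        assert annotation.category_counts() == {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}
        assert truth.genome_length == 15955

    def test_planted_codon_counts_recovered_exactly(self, default_synthesis):
        genome, annotation, truth = default_synthesis
        extracted = extract_codons(annotation, genome)
        got = {to_rna(c): n for c, n in extracted.counts.items()}
        assert got == {k: v for k, v in truth.codon_counts.items() if v > 0}
        assert extracted.remainders == truth.remainders == {"cytb": "T"}

    def test_count_conservation_over_pcgs(self, default_synthesis):
        genome, annotation, _ = default_synthesis
        extracted = extract_codons(annotation, genome)
        pcg_total = sum(
            gene_length(f, annotation.genome_length) for f in annotation.of_category("PCG")
        )
        assert extracted.total_codons * 3 + sum(map(len, extracted.remainders.values())) == pcg_total

    def test_circular_conservation(self, default_synthesis):
        _, annotation, _ = default_synthesis
        total = sum(gene_length(f, annotation.genome_length) for f in annotation) + sum(
            s for _, s in spacer_lengths(annotation)
        )
        assert total == annotation.genome_length

    def test_region_composition_recovered_within_3_sigma(self, default_synthesis):
        genome, annotation, truth = default_synthesis
        for category in ("tRNA", "rRNA", "CR"):
            profile = region_composition(annotation, genome, category)
            targets = truth.region_composition[category]
            n = profile.acgt_total
            for base in "ACGT":
                p = targets[base] / 100.0
                sigma_pct = 100.0 * math.sqrt(p * (1 - p) / n)
                measured = getattr(profile, f"pct_{base.lower()}")
                assert abs(measured - targets[base]) <= 3 * sigma_pct, (category, base)

    def test_determinism_byte_identical_outputs(self, tmp_path):
        paths = []
        for run in ("one", "two"):
            genome, annotation, _ = synthesize(default_config(seed=11))
            fa, tsv = tmp_path / f"{run}.fa", tmp_path / f"{run}.tsv"
            write_fasta(genome, fa)
            write_gene_table(annotation, tsv)
            paths.append((fa.read_bytes(), tsv.read_bytes()))
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self):
        g1, _, _ = synthesize(default_config(seed=1))
        g2, _, _ = synthesize(default_config(seed=2))
        assert g1.residues != g2.residues


class TestOrderEdits:
    def test_swap_produces_one_adjacent_swap_event(self, ref_annotation):
        edited = apply_order_edit(ref_annotation, SwapAdjacent("trnP", "trnT"))
        rep = compare_orders(linearize_order(ref_annotation), linearize_order(edited))
        assert [(e.kind, set(e.genes)) for e in rep.events] == [
            ("adjacent_swap", {"trnP", "trnT"})
        ]

    def test_edit_preserves_lengths_and_closure(self, ref_annotation):
        edited = apply_order_edit(ref_annotation, SwapAdjacent("trnP", "trnT"))
        assert edited.genome_length == ref_annotation.genome_length
        for f in ref_annotation:
            assert edited.length_of(f.name) == ref_annotation.length_of(f.name)

    def test_double_swap_is_identity(self, ref_annotation):
        twice = apply_order_edit(
            apply_order_edit(ref_annotation, SwapAdjacent("trnP", "trnT")),
            SwapAdjacent("trnP", "trnT"),
        )
        assert twice.features == ref_annotation.features

    def test_non_adjacent_swap_rejected(self, ref_annotation):
        with pytest.raises(AnnotationError, match="not adjacent"):
            apply_order_edit(ref_annotation, SwapAdjacent("cox1", "nad2"))

    def test_move_gene_then_compare_detects_translocation(self, ref_annotation):
        edited = apply_order_edit(ref_annotation, MoveGene("trnI", after="trnM"))
        rep = compare_orders(linearize_order(ref_annotation), linearize_order(edited))
        assert ("translocation", ("trnI",)) in [(e.kind, e.genes) for e in rep.events]

    def test_synthesize_with_edit_records_event(self):
        cfg = default_config(seed=5, order_edits=[SwapAdjacent("trnP", "trnT")])
        genome, annotation, truth = synthesize(cfg)
        assert truth.events == [SwapAdjacent("trnP", "trnT")]
        i = [f.name for f in annotation.features].index("trnT")
        assert annotation.features[i + 1].name == "trnP"
        # planted codons still recovered after the rearrangement
        extracted = extract_codons(annotation, genome)
        assert {to_rna(c): n for c, n in extracted.counts.items()} == {
            k: v for k, v in truth.codon_counts.items() if v > 0
        }


class TestInfeasibleConfigs:
    def test_codon_pool_length_mismatch(self):
        cfg = default_config(seed=0)
        cfg.codon_counts = dict(cfg.codon_counts)
        cfg.codon_counts["GGG"] += 1
        with pytest.raises(InfeasibleConfigError, match="pool"):
            synthesize(cfg)

    def test_missing_terminal_codon_in_pool(self):
        cfg = default_config(seed=0)
        cfg.codon_counts = dict(cfg.codon_counts)
        cfg.codon_counts["GUG"] = 0  # nad5 needs a GTG start
        with pytest.raises(InfeasibleConfigError, match="GTG|pool"):
            synthesize(cfg)

    def test_bad_region_composition_sum(self):
        cfg = default_config(seed=0)
        cfg.region_composition["CR"] = {"A": 50.0, "G": 10.0, "T": 10.0, "C": 10.0}
        with pytest.raises(InfeasibleConfigError, match="sums"):
            synthesize(cfg)

    def test_overlap_longer_than_gene_rejected(self):
        layout = [
            LayoutEntry("a", "tRNA", 60, "H", -70),
            LayoutEntry("b", "tRNA", 80, "H", 10),
        ]
        cfg = default_config(seed=0)
        cfg.layout = layout
        cfg.codon_counts = {}
        cfg.terminal_plan = {}
        with pytest.raises(InfeasibleConfigError, match="overlap"):
            synthesize(cfg)

    def test_conflicting_pcg_overlap_rejected(self):
        # Two PCGs overlapping by 4 bp: the shared bases cannot satisfy both
        # planted frames (stop TAA under start ATGA).
        layout = [
            LayoutEntry("p1", "PCG", 9, "H", -4),
            LayoutEntry("p2", "PCG", 9, "H", 10),
        ]
        cfg = default_config(seed=0)
        cfg.layout = layout
        cfg.terminal_plan = {
            "p1": synth.TerminalPlan("ATG", "TAA"),
            "p2": synth.TerminalPlan("ATG", "TAA"),
        }
        cfg.codon_counts = {"AUG": 2, "UAA": 2, "GGG": 2}
        with pytest.raises(InfeasibleConfigError, match="conflict"):
            synthesize(cfg)


class TestRandomLayouts:
    def test_circular_conservation_on_random_layouts(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 30))
            layout = [
                LayoutEntry(
                    f"g{i}",
                    "tRNA",
                    int(rng.integers(50, 400)),
                    "H" if rng.random() < 0.5 else "L",
                    int(rng.integers(0, 40)),
                )
                for i in range(n)
            ]
            ann = layout_to_annotation(layout)
            total = sum(gene_length(f, ann.genome_length) for f in ann) + sum(
                s for _, s in spacer_lengths(ann)
            )
            assert total == ann.genome_length
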