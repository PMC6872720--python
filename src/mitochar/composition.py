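"""Base composition and strand-asymmetry (skew) statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on counts
or percentages interchangeably (the ratio is scale-invariant).  Reported
precision follows the convention of mitogenome descriptions: percentages to
one decimal, skews to three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .annotation import (
    CATEGORIES,
    AnnotationError,
    GenomeSequence,
    MitoAnnotation,
    extract_sequence,
)

REGIONS = CATEGORIES + ("whole",)

#: Default orientation per region: coding strand for gene categories,
#: heavy strand for the control region and the whole genome.
DEFAULT_ORIENT = {"PCG": "coding", "tRNA": "coding", "rRNA": "coding", "CR": "genome", "whole": "genome"}


def at_skew(a: float, t: float) -> float:
    """(A - T)/(A + T); NaN when A + T == 0 (undefined, never 0)."""
    if a + t == 0:
        return math.nan
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C)/(G + C); NaN when G + C == 0."""
    if g + c == 0:
        return math.nan
    return (g - c) / (g + c)


@dataclass(frozen=True)
class CompositionProfile:
    """A/G/T/C counts with derived percentages, AT content and skews.

    Percentages are computed over unambiguous residues only; ``n_excluded``
    counts residues (N) left out of the denominators.
    """

    count_a: int
    count_g: int
    count_t: int
    count_c: int
    n_excluded: int = 0

    @property
    def length(self) -> int:
        return self.count_a + self.count_g + self.count_t + self.count_c + self.n_excluded

    @property
    def acgt_total(self) -> int:
        return self.count_a + self.count_g + self.count_t + self.count_c

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.acgt_total

    @property
    def pct_a(self) -> float:
        return self._pct(self.count_a)

    @property
    def pct_g(self) -> float:
        return self._pct(self.count_g)

    @property
    def pct_t(self) -> float:
        return self._pct(self.count_t)

    @property
    def pct_c(self) -> float:
        return self._pct(self.count_c)

    @property
    def at_content(self) -> float:
        return self.pct_a + self.pct_t

    @property
    def at_skew(self) -> float:
        return at_skew(self.count_a, self.count_t)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.count_g, self.count_c)

    def rounded(self) -> dict[str, float]:
        """Values at reporting precision (1 d.p. percentages, 3 d.p. skews)."""
        return {
            "pct_a": round_half_up(self.pct_a, 1),
            "pct_g": round_half_up(self.pct_g, 1),
            "pct_t": round_half_up(self.pct_t, 1),
            "pct_c": round_half_up(self.pct_c, 1),
            "at_content": round_half_up(self.at_content, 1),
            "at_skew": round_half_up(self.at_skew, 3),
            "gc_skew": round_half_up(self.gc_skew, 3),
        }


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.0855 -> 0.086), unlike banker's round()."""
    if math.isnan(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def base_composition(residues: str) -> CompositionProfile:
    """Count A/G/T/C in a residue string; N is tallied as excluded."""
    if not residues:
        raise AnnotationError("cannot profile an empty sequence")
    profile = CompositionProfile(
        count_a=residues.count("A"),
        count_g=residues.count("G"),
        count_t=residues.count("T"),
        count_c=residues.count("C"),
        n_excluded=residues.count("N"),
    )
    if profile.acgt_total == 0:
        raise AnnotationError("sequence contains no unambiguous A/C/G/T residues")
    return profile


def region_composition(
    annotation: MitoAnnotation,
    genome: GenomeSequence,
    category: str,
    orient: str | None = None,
) -> CompositionProfile:
    """Composition of one region class (or the whole genome).

    Features of the category are concatenated in annotation order, in the
    requested orientation, and profiled as one sequence.  Overlapping
    features contribute their shared bases once per feature (region sizes
    then equal sums of gene lengths, the convention of mitogenome tables).
    ``orient=None`` selects the per-category default (coding strand for
    PCG/tRNA/rRNA, heavy strand for CR and whole).
    """
    if category not in REGIONS:
        raise AnnotationError(f"unknown region {category!r}; expected one of {REGIONS}")
    if len(genome) != annotation.genome_length:
        raise AnnotationError(
            f"sequence length {len(genome)} != annotation genome_length "
            f"{annotation.genome_length}"
        )
    if orient is None:
        orient = DEFAULT_ORIENT[category]
    if category == "whole":
        return base_composition(genome.residues)
    features = annotation.of_category(category)
    if not features:
        raise AnnotationError(f"annotation has no features of category {category!r}")
    concatenated = "".join(extract_sequence(f, genome, orient) for f in features)
    return base_composition(concatenated)
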