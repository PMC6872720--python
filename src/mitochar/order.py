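"""Circular signed gene orders and pairwise rearrangement comparison.

A mitogenome's gene order is a circular sequence of labelled, oriented
blocks; two genomes differ by rearrangement when some gene adjacency
present in one is absent from the other (a *breakpoint*).  This module
canonicalizes orders under rotation, counts breakpoints in unsigned and
signed (orientation-aware) modes, and greedily names minimal events —
adjacent swaps and single-gene translocations; anything beyond that is
reported as unexplained rather than solved (no DCJ/inversion-distance
machinery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import AnnotationError, MitoAnnotation

_SIGN = {"H": 1, "L": -1, None: 0}

_CANONICAL = {
    "cob": "cytb",
    "cytb": "cytb",
    "cyt_b": "cytb",
    "l-rrna": "rrnL",
    "lrrna": "rrnL",
    "rrnl": "rrnL",
    "16s": "rrnL",
    "s-rrna": "rrnS",
    "srrna": "rrnS",
    "rrns": "rrnS",
    "12s": "rrnS",
    "d-loop": "CR",
    "dloop": "CR",
    "control_region": "CR",
    "cr": "CR",
}
for _i in (1, 2, 3):
    _CANONICAL[f"cox{_i}"] = f"cox{_i}"
    _CANONICAL[f"co{_i}"] = f"cox{_i}"
for _i in (1, 2, 3, 4, 5, 6):
    _CANONICAL[f"nad{_i}"] = f"nad{_i}"
    _CANONICAL[f"nd{_i}"] = f"nad{_i}"
_CANONICAL["nad4l"] = "nad4l"
_CANONICAL["nd4l"] = "nad4l"
_CANONICAL["atp6"] = "atp6"
_CANONICAL["atp8"] = "atp8"


def normalize_label(name: str) -> str:
    """Map gene-name synonyms (nd4l/nad4L, cob/cytb, 16S/rrnL...) to one form."""
    low = name.strip().lower()
    if low in _CANONICAL:
        return _CANONICAL[low]
    if low.startswith("trn") and len(low) > 3:
        return "trn" + low[3:].upper()[0] + low[4:]
    return name.strip()


@dataclass(frozen=True)
class GeneOrder:
    """Signed circular gene order: labels with orientations (+1 H, -1 L, 0 CR).

    Equality is rotation-invariant: an order and any rotation of it compare
    equal.  Reflection is a distinct order (orientation matters).
    """

    labels: tuple[str, ...]
    signs: tuple[int, ...]
    anchor: str

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.signs):
            raise AnnotationError("labels and signs must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise AnnotationError("gene labels must be unique within an order")
        if self.anchor not in self.labels:
            raise AnnotationError(f"anchor {self.anchor!r} not among labels")

    def __len__(self) -> int:
        return len(self.labels)

    def elements(self) -> tuple[tuple[str, int], ...]:
        return tuple(zip(self.labels, self.signs))

    def canonical(self) -> tuple[tuple[str, int], ...]:
        """Lexicographically minimal rotation — a rotation-invariant key."""
        elems = self.elements()
        n = len(elems)
        return min(tuple(elems[(i + j) % n] for j in range(n)) for i in range(n))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def rotated_to(self, label: str) -> "GeneOrder":
        if label not in self.labels:
            raise AnnotationError(
                f"anchor {label!r} not in order; available: {', '.join(self.labels)}"
            )
        i = self.labels.index(label)
        n = len(self.labels)
        idx = [(i + j) % n for j in range(n)]
        return GeneOrder(
            labels=tuple(self.labels[k] for k in idx),
            signs=tuple(self.signs[k] for k in idx),
            anchor=label,
        )

    def reflected(self) -> "GeneOrder":
        """Reverse reading direction: order reversed, all signs flipped."""
        labels = (self.labels[0],) + tuple(reversed(self.labels[1:]))
        signs = (-self.signs[0],) + tuple(-s for s in reversed(self.signs[1:]))
        return GeneOrder(labels=labels, signs=signs, anchor=self.anchor)


def linearize_order(
    annotation: MitoAnnotation, anchor: str = "cox1", normalize: bool = True
) -> GeneOrder:
    """Read the circular order off an annotation, rotated to ``anchor``.

    If the anchor lies on the L strand the whole order is reflected and
    sign-flipped so the anchor reads forward (+), the convention used when
    drawing mitogenome orders linearly.
    """
    labels = []
    signs = []
    for f in annotation.features:
        labels.append(normalize_label(f.name) if normalize else f.name)
        signs.append(_SIGN[f.strand])
    anchor = normalize_label(anchor) if normalize else anchor
    if anchor not in labels:
        raise AnnotationError(
            f"anchor {anchor!r} not in annotation; available: {', '.join(labels)}"
        )
    order = GeneOrder(tuple(labels), tuple(signs), anchor=labels[0]).rotated_to(anchor)
    if order.signs[0] < 0:
        order = order.reflected()
    return order


def adjacency_set(order: GeneOrder, signed: bool = False) -> frozenset:
    """Circular neighbour-pair set.

    Unsigned: unordered, orientation-free pairs ``frozenset({x, y})``.
    Signed: ordered pairs with signs, canonicalized under reading-direction
    symmetry ``(x+, y+) == (y-, x-)``.
    """
    if len(order) < 2:
        raise AnnotationError("adjacency_set needs at least two genes")
    n = len(order)
    pairs = []
    for i in range(n):
        x, sx = order.labels[i], order.signs[i]
        y, sy = order.labels[(i + 1) % n], order.signs[(i + 1) % n]
        if signed:
            fwd = ((x, sx), (y, sy))
            rev = ((y, -sy), (x, -sx))
            pairs.append(min(fwd, rev))
        else:
            pairs.append(frozenset((x, y)))
    return frozenset(pairs)


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str  # adjacent_swap | translocation | inversion | unexplained
    genes: tuple[str, ...]


@dataclass
class RearrangementReport:
    identical: bool
    shared_adjacencies: int
    breakpoints_unsigned: int
    breakpoints_signed: int
    events: list[RearrangementEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "identical": self.identical,
            "shared_adjacencies": self.shared_adjacencies,
            "breakpoints_unsigned": self.breakpoints_unsigned,
            "breakpoints_signed": self.breakpoints_signed,
            "events": [{"kind": e.kind, "genes": list(e.genes)} for e in self.events],
        }


def _label_adjacencies(labels: Sequence[str]) -> frozenset:
    n = len(labels)
    return frozenset(frozenset((labels[i], labels[(i + 1) % n])) for i in range(n))


def _rotation_equal(a: Sequence[str], b: Sequence[str]) -> bool:
    if a[0] not in b:
        return False
    i = list(b).index(a[0])
    n = len(b)
    return list(a) == [b[(i + j) % n] for j in range(n)]


def compare_orders(a: GeneOrder, b: GeneOrder) -> RearrangementReport:
    """Breakpoint counts plus a greedy minimal-event scan between two orders.

    Both orders must carry the same label set.  Events are searched only as
    adjacent swaps and single-gene translocations, applied greedily while
    they strictly reduce the unsigned breakpoint count; any residual
    difference is reported as one ``unexplained`` event naming the genes in
    broken adjacencies.
    """
    set_a, set_b = set(a.labels), set(b.labels)
    if set_a != set_b:
        only_a = sorted(set_a - set_b)
        only_b = sorted(set_b - set_a)
        raise AnnotationError(
            f"orders carry different labels (only in first: {only_a}; only in second: {only_b})"
        )
    adj_ua, adj_ub = adjacency_set(a, signed=False), adjacency_set(b, signed=False)
    adj_sa, adj_sb = adjacency_set(a, signed=True), adjacency_set(b, signed=True)
    breakpoints_unsigned = len(adj_ua - adj_ub)
    breakpoints_signed = len(adj_sa - adj_sb)
    identical = a == b or a == b.rotated_to(a.labels[0])
    report = RearrangementReport(
        identical=identical,
        shared_adjacencies=len(adj_ua & adj_ub),
        breakpoints_unsigned=breakpoints_unsigned,
        breakpoints_signed=breakpoints_signed,
    )
    if identical:
        return report
    report.events = _find_events(a, b)
    return report


def _find_events(a: GeneOrder, b: GeneOrder) -> list[RearrangementEvent]:
    work = list(a.labels)
    target = list(b.labels)
    sign_of_a = dict(zip(a.labels, a.signs))
    sign_of_b = dict(zip(b.labels, b.signs))
    n = len(work)
    events: list[RearrangementEvent] = []
    for _ in range(n):
        if _rotation_equal(work, target):
            break
        step = _best_step(work, target)
        if step is None:
            break
        work, event = step
        events.append(event)
    if not _rotation_equal(work, target):
        diff = _label_adjacencies(work) - _label_adjacencies(target)
        involved = tuple(sorted({g for pair in diff for g in pair}))
        events.append(RearrangementEvent("unexplained", involved))
        return events
    flipped = tuple(
        sorted(g for g in work if sign_of_a[g] != sign_of_b[g] and sign_of_a[g] and sign_of_b[g])
    )
    if flipped:
        events.append(RearrangementEvent("inversion", flipped))
    return events


def _best_step(
    work: list[str], target: list[str]
) -> tuple[list[str], RearrangementEvent] | None:
    """One greedy move: the swap/translocation that most reduces breakpoints."""
    n = len(work)
    current = len(_label_adjacencies(work) - _label_adjacencies(target))
    best: tuple[int, list[str], RearrangementEvent] | None = None

    def consider(cand: list[str], event: RearrangementEvent) -> None:
        nonlocal best
        bp = len(_label_adjacencies(cand) - _label_adjacencies(target))
        if bp < current and (best is None or bp < best[0]):
            best = (bp, cand, event)

    for i in range(n):
        j = (i + 1) % n
        cand = list(work)
        cand[i], cand[j] = cand[j], cand[i]
        consider(cand, RearrangementEvent("adjacent_swap", (work[i], work[j])))
    for i in range(n):
        rest = work[:i] + work[i + 1 :]
        for j in range(len(rest)):
            cand = rest[: j + 1] + [work[i]] + rest[j + 1 :]
            if cand == work:
                continue
            consider(cand, RearrangementEvent("translocation", (work[i],)))
    if best is None:
        return None
    return best[1], best[2]


def classify_patterns(orders: Mapping[str, GeneOrder]) -> dict[int, list[str]]:
    """Group orders by exact signed, rotation-normalized equivalence.

    Returns pattern id (1-based, in order of first appearance) -> names.
    """
    if not orders:
        raise AnnotationError("classify_patterns needs at least one order")
    groups: dict[tuple, list[str]] = {}
    for name, order in orders.items():
        groups.setdefault(order.canonical(), []).append(name)
    return {i + 1: names for i, names in enumerate(groups.values())}
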