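"""Signed circular gene orders and rearrangement detection.

A mitochondrial gene order is a signed circular permutation of canonical
gene labels (sign = coding strand).  Rearrangement between two genomes is
quantified by the breakpoint distance: the number of oriented gene
adjacencies of one order missing from the other, where the adjacency
x->y is identified with -y->-x (reading the circle from the other strand).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .genome_io import FeatureTable

Signed = tuple[str, int]  # (label, +1/-1)


class GeneOrderError(ValueError):
    pass


def parse_signed(label: str) -> Signed:
    label = label.strip()
    if label.startswith("-"):
        return (label[1:], -1)
    return (label, +1)


def format_signed(g: Signed) -> str:
    return g[0] if g[1] > 0 else f"-{g[0]}"


@dataclass(frozen=True)
class GeneOrder:
    """A signed circular permutation of gene labels."""

    labels: tuple[Signed, ...]
    source_id: str = ""
    duplicated: tuple[str, ...] = ()  # genes collapsed from multiple copies

    def __post_init__(self):
        if not self.labels:
            raise GeneOrderError("gene order must be non-empty")
        names = [g[0] for g in self.labels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GeneOrderError(f"repeated labels in order: {dupes}")

    @classmethod
    def from_strings(cls, labels: list[str], source_id: str = "") -> "GeneOrder":
        return cls(tuple(parse_signed(x) for x in labels), source_id=source_id)

    def to_strings(self) -> list[str]:
        return [format_signed(g) for g in self.labels]

    @property
    def names(self) -> frozenset[str]:
        return frozenset(g[0] for g in self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def _neg(g: Signed) -> Signed:
    return (g[0], -g[1])


def canonical_adjacency(x: Signed, y: Signed) -> tuple[Signed, Signed]:
    """Orientation-aware adjacency; x->y and -y->-x are the same adjacency."""
    return min((x, y), (_neg(y), _neg(x)))


def adjacency_set(order: GeneOrder) -> frozenset[tuple[Signed, Signed]]:
    n = len(order.labels)
    return frozenset(
        canonical_adjacency(order.labels[i], order.labels[(i + 1) % n])
        for i in range(n))


def order_from_table(table: FeatureTable, collapse_duplicates: bool = True,
                     include_control_region: bool = False) -> GeneOrder:
    """Gene order in J-strand positional order, signs from strand.

    Duplicated genes (same name, multiple copy_index) are collapsed to a
    single entry and reported in ``duplicated`` when requested; adjacency
    analysis is ill-defined on multisets.
    """
    labels: list[Signed] = []
    seen: dict[str, int] = {}
    duplicated: list[str] = []
    for f in table:
        if f.ftype in ("control_region",) and not include_control_region:
            continue
        if f.ftype in ("repeat_region", "other"):
            continue
        sign = +1 if f.strand == "J" else -1
        if f.name in seen:
            if not collapse_duplicates:
                raise GeneOrderError(
                    f"duplicated gene {f.name} cannot enter an order uncollapsed")
            if f.name not in duplicated:
                duplicated.append(f.name)
            continue
        seen[f.name] = 1
        labels.append((f.name, sign))
    return GeneOrder(tuple(labels), source_id=table.genome_id,
                     duplicated=tuple(duplicated))


def canonical_rotation(order: GeneOrder, anchor: str = "cox1") -> GeneOrder:
    """Rotate the circular order so that ``anchor`` comes first."""
    names = [g[0] for g in order.labels]
    if anchor not in names:
        raise GeneOrderError(f"anchor {anchor!r} not present in order")
    i = names.index(anchor)
    return GeneOrder(order.labels[i:] + order.labels[:i],
                     source_id=order.source_id, duplicated=order.duplicated)


def _require_same_labels(a: GeneOrder, b: GeneOrder) -> None:
    if a.names != b.names:
        only_a = sorted(a.names - b.names)
        only_b = sorted(b.names - a.names)
        raise GeneOrderError(
            f"label sets differ (only in {a.source_id or 'first'}: {only_a}; "
            f"only in {b.source_id or 'second'}: {only_b})")


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of oriented adjacencies of ``a`` absent from ``b``."""
    _require_same_labels(a, b)
    return len(adjacency_set(a) - adjacency_set(b))


def broken_adjacencies(a: GeneOrder, b: GeneOrder) -> list[tuple[Signed, Signed]]:
    _require_same_labels(a, b)
    return sorted(adjacency_set(a) - adjacency_set(b))


@dataclass(frozen=True)
class RearrangementReport:
    breakpoint_count: int
    conserved_blocks: tuple[tuple[Signed, ...], ...]
    displaced_genes: tuple[str, ...]


def diff_blocks(a: GeneOrder, b: GeneOrder) -> RearrangementReport:
    """Maximal runs of ``a`` conserved in ``b``, plus fully displaced genes.

    A displaced gene is one whose adjacencies on both sides changed — the
    signature of a single-gene translocation.  Blocks are maximal circular
    runs of ``a`` whose internal adjacencies are all present in ``b``;
    ties in the decomposition resolve leftmost-longest.
    """
    _require_same_labels(a, b)
    adj_b = adjacency_set(b)
    n = len(a.labels)
    shared = [canonical_adjacency(a.labels[i], a.labels[(i + 1) % n]) in adj_b
              for i in range(n)]
    displaced = tuple(a.labels[i][0] for i in range(n)
                      if not shared[i - 1] and not shared[i])
    if all(shared):
        blocks: tuple[tuple[Signed, ...], ...] = (a.labels,)
    else:
        # cut the circle at every breakpoint; blocks are the arcs between cuts
        cuts = [i for i in range(n) if not shared[i]]  # break after position i
        blocks_list = []
        for ci, cut in enumerate(cuts):
            start = (cut + 1) % n
            end = cuts[(ci + 1) % len(cuts)]
            run = []
            i = start
            while True:
                run.append(a.labels[i])
                if i == end:
                    break
                i = (i + 1) % n
            blocks_list.append(tuple(run))
        # leftmost-longest presentation order
        blocks_list.sort(key=lambda r: (-len(r), a.labels.index(r[0])))
        blocks = tuple(blocks_list)
    return RearrangementReport(
        breakpoint_count=sum(1 for s in shared if not s),
        conserved_blocks=blocks,
        displaced_genes=displaced)


def shared_derived_adjacencies(orders: list[GeneOrder], reference: GeneOrder
                               ) -> list[tuple[Signed, Signed]]:
    """Adjacencies present in every query order but absent from the reference."""
    if len(orders) < 2:
        raise GeneOrderError("need at least two query orders")
    for o in orders:
        _require_same_labels(o, reference)
    shared = adjacency_set(orders[0])
    for o in orders[1:]:
        shared &= adjacency_set(o)
    return sorted(shared - adjacency_set(reference))


def report_to_json(report: RearrangementReport) -> str:
    return json.dumps({
        "breakpoint_count": report.breakpoint_count,
        "conserved_blocks": [[format_signed(g) for g in blk]
                             for blk in report.conserved_blocks],
        "displaced_genes": list(report.displaced_genes),
    }, indent=2)


def read_order_file(path: str | Path) -> dict[str, GeneOrder]:
    """Read a gene-order spec file: ``id<TAB>label,label,...`` per line."""
    out: dict[str, GeneOrder] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, labels = line.partition("\t")
        if not labels:
            raise GeneOrderError(f"malformed order line: {line!r}")
        out[name] = GeneOrder.from_strings(labels.split(","), source_id=name)
    return out


def write_order_file(orders: dict[str, GeneOrder], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, o in orders.items():
            fh.write(f"{name}\t{','.join(o.to_strings())}\n")


def load_packaged_order(name: str) -> GeneOrder:
    """Load a reference order shipped with the package.

    Available: ``ancestral_insect`` (the putative ancestral insect
    arrangement), ``delphacid`` (the shared planthopper arrangement) and
    ``sbph_prior`` (the previously published L. striatellus individual,
    with trnH between nad4L and nad6).
    """
    ref = resources.files("mitocomp.data.orders").joinpath(f"{name}.order")
    with resources.as_file(ref) as p:
        orders = read_order_file(p)
    return orders[name]
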