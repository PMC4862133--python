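"""Reading, classifying and aggregating RepeatMasker TE annotations.

This module turns RepeatMasker ``.out`` reports into :class:`TEAnnotation`
records carrying a Wicker-style (order, superfamily) identity, resolves
overlapping hits so that every genomic base is counted once, and aggregates
masked base pairs per order and superfamily.

Coordinates are 0-based half-open internally; the 1-based inclusive
convention of ``.out`` files is converted at the parsing boundary.
"""

from __future__ import annotations

import dataclasses
from bisect import insort
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Closed set of TE orders used throughout the package (Wicker scheme plus
#: the catch-all buckets used in whole-genome TE censuses).
ORDERS = ("LTR", "LINE", "TIR", "Helitron", "Maverick", "Others", "Unknown")

#: RepeatMasker classes that are not transposable elements; dropped at parse
#: time (equivalent to masking with ``nolow``/``norna`` and a TE-only library).
NON_TE_CLASSES = frozenset(
    {
        "Simple_repeat",
        "Low_complexity",
        "Satellite",
        "rRNA",
        "tRNA",
        "snRNA",
        "scRNA",
        "srpRNA",
        "RNA",
        "ARTEFACT",
    }
)

# RepeatMasker class tokens → TE order. "DNA" is RepeatMasker's label for
# TIR transposons, "RC" (rolling circle) for Helitrons.
_CLASS_TO_ORDER = {
    "LTR": "LTR",
    "LINE": "LINE",
    "DNA": "TIR",
    "TIR": "TIR",
    "RC": "Helitron",
    "Helitron": "Helitron",
    "Maverick": "Maverick",
    "Polinton": "Maverick",
    "SINE": "Others",
    "Other": "Others",
    "Others": "Others",
    "Unknown": "Unknown",
    "Unspecified": "Unknown",
}


@dataclass(frozen=True, order=True)
class TEAnnotation:
    """One masked interval on a scaffold, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    strand: str  # '+', '-' or 'unknown'
    family: str
    superfamily: str
    order: str
    score: int
    divergence: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )
        if self.order not in ORDERS:
            raise ValueError(f"unknown TE order {self.order!r}")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CategoryMass:
    """Aggregated TE mass for one order or superfamily."""

    category: str
    level: str  # 'order' or 'superfamily'
    annotated_bp: int
    share_of_te_total: float  # percent of the total TE mass


class Taxonomy:
    """Total mapping from repeat family names to (order, superfamily).

    Lookups fall through exact family name → RepeatMasker ``class/family``
    string → class token alone; anything unresolvable maps to
    ``(Unknown, Unknown)``.
    """

    def __init__(self, mapping: Mapping[str, tuple[str, str]]):
        self._by_family: dict[str, tuple[str, str]] = {}
        for family, (order, superfamily) in mapping.items():
            if order not in ORDERS:
                raise ValueError(f"taxonomy entry {family!r} has unknown order {order!r}")
            self._by_family[family] = (order, superfamily)
        # invariant: a superfamily never spans two orders
        seen: dict[str, str] = {}
        for order, superfamily in self._by_family.values():
            if superfamily in seen and seen[superfamily] != order:
                raise ValueError(f"superfamily {superfamily!r} mapped to two orders")
            seen[superfamily] = order

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"family", "superfamily", "order"}
        if not required.issubset(df.columns):
            raise ValueError(f"taxonomy TSV needs columns {sorted(required)}")
        return cls({r.family: (r.order, r.superfamily) for r in df.itertuples()})

    @classmethod
    def default(cls) -> "Taxonomy":
        with resources.as_file(
            resources.files("tecensus.data") / "te_taxonomy.tsv"
        ) as p:
            return cls.from_tsv(p)

    def classify(self, name: str) -> tuple[str, str]:
        """Resolve a family or ``class/family`` string to (order, superfamily)."""
        name = name.strip()
        if name in self._by_family:
            return self._by_family[name]
        head, sep, tail = name.partition("/")
        if sep:
            # order/superfamily is the usual layout, but superfamily/order
            # strings also occur in the wild; try both sides
            for candidate in (tail, tail.split("-")[0], head, head.split("-")[0]):
                if candidate in self._by_family:
                    return self._by_family[candidate]
            order = _CLASS_TO_ORDER.get(head) or _CLASS_TO_ORDER.get(head.split("-")[0])
            if order is None or order == "Unknown":
                return ("Unknown", "Unknown")
            if order in ("Helitron", "Maverick"):
                return (order, order)
            # order is recognisable but the superfamily is not in the taxonomy
            return (order, "Unknown")
        stem = name.split("-")[0]
        if stem in self._by_family:
            return self._by_family[stem]
        if name in _CLASS_TO_ORDER:
            order = _CLASS_TO_ORDER[name]
            if order in ("Helitron", "Maverick"):
                return (order, order)
        return ("Unknown", "Unknown")


def classify(family: str, taxonomy: Taxonomy | None = None) -> tuple[str, str]:
    """Convenience wrapper around :meth:`Taxonomy.classify`."""
    return (taxonomy or Taxonomy.default()).classify(family)


def _is_header(line: str) -> bool:
    stripped = line.strip()
    if not stripped:
        return True
    first = stripped.split()[0]
    return first in ("SW", "score", "bit")


def parse_repeatmasker_out(
    path: str | Path,
    min_score: int = 250,
    taxonomy: Taxonomy | None = None,
    drop_non_te: bool = True,
) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` report into annotations.

    Records below ``min_score`` are dropped (the census default cutoff is a
    Smith-Waterman score of 250), as are simple/low-complexity/satellite/RNA
    classes when ``drop_non_te`` is set. Records flagged ``*`` (overlapped by
    a higher-scoring hit) are retained; overlap policy is applied explicitly
    by :func:`resolve_overlaps`.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` (with
    the line number) for an empty file or a malformed record. A header-only
    file yields an empty list.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: file is empty (expected a RepeatMasker header)")
    taxonomy = taxonomy or Taxonomy.default()
    annotations: list[TEAnnotation] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if _is_header(line):
            continue
        fields = line.split()
        if len(fields) < 14:
            raise ValueError(f"{path}:{lineno}: expected >=14 fields, got {len(fields)}")
        try:
            score = int(fields[0])
            divergence = float(fields[1])
            scaffold = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from None
        if end < begin:
            raise ValueError(f"{path}:{lineno}: end ({end}) < begin ({begin})")
        strand = "+" if fields[8] == "+" else "-"
        family = fields[9]
        repeat_class = fields[10]
        if drop_non_te and (
            repeat_class in NON_TE_CLASSES or repeat_class.split("/")[0] in NON_TE_CLASSES
        ):
            continue
        if score < min_score:
            continue
        order, superfamily = taxonomy.classify(repeat_class)
        if order == "Unknown":
            fam_order, fam_superfamily = taxonomy.classify(family)
            if fam_order != "Unknown":
                order, superfamily = fam_order, fam_superfamily
        annotations.append(
            TEAnnotation(
                scaffold_id=scaffold,
                start=begin - 1,  # 1-based inclusive → 0-based half-open
                end=end,
                strand=strand,
                family=family,
                superfamily=superfamily,
                order=order,
                score=score,
                divergence=divergence,
            )
        )
    return annotations


def write_repeatmasker_out(annotations: Iterable[TEAnnotation], path: str | Path) -> None:
    """Write annotations in the ``.out`` dialect read by :func:`parse_repeatmasker_out`."""
    lines = [
        "   SW  perc perc perc  query     position in query    matching repeat "
        "       position in repeat",
        "score  div. del. ins.  sequence  begin end   (left)   repeat class/family "
        " begin end (left) ID",
        "",
    ]
    for i, a in enumerate(sorted(annotations), start=1):
        superfamily = a.superfamily.replace(" ", "_")
        cls = f"{a.order}/{superfamily}"
        strand = "+" if a.strand == "+" else "C"
        div = 0.0 if a.divergence is None else a.divergence
        lines.append(
            f"{a.score} {div:.1f} 0.0 0.0 {a.scaffold_id} {a.start + 1} {a.end} (0) "
            f"{strand} {a.family} {cls} 1 {a.length} (0) {i}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _subtract(start: int, end: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of [start, end) not covered by the sorted disjoint ``claimed`` list."""
    pieces: list[tuple[int, int]] = []
    cursor = start
    for cs, ce in claimed:
        if ce <= cursor:
            continue
        if cs >= end:
            break
        if cs > cursor:
            pieces.append((cursor, cs))
        cursor = max(cursor, ce)
        if cursor >= end:
            break
    if cursor < end:
        pieces.append((cursor, end))
    return pieces


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def resolve_overlaps(annotations: Iterable[TEAnnotation]) -> list[TEAnnotation]:
    """Make annotations pairwise disjoint per scaffold.

    Each base is assigned to exactly one input annotation: the highest
    Smith-Waterman score wins, ties broken by earlier start and then by
    lexicographic family name. Annotations partially shadowed by better hits
    are trimmed (possibly into several fragments); fully shadowed ones drop
    out, so a duplicated record survives exactly once.
    """
    by_scaffold: dict[str, list[TEAnnotation]] = {}
    for a in annotations:
        by_scaffold.setdefault(a.scaffold_id, []).append(a)
    out: list[TEAnnotation] = []
    for scaffold in sorted(by_scaffold):
        claimed: list[tuple[int, int]] = []
        ranked = sorted(
            by_scaffold[scaffold], key=lambda a: (-a.score, a.start, a.family)
        )
        for a in ranked:
            for s, e in _subtract(a.start, a.end, claimed):
                out.append(dataclasses.replace(a, start=s, end=e))
                insort(claimed, (s, e))
            claimed = _merge(claimed)
    return sorted(out)


def category_totals(
    annotations: Iterable[TEAnnotation], policy: str = "distinct"
) -> list[CategoryMass]:
    """Sum annotated bp per superfamily and per order.

    ``policy='distinct'`` (default) expects overlap-resolved input and sums
    lengths as given; ``policy='union'`` sums raw hit lengths without
    deduplication, as a sensitivity check on the overlap policy.
    """
    if policy == "union":
        annotations = list(annotations)
    elif policy == "distinct":
        annotations = list(annotations)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    order_bp: dict[str, int] = {o: 0 for o in ORDERS}
    super_bp: dict[tuple[str, str], int] = {}
    for a in annotations:
        order_bp[a.order] += a.length
        key = (a.order, a.superfamily)
        super_bp[key] = super_bp.get(key, 0) + a.length
    total = sum(order_bp.values())

    def share(bp: int) -> float:
        return 0.0 if total == 0 else 100.0 * bp / total

    masses = [
        CategoryMass(order, "order", bp, share(bp)) for order, bp in order_bp.items()
    ]
    for (order, superfamily), bp in sorted(super_bp.items()):
        masses.append(CategoryMass(superfamily, "superfamily", bp, share(bp)))
    return masses


def mass_table(masses: Iterable[CategoryMass]) -> pd.DataFrame:
    """Tabulate category masses with bp, kb and percent-of-TE-total columns."""
    rows = [
        {
            "level": m.level,
            "category": m.category,
            "bp": m.annotated_bp,
            "kb": m.annotated_bp / 1000.0,
            "share_pct": m.share_of_te_total,
        }
        for m in masses
    ]
    return pd.DataFrame(rows, columns=["level", "category", "bp", "kb", "share_pct"])
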