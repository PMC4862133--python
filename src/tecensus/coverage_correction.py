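"""Coverage-based correction of assembly TE abundance.

Collapsed repeat copies inflate read depth over the copies that survive
assembly. Summing the aligned read bases over TE-annotated positions and
dividing by a reference average coverage therefore estimates the
pre-collapse TE mass:

    corrected_bp = Σ depth over category positions / C̄
    factor       = corrected_bp / annotated_bp

The reference coverage C̄ comes either from a gene interval set (genes are
assumed collapse-free) or from an external scalar such as an assembler's
coverage estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation_io import ORDERS, TEAnnotation

logger = logging.getLogger(__name__)

TOTAL = "Total"


@dataclass
class CoverageTrack:
    """Per-base aligned-read depth for one scaffold."""

    scaffold_id: str
    depth: np.ndarray  # int64, one entry per base

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class ReferenceCoverage:
    """Mean depth (×) used as the correction denominator."""

    value: float
    source: str  # 'gene_intervals' or 'external_scalar'

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("reference coverage must be positive")


@dataclass
class DepthSummary:
    tracks: dict[str, CoverageTrack]
    n_used: int = 0
    n_unmapped: int = 0
    n_filtered: int = 0

    def total_aligned_bases(self) -> int:
        return int(sum(t.depth.sum() for t in self.tracks.values()))


def depth_track(
    alignments: str | Path | pysam.AlignmentFile,
    scaffold_lengths: Mapping[str, int],
    min_mapq: int = 0,
) -> DepthSummary:
    """Per-base depth from a SAM/BAM stream.

    Only mapped primary alignments are counted (secondary and supplementary
    records are filtered); depth at a position is the number of read bases
    aligned there, so insertions and clips contribute nothing and deletions
    add no read base. By default no MAPQ filter is applied: multi-mapped
    placements carry the collapse signal.
    """
    own = isinstance(alignments, (str, Path))
    af = (
        pysam.AlignmentFile(str(alignments), check_sq=False) if own else alignments
    )
    try:
        for name in af.references or ():
            if name not in scaffold_lengths:
                raise ValueError(f"scaffold {name!r} absent from the length table")
        tracks = {
            name: CoverageTrack(name, np.zeros(length, dtype=np.int64))
            for name, length in scaffold_lengths.items()
        }
        summary = DepthSummary(tracks)
        for read in af:
            if read.is_unmapped:
                summary.n_unmapped += 1
                continue
            if read.is_secondary or read.is_supplementary or read.mapping_quality < min_mapq:
                summary.n_filtered += 1
                continue
            name = read.reference_name
            if name not in tracks:
                raise ValueError(f"scaffold {name!r} absent from the length table")
            depth = tracks[name].depth
            for s, e in read.get_blocks():
                depth[s:e] += 1
            summary.n_used += 1
        if summary.n_unmapped:
            logger.info("skipped %d unmapped records", summary.n_unmapped)
        return summary
    finally:
        if own:
            af.close()


def read_depth_tsv(path: str | Path, scaffold_lengths: Mapping[str, int]) -> DepthSummary:
    """Read the (scaffold, pos, depth) TSV dialect; pos is 0-based.

    Positions absent from the file have depth zero.
    """
    tracks = {
        name: CoverageTrack(name, np.zeros(length, dtype=np.int64))
        for name, length in scaffold_lengths.items()
    }
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["scaffold", "pos", "depth"], dtype={"scaffold": str}
    )
    for scaffold, grp in df.groupby("scaffold"):
        if scaffold not in tracks:
            raise ValueError(f"scaffold {scaffold!r} absent from the length table")
        tracks[scaffold].depth[grp["pos"].to_numpy()] = grp["depth"].to_numpy()
    return DepthSummary(tracks)


def write_depth_tsv(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    """Write non-zero depths as (scaffold, pos, depth) rows."""
    with open(path, "w") as fh:
        for name in sorted(tracks):
            depth = tracks[name].depth
            for pos in np.nonzero(depth)[0]:
                fh.write(f"{name}\t{pos}\t{depth[pos]}\n")


def mean_feature_coverage(
    tracks: Mapping[str, CoverageTrack],
    features: Iterable[tuple[str, int, int]],
    source: str = "gene_intervals",
) -> ReferenceCoverage:
    """Mean depth over a set of overlap-resolved intervals.

    value = Σ depth over feature positions / Σ feature lengths. Used with
    gene intervals to estimate the genome-wide single-copy coverage.
    """
    total_depth = 0
    total_len = 0
    for scaffold, start, end in features:
        if scaffold not in tracks:
            raise ValueError(f"feature scaffold {scaffold!r} has no coverage track")
        total_depth += int(tracks[scaffold].depth[start:end].sum())
        total_len += end - start
    if total_len == 0:
        raise ValueError("zero total feature length")
    value = total_depth / total_len
    if value == 0:
        raise ValueError("features have zero coverage; cannot form a reference")
    return ReferenceCoverage(value, source)


def corrected_mass(
    tracks: Mapping[str, CoverageTrack],
    annotations: Iterable[TEAnnotation],
    ref_cov: ReferenceCoverage,
) -> pd.DataFrame:
    """Per-category read mass, corrected bp and correction factor.

    Expects overlap-resolved annotations. Returns one row per superfamily
    (within its order), per order, and a ``Total`` row; ``factor`` is NaN
    where annotated_bp is zero.
    """
    annotated: dict[tuple[str, str, str], int] = {}
    read_mass: dict[tuple[str, str, str], int] = {}

    def bump(key: tuple[str, str, str], bp: int, mass: int) -> None:
        annotated[key] = annotated.get(key, 0) + bp
        read_mass[key] = read_mass.get(key, 0) + mass

    for a in annotations:
        if a.scaffold_id not in tracks:
            raise ValueError(f"annotation scaffold {a.scaffold_id!r} has no coverage track")
        mass = int(tracks[a.scaffold_id].depth[a.start : a.end].sum())
        bump(("superfamily", a.order, a.superfamily), a.length, mass)
        bump(("order", a.order, a.order), a.length, mass)
        bump(("total", TOTAL, TOTAL), a.length, mass)

    order_rank = {o: i for i, o in enumerate(ORDERS)}
    keys = sorted(
        annotated,
        key=lambda k: (
            order_rank.get(k[1], len(ORDERS)),
            {"order": 0, "superfamily": 1, "total": 2}[k[0]],
            k[2],
        ),
    )
    rows = []
    for level, order, category in keys:
        ann = annotated[(level, order, category)]
        mass = read_mass[(level, order, category)]
        corr = mass / ref_cov.value
        rows.append(
            {
                "level": level,
                "order": order,
                "category": category,
                "annotated_bp": ann,
                "read_mass_bp": mass,
                "corrected_bp": corr,
                "factor": corr / ann if ann else float("nan"),
                "delta_bp": corr - ann,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "level",
            "order",
            "category",
            "annotated_bp",
            "read_mass_bp",
            "corrected_bp",
            "factor",
            "delta_bp",
        ],
    )


def correction_factors(
    annotated: Sequence[float], corrected: Sequence[float]
) -> np.ndarray:
    """Corrected/annotated ratio per category, rounded to 2 decimals.

    Categories with zero annotated mass get NaN (undefined factor).
    """
    ann = np.asarray(annotated, dtype=float)
    corr = np.asarray(corrected, dtype=float)
    if ann.shape != corr.shape:
        raise ValueError("annotated and corrected columns must align")
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(ann > 0, corr / ann, np.nan)
    return np.round(factors, 2)


def genome_fraction(
    corrected_bp: float,
    assembly_size_bp: float,
    variant: str = "gaps",
    annotated_bp: float | None = None,
) -> float:
    """TE percent of the genome under two genome-size conventions.

    ``gaps``: the extra corrected mass is assumed to sit in assembly gaps, so
    the assembly size stands for the genome size. ``inflate``: the delta
    (corrected − annotated) is added to the genome size instead.
    """
    if assembly_size_bp <= 0:
        raise ValueError("assembly size must be positive")
    if variant == "gaps":
        return 100.0 * corrected_bp / assembly_size_bp
    if variant == "inflate":
        if annotated_bp is None:
            raise ValueError("variant 'inflate' needs annotated_bp to form the delta")
        delta = corrected_bp - annotated_bp
        return 100.0 * corrected_bp / (assembly_size_bp + delta)
    raise ValueError(f"unknown variant {variant!r}")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Minimal BED3 reader (0-based half-open intervals)."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold, start, end in intervals:
            fh.write(f"{scaffold}\t{start}\t{end}\n")


def plot_correction(table: pd.DataFrame, level: str = "order"):
    """Bar chart of annotated vs corrected kb per category."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = table[table["level"] == level]
    x = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(x - 0.2, sub["annotated_bp"] / 1000, width=0.4, label="annotated")
    ax.bar(x + 0.2, sub["corrected_bp"] / 1000, width=0.4, label="corrected")
    ax.set_xticks(x, sub["category"], rotation=45, ha="right")
    ax.set_ylabel("kb")
    ax.legend()
    fig.tight_layout()
    return fig
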