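"""Windowed TE density along chromosome-ordered scaffolds.

Mapped scaffolds are abutted in their reported order to form a single
chromosome coordinate that starts at the telomere; TE density (TE bp /
window length) is computed in fixed non-overlapping windows (50 kb by
default). The proximal region is the span nearest the centromere, i.e. the
highest chromosome coordinates; the dot chromosome ("6") is treated as a
single region of its own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import TEAnnotation

logger = logging.getLogger(__name__)

PROXIMAL = "proximal"
CENTRAL_DISTAL = "central_distal"
DOT_REGION = "whole_chromosome_6"

#: Chromosome label treated as the dot chromosome (single region, no
#: proximal/central split).
DOT_CHROMOSOME = "6"


@dataclass(frozen=True)
class ScaffoldPlacement:
    scaffold_id: str
    chromosome: str
    index: int  # order along the chromosome, telomere first
    orientation: str  # 'forward' or 'reverse'
    length: int


class ChromosomeMap:
    """Ordered scaffold → chromosome assignment with concatenated coordinates."""

    def __init__(self, placements: Iterable[ScaffoldPlacement]):
        self.placements = sorted(placements, key=lambda p: (p.chromosome, p.index))
        self._offset: dict[str, int] = {}
        self._by_scaffold: dict[str, ScaffoldPlacement] = {}
        lengths: dict[str, int] = {}
        for p in self.placements:
            if p.scaffold_id in self._by_scaffold:
                raise ValueError(f"scaffold {p.scaffold_id!r} placed twice")
            self._offset[p.scaffold_id] = lengths.get(p.chromosome, 0)
            self._by_scaffold[p.scaffold_id] = p
            lengths[p.chromosome] = lengths.get(p.chromosome, 0) + p.length
        self._chrom_length = lengths

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromosomeMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})
        return cls(
            ScaffoldPlacement(
                r.scaffold_id, str(r.chromosome), int(r.index), r.orientation, int(r.length)
            )
            for r in df.itertuples()
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                (p.scaffold_id, p.chromosome, p.index, p.orientation, p.length)
                for p in self.placements
            ],
            columns=["scaffold_id", "chromosome", "index", "orientation", "length"],
        ).to_csv(path, sep="\t", index=False)

    def chromosomes(self) -> list[str]:
        return sorted(self._chrom_length)

    def chromosome_length(self, chromosome: str) -> int:
        return self._chrom_length[chromosome]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._by_scaffold

    def lift(self, scaffold_id: str, start: int, end: int) -> tuple[str, int, int]:
        """Map a scaffold interval to chromosome coordinates.

        Reverse-oriented scaffolds are flipped in place before the scaffold
        offset is added, so coordinates always run telomere → centromere.
        """
        p = self._by_scaffold[scaffold_id]
        if p.orientation == "reverse":
            start, end = p.length - end, p.length - start
        off = self._offset[scaffold_id]
        return p.chromosome, off + start, off + end


@dataclass(frozen=True)
class WindowDensity:
    """One fixed-width window on a chromosome with its TE content."""

    chromosome: str
    start: int
    end: int
    te_bp: int = 0
    is_full: bool = True

    @property
    def density(self) -> float:
        return self.te_bp / (self.end - self.start)


def make_windows(
    chrom_map: ChromosomeMap, width: int = 50_000, include_partial: bool = False
) -> list[WindowDensity]:
    """Tile each chromosome with consecutive half-open windows of ``width`` bp.

    The trailing sub-width window is appended only when ``include_partial``
    is set (plotting mode); statistics use whole windows only.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    windows: list[WindowDensity] = []
    for chrom in chrom_map.chromosomes():
        length = chrom_map.chromosome_length(chrom)
        pos = 0
        while pos + width <= length:
            windows.append(WindowDensity(chrom, pos, pos + width))
            pos += width
        if include_partial and pos < length:
            windows.append(WindowDensity(chrom, pos, length, is_full=False))
    return windows


def te_bp_per_window(
    windows: Sequence[WindowDensity],
    annotations: Iterable[TEAnnotation],
    chrom_map: ChromosomeMap,
) -> list[WindowDensity]:
    """Intersect overlap-resolved annotations with windows.

    An annotation spanning a window boundary contributes its overlap to each
    side. Annotations on scaffolds absent from the map are skipped and
    counted in a log message.
    """
    starts: dict[str, np.ndarray] = {}
    te_bp: dict[str, np.ndarray] = {}
    index_of: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        index_of.setdefault(w.chromosome, []).append(i)
    bounds = {
        chrom: np.array([windows[i].start for i in idx] + [windows[idx[-1]].end])
        for chrom, idx in index_of.items()
    }
    acc = {chrom: np.zeros(len(idx), dtype=np.int64) for chrom, idx in index_of.items()}
    skipped = 0
    for a in annotations:
        if a.scaffold_id not in chrom_map:
            skipped += 1
            continue
        chrom, s, e = chrom_map.lift(a.scaffold_id, a.start, a.end)
        if chrom not in bounds:
            continue
        edges = bounds[chrom]
        lo = int(np.searchsorted(edges, s, side="right")) - 1
        hi = int(np.searchsorted(edges, e, side="left"))
        for k in range(max(lo, 0), min(hi, len(edges) - 1)):
            overlap = min(e, edges[k + 1]) - max(s, edges[k])
            if overlap > 0:
                acc[chrom][k] += overlap
    if skipped:
        logger.info("skipped %d annotations on scaffolds absent from the map", skipped)
    out = list(windows)
    for chrom, idx in index_of.items():
        for k, i in enumerate(idx):
            out[i] = replace(out[i], te_bp=int(acc[chrom][k]))
    return out


def partition_regions(
    windows: Sequence[WindowDensity],
    chrom_map: ChromosomeMap,
    proximal_span: int = 3_000_000,
    dot_chromosome: str = DOT_CHROMOSOME,
) -> list[str]:
    """Label each window proximal / central_distal / dot-chromosome region.

    Proximal windows are those whose start lies in the most
    centromere-proximal ``proximal_span`` bp, i.e. the last span of the
    concatenated chromosome (coordinates run telomere → centromere). The dot
    chromosome is one undivided region.
    """
    regions: list[str] = []
    warned: set[str] = set()
    for w in windows:
        if w.chromosome == dot_chromosome:
            regions.append(DOT_REGION)
            continue
        length = chrom_map.chromosome_length(w.chromosome)
        if length <= proximal_span:
            if w.chromosome not in warned:
                warnings.warn(
                    f"chromosome {w.chromosome} shorter than the {proximal_span} bp "
                    "proximal span; treating it as entirely proximal",
                    stacklevel=2,
                )
                warned.add(w.chromosome)
            regions.append(PROXIMAL)
        elif w.start >= length - proximal_span:
            regions.append(PROXIMAL)
        else:
            regions.append(CENTRAL_DISTAL)
    return regions


def region_stats(
    windows: Sequence[WindowDensity], regions: Sequence[str]
) -> pd.DataFrame:
    """Mean TE density (percent), sample sd and window count per (chromosome, region).

    Only whole windows enter the statistics. A pooled ``Total`` block sums
    over chromosomes per region and overall.
    """
    rows = [
        (w.chromosome, r, w.density)
        for w, r in zip(windows, regions)
        if w.is_full
    ]
    df = pd.DataFrame(rows, columns=["chromosome", "region", "density"])
    out_rows = []

    def summarise(chrom: str, region: str, values: pd.Series) -> None:
        n = len(values)
        mean = float(values.mean()) * 100 if n else float("nan")
        sd = float(values.std(ddof=1)) * 100 if n > 1 else (0.0 if n == 1 else float("nan"))
        out_rows.append((chrom, region, mean, sd, n))

    for (chrom, region), grp in df.groupby(["chromosome", "region"], sort=True):
        summarise(chrom, region, grp["density"])
    for region, grp in df.groupby("region", sort=True):
        summarise("Total", region, grp["density"])
    summarise("Total", "all", df["density"])
    return pd.DataFrame(
        out_rows, columns=["chromosome", "region", "mean_pct", "sd_pct", "n_windows"]
    )


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Returns the scipy result object (``.statistic`` is the maximum ECDF gap
    D, ``.pvalue`` the two-sided p). Samples of fewer than two values are
    refused.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("KS comparison needs at least 2 values per sample")
    return stats.ks_2samp(a, b)


def ks_matrix(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise KS comparisons with raw and Holm-adjusted p-values."""
    labels = list(samples)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            res = ks_compare(samples[la], samples[lb])
            rows.append((la, lb, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "D", "p"])
    if len(df):
        # Holm step-down adjustment of the raw p-values
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[idx])
            adjusted[idx] = min(1.0, running)
        df["p_holm"] = adjusted
    else:
        df["p_holm"] = []
    return df


def window_table(windows: Sequence[WindowDensity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.chromosome, w.start, w.end, w.te_bp, w.density, w.is_full)
            for w in windows
        ],
        columns=["chromosome", "start", "end", "te_bp", "density", "is_full"],
    )


def plot_density(windows: Sequence[WindowDensity], proximal_span: int = 3_000_000):
    """One panel per chromosome: TE density along the chromosome, telomere left.

    A vertical line marks the start of the proximal span.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    chroms = sorted({w.chromosome for w in windows})
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        ws = [w for w in windows if w.chromosome == chrom]
        x = [(w.start + w.end) / 2 / 1e6 for w in ws]
        y = [w.density for w in ws]
        ax.scatter(x, y, s=6)
        end = max(w.end for w in ws)
        if chrom != DOT_CHROMOSOME and end > proximal_span:
            ax.axvline((end - proximal_span) / 1e6, color="red", lw=1)
        ax.set_ylabel(f"chr {chrom}")
        ax.set_ylim(0, 1)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    return fig
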