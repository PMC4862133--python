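"""Cross-assembly TE-fraction comparison and assembly summary statistics.

Assemblies are grouped by sequencing technology (Sanger vs NGS); group means
are compared with a two-sided Mann-Whitney U test (exact null distribution
for small tie-free samples). Nx scaffold statistics (N50/N90 index and
length) summarise assembly contiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GenomeRecord:
    """One assembly: identity, sequencing-method group and TE fraction."""

    species: str
    strain: str
    subgenus: str
    group: str
    subgroup: str
    seq_method: str  # 'Sanger' or 'NGS'
    te_percent: float

    def __post_init__(self) -> None:
        if not (0 <= self.te_percent <= 100):
            raise ValueError("te_percent must be in [0, 100]")


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float
    pvalue: float
    method: str  # 'exact' or 'asymptotic'


def read_genome_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.fillna({"strain": ""})


def records_from_table(df: pd.DataFrame) -> list[GenomeRecord]:
    return [
        GenomeRecord(
            r.species, str(getattr(r, "strain", "") or ""), r.subgenus, r.group,
            r.subgroup, r.seq_method, float(r.te_percent),
        )
        for r in df.itertuples()
    ]


def group_means(df: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean TE percent and count per sequencing-method group."""
    out = (
        df.groupby("seq_method")["te_percent"]
        .agg(mean_te_pct="mean", n="count")
        .reset_index()
    )
    out["mean_te_pct_2dp"] = out["mean_te_pct"].round(2)
    return out


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test between two samples.

    The exact null distribution is used when both samples have at most 25
    values and there are no ties; otherwise the normal approximation with
    continuity correction. The method used is recorded in the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; p = 1", stacklevel=2)
        return MannWhitneyResult(float(len(a) * len(b) / 2), 1.0, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


def nx_stats(scaffold_lengths: Sequence[int], fraction: float = 0.5) -> tuple[int, int]:
    """Nx (index, length) of a scaffold length list.

    With lengths sorted descending, the index is the number of scaffolds
    whose cumulative length first reaches ``fraction`` of the total, and the
    length is that scaffold's length (N50 at fraction 0.5, N90 at 0.9).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    lengths = sorted((int(x) for x in scaffold_lengths), reverse=True)
    if not lengths:
        raise ValueError("empty scaffold length list")
    threshold = fraction * sum(lengths)
    running = 0
    for i, length in enumerate(lengths, start=1):
        running += length
        if running >= threshold:
            return i, length
    raise AssertionError("unreachable: cumulative sum covers the total")


def paired_subgroups(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table of subgroups sequenced with both technologies.

    No test is attached: the records are not phylogenetically independent,
    so the pairing is reported as-is (mean TE percent per technology within
    each subgroup that has both).
    """
    pivot = (
        df.groupby(["subgroup", "seq_method"])["te_percent"].mean().unstack("seq_method")
    )
    both = pivot.dropna(subset=["Sanger", "NGS"]).reset_index()
    both.columns.name = None
    return both.rename(columns={"Sanger": "sanger_te_pct", "NGS": "ngs_te_pct"})[
        ["subgroup", "sanger_te_pct", "ngs_te_pct"]
    ]


def plot_group_boxplot(df: pd.DataFrame):
    """Boxplot of TE percent by sequencing technology."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = sorted(df["seq_method"].unique())
    data = [df.loc[df["seq_method"] == g, "te_percent"] for g in groups]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel("TE % of assembly")
    fig.tight_layout()
    return fig
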