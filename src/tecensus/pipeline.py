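"""Composed pipeline: annotations → windows → correction → comparison.

Each stage is independently invokable (see :mod:`tecensus.cli`); the
pipeline is their composition over one :class:`RunConfig`. Every emitted
table carries a provenance header with the tool version, a hash of the run
manifest and the seed, so a re-run from the same manifest is byte-identical
for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from ._provenance import manifest_hash, write_table
from .annotation_io import Taxonomy, category_totals, mass_table, parse_repeatmasker_out, resolve_overlaps
from .coverage_correction import (
    ReferenceCoverage,
    corrected_mass,
    depth_track,
    genome_fraction,
    mean_feature_coverage,
    read_bed,
    read_depth_tsv,
)
from .genome_comparison import group_means, mann_whitney, paired_subgroups, read_genome_table
from .window_density import (
    ChromosomeMap,
    ks_matrix,
    make_windows,
    partition_regions,
    region_stats,
    te_bp_per_window,
    window_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    outdir: str
    annotations: str | None = None
    taxonomy: str | None = None
    chrom_map: str | None = None
    alignments: str | None = None  # SAM/BAM or depth TSV (by extension)
    genes: str | None = None
    genome_table: str | None = None
    assembly_size: float | None = None
    window_width: int = 50_000
    proximal_span: int = 3_000_000
    min_score: int = 250
    min_mapq: int = 0
    ref_coverage: float | None = None  # external scalar; genes BED otherwise
    seed: int = 0

    def manifest(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["version"] = __version__
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage whose inputs are configured; return written paths.

    Stages with missing optional inputs are skipped with a log message;
    a missing *configured* input raises ``FileNotFoundError``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = config.manifest()
    written: dict[str, Path] = {}

    for attr in ("annotations", "taxonomy", "chrom_map", "alignments", "genes", "genome_table"):
        value = getattr(config, attr)
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"{attr} input not found: {value}")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps({**manifest, "manifest_hash": manifest_hash(manifest)}, indent=2, sort_keys=True)
        + "\n"
    )
    written["manifest"] = manifest_path

    taxonomy = Taxonomy.from_tsv(config.taxonomy) if config.taxonomy else Taxonomy.default()

    resolved = None
    if config.annotations:
        parsed = parse_repeatmasker_out(config.annotations, config.min_score, taxonomy)
        resolved = resolve_overlaps(parsed)
        masses = category_totals(resolved)
        path = outdir / "category_mass.tsv"
        write_table(mass_table(masses), path, manifest)
        written["category_mass"] = path
    else:
        logger.info("no annotations configured; skipping the summary stage")

    if config.chrom_map and resolved is not None:
        chrom_map = ChromosomeMap.from_tsv(config.chrom_map)
        windows = make_windows(chrom_map, config.window_width, include_partial=False)
        windows = te_bp_per_window(windows, resolved, chrom_map)
        regions = partition_regions(windows, chrom_map, config.proximal_span)
        path = outdir / "windows.tsv"
        write_table(window_table(windows), path, manifest)
        written["windows"] = path
        path = outdir / "region_stats.tsv"
        write_table(region_stats(windows, regions), path, manifest)
        written["region_stats"] = path
        samples = {}
        for chrom in chrom_map.chromosomes():
            values = [w.density for w in windows if w.chromosome == chrom]
            if len(values) >= 2:
                samples[chrom] = values
        if len(samples) >= 2:
            path = outdir / "ks_matrix.tsv"
            write_table(ks_matrix(samples), path, manifest)
            written["ks_matrix"] = path
    elif config.chrom_map:
        logger.info("chromosome map given without annotations; skipping windows")

    if config.alignments and resolved is not None:
        lengths_needed = {a.scaffold_id for a in resolved}
        if config.alignments.endswith((".sam", ".bam", ".cram")):
            import pysam

            with pysam.AlignmentFile(config.alignments, check_sq=False) as af:
                lengths = dict(zip(af.references, af.lengths))
            summary = depth_track(config.alignments, lengths, config.min_mapq)
        else:
            # depth TSV dialect needs an explicit universe of scaffolds
            depth_df = pd.read_csv(
                config.alignments, sep="\t", comment="#",
                names=["scaffold", "pos", "depth"], dtype={"scaffold": str},
            )
            lengths = {
                scaf: int(grp["pos"].max()) + 1 for scaf, grp in depth_df.groupby("scaffold")
            }
            for scaf in lengths_needed:
                lengths.setdefault(scaf, 1)
            summary = read_depth_tsv(config.alignments, lengths)
        if config.ref_coverage is not None:
            ref = ReferenceCoverage(config.ref_coverage, "external_scalar")
        elif config.genes:
            ref = mean_feature_coverage(summary.tracks, read_bed(config.genes))
        else:
            raise ValueError("correction needs --ref-cov or a genes BED")
        table = corrected_mass(summary.tracks, resolved, ref)
        table.attrs["reference_coverage"] = ref.value
        table.attrs["reference_source"] = ref.source
        if config.assembly_size:
            total = table.loc[table["level"] == "total", :].iloc[0]
            table.loc[table["level"] == "total", "genome_fraction_gaps_pct"] = genome_fraction(
                total["corrected_bp"], config.assembly_size, "gaps"
            )
        path = outdir / "correction.tsv"
        write_table(table, path, manifest)
        written["correction"] = path
    elif config.alignments:
        logger.info("alignments given without annotations; skipping correction")
    else:
        logger.info("no alignments configured; skipping the correction stage")

    if config.genome_table:
        df = read_genome_table(config.genome_table)
        summary_df = group_means(df)
        sanger = df.loc[df["seq_method"] == "Sanger", "te_percent"]
        ngs = df.loc[df["seq_method"] == "NGS", "te_percent"]
        path = outdir / "group_summary.tsv"
        write_table(summary_df, path, manifest)
        written["group_summary"] = path
        if len(sanger) and len(ngs):
            mw = mann_whitney(sanger, ngs)
            test_df = pd.DataFrame(
                [{"U": mw.statistic, "p": mw.pvalue, "method": mw.method}]
            )
            path = outdir / "mannwhitney.tsv"
            write_table(test_df, path, manifest)
            written["mannwhitney"] = path
        paired = paired_subgroups(df)
        path = outdir / "paired_subgroups.tsv"
        write_table(paired, path, manifest)
        written["paired_subgroups"] = path

    return written
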