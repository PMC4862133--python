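"""Self-contained synthetic worlds for testing the TE census pipeline.

A world consists of a "true" multi-scaffold genome carrying TE copies drawn
from family consensus sequences (substitution-only divergence, so true and
assembled masses are exact integers), a collapsed assembly in which all but
``m`` of a family's ``n`` near-identical copies have been merged away, the
annotations an annotator would produce on that assembly, gene intervals in
collapse-free background sequence, and simulated read alignments whose
depth over a retained copy is inflated by the number of source copies it
absorbed. This emulates the assembly artifact whereby a repeat locus in a
short-read assembly is a consensus of several true loci: the sequence is
present once, but the reads of every source copy still map onto it.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation_io import TEAnnotation, write_repeatmasker_out
from .coverage_correction import CoverageTrack, DepthSummary, write_bed
from .window_density import ChromosomeMap, ScaffoldPlacement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ScaffoldPlan:
    name: str
    length: int
    chromosome: str = "U"


@dataclass(frozen=True)
class FamilyPlan:
    """One TE family: n near-identical copies, m of which survive assembly."""

    name: str
    order: str
    superfamily: str
    unit_length: int
    n_copies: int
    m_retained: int
    identity: float = 0.95

    def __post_init__(self) -> None:
        if not (1 <= self.m_retained <= self.n_copies):
            raise ValueError("need 1 <= m_retained <= n_copies")
        if self.unit_length < 50:
            raise ValueError("unit_length must be >= 50")
        if not (0 < self.identity <= 1):
            raise ValueError("identity must be in (0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    scaffolds: list[ScaffoldPlan] = field(default_factory=list)
    families: list[FamilyPlan] = field(default_factory=list)
    coverage: float = 50.0
    coverage_mode: str = "noiseless"  # or 'poisson'
    read_length: int = 100
    gene_count: int = 20
    gene_length: int = 2000

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        payload = json.loads(Path(path).read_text())
        payload["scaffolds"] = [ScaffoldPlan(**s) for s in payload.get("scaffolds", [])]
        payload["families"] = [FamilyPlan(**f) for f in payload.get("families", [])]
        return cls(**payload)


def default_config(seed: int = 0, coverage_mode: str = "noiseless") -> SimConfig:
    """The stock CI world: 5 × 200 kb scaffolds, 6 families across 4 orders."""
    return SimConfig(
        seed=seed,
        scaffolds=[ScaffoldPlan(f"scaf{i}", 200_000, "U") for i in range(1, 6)],
        families=[
            FamilyPlan("Gypsy-sim", "LTR", "Gypsy", 2000, 20, 5),
            FamilyPlan("Copia-sim", "LTR", "Copia", 1500, 10, 5),
            FamilyPlan("Jockey-sim", "LINE", "Jockey", 1800, 12, 6),
            FamilyPlan("R1-sim", "LINE", "R1", 1000, 8, 2),
            FamilyPlan("hAT-sim", "TIR", "hAT", 1200, 15, 5),
            FamilyPlan("Helitron-sim", "Helitron", "Helitron", 1500, 24, 8),
        ],
        coverage=50.0,
        coverage_mode=coverage_mode,
        read_length=100,
    )


@dataclass
class FamilyTruth:
    plan: FamilyPlan
    true_copies: list[tuple[str, int, int]]  # true-genome coordinates
    retained_copies: list[tuple[str, int, int]]  # assembly coordinates
    multiplicities: list[int]  # source copies absorbed per retained copy

    @property
    def true_bp(self) -> int:
        return self.plan.n_copies * self.plan.unit_length

    @property
    def assembled_bp(self) -> int:
        return self.plan.m_retained * self.plan.unit_length


@dataclass
class SyntheticTruth:
    families: dict[str, FamilyTruth]

    def category_bp(self, level: str) -> dict[str, tuple[int, int]]:
        """(true_bp, assembled_bp) per order or superfamily."""
        out: dict[str, tuple[int, int]] = {}
        for ft in self.families.values():
            key = ft.plan.order if level == "order" else ft.plan.superfamily
            t, a = out.get(key, (0, 0))
            out[key] = (t + ft.true_bp, a + ft.assembled_bp)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {
                "plan": dataclasses.asdict(ft.plan),
                "true_copies": ft.true_copies,
                "retained_copies": ft.retained_copies,
                "multiplicities": ft.multiplicities,
            }
            for name, ft in self.families.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class World:
    config: SimConfig
    true_genome: dict[str, str]
    assembly: dict[str, str]
    annotations: list[TEAnnotation]
    genes: list[tuple[str, int, int]]  # assembly coordinates
    truth: SyntheticTruth

    @property
    def assembly_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.assembly.items()}

    def chromosome_map(self) -> ChromosomeMap:
        return ChromosomeMap(
            ScaffoldPlacement(p.name, p.chromosome, i, "forward", len(self.assembly[p.name]))
            for i, p in enumerate(self.config.scaffolds)
        )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, consensus: np.ndarray, identity: float) -> np.ndarray:
    copy = consensus.copy()
    mask = rng.random(len(copy)) < (1.0 - identity)
    # shift by 1-3 mod 4 so a mutated base always differs
    copy[mask] = (copy[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return copy


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    scaffolds: Sequence[ScaffoldPlan],
    length: int,
    max_tries: int = 2000,
) -> tuple[str, int, int]:
    weights = np.array([s.length for s in scaffolds], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        plan = scaffolds[int(rng.choice(len(scaffolds), p=weights))]
        if plan.length <= length:
            continue
        start = int(rng.integers(0, plan.length - length))
        end = start + length
        if all(e <= start or s >= end for s, e in occupied[plan.name]):
            occupied[plan.name].append((start, end))
            return plan.name, start, end
    raise ValueError("infeasible placement: TE plan does not fit in the genome")


def build_world(config: SimConfig) -> World:
    """Generate the true genome, collapsed assembly, annotations and truth."""
    if not config.scaffolds:
        raise ValueError("config needs at least one scaffold")
    total_genome = sum(s.length for s in config.scaffolds)
    total_te = sum(f.unit_length * f.n_copies for f in config.families)
    if total_te >= 0.6 * total_genome:
        raise ValueError("infeasible placement: TE plan exceeds the genome budget")

    rng = np.random.default_rng(config.seed)
    background = {s.name: _random_seq(rng, s.length) for s in config.scaffolds}
    occupied: dict[str, list[tuple[int, int]]] = {s.name: [] for s in config.scaffolds}

    placements: dict[str, list[tuple[str, int, int]]] = {}
    copy_seqs: dict[str, list[np.ndarray]] = {}
    for fam in config.families:
        consensus = _random_seq(rng, fam.unit_length)
        placements[fam.name] = []
        copy_seqs[fam.name] = []
        for _ in range(fam.n_copies):
            where = _place(rng, occupied, config.scaffolds, fam.unit_length)
            placements[fam.name].append(where)
            copy_seqs[fam.name].append(_mutate(rng, consensus, fam.identity))

    true_arrays = {name: seq.copy() for name, seq in background.items()}
    for fam in config.families:
        for (scaf, s, e), seq in zip(placements[fam.name], copy_seqs[fam.name]):
            true_arrays[scaf][s:e] = seq

    # collapse: the first m copies survive; dropped copies are excised from
    # the assembly and absorbed round-robin by the survivors
    dropped: dict[str, list[tuple[int, int]]] = {s.name: [] for s in config.scaffolds}
    families_truth: dict[str, FamilyTruth] = {}
    for fam in config.families:
        m = fam.m_retained
        mult = [1] * m
        for j in range(m, fam.n_copies):
            scaf, s, e = placements[fam.name][j]
            dropped[scaf].append((s, e))
            mult[(j - m) % m] += 1
        families_truth[fam.name] = FamilyTruth(fam, placements[fam.name], [], mult)

    for name in dropped:
        dropped[name].sort()

    def to_assembly(scaf: str, pos: int) -> int:
        return pos - sum(e - s for s, e in dropped[scaf] if e <= pos)

    assembly_arrays: dict[str, np.ndarray] = {}
    for plan in config.scaffolds:
        keep = np.ones(plan.length, dtype=bool)
        for s, e in dropped[plan.name]:
            keep[s:e] = False
        assembly_arrays[plan.name] = true_arrays[plan.name][keep]

    annotations: list[TEAnnotation] = []
    for fam in config.families:
        ft = families_truth[fam.name]
        divergence = round(100.0 * (1.0 - fam.identity), 2)
        for scaf, s, e in placements[fam.name][: fam.m_retained]:
            a_start, a_end = to_assembly(scaf, s), to_assembly(scaf, e)
            ft.retained_copies.append((scaf, a_start, a_end))
            annotations.append(
                TEAnnotation(
                    scaffold_id=scaf,
                    start=a_start,
                    end=a_end,
                    strand="+",
                    family=fam.name,
                    superfamily=fam.superfamily,
                    order=fam.order,
                    score=1000,
                    divergence=divergence,
                )
            )

    # genes live in background sequence untouched by TEs or the collapse
    genes: list[tuple[str, int, int]] = []
    for _ in range(config.gene_count):
        scaf, s, e = _place(rng, occupied, config.scaffolds, config.gene_length)
        genes.append((scaf, to_assembly(scaf, s), to_assembly(scaf, e)))
    genes.sort()

    return World(
        config=config,
        true_genome={n: _to_str(a) for n, a in true_arrays.items()},
        assembly={n: _to_str(a) for n, a in assembly_arrays.items()},
        annotations=sorted(annotations),
        genes=genes,
        truth=SyntheticTruth(families_truth),
    )


@dataclass
class Alignments:
    """Simulated reads on the collapsed assembly.

    The same read list backs both serializations (SAM and depth TSV), so the
    two emission paths agree by construction.
    """

    reads: list[tuple[str, int, int]]  # (scaffold, start, length)
    scaffold_lengths: dict[str, int]
    assembly: Mapping[str, str] | None = None

    def depth_summary(self) -> DepthSummary:
        diffs = {
            name: np.zeros(length + 1, dtype=np.int64)
            for name, length in self.scaffold_lengths.items()
        }
        for scaf, start, length in self.reads:
            diffs[scaf][start] += 1
            diffs[scaf][start + length] -= 1
        tracks = {
            name: CoverageTrack(name, np.cumsum(d[:-1]))
            for name, d in diffs.items()
        }
        return DepthSummary(tracks, n_used=len(self.reads))

    def to_sam(self, path: str | Path) -> None:
        names = sorted(self.scaffold_lengths)
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": n, "LN": self.scaffold_lengths[n]} for n in names],
            }
        )
        ref_id = {n: i for i, n in enumerate(names)}
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            ordered = sorted(enumerate(self.reads), key=lambda t: (ref_id[t[1][0]], t[1][1]))
            for i, (scaf, start, length) in ordered:
                seg = pysam.AlignedSegment(header)
                seg.query_name = f"read{i}"
                seg.flag = 0
                seg.reference_id = ref_id[scaf]
                seg.reference_start = start
                seg.mapping_quality = 60
                seg.cigarstring = f"{length}M"
                if self.assembly is not None:
                    seg.query_sequence = self.assembly[scaf][start : start + length]
                out.write(seg)

    def write_depth_tsv(self, path: str | Path) -> None:
        from .coverage_correction import write_depth_tsv

        write_depth_tsv(self.depth_summary().tracks, path)


def _depth_segments(world: World) -> dict[str, list[tuple[int, int, float]]]:
    """Per assembly scaffold: (start, end, expected depth multiplier) segments."""
    per_scaffold: dict[str, list[tuple[int, int, int]]] = {
        name: [] for name in world.assembly
    }
    for ft in world.truth.families.values():
        for (scaf, s, e), mult in zip(ft.retained_copies, ft.multiplicities):
            per_scaffold[scaf].append((s, e, mult))
    segments: dict[str, list[tuple[int, int, float]]] = {}
    for name, seq in world.assembly.items():
        length = len(seq)
        copies = sorted(per_scaffold[name])
        segs: list[tuple[int, int, float]] = []
        cursor = 0
        for s, e, mult in copies:
            if s > cursor:
                segs.append((cursor, s, 1.0))
            segs.append((s, e, float(mult)))
            cursor = e
        if cursor < length:
            segs.append((cursor, length, 1.0))
        segments[name] = segs
    return segments


def simulate_alignments(
    world: World, config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> Alignments:
    """Reads from the true genome placed on the collapsed assembly.

    Reads originating from any of a family's n source copies align to its
    retained copies, so the expected depth over a retained copy is
    C × multiplicity; background (and gene) sequence has expected depth C.
    ``noiseless`` mode tiles each constant-depth segment with exactly-covering
    reads (requires integer depths); ``poisson`` mode draws per-segment read
    counts from a Poisson law at the segment's expected depth.
    """
    config = config or world.config
    mode = config.coverage_mode
    reads: list[tuple[str, int, int]] = []
    segments = _depth_segments(world)
    if mode == "noiseless":
        for name in sorted(segments):
            for s, e, mult in segments[name]:
                depth = config.coverage * mult
                if abs(depth - round(depth)) > 1e-9:
                    raise ValueError(
                        "noiseless mode needs integer expected depths; "
                        f"got {depth} on {name}"
                    )
                reads.extend((name, s, e - s) for _ in range(int(round(depth))))
    elif mode == "poisson":
        rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        for name in sorted(segments):
            for s, e, mult in segments[name]:
                seg_len = e - s
                read_len = min(config.read_length, seg_len)
                expected = config.coverage * mult
                n_reads = int(rng.poisson(expected * seg_len / read_len))
                if seg_len == read_len:
                    starts = np.full(n_reads, s)
                else:
                    starts = rng.integers(s, e - read_len + 1, size=n_reads)
                reads.extend((name, int(st), read_len) for st in starts)
    else:
        raise ValueError(f"unknown coverage mode {mode!r}")
    return Alignments(reads, world.assembly_lengths, world.assembly)


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """True vs assembled bp per category; the expected correction factor oracle."""
    rows = []
    for level in ("order", "superfamily"):
        for category, (true_bp, assembled_bp) in sorted(truth.category_bp(level).items()):
            rows.append(
                {
                    "level": level,
                    "category": category,
                    "true_bp": true_bp,
                    "assembled_bp": assembled_bp,
                    "expected_factor": true_bp / assembled_bp,
                }
            )
    total_true = sum(ft.true_bp for ft in truth.families.values())
    total_asm = sum(ft.assembled_bp for ft in truth.families.values())
    if total_asm:
        rows.append(
            {
                "level": "total",
                "category": "Total",
                "true_bp": total_true,
                "assembled_bp": total_asm,
                "expected_factor": total_true / total_asm,
            }
        )
    return pd.DataFrame(
        rows, columns=["level", "category", "true_bp", "assembled_bp", "expected_factor"]
    )


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_world(world: World, outdir: str | Path) -> dict[str, Path]:
    """Emit the world as FASTA + .out + BED + truth JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "true_genome": outdir / "true_genome.fasta",
        "assembly": outdir / "assembly.fasta",
        "annotations": outdir / "annotations.out",
        "genes": outdir / "genes.bed",
        "truth": outdir / "truth.json",
        "chrom_map": outdir / "chromosome_map.tsv",
    }
    write_fasta(world.true_genome, paths["true_genome"])
    write_fasta(world.assembly, paths["assembly"])
    write_repeatmasker_out(world.annotations, paths["annotations"])
    write_bed(world.genes, paths["genes"])
    world.truth.to_json(paths["truth"])
    world.chromosome_map().to_tsv(paths["chrom_map"])
    return paths


def build_density_world(
    seed: int = 0,
    chromosome_lengths: Mapping[str, int] | None = None,
    window: int = 50_000,
    background_density: float = 0.05,
    proximal_density: float = 0.30,
    dot_density: float = 0.40,
    proximal_span: int = 3_000_000,
) -> tuple[ChromosomeMap, list[TEAnnotation]]:
    """Interval-only world with TE enrichment near the centromere.

    Emulates the chromosomal pattern of real Drosophila assemblies: a flat
    TE density along chromosome arms, a strong rise in the proximal span
    (highest coordinates) and a uniformly dense dot chromosome. Returns a
    single-scaffold-per-chromosome map plus score-1000 annotations; no
    sequence is generated, so multi-megabase chromosomes are cheap.
    """
    if chromosome_lengths is None:
        chromosome_lengths = {"X": 8_000_000, "2": 8_000_000, "3": 8_000_000, "6": 1_500_000}
    rng = np.random.default_rng(seed)
    placements = []
    annotations: list[TEAnnotation] = []
    for i, (chrom, length) in enumerate(sorted(chromosome_lengths.items())):
        scaf = f"scaf_{chrom}"
        placements.append(ScaffoldPlacement(scaf, chrom, i, "forward", length))
        for start in range(0, length - window + 1, window):
            if chrom == "6":
                target = dot_density
            elif start >= length - proximal_span:
                target = proximal_density
            else:
                target = background_density
            te_len = int(np.clip(rng.normal(target, 0.15 * target), 0, 0.95) * window)
            if te_len < 1:
                continue
            offset = int(rng.integers(0, window - te_len + 1))
            annotations.append(
                TEAnnotation(
                    scaffold_id=scaf,
                    start=start + offset,
                    end=start + offset + te_len,
                    strand="+",
                    family="Gypsy-sim",
                    superfamily="Gypsy",
                    order="LTR",
                    score=1000,
                )
            )
    return ChromosomeMap(placements), annotations
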