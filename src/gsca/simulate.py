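"""Synthetic genomes, peak compendia and gene sets with planted structure.

The generator emulates the statistical structure the enrichment analysis
assumes: background datasets bind uniformly along the genome, planted
datasets bind the target gene set's loci at ``enrichment_fold`` times the
background per-bp density, and datasets inside a co-occupancy group share a
stated fraction of their in-locus peak positions verbatim.  A "target gene
locus" for planting purposes is the gene span extended by the peak-to-gene
mapping window on both sides, so planted peaks are guaranteed mappable
under default mapping settings.

All randomness flows from a single integer seed; per-component generators
are derived with fixed offsets so partial regeneration stays reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .compendium import (
    GenomicRegion,
    PeakDataset,
    build_compendium,
    merge_regions,
)
from .errors import ValidationError
from .gene_model import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "default_config",
    "null_config",
    "config_from_dict",
    "config_from_yaml",
    "simulate_annotation",
    "simulate_compendium",
    "write_fixture",
    "load_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe the standard benchmark condition: a 20-dataset
    compendium (~2,000-2,400 merged regions) over a 50 Mb two-chromosome
    genome with 300 genes, a 200-gene target set, five datasets planted at
    3x binding density in the target loci, and those five split into two
    co-occupancy groups sharing 90% of their in-locus peak positions.
    """

    n_chroms: int = 2
    chrom_length: int = 25_000_000
    n_genes: int = 300
    gene_length: int = 10_000
    n_datasets: int = 20
    peaks_per_dataset: int = 130
    peak_width: int = 400
    planted_tf_ids: tuple[str, ...] = ("D00", "D01", "D02", "D03", "D04")
    target_gene_set_size: int = 200
    enrichment_fold: float = 3.0
    cooccupancy_groups: tuple[tuple[tuple[str, ...], float], ...] = (
        (("D00", "D01", "D02"), 0.9),
        (("D03", "D04"), 0.9),
    )
    bit_flip_noise: float = 0.0
    locus_window_bp: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "gene_length",
                     "n_datasets", "peaks_per_dataset", "peak_width",
                     "target_gene_set_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.enrichment_fold < 1:
            raise ValidationError("enrichment_fold must be >= 1")
        if not (0 <= self.bit_flip_noise <= 0.5):
            raise ValidationError("bit_flip_noise must lie in [0, 0.5]")
        if self.target_gene_set_size > self.n_genes:
            raise ValidationError("target_gene_set_size exceeds n_genes")
        per_chrom = -(-self.n_genes // self.n_chroms)  # ceil
        if per_chrom * self.gene_length + per_chrom + 1 > self.chrom_length:
            raise ValidationError("genes cannot fit on the chromosomes without overlap")
        ids = set(self.dataset_ids())
        unknown = set(self.planted_tf_ids) - ids
        if unknown:
            raise ValidationError(f"planted_tf_ids not among datasets: {sorted(unknown)}")
        grouped: set[str] = set()
        for members, shared in self.cooccupancy_groups:
            if not (0.0 <= shared <= 1.0):
                raise ValidationError("group shared fraction must lie in [0, 1]")
            if set(members) - set(self.planted_tf_ids):
                raise ValidationError("co-occupancy groups must contain planted datasets only")
            if grouped & set(members):
                raise ValidationError("co-occupancy groups must be disjoint")
            grouped |= set(members)

    def dataset_ids(self) -> list[str]:
        return [f"D{i:02d}" for i in range(self.n_datasets)]


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard planted-enrichment benchmark condition."""
    return dataclasses.replace(SimulationConfig(seed=seed), **overrides)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The matched null condition: same sizes, nothing planted."""
    cfg = SimulationConfig(
        seed=seed, planted_tf_ids=(), enrichment_fold=1.0, cooccupancy_groups=()
    )
    return dataclasses.replace(cfg, **overrides)


def config_from_dict(payload: dict) -> SimulationConfig:
    payload = dict(payload)
    if "planted_tf_ids" in payload:
        payload["planted_tf_ids"] = tuple(payload["planted_tf_ids"])
    if "cooccupancy_groups" in payload:
        payload["cooccupancy_groups"] = tuple(
            (tuple(members), float(shared)) for members, shared in payload["cooccupancy_groups"]
        )
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**payload)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValidationError(f"{path}: simulation config must be a YAML mapping")
    return config_from_dict(payload)


@dataclass
class SimulatedTruth:
    """Ground truth of one simulation, reproducible from (config, seed)."""

    gene_set: tuple[str, ...]
    enriched: tuple[str, ...]
    groups: tuple[tuple[tuple[str, ...], float], ...]
    datasets: list[PeakDataset] = field(default_factory=list)

    def partition(self) -> dict[str, int]:
        """Planted co-occupancy partition: group index per grouped dataset."""
        return {d: gi for gi, (members, _) in enumerate(self.groups, 1) for d in members}

    def to_dict(self) -> dict:
        return {
            "gene_set": list(self.gene_set),
            "enriched": list(self.enriched),
            "groups": [[list(m), s] for m, s in self.groups],
            "datasets": [
                {
                    "dataset_id": d.dataset_id,
                    "tf": d.tf,
                    "cell_type": d.cell_type,
                    "peaks": [[p.chrom, p.start, p.end] for p in d.peaks],
                }
                for d in self.datasets
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulatedTruth":
        datasets = [
            PeakDataset(
                d["dataset_id"], d["tf"], d["cell_type"],
                [GenomicRegion(c, s, e) for c, s, e in d["peaks"]],
            )
            for d in payload["datasets"]
        ]
        groups = tuple((tuple(m), float(s)) for m, s in payload["groups"])
        return cls(tuple(payload["gene_set"]), tuple(payload["enriched"]), groups, datasets)


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chroms)]


def simulate_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """Place non-overlapping fixed-length genes with positive random gaps."""
    rng = np.random.default_rng([config.seed, 0])
    chroms = _chrom_names(config)
    base = config.n_genes // config.n_chroms
    extra = config.n_genes % config.n_chroms
    genes: list[GeneAnnotation] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        count = base + (1 if ci < extra else 0)
        if count == 0:
            continue
        slack = config.chrom_length - count * config.gene_length
        if slack <= count:
            raise ValidationError(f"genes cannot fit on {chrom} with positive gaps")
        cuts = np.sort(rng.choice(slack - 1, size=count, replace=False) + 1)
        starts = cuts + np.arange(count) * config.gene_length
        strands = rng.choice(np.array(["+", "-"]), size=count)
        for s, strand in zip(starts.tolist(), strands.tolist()):
            genes.append(
                GeneAnnotation(f"G{gi:04d}", chrom, strand, int(s), int(s) + config.gene_length)
            )
            gi += 1
    return genes


def _interval_complement(
    loci: Sequence[GenomicRegion], chroms: Sequence[str], length: int
) -> list[GenomicRegion]:
    by_chrom: dict[str, list[GenomicRegion]] = {c: [] for c in chroms}
    for iv in loci:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicRegion] = []
    for c in chroms:
        pos = 0
        for iv in sorted(by_chrom[c]):
            if iv.start > pos:
                out.append(GenomicRegion(c, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < length:
            out.append(GenomicRegion(c, pos, length))
    return out


def _place_peaks(
    rng: np.random.Generator,
    intervals: Sequence[GenomicRegion],
    count: int,
    width: int,
) -> list[GenomicRegion]:
    """Draw ``count`` fixed-width peaks uniformly over the allowed start
    positions of an interval set (peaks lie entirely inside an interval)."""
    if count == 0:
        return []
    hosts = [iv for iv in intervals if iv.length >= width]
    if not hosts:
        raise ValidationError(f"no interval can host a peak of width {width}")
    mass = np.array([iv.length - width + 1 for iv in hosts], dtype=float)
    idx = rng.choice(len(hosts), size=count, p=mass / mass.sum())
    offsets = rng.integers(0, mass[idx].astype(np.int64))
    return [
        GenomicRegion(hosts[i].chrom, hosts[i].start + int(o), hosts[i].start + int(o) + width)
        for i, o in zip(idx.tolist(), offsets.tolist())
    ]


def _apply_bit_flip_noise(
    datasets: list[PeakDataset], p: float, seed: int
) -> list[PeakDataset]:
    """Toggle occupancy bits of the provisional universe with probability p
    and translate the flips back into peak lists."""
    comp = build_compendium(datasets)
    rng = np.random.default_rng([seed, 4])
    flips = rng.random(comp.occupancy.shape) < p
    new_occ = comp.occupancy.astype(bool) ^ flips
    index = comp.index
    noisy: list[PeakDataset] = []
    for j, d in enumerate(datasets):
        col = new_occ[:, j]
        kept = [pk for pk in d.peaks if col[index.overlapping(pk).start]]
        gained = np.nonzero(col & ~comp.occupancy[:, j].astype(bool))[0]
        added = [comp.regions[r] for r in gained.tolist()]
        noisy.append(PeakDataset(d.dataset_id, d.tf, d.cell_type, kept + added))
    return noisy


def simulate_compendium(
    config: SimulationConfig, annotation: Sequence[GeneAnnotation]
) -> tuple[list[PeakDataset], SimulatedTruth]:
    """Generate the peak datasets and the ground truth for one study.

    Planted datasets place a fraction f of their peaks in the target loci
    such that the per-bp density there is ``enrichment_fold`` times the
    background density: f = fold * L_t / (L_b + fold * L_t) with L_t / L_b
    the target / background genome lengths.  Within a co-occupancy group a
    fraction of in-locus peak positions is shared verbatim across members.
    """
    chroms = _chrom_names(config)
    L = config.chrom_length
    genome = [GenomicRegion(c, 0, L) for c in chroms]
    symbols = [g.symbol for g in annotation]
    rng_set = np.random.default_rng([config.seed, 1])
    target = sorted(rng_set.choice(symbols, size=config.target_gene_set_size, replace=False).tolist())
    target_set = set(target)
    W = config.locus_window_bp
    loci = merge_regions(
        GenomicRegion(g.chrom, max(0, g.tx_start - W), min(L, g.tx_end + W))
        for g in annotation
        if g.symbol in target_set
    )
    background = _interval_complement(loci, chroms, L)
    L_t = sum(iv.length for iv in loci)
    L_b = sum(iv.length for iv in background)
    fold = config.enrichment_fold
    frac = fold * L_t / (L_b + fold * L_t)
    P = config.peaks_per_dataset
    n_target = int(round(frac * P))
    if n_target > 0 and not any(iv.length >= config.peak_width for iv in loci):
        raise ValidationError("target loci too small for the configured peak width")

    group_of: dict[str, int] = {}
    shared_peaks: dict[int, list[GenomicRegion]] = {}
    shared_count: dict[int, int] = {}
    for gi, (members, shared_frac) in enumerate(config.cooccupancy_groups):
        rng_g = np.random.default_rng([config.seed, 3, gi])
        count = int(round(shared_frac * n_target))
        shared_peaks[gi] = _place_peaks(rng_g, loci, count, config.peak_width)
        shared_count[gi] = count
        for m in members:
            group_of[m] = gi

    planted = set(config.planted_tf_ids)
    datasets: list[PeakDataset] = []
    for di, dataset_id in enumerate(config.dataset_ids()):
        rng_d = np.random.default_rng([config.seed, 2, di])
        if dataset_id in planted:
            gi = group_of.get(dataset_id)
            shared = shared_peaks[gi] if gi is not None else []
            own_target = n_target - (shared_count[gi] if gi is not None else 0)
            peaks = (
                list(shared)
                + _place_peaks(rng_d, loci, own_target, config.peak_width)
                + _place_peaks(rng_d, background, P - n_target, config.peak_width)
            )
        else:
            peaks = _place_peaks(rng_d, genome, P, config.peak_width)
        datasets.append(PeakDataset(dataset_id, f"TF{di:02d}", "sim", peaks))

    if config.bit_flip_noise > 0:
        datasets = _apply_bit_flip_noise(datasets, config.bit_flip_noise, config.seed)

    enriched = tuple(sorted(planted)) if fold > 1 else ()
    truth = SimulatedTruth(tuple(target), enriched, config.cooccupancy_groups, datasets)
    logger.info(
        "simulated %d datasets (%d planted at fold %.2f) over %d bp; target loci %d bp",
        config.n_datasets, len(planted), fold, L_b + L_t, L_t,
    )
    return datasets, truth


def write_fixture(
    datasets: Sequence[PeakDataset],
    annotation: Sequence[GeneAnnotation],
    truth: SimulatedTruth,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Emit the fixture file tree in exactly the formats the readers accept:
    BED peak files + manifest TSV + annotation TSV + gene-set text + truth
    JSON (+ the config as YAML when given)."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    with open(out / "manifest.tsv", "w") as mf:
        mf.write("dataset_id\ttf\tcell_type\tgroup\tpath\n")
        for d in datasets:
            bed = out / "peaks" / f"{d.dataset_id}.bed"
            with open(bed, "w") as fh:
                for p in d.peaks:
                    fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            mf.write(f"{d.dataset_id}\t{d.tf}\t{d.cell_type}\t{d.dataset_id}\tpeaks/{d.dataset_id}.bed\n")
    paths["manifest"] = out / "manifest.tsv"
    with open(out / "annotation.tsv", "w") as fh:
        fh.write("symbol\tchrom\tstrand\tstart\tend\n")
        for g in annotation:
            fh.write(f"{g.symbol}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")
    paths["annotation"] = out / "annotation.tsv"
    (out / "gene_set.txt").write_text("".join(f"{s}\n" for s in truth.gene_set))
    paths["gene_set"] = out / "gene_set.txt"
    (out / "truth.json").write_text(json.dumps(truth.to_dict()) + "\n")
    paths["truth"] = out / "truth.json"
    if config is not None:
        (out / "sim_config.yaml").write_text(
            yaml.safe_dump(_config_to_plain(config), sort_keys=True)
        )
        paths["config"] = out / "sim_config.yaml"
    return paths


def _config_to_plain(config: SimulationConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["planted_tf_ids"] = list(payload["planted_tf_ids"])
    payload["cooccupancy_groups"] = [
        [list(members), shared] for members, shared in payload["cooccupancy_groups"]
    ]
    return payload


def load_truth(path: str | Path) -> SimulatedTruth:
    return SimulatedTruth.from_dict(json.loads(Path(path).read_text()))
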