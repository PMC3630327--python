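"""ChIP-Seq peak compendium: merged region universe and occupancy matrix.

A *compendium* integrates many peak datasets (one per transcription factor /
cell type experiment) over a single non-redundant universe of genomic
regions.  The universe is the bp-merged union of all peaks; two intervals
merge iff they share at least one base pair.  Coordinates are 0-based
half-open throughout (BED dialect), so adjacent intervals such as
[100, 200) and [200, 300) do NOT merge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import BuildError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion",
    "PeakDataset",
    "DatasetInfo",
    "RegionIndex",
    "Compendium",
    "read_peak_bed",
    "read_alias_table",
    "merge_regions",
    "consolidate_samples",
    "build_compendium",
]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "coordinates must satisfy 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        """True iff the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakDataset:
    """One ChIP-Seq experiment: a TF, a cell type, and its called peaks.

    Peaks are kept sorted by (chrom, start, end); they may overlap each
    other within the dataset.
    """

    dataset_id: str
    tf: str
    cell_type: str
    peaks: list[GenomicRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)


@dataclass(frozen=True)
class DatasetInfo:
    """Lightweight per-dataset metadata carried inside a Compendium."""

    dataset_id: str
    tf: str
    cell_type: str
    n_peaks: int


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping alternative chromosome names
    (e.g. "1" -> "chr1")."""
    aliases: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            aliases[parts[0]] = parts[1]
    return aliases


def read_peak_bed(
    path: str | Path,
    dataset_id: str,
    tf: str,
    cell_type: str,
    aliases: Mapping[str, str] | None = None,
) -> PeakDataset:
    """Read a BED3+ peak file into a PeakDataset.

    Only the first three columns (chrom, start, end) are used; extra BED
    columns are ignored.  Zero-length and inverted intervals are rejected.
    """
    peaks: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns, got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: start/end must be integers"
                ) from None
            if start < 0 or start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: need 0 <= start < end, got [{start}, {end})"
                )
            if aliases:
                chrom = aliases.get(chrom, chrom)
            peaks.append(GenomicRegion(chrom, start, end))
    if not peaks:
        logger.warning("dataset %s: peak file %s contains no peaks", dataset_id, path)
    return PeakDataset(dataset_id, tf, cell_type, peaks)


def merge_regions(intervals: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    """Merge intervals into a minimal sorted list of pairwise non-overlapping
    regions covering exactly the same base pairs.

    Two intervals merge iff their half-open intersection is non-empty;
    merely adjacent intervals stay separate.
    """
    merged: list[GenomicRegion] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in sorted(intervals):
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                merged.append(GenomicRegion(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        merged.append(GenomicRegion(cur_chrom, cur_start, cur_end))
    return merged


def consolidate_samples(
    datasets: Sequence[PeakDataset],
    group_key: Mapping[str, str],
    group_meta: Mapping[str, tuple[str, str]] | None = None,
) -> list[PeakDataset]:
    """Merge samples of the same TF profiled in related cell types.

    ``group_key`` maps every dataset_id to a group label; datasets sharing
    a label are replaced by a single dataset whose peak list is the merged
    union of the members' peaks.  Which samples count as "related" is a
    curation judgment, so the grouping is user-supplied metadata.  Groups
    must be same-TF; ``group_meta`` may override the consolidated
    (tf, cell_type) per label.
    """
    missing = [d.dataset_id for d in datasets if d.dataset_id not in group_key]
    if missing:
        raise ValidationError(f"datasets missing from group_key: {', '.join(missing)}")

    order: list[str] = []
    members: dict[str, list[PeakDataset]] = {}
    for d in datasets:
        label = group_key[d.dataset_id]
        if label not in members:
            members[label] = []
            order.append(label)
        members[label].append(d)

    out: list[PeakDataset] = []
    for label in order:
        group = members[label]
        tfs = sorted({d.tf for d in group})
        if len(tfs) > 1:
            raise ValidationError(
                f"group {label!r} mixes transcription factors {tfs}; "
                "consolidation groups must be same-TF"
            )
        if group_meta and label in group_meta:
            tf, cell_type = group_meta[label]
        else:
            tf = tfs[0]
            cell_type = "+".join(sorted({d.cell_type for d in group}))
        if len(group) == 1:
            d = group[0]
            if d.dataset_id == label and d.tf == tf and d.cell_type == cell_type:
                out.append(d)  # singleton group: pass through unchanged
                continue
            out.append(PeakDataset(label, tf, cell_type, list(d.peaks)))
            continue
        peaks = merge_regions(p for d in group for p in d.peaks)
        out.append(PeakDataset(label, tf, cell_type, peaks))
    return out


class RegionIndex:
    """Sorted-array index over a merged (sorted, pairwise disjoint) region
    list, supporting any-bp-overlap queries."""

    def __init__(self, regions: Sequence[GenomicRegion]):
        self.n = len(regions)
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        prev: GenomicRegion | None = None
        starts: list[int] = []
        ends: list[int] = []
        offset = 0
        for i, r in enumerate(regions):
            if prev is not None and r.chrom == prev.chrom:
                if r.start < prev.end:
                    raise ValidationError(
                        "RegionIndex requires a merged universe: regions "
                        f"{prev} and {r} overlap or are unsorted"
                    )
            elif prev is not None:
                if prev.chrom in self._chroms:
                    raise ValidationError("regions are not sorted by chromosome")
                self._chroms[prev.chrom] = (np.array(starts), np.array(ends), offset)
                offset = i
                starts, ends = [], []
            starts.append(r.start)
            ends.append(r.end)
            prev = r
        if prev is not None:
            if prev.chrom in self._chroms:
                raise ValidationError("regions are not sorted by chromosome")
            self._chroms[prev.chrom] = (np.array(starts), np.array(ends), offset)

    def overlapping(self, region: GenomicRegion) -> range:
        """Global indices of universe regions sharing >= 1 bp with ``region``."""
        entry = self._chroms.get(region.chrom)
        if entry is None:
            return range(0, 0)
        starts, ends, offset = entry
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return range(offset + lo, offset + hi)

    def mark(self, regions: Iterable[GenomicRegion]) -> np.ndarray:
        """Boolean occupancy vector over the universe for a set of intervals."""
        hit = np.zeros(self.n, dtype=bool)
        for r in regions:
            rng = self.overlapping(r)
            if rng.stop > rng.start:
                hit[rng.start : rng.stop] = True
        return hit


@dataclass
class Compendium:
    """Merged region universe + binary dataset-occupancy matrix + metadata.

    ``occupancy`` has shape (N regions, D datasets); every row sums to >= 1
    because the universe is built from the datasets' own peaks.
    """

    regions: list[GenomicRegion]
    datasets: list[DatasetInfo]
    occupancy: np.ndarray
    _index: RegionIndex | None = field(default=None, repr=False, compare=False)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    @property
    def index(self) -> RegionIndex:
        if self._index is None:
            self._index = RegionIndex(self.regions)
        return self._index

    def column(self, dataset_id: str) -> int:
        for j, d in enumerate(self.datasets):
            if d.dataset_id == dataset_id:
                return j
        raise ValidationError(f"dataset {dataset_id!r} not in compendium")

    def save(self, out_dir: str | Path) -> None:
        """Write universe.bed, occupancy.tsv (sparse triplets) and
        datasets.json into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "universe.bed", "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
        with open(out / "occupancy.tsv", "w") as fh:
            fh.write("region_index\tdataset_id\tvalue\n")
            rows, cols = np.nonzero(self.occupancy)
            ids = self.dataset_ids
            for r, c in zip(rows.tolist(), cols.tolist()):
                fh.write(f"{r}\t{ids[c]}\t1\n")
        meta = {
            "n_regions": self.n_regions,
            "datasets": [
                {
                    "dataset_id": d.dataset_id,
                    "tf": d.tf,
                    "cell_type": d.cell_type,
                    "n_peaks": d.n_peaks,
                }
                for d in self.datasets
            ],
        }
        (out / "datasets.json").write_text(json.dumps(meta, indent=1) + "\n")

    @classmethod
    def load(cls, in_dir: str | Path) -> "Compendium":
        src = Path(in_dir)
        regions: list[GenomicRegion] = []
        with open(src / "universe.bed") as fh:
            for line in fh:
                chrom, s, e = line.rstrip("\n").split("\t")[:3]
                regions.append(GenomicRegion(chrom, int(s), int(e)))
        meta = json.loads((src / "datasets.json").read_text())
        datasets = [DatasetInfo(**d) for d in meta["datasets"]]
        if meta["n_regions"] != len(regions):
            raise ParseError(f"{src}: datasets.json disagrees with universe.bed size")
        col = {d.dataset_id: j for j, d in enumerate(datasets)}
        occ = np.zeros((len(regions), len(datasets)), dtype=np.uint8)
        with open(src / "occupancy.tsv") as fh:
            header = fh.readline()
            if not header.startswith("region_index"):
                raise ParseError(f"{src}/occupancy.tsv: missing header")
            for lineno, line in enumerate(fh, 2):
                r, d, v = line.rstrip("\n").split("\t")
                if d not in col:
                    raise ParseError(f"{src}/occupancy.tsv: line {lineno}: unknown dataset {d!r}")
                occ[int(r), col[d]] = int(v)
        return cls(regions, datasets, occ)


def build_compendium(datasets: Sequence[PeakDataset]) -> Compendium:
    """Build the merged universe and the N x D occupancy matrix.

    occupancy[r, d] = 1 iff any peak of dataset d overlaps universe region r
    by at least one base pair (no minimum-fraction threshold).
    """
    if not datasets:
        raise BuildError("cannot build a compendium from zero datasets")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate dataset ids: {', '.join(dupes)}")
    all_peaks = [p for d in datasets for p in d.peaks]
    if not all_peaks:
        raise BuildError("all datasets are empty; nothing to build")
    universe = merge_regions(all_peaks)
    index = RegionIndex(universe)
    occ = np.zeros((len(universe), len(datasets)), dtype=np.uint8)
    for j, d in enumerate(datasets):
        occ[index.mark(d.peaks), j] = 1
    infos = [DatasetInfo(d.dataset_id, d.tf, d.cell_type, len(d.peaks)) for d in datasets]
    logger.info(
        "built compendium: %d regions from %d datasets (%d peaks)",
        len(universe), len(datasets), len(all_peaks),
    )
    return Compendium(universe, infos, occ, index)
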