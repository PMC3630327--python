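"""Gene annotation, peak-to-gene assignment, and ortholog symbol mapping.

The assignment rule: a region overlapping a gene body or promoter (the gene
span extended upstream of the strand-aware TSS by ``promoter_bp``) is
associated with the overlapped gene(s); an intergenic region is associated
with the nearest gene on each side whose span lies within ``window_bp`` of
the region's nearest edge.  Every region is assigned to at most two genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compendium import GenomicRegion
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "GeneIndex",
    "PeakGeneMap",
    "OrthologTable",
    "read_annotation",
    "assign_peak_to_genes",
    "build_peak_gene_map",
    "map_gene_set_to_regions",
    "read_gene_set",
    "read_orthologs",
    "translate_symbols",
]

DEFAULT_WINDOW_BP = 50_000
DEFAULT_PROMOTER_BP = 2_000

RULE_GENE_BODY = "gene_body"
RULE_PROMOTER = "promoter"
RULE_INTERGENIC = "intergenic_nearest"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus: symbol, chromosome, strand and transcribed span
    (0-based half-open)."""

    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.symbol}: strand must be '+' or '-'")
        if self.tx_start < 0 or self.tx_start >= self.tx_end:
            raise ValidationError(
                f"gene {self.symbol}: need 0 <= tx_start < tx_end, "
                f"got [{self.tx_start}, {self.tx_end})"
            )


_GTF_SUFFIXES = {".gtf", ".gff", ".gff3"}
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: Path) -> list[GeneAnnotation]:
    # Gene span = min start .. max end over that gene's gene/transcript rows.
    spans: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF columns")
            feature = parts[2]
            if feature not in ("gene", "transcript"):
                continue
            try:
                start0, end = int(parts[3]) - 1, int(parts[4])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: unparseable coordinates") from None
            attrs = dict(_ATTR_RE.findall(parts[8]))
            symbol = attrs.get("gene_name") or attrs.get("gene_id")
            if not symbol:
                raise ParseError(f"{path}: line {lineno}: no gene_name/gene_id attribute")
            if symbol not in spans:
                spans[symbol] = [parts[0], parts[6], start0, end]
                order.append(symbol)
            else:
                rec = spans[symbol]
                if rec[0] != parts[0]:
                    raise ParseError(f"{path}: gene {symbol} spans multiple chromosomes")
                rec[2] = min(rec[2], start0)
                rec[3] = max(rec[3], end)
    return [GeneAnnotation(sym, *spans[sym][:2], spans[sym][2], spans[sym][3]) for sym in order]


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation from a TSV (columns symbol, chrom, strand,
    start, end) or a GTF/GFF file (gene/transcript features).

    Duplicate symbols in a TSV are an error; in a GTF, multiple rows per
    gene are aggregated into one min-max span.
    """
    path = Path(path)
    if path.suffix.lower() in _GTF_SUFFIXES:
        return _read_gtf(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "strand": str})
    except Exception as exc:  # noqa: BLE001 - normalize pandas parse failures
        raise ParseError(f"{path}: {exc}") from exc
    required = {"symbol", "chrom", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns: {', '.join(sorted(missing))}")
    dupes = sorted(df.loc[df["symbol"].duplicated(), "symbol"].unique())
    if dupes:
        raise ValidationError(f"{path}: duplicate gene symbols: {', '.join(dupes)}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: gene {row.symbol}: unparseable coordinates") from None
        genes.append(GeneAnnotation(str(row.symbol), str(row.chrom), str(row.strand), start, end))
    return genes


class GeneIndex:
    """Per-chromosome sorted arrays over a gene annotation, supporting
    overlap and nearest-neighbor queries."""

    def __init__(self, genes: Sequence[GeneAnnotation]):
        syms = [g.symbol for g in genes]
        if len(set(syms)) != len(syms):
            raise ValidationError("gene symbols must be unique in an annotation")
        self.symbols = frozenset(syms)
        self._chroms: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[GeneAnnotation]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tx_start, g.tx_end, g.symbol))
            starts = np.array([g.tx_start for g in gs])
            ends = np.array([g.tx_end for g in gs])
            plus = np.array([g.strand == "+" for g in gs])
            end_order = np.argsort(ends, kind="stable")
            self._chroms[chrom] = {
                "starts": starts,
                "ends": ends,
                "plus": plus,
                "symbols": np.array([g.symbol for g in gs], dtype=object),
                "end_order": end_order,
                "ends_sorted": ends[end_order],
            }

    def assign(
        self,
        region: GenomicRegion,
        window_bp: int = DEFAULT_WINDOW_BP,
        promoter_bp: int = DEFAULT_PROMOTER_BP,
    ) -> tuple[frozenset[str], str | None]:
        """Assign a region to <= 2 gene symbols; returns (symbols, rule).

        Rule is one of gene_body / promoter / intergenic_nearest, or None
        when the region is unassigned.
        """
        entry = self._chroms.get(region.chrom)
        if entry is None:
            return frozenset(), None
        gs, ge = entry["starts"], entry["ends"]
        plus, symbols = entry["plus"], entry["symbols"]
        ext_s = np.where(plus, np.maximum(gs - promoter_bp, 0), gs)
        ext_e = np.where(plus, ge, ge + promoter_bp)
        ov = (ext_s < region.end) & (ext_e > region.start)
        if ov.any():
            cand = np.nonzero(ov)[0]
            gap = np.maximum(
                0, np.maximum(gs[cand] - region.end, region.start - ge[cand])
            )
            body = (gs[cand] < region.end) & (ge[cand] > region.start)
            # Smallest edge distance wins; body overlap outranks a
            # promoter-only tie at distance 0; then alphabetical symbol.
            ranked = sorted(
                zip(gap.tolist(), (~body).tolist(), symbols[cand].tolist())
            )
            chosen = ranked[:2]
            rule = RULE_GENE_BODY if any(not nb for _, nb, _ in chosen) else RULE_PROMOTER
            return frozenset(sym for _, _, sym in chosen), rule
        # Intergenic: nearest gene on each side within the window.
        picked: list[str] = []
        ends_sorted, end_order = entry["ends_sorted"], entry["end_order"]
        pos = int(np.searchsorted(ends_sorted, region.start, side="right")) - 1
        if pos >= 0:
            e_max = int(ends_sorted[pos])
            if region.start - e_max <= window_bp:
                ties = end_order[ends_sorted == e_max]
                picked.append(min(symbols[ties]))
        pos = int(np.searchsorted(gs, region.end, side="left"))
        if pos < len(gs):
            s_min = int(gs[pos])
            if s_min - region.end <= window_bp:
                ties = np.nonzero(gs == s_min)[0]
                picked.append(min(symbols[ties]))
        if picked:
            return frozenset(picked), RULE_INTERGENIC
        return frozenset(), None


def assign_peak_to_genes(
    region: GenomicRegion,
    genes: Sequence[GeneAnnotation] | GeneIndex,
    window_bp: int = DEFAULT_WINDOW_BP,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> frozenset[str]:
    """Convenience wrapper returning only the assigned symbols for one region."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.assign(region, window_bp, promoter_bp)[0]


@dataclass
class PeakGeneMap:
    """Region-index -> gene-symbol assignment over a compendium universe.

    Only assigned regions appear in ``assignments``; every value has at
    most two symbols.  ``rules`` records which rule produced each
    assignment.
    """

    assignments: dict[int, frozenset[str]]
    rules: dict[int, str]
    n_regions: int
    known_symbols: frozenset[str]
    window_bp: int = DEFAULT_WINDOW_BP
    promoter_bp: int = DEFAULT_PROMOTER_BP

    def __post_init__(self) -> None:
        for i, syms in self.assignments.items():
            if len(syms) > 2:
                raise ValidationError(f"region {i} assigned to {len(syms)} genes (max 2)")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# n_regions={self.n_regions} window_bp={self.window_bp} "
                f"promoter_bp={self.promoter_bp}\n"
            )
            fh.write("region_index\tsymbols\trule\n")
            for i in sorted(self.assignments):
                syms = ",".join(sorted(self.assignments[i]))
                fh.write(f"{i}\t{syms}\t{self.rules[i]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PeakGeneMap":
        assignments: dict[int, frozenset[str]] = {}
        rules: dict[int, str] = {}
        meta = {"n_regions": 0, "window_bp": DEFAULT_WINDOW_BP, "promoter_bp": DEFAULT_PROMOTER_BP}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for token in first[1:].split():
                    key, _, val = token.partition("=")
                    if key in meta:
                        meta[key] = int(val)
                header = fh.readline()
            else:
                header = first
            if not header.startswith("region_index"):
                raise ParseError(f"{path}: missing peak-gene map header")
            for lineno, line in enumerate(fh, 3):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}: line {lineno}: expected 3 columns")
                idx = int(parts[0])
                assignments[idx] = frozenset(parts[1].split(",")) if parts[1] else frozenset()
                rules[idx] = parts[2]
        known = frozenset(s for syms in assignments.values() for s in syms)
        return cls(assignments, rules, meta["n_regions"], known,
                   meta["window_bp"], meta["promoter_bp"])


def build_peak_gene_map(
    regions: Sequence[GenomicRegion],
    genes: Sequence[GeneAnnotation] | GeneIndex,
    window_bp: int = DEFAULT_WINDOW_BP,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> PeakGeneMap:
    """Assign every universe region to <= 2 genes under the mapping rule."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    assignments: dict[int, frozenset[str]] = {}
    rules: dict[int, str] = {}
    for i, region in enumerate(regions):
        syms, rule = index.assign(region, window_bp, promoter_bp)
        if syms:
            assignments[i] = syms
            rules[i] = rule
    logger.info(
        "peak-gene map: %d of %d regions assigned (window=%d bp, promoter=%d bp)",
        len(assignments), len(regions), window_bp, promoter_bp,
    )
    return PeakGeneMap(assignments, rules, len(regions), index.symbols, window_bp, promoter_bp)


def map_gene_set_to_regions(gene_set: Iterable[str], pgmap: PeakGeneMap) -> set[int]:
    """Universe regions whose assigned genes intersect the query gene set.

    The size of the result is the *n* of the enrichment test.  Symbols
    absent from the annotation are reported via a warning, never an error.
    """
    query = set(gene_set)
    unknown = sorted(query - pgmap.known_symbols)
    if unknown:
        shown = ", ".join(unknown[:10]) + ("..." if len(unknown) > 10 else "")
        logger.warning(
            "%d of %d query symbols not found in the annotation: %s",
            len(unknown), len(query), shown,
        )
    return {i for i, syms in pgmap.assignments.items() if syms & query}


def read_gene_set(path: str | Path, set_name: str | None = None) -> tuple[str, set[str]]:
    """Read a gene set from a one-symbol-per-line text file or a GMT file.

    For GMT input, ``set_name`` selects a set by name (default: first set).
    Returns (name, symbols).
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                if set_name is None or parts[0] == set_name:
                    return parts[0], {s for s in parts[2:] if s}
        raise ParseError(f"{path}: gene set {set_name!r} not found")
    symbols = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                symbols.add(token)
    return path.stem, symbols


@dataclass
class OrthologTable:
    """Source-symbol -> target-symbol(s) mapping (e.g. human -> mouse).

    Lookups of unmapped symbols return the empty set, never fail.
    """

    pairs: dict[str, frozenset[str]] = field(default_factory=dict)

    def targets(self, symbol: str) -> frozenset[str]:
        return self.pairs.get(symbol, frozenset())

    def unmapped(self, gene_set: Iterable[str]) -> list[str]:
        return sorted(s for s in gene_set if s not in self.pairs)


def read_orthologs(path: str | Path) -> OrthologTable:
    """Read a two-column TSV (source_symbol, target_symbol); multiple rows
    per source express 1-to-many orthology."""
    pairs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            pairs.setdefault(parts[0], set()).add(parts[1])
    return OrthologTable({k: frozenset(v) for k, v in pairs.items()})


def translate_symbols(gene_set: Iterable[str], table: OrthologTable) -> set[str]:
    """Translate a gene set through an ortholog table: union of targets;
    1-to-many expands; unmapped symbols are dropped and reported."""
    query = set(gene_set)
    unmapped = table.unmapped(query)
    if unmapped:
        shown = ", ".join(unmapped[:10]) + ("..." if len(unmapped) > 10 else "")
        logger.warning("%d of %d symbols have no ortholog: %s", len(unmapped), len(query), shown)
    out: set[str] = set()
    for s in query:
        out |= table.targets(s)
    return out
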