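"""Gene Set Control Analysis core: per-dataset hypergeometric enrichment.

For a universe of N regions bound by at least one dataset, a query gene set
mapping to n regions, and a dataset occupying m regions of which k fall in
the gene-set regions, the enrichment p-value is the upper tail
P(X >= k) of X ~ Hypergeometric(N, n, m).  The test unit is the merged
universe region, which keeps N coherent across datasets, and counting every
region of a locus individually weights loci by their number of binding
events.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .compendium import Compendium, GenomicRegion, RegionIndex
from .errors import ValidationError
from .gene_model import PeakGeneMap, map_gene_set_to_regions

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "GscaReport",
    "hypergeom_upper_tail",
    "correct_pvalues",
    "run_gsca",
    "region_set_overlap_test",
]

DEFAULT_ALPHA = 0.001

#: tiny positive floor keeping p_raw strictly above zero after underflow
_P_FLOOR = 5e-324


def hypergeom_upper_tail(N: int, n: int, m: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes n, draws m).

    Computed through log-gamma functions, so it stays finite and accurate
    for universes of hundreds of thousands of regions.  Returns exactly 1.0
    when k is at (or below) the lower support bound.
    """
    N, n, m, k = int(N), int(n), int(m), int(k)
    if N < 0 or not (0 <= n <= N) or not (0 <= m <= N):
        raise ValidationError(f"need 0 <= n, m <= N, got N={N}, n={n}, m={m}")
    lo, hi = max(0, m + n - N), min(m, n)
    if not (lo <= k <= hi):
        raise ValidationError(f"k={k} outside valid range [{lo}, {hi}] for N={N}, n={n}, m={m}")
    if k <= lo:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, n, m))
    if p < 1e-12:
        # survival function via 1 - cdf loses accuracy deep in the tail;
        # re-sum the few remaining pmf terms in log space.
        support = np.arange(k, hi + 1)
        p = float(np.exp(logsumexp(hypergeom.logpmf(support, N, n, m))))
    return min(1.0, max(p, _P_FLOOR))


_KNOWN_METHODS = {"bonferroni", "holm", "fdr_bh", "sidak"}


def correct_pvalues(p_values: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiplicity-adjust raw p-values across one query's datasets.

    Bonferroni (p * D capped at 1) is the default; a few other standard
    methods are accepted by name.
    """
    if method not in _KNOWN_METHODS:
        raise ValidationError(f"unknown correction method: {method!r}")
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)):
        raise ValidationError("raw p-values must lie in (0, 1]")
    return multipletests(arr, method=method)[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """One dataset's enrichment record: the 2x2 margins and the verdict."""

    dataset_id: str
    tf: str
    cell_type: str
    N: int
    n: int
    m: int
    k: int
    p_raw: float
    p_corrected: float
    significant: bool


@dataclass
class GscaReport:
    """Full per-query report: one row per compendium dataset, sorted by
    ascending raw p-value."""

    query: str
    parameters: dict
    results: list[EnrichmentResult]

    _COLUMNS = ["dataset_id", "tf", "cell_type", "N", "n", "m", "k",
                "p_raw", "p_corrected", "significant"]

    def significant_datasets(self) -> list[str]:
        return [r.dataset_id for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results], columns=self._COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame().copy()
        df["p_raw"] = df["p_raw"].map("{:.6e}".format)
        df["p_corrected"] = df["p_corrected"].map("{:.6e}".format)
        df["significant"] = df["significant"].map({True: "yes", False: "no"})
        df.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "parameters": self.parameters,
            "results": [vars(r) for r in self.results],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GscaReport":
        results = [EnrichmentResult(**row) for row in payload["results"]]
        return cls(payload["query"], dict(payload["parameters"]), results)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "GscaReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def run_gsca(
    compendium: Compendium,
    pgmap: PeakGeneMap,
    gene_set: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    correction: str = "bonferroni",
    query_name: str = "query",
) -> GscaReport:
    """Score every compendium dataset for over-representation of its
    binding events among the query gene set's regions.

    A dataset is flagged significant iff its corrected p-value is below
    ``alpha``.  With n = 0 (no query region maps) every raw p-value is 1
    and a warning is logged.
    """
    if not compendium.datasets or compendium.n_regions == 0:
        raise ValidationError("empty compendium")
    if pgmap.n_regions != compendium.n_regions:
        raise ValidationError(
            f"peak-gene map covers {pgmap.n_regions} regions but the "
            f"compendium has {compendium.n_regions}"
        )
    gene_set = set(gene_set)
    hit_regions = map_gene_set_to_regions(gene_set, pgmap)
    N = compendium.n_regions
    n = len(hit_regions)
    occ = compendium.occupancy
    m = occ.sum(axis=0).astype(int)
    if n > 0:
        rows = np.fromiter(sorted(hit_regions), dtype=int)
        k = occ[rows].sum(axis=0).astype(int)
        p_raw = np.array([hypergeom_upper_tail(N, n, mi, ki) for mi, ki in zip(m, k)])
    else:
        logger.warning("query %r maps to zero universe regions; no enrichment is possible", query_name)
        k = np.zeros_like(m)
        p_raw = np.ones_like(m, dtype=float)
    p_adj = correct_pvalues(p_raw, correction)
    results = [
        EnrichmentResult(
            dataset_id=info.dataset_id,
            tf=info.tf,
            cell_type=info.cell_type,
            N=N,
            n=n,
            m=int(m[j]),
            k=int(k[j]),
            p_raw=float(p_raw[j]),
            p_corrected=float(p_adj[j]),
            significant=bool(p_adj[j] < alpha),
        )
        for j, info in enumerate(compendium.datasets)
    ]
    results.sort(key=lambda r: (r.p_raw, r.dataset_id))
    parameters = {
        "alpha": alpha,
        "correction": correction,
        "window_bp": pgmap.window_bp,
        "promoter_bp": pgmap.promoter_bp,
        "gene_set_size": len(gene_set),
    }
    n_sig = sum(r.significant for r in results)
    logger.info("GSCA %r: N=%d, n=%d; %d of %d datasets significant at alpha=%g",
                query_name, N, n, n_sig, len(results), alpha)
    return GscaReport(query_name, parameters, results)


def region_set_overlap_test(
    set_a: Sequence[GenomicRegion],
    set_b: Sequence[GenomicRegion],
    universe: Sequence[GenomicRegion] | Compendium,
) -> float:
    """Hypergeometric upper-tail p-value for the overlap of two region sets
    over a merged universe (e.g. tissue-specific enhancers vs regulatory
    regions): N = universe size, n/m = regions touched by each set, k =
    regions touched by both."""
    if isinstance(universe, Compendium):
        index = universe.index
    else:
        if len(universe) == 0:
            raise ValidationError("empty universe")
        index = RegionIndex(universe)
    if index.n == 0:
        raise ValidationError("empty universe")
    a = index.mark(set_a)
    b = index.mark(set_b)
    return hypergeom_upper_tail(index.n, int(a.sum()), int(b.sum()), int((a & b).sum()))
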