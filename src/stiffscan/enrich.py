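"""Region-level statistics: TFBS enrichment, signal summaries, subset labels.

Feature (e.g. transcription-factor-binding-site) enrichment in a region set
against a background transcript list is tested per feature with a two-sided
Fisher's exact test on the 2x2 incidence table, with family-wise error
controlled by Bonferroni correction across all features tested. Enrichment
magnitude is reported as the odds ratio (a*d)/(b*c), Haldane-corrected (+0.5
on every cell) whenever a zero cell would make it degenerate.

Also here: per-base averaging of bedGraph signal over regions (conservation
scores), mean cluster overlap counts (DNase I hypersensitivity), the
fraction of regions whose signal exceeds a threshold in any cell line
(histone marks), and the bookkeeping that crosses predictor confidence
(PS+/-) with reporter activity (L+/-) into four subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .model import CandidateRegion

__all__ = [
    "IncidenceTable",
    "EnrichmentResult",
    "SubsetLabel",
    "fisher_enrichment",
    "bonferroni_alpha",
    "enrich_all",
    "mean_region_signal",
    "count_overlapping_clusters",
    "fraction_above_threshold",
    "assign_subsets",
    "SUBSET_OF",
]

#: (predictor call, activity call) -> subset number
SUBSET_OF = {("+", "+"): 1, ("+", "-"): 2, ("-", "+"): 3, ("-", "-"): 4}
SUBSET_NAMES = {1: "PS+L+", 2: "PS+L-", 3: "PS-L+", 4: "PS-L-"}


@dataclass
class IncidenceTable:
    """Per-feature 2x2 counts: region set (a with / b without the feature)
    versus background (c with / d without)."""

    table: pd.DataFrame  # columns: feature, a, b, c, d

    def __post_init__(self) -> None:
        need = ["feature", "a", "b", "c", "d"]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValueError(f"incidence table missing column(s): {missing}")
        counts = self.table[["a", "b", "c", "d"]]
        if (counts < 0).any().any():
            raise ValueError("negative count in incidence table")
        if not (counts == counts.astype(int)).all().all():
            raise ValueError("non-integer count in incidence table")
        if self.table["feature"].duplicated().any():
            raise ValueError("duplicate feature ids")
        set_sizes = (self.table["a"] + self.table["b"]).unique()
        bg_sizes = (self.table["c"] + self.table["d"]).unique()
        if len(set_sizes) > 1 or len(bg_sizes) > 1:
            raise ValueError("inconsistent margins across features")

    @property
    def n_features(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IncidenceTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    feature: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    alpha_corrected: float
    significant: bool
    degenerate: bool = False


def fisher_enrichment(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Odds ratio and Fisher's exact p for one 2x2 incidence table.

    p is the two-sided exact probability (sum of hypergeometric outcomes no
    more likely than the observed table); one-sided alternatives are
    available via ``alternative``. The odds ratio is (a*d)/(b*c) with +0.5 on
    every cell iff any cell is zero.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"cell {name} must be a non-negative integer")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("degenerate table: a margin is zero")
    if any(x == 0 for x in (a, b, c, d)):
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(odds), float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha/m."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def enrich_all(
    table: IncidenceTable, alpha: float = 0.05, alternative: str = "two-sided"
) -> list[EnrichmentResult]:
    """Test every feature; Bonferroni threshold is alpha / n_features.

    Degenerate features (a zero margin) are reported with NaN statistics
    rather than aborting the batch. Results are sorted by p ascending, ties
    by feature id.
    """
    m = table.n_features
    if m == 0:
        return []
    corrected = bonferroni_alpha(alpha, m)
    results = []
    for row in table.table.itertuples(index=False):
        a, b, c, d = int(row.a), int(row.b), int(row.c), int(row.d)
        try:
            odds, p = fisher_enrichment(a, b, c, d, alternative=alternative)
            results.append(
                EnrichmentResult(str(row.feature), a, b, c, d, odds, p, corrected, p < corrected)
            )
        except ValueError:
            results.append(
                EnrichmentResult(
                    str(row.feature), a, b, c, d, np.nan, np.nan, corrected, False, degenerate=True
                )
            )
    results.sort(key=lambda r: (np.inf if np.isnan(r.p_value) else r.p_value, r.feature))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, r.significant)
            for r in results
        ],
        columns=["feature", "a", "b", "c", "d", "odds_ratio", "p_value", "significant"],
    )


def _region_tuple(region) -> tuple[str, int, int]:
    if isinstance(region, CandidateRegion):
        return region.chrom, region.start, region.end
    chrom, start, end = region[0], int(region[1]), int(region[2])
    return chrom, start, end


def mean_region_signal(track: pd.DataFrame, region) -> float:
    """Per-base mean of a bedGraph track over one region.

    The track must be sorted and non-overlapping per chromosome; bases not
    covered by any interval contribute 0. Regions on chromosomes absent from
    the track raise.
    """
    chrom, start, end = _region_tuple(region)
    if end <= start:
        raise ValueError("empty region")
    sub = track[track["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"region chromosome {chrom!r} not covered by track contigs")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("track intervals must be sorted and non-overlapping")
    values = sub["value"].to_numpy()
    overlap = np.maximum(0, np.minimum(ends, end) - np.maximum(starts, start))
    return float(np.sum(overlap * values) / (end - start))


def count_overlapping_clusters(clusters: pd.DataFrame, regions: Sequence) -> float:
    """Mean number of clusters per region; a cluster counts when the half-open
    intervals intersect in at least 1 bp."""
    if len(regions) == 0:
        return 0.0
    total = 0
    for region in regions:
        chrom, start, end = _region_tuple(region)
        sub = clusters[clusters["chrom"] == chrom]
        total += int(((sub["start"] < end) & (sub["end"] > start)).sum())
    return total / len(regions)


def fraction_above_threshold(
    signal: Mapping[str, Mapping[str, float]], threshold: float
) -> float:
    """Fraction of regions whose signal exceeds ``threshold`` in ANY cell line.

    ``signal`` maps region id -> {cell line -> mean intensity}. Reference
    threshold settings are 10 and 50.
    """
    if not signal:
        raise ValueError("empty region set")
    qualifying = sum(
        1 for per_cell in signal.values() if any(v > threshold for v in per_cell.values())
    )
    return qualifying / len(signal)


@dataclass
class SubsetLabel:
    region_id: str
    ps: str  # "+" | "-"
    luc: str  # "+" | "-"

    @property
    def subset(self) -> int:
        return SUBSET_OF[(self.ps, self.luc)]

    @property
    def subset_name(self) -> str:
        return SUBSET_NAMES[self.subset]


def assign_subsets(
    ps_calls: Mapping[str, str],
    luciferase_ratios: Mapping[str, float],
    activity_fold: float = 3.0,
) -> list[SubsetLabel]:
    """Cross predictor confidence with reporter activity into subsets 1-4.

    A region is active (L+) iff its normalized luciferase ratio strictly
    exceeds ``activity_fold`` (default 3-fold over negative controls; set 10
    to isolate the high-activity regime). Regions without a ratio are skipped
    with a warning.
    """
    labels = []
    n_missing = 0
    for region_id, ps in ps_calls.items():
        if ps not in "+-":
            raise ValueError(f"bad predictor call {ps!r} for {region_id}")
        if region_id not in luciferase_ratios:
            n_missing += 1
            continue
        luc = "+" if luciferase_ratios[region_id] > activity_fold else "-"
        labels.append(SubsetLabel(region_id=region_id, ps=ps, luc=luc))
    if n_missing:
        warnings.warn(f"skipped {n_missing} region(s) without a luciferase ratio")
    return labels
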