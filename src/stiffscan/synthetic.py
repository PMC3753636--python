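"""Seeded generators for every input the toolkit consumes, with known truth.

The generators emulate the statistical structure the pipeline assumes — not
real promoter biology (no CpG islands, no TATA boxes):

* a genome drawn from a first-order (dinucleotide-level) background chain
  with planted TSS-relative spans whose dinucleotide composition shifts the
  expected window-mean stiffness profile away from background by a controlled
  effect size, plus optional soft-masked decoy stretches for the repeat
  filter;
* strand-specific tag sets with a peak at a chosen 5'-end offset over uniform
  noise;
* feature-by-region incidence tables with one planted enriched feature;
* piecewise-constant bedGraph signal tracks.

Effect size is defined in profile space: the Euclidean distance between the
expected promoter and background 500-bp window-mean vectors, each channel
whitened by the background window-mean standard deviation. A mixing weight
between the background and target base compositions is calibrated by
bisection to hit the requested effect (capped at the target composition's
maximum, with the realized value reported). All randomness flows through
``numpy.random.default_rng`` (PCG64), so outputs are byte-stable for a fixed
seed across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import CandidateRegion, GridSpec, ScoreTrack, TssPrediction
from .physics import STEPS, StiffnessTable, revcomp
from .tagprof import TagSet, dedupe_5prime
from .enrich import IncidenceTable

__all__ = [
    "SyntheticSpec",
    "GenomeTruth",
    "gen_stiffness_table",
    "gen_genome",
    "gen_training_examples",
    "gen_tags",
    "gen_incidence",
    "gen_track",
    "calibrate_mixture_weight",
    "profile_effect",
    "match_calls",
    "score_auroc",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark.

    Defaults describe the standard benchmark: a 120-kb genome with 20 planted
    promoter-composition spans in the strong-signal regime (12 sd
    profile-space effect, near the ceiling of the default A/T-rich target
    composition) with 250 training examples per class so the classifier runs
    in its full-covariance mode; tags peaking 1000 bp into 1200-bp regions
    with 80% peak weight; and a 50-feature incidence table with one
    10-fold-enriched feature over a 10% background rate.
    """

    seed: int = 0
    # genome model
    genome_length: int = 120_000
    n_promoters: int = 20
    n_training: int = 250
    promoter_effect: float = 12.0
    background_base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    promoter_base_freqs: tuple[float, float, float, float] = (0.40, 0.10, 0.10, 0.40)
    min_plant_separation: int = 2400
    core_length: int = 500
    distal_weight: float = 1 / 3
    n_masked_decoys: int = 0
    masked_decoy_length: int = 1500
    chrom_name: str = "chrS"
    # tag model: peak at a chosen TSS offset plus uniform noise
    tag_peak_offset: int = 1000
    tag_peak_weight: float = 0.8
    tag_jitter: int = 0
    tags_per_region: int = 50
    opposite_strand_fraction: float = 0.0
    # enrichment model
    n_features: int = 50
    planted_feature: int | None = None
    enrichment_fold: float = 10.0
    set_size: int = 100
    background_size: int = 2000
    background_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("tag_peak_weight", "opposite_strand_fraction", "background_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for freqs in (self.background_base_freqs, self.promoter_base_freqs):
            if abs(sum(freqs) - 1) > 1e-9 or min(freqs) < 0:
                raise ValueError("base frequencies must be a probability vector")
        if self.promoter_effect < 0:
            raise ValueError("promoter_effect must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("background_base_freqs", "promoter_base_freqs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def gen_stiffness_table(seed: int) -> StiffnessTable:
    """Random positive stiffness constants with reverse-complement symmetry.

    Rotational channels land in 0.01-0.06 kcal/(mol*deg^2), translational in
    0.5-4 kcal/(mol*A^2) — the magnitude ranges of MD-derived constants — so
    synthetic tables are drop-in replacements in every consumer.
    """
    rng = np.random.default_rng(seed)
    entries: dict[str, np.ndarray] = {}
    for step in STEPS:
        rc = revcomp(step)
        if rc in entries:
            entries[step] = entries[rc].copy()
            continue
        rot = rng.uniform(0.01, 0.06, size=3)
        trans = rng.uniform(0.5, 4.0, size=3)
        entries[step] = np.concatenate([rot, trans])
    return StiffnessTable(entries=entries, source_label=f"synthetic(seed={seed})")


# ---------------------------------------------------------------------------
# effect-size calibration in profile space


def _step_freqs_iid(base_freqs: np.ndarray) -> np.ndarray:
    """Expected dinucleotide-step frequencies of an iid chain (16,)."""
    p = np.asarray(base_freqs, dtype=float)
    return np.outer(p, p).ravel()


def _expected_step_mean(table: StiffnessTable, base_freqs) -> np.ndarray:
    return _step_freqs_iid(np.asarray(base_freqs)) @ table.matrix


def _background_window_sd(table: StiffnessTable, base_freqs, window_length: int) -> np.ndarray:
    """Approximate sd of the 6 window-mean channels under the background chain.

    Steps are treated as independent draws from the stationary step
    distribution; the mild overlap correlation between adjacent steps is
    ignored (the effect scale, not the generator, depends on it).
    """
    f = _step_freqs_iid(np.asarray(base_freqs))
    mu = f @ table.matrix
    second = f @ (table.matrix**2)
    var = np.maximum(second - mu**2, 1e-30)
    return np.sqrt(var / (window_length - 1))


def profile_effect(
    table: StiffnessTable,
    mixture_weight: float,
    background_base_freqs,
    promoter_base_freqs,
    window_length: int = 500,
) -> float:
    """Whitened distance between expected window means at a mixing weight."""
    bg = np.asarray(background_base_freqs, dtype=float)
    tg = np.asarray(promoter_base_freqs, dtype=float)
    mixed = (1 - mixture_weight) * bg + mixture_weight * tg
    delta = _expected_step_mean(table, mixed) - _expected_step_mean(table, bg)
    sd = _background_window_sd(table, bg, window_length)
    return float(np.linalg.norm(delta / sd))


def calibrate_mixture_weight(
    table: StiffnessTable,
    effect: float,
    background_base_freqs,
    promoter_base_freqs,
    window_length: int = 500,
) -> tuple[float, float]:
    """Bisection for the mixing weight achieving a profile-space effect.

    Returns ``(weight, realized_effect)``; the weight caps at 1 when the
    target composition cannot produce the requested effect.
    """
    if effect <= 0:
        return 0.0, 0.0
    f = lambda w: profile_effect(
        table, w, background_base_freqs, promoter_base_freqs, window_length
    )
    max_eff = f(1.0)
    if effect >= max_eff:
        return 1.0, max_eff
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < effect:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    return w, f(w)


# ---------------------------------------------------------------------------
# genome generation


def _sample_iid(rng: np.random.Generator, length: int, base_freqs) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(base_freqs, dtype=float))


def _promoter_span_codes(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    span_len: int,
    w_mix: float,
) -> np.ndarray:
    """Promoter-span base codes, 5'->3' on the promoter's own strand.

    Promoter composition is structured along the span — the full mixture
    weight over the 5'-side core (``core_length`` bp), a ``distal_weight``
    fraction of it over the remainder — so the planted profile varies along
    position. A homogeneous span would leave the TSS position and strand
    degenerate: with a reverse-complement-symmetric stiffness table, any grid
    placement inside it scores identically in expectation.
    """
    bg = np.asarray(spec.background_base_freqs, dtype=float)
    tg = np.asarray(spec.promoter_base_freqs, dtype=float)
    core = min(spec.core_length, span_len)
    mixed_core = (1 - w_mix) * bg + w_mix * tg
    w_distal = w_mix * spec.distal_weight
    mixed_distal = (1 - w_distal) * bg + w_distal * tg
    return np.concatenate(
        [_sample_iid(rng, core, mixed_core), _sample_iid(rng, span_len - core, mixed_distal)]
    )


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class GenomeTruth:
    """A generated genome plus its planted ground truth."""

    genome: dict[str, str]
    truth: pd.DataFrame  # chrom, tss, strand, plant_start, plant_end
    mixture_weight: float
    realized_effect: float
    spec: SyntheticSpec

    def truth_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# realized_profile_effect={self.realized_effect:.4f} "
                     f"mixture_weight={self.mixture_weight:.4f}\n")
            for i, row in enumerate(self.truth.itertuples(index=False)):
                fh.write(
                    f"{row.chrom}\t{row.tss}\t{row.tss + 1}\ttss_{i:04d}\t0\t{row.strand}\n"
                )


def gen_genome(
    spec: SyntheticSpec,
    table: StiffnessTable,
    grid: GridSpec = GridSpec(),
) -> GenomeTruth:
    """Background chain genome with planted promoter-composition spans.

    Planted TSSs sit on the grid-stride lattice, at least
    ``min_plant_separation`` apart and clear of the chromosome edges; each
    plant rewrites the full grid span around its TSS (strand-aware) with the
    calibrated promoter-mixture composition. Optional soft-masked decoy
    stretches (lowercase) are dropped into the gaps between plants.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    span_len = grid.span_end - grid.span_start
    margin = max(abs(grid.span_start), grid.last_window_end) + grid.stride
    w_mix, realized = calibrate_mixture_weight(
        table,
        spec.promoter_effect,
        spec.background_base_freqs,
        spec.promoter_base_freqs,
        grid.window_length,
    )

    n = spec.n_promoters
    usable = L - 2 * margin
    slot = usable // n if n else usable
    if n and slot < spec.min_plant_separation + grid.stride:
        raise ValueError(
            f"plants don't fit: need about {n * (spec.min_plant_separation + grid.stride) + 2 * margin} bp, "
            f"have {L}"
        )

    codes = _sample_iid(rng, L, spec.background_base_freqs)
    rows = []
    jitter_max = max(0, slot - spec.min_plant_separation - grid.stride)
    for i in range(n):
        jitter = int(rng.integers(0, jitter_max + 1)) if jitter_max else 0
        tss = margin + i * slot + jitter
        tss -= tss % grid.stride  # snap to the scan lattice
        strand = "+" if rng.random() < 0.5 else "-"
        plant = _promoter_span_codes(rng, spec, span_len, w_mix)
        if strand == "+":
            start = tss + grid.span_start
        else:
            plant = 3 - plant[::-1]  # reverse complement in code space
            start = tss + 1 - grid.span_end
        codes[start : start + span_len] = plant
        rows.append((spec.chrom_name, tss, strand, start, start + span_len))
    truth = pd.DataFrame(rows, columns=["chrom", "tss", "strand", "plant_start", "plant_end"])

    seq = _codes_to_seq(codes)
    if spec.n_masked_decoys:
        seq_list = list(seq)
        occupied = [(r[3], r[4]) for r in rows]
        placed = 0
        attempts = 0
        while placed < spec.n_masked_decoys and attempts < 1000:
            attempts += 1
            s = int(rng.integers(margin, L - margin - spec.masked_decoy_length))
            e = s + spec.masked_decoy_length
            if any(s < pe and e > ps for ps, pe in occupied):
                continue
            seq_list[s:e] = [c.lower() for c in seq_list[s:e]]
            occupied.append((s, e))
            placed += 1
        seq = "".join(seq_list)

    return GenomeTruth(
        genome={spec.chrom_name: seq},
        truth=truth,
        mixture_weight=w_mix,
        realized_effect=realized,
        spec=spec,
    )


def gen_training_examples(
    spec: SyntheticSpec,
    table: StiffnessTable,
    grid: GridSpec,
    n: int,
    label: str,
    seed: int,
) -> list[tuple[str, int, str]]:
    """Training triples (sequence, TSS offset, strand) for one class.

    ``label`` 'promoter' uses the calibrated promoter-mixture composition over
    the full grid span; 'background' uses the background chain. Every other
    example is stored in antisense representation to exercise the
    reverse-complement training path.
    """
    if label == "promoter":
        w_mix, _ = calibrate_mixture_weight(
            table,
            spec.promoter_effect,
            spec.background_base_freqs,
            spec.promoter_base_freqs,
            grid.window_length,
        )
    elif label == "background":
        w_mix = 0.0
    else:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    span_len = grid.span_end - grid.span_start
    offset = -grid.span_start
    out = []
    for i in range(n):
        if label == "promoter":
            codes = _promoter_span_codes(rng, spec, span_len, w_mix)
        else:
            codes = _sample_iid(rng, span_len, spec.background_base_freqs)
        seq = _codes_to_seq(codes)
        if i % 2:
            out.append((revcomp(seq), span_len - 1 - offset, "-"))
        else:
            out.append((seq, offset, "+"))
    return out


# ---------------------------------------------------------------------------
# tags, incidence tables, tracks


def gen_tags(
    regions: Sequence[CandidateRegion],
    seed: int,
    peak_offset: int = 1000,
    peak_weight: float = 0.8,
    jitter: int = 0,
    tags_per_region: int = 50,
    opposite_strand_fraction: float = 0.0,
    cell_line: str = "synthetic",
    provenance: str = "CAGE",
) -> TagSet:
    """Strand-specific tag 5'-ends: a peak at ``peak_offset`` plus uniform noise.

    Each tag independently falls on the peak (probability ``peak_weight``,
    with +/- ``jitter`` bp of uniform jitter) or uniformly in the region; a
    stated fraction lands on the opposite strand as decoys. The returned set
    is already deduplicated.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        length = region.length
        for _ in range(tags_per_region):
            if rng.random() < peak_weight:
                d = peak_offset + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
                d = min(max(d, 0), length - 1)
            else:
                d = int(rng.integers(0, length))
            strand = region.strand
            if rng.random() < opposite_strand_fraction:
                strand = "-" if strand == "+" else "+"
            pos = region.start + d if region.strand == "+" else region.end - 1 - d
            rows.append((region.chrom, pos, strand, cell_line))
    raw = pd.DataFrame(rows, columns=["chrom", "position", "strand", "cell_line"])
    return dedupe_5prime(raw, provenance=provenance)


def gen_incidence(
    seed: int,
    n_features: int = 50,
    planted_feature: int | None = None,
    fold: float = 10.0,
    set_size: int = 100,
    background_size: int = 2000,
    background_rate: float = 0.1,
) -> tuple[IncidenceTable, str]:
    """Incidence table with null features and one planted enrichment.

    Null features: background counts binomial at the background rate, region
    counts hypergeometric given the background pool (exactly the Fisher
    null). The planted feature's region count is inflated ``fold``-fold.
    Returns the table and the planted feature id.
    """
    rng = np.random.default_rng(seed)
    if planted_feature is None:
        planted_feature = int(rng.integers(n_features))
    rows = []
    for i in range(n_features):
        c = int(rng.binomial(background_size, background_rate))
        if i == planted_feature:
            a = int(rng.binomial(set_size, min(1.0, background_rate * fold)))
        elif c > 0:
            a = int(rng.hypergeometric(c, background_size - c, set_size))
        else:
            a = 0
        rows.append((f"TF{i:03d}", a, set_size - a, c, background_size - c))
    table = IncidenceTable(pd.DataFrame(rows, columns=["feature", "a", "b", "c", "d"]))
    return table, f"TF{planted_feature:03d}"


def gen_track(
    seed: int,
    chrom: str,
    length: int,
    n_segments: int = 50,
    value_range: tuple[float, float] = (0.0, 10.0),
    coverage: float = 1.0,
) -> pd.DataFrame:
    """Sorted, non-overlapping piecewise-constant bedGraph intervals.

    ``coverage`` < 1 leaves a uniform fraction of each segment uncovered, to
    exercise the uncovered-base convention in signal averaging.
    """
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_segments - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    rows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        e_cov = s + max(1, int((e - s) * coverage))
        value = float(rng.uniform(*value_range))
        rows.append((chrom, int(s), int(min(e_cov, e)), value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# truth matching / benchmark metrics


def match_calls(
    calls: Sequence[TssPrediction],
    truth: pd.DataFrame,
    tolerance: int = 50,
) -> dict[str, float]:
    """Recall/precision of calls against planted TSSs (strand-ignored).

    A plant is recovered if any call lies within ``tolerance`` bp of its TSS;
    a call is correct if it lies within ``tolerance`` bp of any plant.
    """
    recovered = 0
    for row in truth.itertuples(index=False):
        if any(c.chrom == row.chrom and abs(c.position - row.tss) <= tolerance for c in calls):
            recovered += 1
    correct = 0
    for c in calls:
        sub = truth[truth["chrom"] == c.chrom]
        if len(sub) and (np.abs(sub["tss"].to_numpy() - c.position) <= tolerance).any():
            correct += 1
    return {
        "n_truth": len(truth),
        "n_calls": len(calls),
        "recall": recovered / len(truth) if len(truth) else float("nan"),
        "precision": correct / len(calls) if calls else float("nan"),
    }


def score_auroc(
    tracks: Sequence[ScoreTrack], truth: pd.DataFrame, tolerance: int = 25
) -> float:
    """AUROC of the scan score for separating plant-TSS positions from the rest.

    Computed as the Mann-Whitney rank statistic over valid scanned positions;
    positives are positions within ``tolerance`` bp of a planted TSS.
    """
    scores, labels = [], []
    for tr in tracks:
        ok = tr.valid
        pos = tr.positions[ok]
        s = tr.score[ok]
        sub = truth[truth["chrom"] == tr.chrom]
        tss = sub["tss"].to_numpy()
        lab = (
            (np.abs(pos[:, None] - tss[None, :]) <= tolerance).any(axis=1)
            if len(tss)
            else np.zeros(len(pos), dtype=bool)
        )
        scores.append(s)
        labels.append(lab)
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative positions for AUROC")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
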