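"""Promoter/TSS classification from windowed stiffness profiles.

The classifier is comparative: a candidate TSS position is described by the
window-averaged six-channel stiffness profile over a fixed TSS-relative grid
(default -250/+900 bp tiled with 500-bp windows every 50 bp, giving a
D = 6 x n_windows feature vector), and is scored against two reference
profiles — one trained on known promoters, one on background sequence — by
Mahalanobis distance. The score is ``d_background - d_promoter``: positive
means the position sits closer (in covariance-scaled units) to the promoter
class than to background.

Exposed in two equivalent styles: module-level operations
(:func:`build_reference_profile`, :func:`mahalanobis`, :func:`scan`,
:func:`call_tss`, :func:`filter_candidates`, :func:`make_regions`) and a
statsmodels-flavoured :class:`PromoterModel` whose :meth:`~PromoterModel.fit`
returns a :class:`PromoterModelResults` carrying the fitted reference
profiles, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .physics import (
    CHANNELS,
    StiffnessTable,
    _window_sums,
    revcomp,
    step_series,
)

__all__ = [
    "GridSpec",
    "ReferenceProfile",
    "TssPrediction",
    "CandidateRegion",
    "ScoreTrack",
    "build_reference_profile",
    "mahalanobis",
    "scan",
    "call_tss",
    "filter_candidates",
    "make_regions",
    "write_calls_bed",
    "PromoterModel",
    "PromoterModelResults",
]

ROLE_SPANS = {
    # role -> (upstream bp, downstream bp) relative to the TSS on its own strand
    "core_promoter": (1000, 200),
    "tested_1200": (1000, 200),
    "expanded_2000": (1000, 1000),
}


@dataclass(frozen=True)
class GridSpec:
    """TSS-relative window grid defining the classifier's feature space.

    The span covers ``[span_start, span_end)`` bp around the candidate TSS and
    is tiled with ``window_length``-bp windows every ``stride`` bp; each window
    contributes its six channel means, so the feature dimension is
    ``6 * n_windows``.
    """

    span_start: int = -250
    span_end: int = 900
    window_length: int = 500
    stride: int = 50

    def __post_init__(self) -> None:
        if self.span_end - self.span_start < self.window_length:
            raise ValueError("grid span must cover at least one window")
        if self.stride < 1 or self.window_length < 2:
            raise ValueError("invalid grid stride/window_length")

    @property
    def n_windows(self) -> int:
        return (self.span_end - self.span_start - self.window_length) // self.stride + 1

    @property
    def offsets(self) -> np.ndarray:
        """Window start offsets relative to the TSS."""
        return self.span_start + self.stride * np.arange(self.n_windows)

    @property
    def dim(self) -> int:
        return 6 * self.n_windows

    @property
    def last_window_end(self) -> int:
        return int(self.offsets[-1]) + self.window_length

    def to_dict(self) -> dict:
        return {
            "span_start": self.span_start,
            "span_end": self.span_end,
            "window_length": self.window_length,
            "stride": self.stride,
        }


@dataclass
class ReferenceProfile:
    """A trained class profile: mean feature vector plus covariance.

    ``covariance`` is either a full (D, D) matrix or, when the training set is
    too small for a stable full estimate, a (D,) diagonal; both carry a small
    ridge (lambda*I) so the Mahalanobis quadratic form is always defined.
    """

    label: str
    grid: GridSpec | None
    mean: np.ndarray
    covariance: np.ndarray
    diagonal: bool = False
    n_training: int = 0
    table_checksum: str = ""
    _chol: tuple | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("reference mean must be finite")
        if self.diagonal:
            if self.covariance.shape != self.mean.shape or np.any(self.covariance <= 0):
                raise ValueError("diagonal covariance must be positive, shape (D,)")
        else:
            d = len(self.mean)
            if self.covariance.shape != (d, d):
                raise ValueError("covariance shape mismatch")

    @property
    def dim(self) -> int:
        return len(self.mean)

    def mahalanobis(self, x: np.ndarray) -> np.ndarray | float:
        """Mahalanobis distance of x (D,) or a stack (n, D) from this profile."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        x2 = np.atleast_2d(x)
        if x2.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: got {x2.shape[1]}, expected {self.dim}")
        xc = x2 - self.mean
        if self.diagonal:
            d2 = np.sum(xc * xc / self.covariance, axis=1)
        else:
            if self._chol is None:
                self._chol = cho_factor(self.covariance, lower=True)
            sol = cho_solve(self._chol, xc.T)
            d2 = np.sum(xc.T * sol, axis=0)
        d = np.sqrt(np.maximum(d2, 0.0))
        return float(d[0]) if scalar else d

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "grid": self.grid.to_dict() if self.grid is not None else None,
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "diagonal": self.diagonal,
            "n_training": self.n_training,
            "table_checksum": self.table_checksum,
            "channel_order": list(CHANNELS),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceProfile":
        grid = GridSpec(**d["grid"]) if d.get("grid") else None
        return cls(
            label=d["label"],
            grid=grid,
            mean=np.array(d["mean"], dtype=float),
            covariance=np.array(d["covariance"], dtype=float),
            diagonal=bool(d.get("diagonal", False)),
            n_training=int(d.get("n_training", 0)),
            table_checksum=d.get("table_checksum", ""),
        )


def mahalanobis(x: np.ndarray, ref: ReferenceProfile) -> float:
    """sqrt((x - mean)^T Sigma^-1 (x - mean)) against a reference profile."""
    return ref.mahalanobis(np.asarray(x, dtype=float))


@dataclass
class TssPrediction:
    """One scored candidate TSS position."""

    chrom: str
    position: int
    strand: str
    d_promoter: float
    d_background: float

    @property
    def score(self) -> float:
        return self.d_background - self.d_promoter

    @property
    def label(self) -> str:
        # tie (score == 0) deliberately falls to background: conservative calling
        return "promoter" if self.score > 0 else "background"


@dataclass
class CandidateRegion:
    """A strand-aware region derived from a predicted TSS.

    Roles: ``core_promoter`` / ``tested_1200`` span -1000/+200 bp around the
    TSS following the strand (upstream is 5' on the region's own strand);
    ``expanded_2000`` spans +/-1000 bp. Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    strand: str
    tss_position: int
    role: str = "tested_1200"
    name: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (self.start <= self.tss_position < self.end) and not self.truncated:
            raise ValueError("tss_position outside region")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Biological 5'-end of the region: leftmost base on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end - 1


def make_regions(
    call: TssPrediction | CandidateRegion,
    role: str,
    chrom_length: int | None = None,
) -> CandidateRegion:
    """Build the role-specific region around a predicted TSS (strand-aware)."""
    if role not in ROLE_SPANS:
        raise ValueError(f"unknown role {role!r}")
    up, down = ROLE_SPANS[role]
    tss = call.position if isinstance(call, TssPrediction) else call.tss_position
    if call.strand == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down, tss + up
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if chrom_length is not None and end > chrom_length:
        end, truncated = chrom_length, True
    if truncated:
        warnings.warn(f"region for TSS {call.chrom}:{tss} truncated to chromosome bounds")
    return CandidateRegion(
        chrom=call.chrom,
        start=start,
        end=end,
        strand=call.strand,
        tss_position=tss,
        role=role,
        truncated=truncated,
    )


@dataclass
class ScoreTrack:
    """Per-chromosome, per-strand score series from a genome scan.

    ``valid`` is False at no-call positions (grid overlapping invalid
    windows); distances are NaN there.
    """

    chrom: str
    strand: str
    positions: np.ndarray
    d_promoter: np.ndarray
    d_background: np.ndarray
    valid: np.ndarray

    @property
    def score(self) -> np.ndarray:
        return self.d_background - self.d_promoter

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "position": self.positions,
                "strand": self.strand,
                "d_promoter": self.d_promoter,
                "d_background": self.d_background,
                "score": self.score,
                "valid": self.valid,
            }
        )


class _ChromScanner:
    """Precomputed window sums for one chromosome; serves grid features fast.

    Relies on the reverse-complement symmetry of the stiffness table: the
    antisense profile is the reversed sense profile, so minus-strand grid
    windows are served from the forward window-sum arrays at mirrored starts.
    """

    def __init__(self, seq: str, table: StiffnessTable, grid: GridSpec, min_valid: float = 0.9):
        self.L = len(seq)
        self.grid = grid
        self.min_valid = min_valid
        profile = step_series(seq, table)
        self.sums, self.counts = _window_sums(profile, grid.window_length)

    def _starts(self, positions: np.ndarray, strand: str) -> np.ndarray:
        g = self.grid
        offs = g.offsets  # (nw,)
        if strand == "+":
            return positions[:, None] + offs[None, :]
        # antisense grid window k maps to the forward window mirrored about the
        # candidate position (symmetric table => reversed step series)
        return positions[:, None] + 1 - g.window_length - offs[None, :]

    def features(self, positions: np.ndarray, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Grid feature matrix (n, D) and validity flags for candidate positions."""
        positions = np.asarray(positions, dtype=np.intp)
        starts = self._starts(positions, strand)
        n_starts = len(self.sums)
        in_range = (starts >= 0) & (starts < n_starts)
        safe = np.where(in_range, starts, 0)
        sums = self.sums[safe]  # (n, nw, 6)
        counts = self.counts[safe].astype(float)  # (n, nw)
        per = self.grid.window_length - 1
        ok = in_range & (counts / per >= self.min_valid) & (counts > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts[..., None]
        valid = ok.all(axis=1)
        feats = means.reshape(len(positions), -1)
        feats[~valid] = np.nan
        return feats, valid

    def position_range(self, strand: str) -> tuple[int, int]:
        """Inclusive candidate-position bounds where the whole grid fits."""
        g = self.grid
        if strand == "+":
            lo = -g.span_start
            hi = self.L - g.last_window_end
        else:
            lo = g.last_window_end - 1
            hi = self.L - 1 + g.span_start
        return lo, hi


def _extract_training_features(
    training: Iterable[tuple[str, int, str]],
    table: StiffnessTable,
    grid: GridSpec,
    min_valid: float,
) -> np.ndarray:
    rows = []
    n_skipped = 0
    for i, (seq, tss_offset, strand) in enumerate(training):
        if strand == "-":
            seq = revcomp(seq)
            tss_offset = len(seq) - 1 - tss_offset
        sc = _ChromScanner(seq, table, grid, min_valid=min_valid)
        x, ok = sc.features(np.array([tss_offset]), "+")
        if not ok[0]:
            n_skipped += 1
            continue
        rows.append(x[0])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} training example(s) with invalid grid windows")
    if not rows:
        raise ValueError("no usable training examples")
    return np.vstack(rows)


def build_reference_profile(
    training: Iterable[tuple[str, int, str]],
    table: StiffnessTable,
    grid: GridSpec,
    label: str,
    shrinkage: float = 1e-6,
    force_diagonal: bool | None = None,
    min_valid: float = 0.9,
) -> ReferenceProfile:
    """Train a class reference profile from (sequence, TSS offset, strand) triples.

    Antisense examples are reverse-complemented before feature extraction. The
    covariance is the full sample covariance plus ``lambda*I`` shrinkage
    (lambda = shrinkage * trace/D, floored at 1e-9) when the training count
    reaches D+2; below that a diagonal covariance is used instead (warned).
    """
    X = _extract_training_features(training, table, grid, min_valid)
    n, D = X.shape
    mean = X.mean(axis=0)
    diagonal = force_diagonal if force_diagonal is not None else n < D + 2
    if force_diagonal is None and diagonal and n >= 2:
        warnings.warn(
            f"{label}: {n} training examples < D+2 = {D + 2}; using diagonal covariance"
        )
    if diagonal:
        var = X.var(axis=0, ddof=1) if n > 1 else np.zeros(D)
        lam = max(shrinkage * var.sum() / D, 1e-9)
        cov = var + lam
    else:
        S = np.cov(X, rowvar=False, ddof=1)
        lam = max(shrinkage * np.trace(S) / D, 1e-9)
        cov = S + lam * np.eye(D)
    return ReferenceProfile(
        label=label,
        grid=grid,
        mean=mean,
        covariance=cov,
        diagonal=diagonal,
        n_training=n,
        table_checksum=table.checksum(),
    )


def scan(
    genome: Mapping[str, str],
    table: StiffnessTable,
    promoter_ref: ReferenceProfile,
    background_ref: ReferenceProfile,
    stride: int = 50,
    min_valid: float = 0.9,
) -> list[ScoreTrack]:
    """Score every candidate TSS position on both strands of every chromosome.

    Candidate positions run at ``stride`` bp wherever the full grid fits inside
    the chromosome; positions whose grid overlaps invalid windows become
    no-calls (``valid`` False).
    """
    if promoter_ref.grid != background_ref.grid:
        raise ValueError("reference profiles were trained on different grids")
    if promoter_ref.table_checksum != background_ref.table_checksum:
        raise ValueError("model/parameter incoherence: reference table checksums differ")
    if promoter_ref.table_checksum and promoter_ref.table_checksum != table.checksum():
        raise ValueError("model/parameter incoherence: scan table differs from training table")
    grid = promoter_ref.grid
    tracks: list[ScoreTrack] = []
    for chrom in sorted(genome):
        sc = _ChromScanner(genome[chrom], table, grid, min_valid=min_valid)
        for strand in "+-":
            lo, hi = sc.position_range(strand)
            first = -(-lo // stride) * stride  # first multiple of stride >= lo
            positions = np.arange(first, hi + 1, stride, dtype=np.intp)
            if len(positions) == 0:
                continue
            feats, valid = sc.features(positions, strand)
            d_p = np.full(len(positions), np.nan)
            d_b = np.full(len(positions), np.nan)
            if valid.any():
                d_p[valid] = promoter_ref.mahalanobis(feats[valid])
                d_b[valid] = background_ref.mahalanobis(feats[valid])
            tracks.append(
                ScoreTrack(
                    chrom=chrom,
                    strand=strand,
                    positions=positions.astype(int),
                    d_promoter=d_p,
                    d_background=d_b,
                    valid=valid,
                )
            )
    return tracks


def _local_maxima(scores: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateau edges resolve to the leftmost position."""
    n = len(scores)
    if n == 0:
        return np.zeros(0, dtype=int)
    left = np.concatenate([[-np.inf], scores[:-1]])
    right = np.concatenate([scores[1:], [-np.inf]])
    return np.where((scores > left) & (scores >= right))[0]


def call_tss(
    tracks: Sequence[ScoreTrack] | ScoreTrack,
    tau: float,
    min_separation: int = 1200,
) -> list[TssPrediction]:
    """Greedy peak calling on score tracks.

    Local score maxima strictly above ``tau`` are accepted in descending score
    order (ties: leftmost coordinate, then '+' strand first); a candidate
    within ``min_separation`` bp of an already accepted call on the same
    chromosome is suppressed, regardless of strand.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if isinstance(tracks, ScoreTrack):
        tracks = [tracks]
    candidates: list[TssPrediction] = []
    for tr in tracks:
        ok = tr.valid
        pos, dp, db = tr.positions[ok], tr.d_promoter[ok], tr.d_background[ok]
        s = db - dp
        for i in _local_maxima(s):
            if s[i] > tau:
                candidates.append(
                    TssPrediction(tr.chrom, int(pos[i]), tr.strand, float(dp[i]), float(db[i]))
                )
    candidates.sort(key=lambda c: (-c.score, c.chrom, c.position, c.strand))
    accepted: list[TssPrediction] = []
    for c in candidates:
        if all(
            c.chrom != a.chrom or abs(c.position - a.position) >= min_separation
            for a in accepted
        ):
            accepted.append(c)
    accepted.sort(key=lambda c: (c.chrom, c.position, c.strand))
    return accepted


def _masked_fraction(seq_slice: str) -> float:
    if not seq_slice:
        return 0.0
    lower = sum(1 for ch in seq_slice if ch.islower())
    return lower / len(seq_slice)


def _mask_covered_fraction(mask_df: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    sub = mask_df[mask_df["chrom"] == chrom]
    if sub.empty or end <= start:
        return 0.0
    covered = 0
    for s, e in zip(sub["start"], sub["end"]):
        covered += max(0, min(e, end) - max(s, start))
    return covered / (end - start)


def filter_candidates(
    calls: Sequence[TssPrediction],
    annotated_tss: pd.DataFrame,
    genome: Mapping[str, str],
    min_distance: int = 1200,
    max_repeat_fraction: float = 0.70,
    mask_intervals: pd.DataFrame | None = None,
) -> tuple[list[TssPrediction], pd.DataFrame]:
    """Candidate-selection filters for the high-confidence prediction set.

    A call is kept iff (a) its position is at least ``min_distance`` bp from
    every annotated TSS (position-to-position, strand ignored) and (b) the
    repeat-masked fraction of its 1200-bp tested region is at most
    ``max_repeat_fraction`` (strictly greater rejects). Masking comes from
    soft-masked lowercase sequence, or from ``mask_intervals`` (BED-like
    DataFrame) when given. Returns (kept, rejections table).
    """
    if annotated_tss is None:
        raise ValueError("annotation is required")
    if "position" not in annotated_tss.columns:
        raise ValueError("annotated_tss needs columns chrom, position")
    kept: list[TssPrediction] = []
    rows = []
    ann_by_chrom = {
        chrom: np.sort(sub["position"].to_numpy())
        for chrom, sub in annotated_tss.groupby("chrom")
    }
    for i, call in enumerate(calls):
        reason = ""
        ann = ann_by_chrom.get(call.chrom)
        if ann is not None and len(ann):
            j = np.searchsorted(ann, call.position)
            near = min(
                abs(call.position - ann[max(0, j - 1)]),
                abs(call.position - ann[min(len(ann) - 1, j)]),
            )
            if near < min_distance:
                reason = f"too close to annotated TSS ({near} bp)"
        if not reason:
            region = make_regions(call, "tested_1200", chrom_length=len(genome[call.chrom]))
            if mask_intervals is not None:
                frac = _mask_covered_fraction(mask_intervals, region.chrom, region.start, region.end)
            else:
                frac = _masked_fraction(genome[call.chrom][region.start : region.end])
            if frac > max_repeat_fraction:
                reason = f"repeat fraction {frac:.2f} > {max_repeat_fraction:.2f}"
        if reason:
            rows.append((i, call.chrom, call.position, call.strand, reason))
        else:
            kept.append(call)
    rejects = pd.DataFrame(rows, columns=["call_index", "chrom", "position", "strand", "reason"])
    return kept, rejects


def write_calls_bed(calls: Sequence[TssPrediction], path: str | Path) -> None:
    """BED6 output: name = call id, score = 1000-scaled clipped score, strand."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            bed_score = int(np.clip(round(1000 * c.score), 0, 1000))
            fh.write(
                f"{c.chrom}\t{c.position}\t{c.position + 1}\tcall_{i:05d}\t{bed_score}\t{c.strand}\n"
            )


class PromoterModel:
    """Two-class stiffness-profile classifier, statsmodels-style.

    Parameters
    ----------
    promoter_training, background_training
        Iterables of ``(sequence, tss_offset, strand)`` triples; each sequence
        must cover the full grid span around its TSS offset.
    table
        Stiffness parameter table; defaults to the packaged table.
    grid
        TSS-relative window grid (default -250/+900, 500-bp windows, 50-bp
        stride).
    """

    def __init__(
        self,
        promoter_training: Sequence[tuple[str, int, str]],
        background_training: Sequence[tuple[str, int, str]],
        table: StiffnessTable | None = None,
        grid: GridSpec = GridSpec(),
        shrinkage: float = 1e-6,
        min_valid: float = 0.9,
    ):
        if table is None:
            from .physics import default_stiffness_table

            table = default_stiffness_table()
        self.promoter_training = list(promoter_training)
        self.background_training = list(background_training)
        self.table = table
        self.grid = grid
        self.shrinkage = shrinkage
        self.min_valid = min_valid

    def fit(self, force_diagonal: bool | None = None) -> "PromoterModelResults":
        promoter = build_reference_profile(
            self.promoter_training,
            self.table,
            self.grid,
            "promoter",
            shrinkage=self.shrinkage,
            force_diagonal=force_diagonal,
            min_valid=self.min_valid,
        )
        background = build_reference_profile(
            self.background_training,
            self.table,
            self.grid,
            "background",
            shrinkage=self.shrinkage,
            force_diagonal=force_diagonal,
            min_valid=self.min_valid,
        )
        return PromoterModelResults(self, promoter, background)


class PromoterModelResults:
    """Fitted reference profiles plus scanning/calling conveniences."""

    def __init__(
        self,
        model: PromoterModel | None,
        promoter: ReferenceProfile,
        background: ReferenceProfile,
        table: StiffnessTable | None = None,
    ):
        self.model = model
        self.promoter = promoter
        self.background = background
        self.table = table if table is not None else (model.table if model else None)

    def score_features(self, X: np.ndarray) -> pd.DataFrame:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d_p = self.promoter.mahalanobis(X)
        d_b = self.background.mahalanobis(X)
        score = d_b - d_p
        return pd.DataFrame(
            {
                "d_promoter": d_p,
                "d_background": d_b,
                "score": score,
                "label": np.where(score > 0, "promoter", "background"),
            }
        )

    def scan(self, genome: Mapping[str, str], stride: int = 50, min_valid: float | None = None) -> list[ScoreTrack]:
        if self.table is None:
            raise ValueError("results carry no stiffness table; pass one at construction")
        mv = self.model.min_valid if (min_valid is None and self.model) else (min_valid or 0.9)
        return scan(genome, self.table, self.promoter, self.background, stride=stride, min_valid=mv)

    def call_tss(
        self,
        tracks: Sequence[ScoreTrack],
        tau: float | None = None,
        quantile: float = 0.95,
        min_separation: int = 1200,
    ) -> list[TssPrediction]:
        """Peak-call predictions; with ``tau=None`` the threshold is the given
        quantile of the genome-wide valid score distribution (the
        high-confidence cut), floored at 0."""
        if tau is None:
            scores = np.concatenate([t.score[t.valid] for t in tracks]) if tracks else np.zeros(0)
            tau = float(max(0.0, np.quantile(scores, quantile))) if len(scores) else 0.0
        return call_tss(tracks, tau=tau, min_separation=min_separation)

    def summary(self) -> str:
        g = self.promoter.grid
        lines = [
            "Stiffness-profile promoter classifier",
            "=" * 53,
            f"grid span          : {g.span_start:+d}/{g.span_end:+d} bp around TSS",
            f"windows            : {g.n_windows} x {g.window_length} bp (stride {g.stride} bp)",
            f"feature dimension  : {self.promoter.dim} (6 channels x {g.n_windows} windows)",
            f"covariance         : {'diagonal' if self.promoter.diagonal else 'full + ridge'}",
            f"n training         : promoter {self.promoter.n_training}, "
            f"background {self.background.n_training}",
            f"table checksum     : {self.promoter.table_checksum}",
        ]
        if self.model is not None:
            for label, training in (
                ("promoter", self.model.promoter_training),
                ("background", self.model.background_training),
            ):
                X = _extract_training_features(
                    training, self.model.table, self.model.grid, self.model.min_valid
                )
                s = self.score_features(X)["score"]
                lines.append(
                    f"training scores    : {label:<10} mean {s.mean():+8.2f}  sd {s.std(ddof=0):6.2f}"
                )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        payload = {
            "promoter": self.promoter.to_dict(),
            "background": self.background.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(
        cls, path: str | Path, table: StiffnessTable | None = None
    ) -> "PromoterModelResults":
        d = json.loads(Path(path).read_text())
        return cls(
            model=None,
            promoter=ReferenceProfile.from_dict(d["promoter"]),
            background=ReferenceProfile.from_dict(d["background"]),
            table=table,
        )
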