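"""Sequence-dependent DNA deformability profiles.

DNA helical deformability is parameterized at the dinucleotide-step level:
each of the 16 steps (AA..TT) carries a diagonal stiffness (force-constant)
vector over the six helical deformation channels — the rotations twist, tilt
and roll, in kcal/(mol·deg^2), and the translations shift, slide and rise, in
kcal/(mol·Å^2). Off-diagonal (coupled) stiffness terms are deliberately not
modelled: the diagonal constants alone define the physical signal used for
promoter detection.

A sequence is annotated step by step with these vectors and the resulting
six-channel series is averaged over fixed-length windows (500 bp by default),
yielding the smoothed physical profile that downstream classification
consumes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "STEPS",
    "StiffnessTable",
    "PhysicalProfile",
    "WindowedProfile",
    "revcomp",
    "load_stiffness_table",
    "default_stiffness_table",
    "step_series",
    "window_average",
    "write_windowed_bedgraph",
]

#: Canonical channel order, frozen across the whole package and all file headers.
CHANNELS: tuple[str, ...] = ("twist", "tilt", "roll", "shift", "slide", "rise")

#: All 16 dinucleotide steps in lexicographic order.
STEPS: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 0..3 lookup over raw byte values; 255 marks non-ACGT (incl. IUPAC codes)
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (soft-masking survives)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _revcomp_step(step: str) -> str:
    return step.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class StiffnessTable:
    """Diagonal dinucleotide stiffness constants for the six helical channels.

    Parameters
    ----------
    entries
        Mapping from each of the 16 dinucleotide steps to a length-6 vector of
        strictly positive force constants in :data:`CHANNELS` order.
    source_label
        Free-text provenance of the parameter set.
    """

    entries: Mapping[str, np.ndarray]
    source_label: str = ""
    _matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [s for s in STEPS if s not in self.entries]
        if missing:
            raise ValueError(f"missing dinucleotide step(s): {', '.join(missing)}")
        extra = [s for s in self.entries if s not in STEPS]
        if extra:
            raise ValueError(f"unknown dinucleotide step(s): {', '.join(extra)}")
        mat = np.empty((16, 6), dtype=float)
        for i, step in enumerate(STEPS):
            v = np.asarray(self.entries[step], dtype=float)
            if v.shape != (6,):
                raise ValueError(f"step {step}: expected 6 constants, got shape {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"step {step}: non-finite constant")
            if np.any(v <= 0):
                ch = CHANNELS[int(np.argmin(v))]
                raise ValueError(f"step {step}, channel {ch}: non-positive constant")
            mat[i] = v
        # strand symmetry of diagonal stiffness: K(XY) == K(revcomp(XY))
        for i, step in enumerate(STEPS):
            j = STEPS.index(_revcomp_step(step))
            if np.max(np.abs(mat[i] - mat[j])) > 1e-9:
                raise ValueError(
                    f"reverse-complement symmetry violated: {step} vs {_revcomp_step(step)}"
                )
        object.__setattr__(self, "_matrix", mat)

    @property
    def matrix(self) -> np.ndarray:
        """(16, 6) array of constants, rows in :data:`STEPS` order."""
        return self._matrix

    def checksum(self) -> str:
        """Stable hex digest of the numeric content (model/parameter coherence)."""
        h = hashlib.sha256()
        h.update(np.round(self._matrix, 12).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._matrix, index=list(STEPS), columns=list(CHANNELS)).rename_axis(
            "step"
        )


def load_stiffness_table(path: str | Path) -> StiffnessTable:
    """Load a stiffness table from TSV.

    The file has a header row ``step twist tilt roll shift slide rise`` and one
    row per step; ``#`` comments are allowed. A file listing only the 10 unique
    steps is completed to all 16 by reverse-complement symmetry.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "step" not in cols:
        raise ValueError(f"{path}: missing 'step' column")
    absent = [c for c in CHANNELS if c not in cols]
    if absent:
        raise ValueError(f"{path}: missing channel column(s): {', '.join(absent)}")
    entries: dict[str, np.ndarray] = {}
    for row_i, row in df.iterrows():
        step = str(row["step"]).upper()
        if step not in STEPS:
            raise ValueError(f"{path} row {row_i}: unknown step {step!r}")
        v = np.array([row[c] for c in CHANNELS], dtype=float)
        for k, x in enumerate(v):
            if not np.isfinite(x):
                raise ValueError(f"{path} row {row_i} ({step}), column {CHANNELS[k]}: non-finite constant")
            if x <= 0:
                raise ValueError(f"{path} row {row_i} ({step}), column {CHANNELS[k]}: non-positive constant")
        if step in entries and np.max(np.abs(entries[step] - v)) > 1e-9:
            raise ValueError(f"{path}: duplicate step {step} with conflicting values")
        entries[step] = v
    # complete by reverse-complement symmetry; verify explicit pairs agree
    for step in list(entries):
        rc = _revcomp_step(step)
        if rc in entries:
            if np.max(np.abs(entries[rc] - entries[step])) > 1e-9:
                raise ValueError(f"{path}: symmetry violation between {step} and {rc}")
        else:
            entries[rc] = entries[step].copy()
    missing = [s for s in STEPS if s not in entries]
    if missing:
        raise ValueError(f"{path}: missing dinucleotide step(s): {', '.join(missing)}")
    return StiffnessTable(entries=entries, source_label=str(path))


def default_stiffness_table() -> StiffnessTable:
    """The stiffness table shipped with the package.

    The shipped file is a synthetic representative parameter set (see its
    header comments); swap in your preferred MD-derived table via
    :func:`load_stiffness_table` for real analyses.
    """
    here = Path(__file__).parent / "data" / "stiffness_synthetic_default.tsv"
    return load_stiffness_table(here)


@dataclass
class PhysicalProfile:
    """Per-dinucleotide-step six-channel stiffness series along one sequence.

    ``values[i]`` annotates the step spanning bases ``i`` and ``i+1``; ``mask[i]``
    is False when either base is not A/C/G/T (assembly gaps, IUPAC ambiguity),
    in which case the numeric row is meaningless and excluded from averages.
    """

    values: np.ndarray  # (n_steps, 6)
    mask: np.ndarray  # (n_steps,) bool, True = valid
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.values) != len(self.mask):
            raise ValueError("values and mask length mismatch")

    def __len__(self) -> int:
        return len(self.mask)


@dataclass
class WindowedProfile:
    """Window-averaged physical profile.

    A window ``[s, s+w)`` on 0-based half-open bp coordinates owns the steps
    ``s .. s+w-2``; its mean is the unweighted arithmetic mean of the unmasked
    step vectors. Windows whose valid-step fraction falls below ``min_valid``
    are invalid and carry NaN means.
    """

    window_length: int
    stride: int
    starts: np.ndarray  # (n_windows,) window start bp
    means: np.ndarray  # (n_windows, 6), NaN where invalid
    valid_fraction: np.ndarray  # (n_windows,)
    min_valid: float = 0.9
    origin: str = ""

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.window_length // 2

    @property
    def valid(self) -> np.ndarray:
        return self.valid_fraction >= self.min_valid

    def __len__(self) -> int:
        return len(self.starts)


def step_series(seq: str, table: StiffnessTable) -> PhysicalProfile:
    """Annotate a sequence at the dinucleotide level with stiffness vectors.

    Case-insensitive; soft-masked (lowercase) bases are ordinary bases here —
    repeat masking is handled by the candidate filter, not the physics.
    """
    if len(seq) < 2:
        raise ValueError("sequence too short (need at least 2 bases)")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    left, right = codes[:-1], codes[1:]
    mask = (left != 255) & (right != 255)
    idx = np.where(mask, 4 * left.astype(np.intp) + right.astype(np.intp), 0)
    values = table.matrix[idx]
    values[~mask] = 0.0
    return PhysicalProfile(values=values, mask=mask)


def _window_sums(profile: PhysicalProfile, window_length: int):
    """Sums and valid counts over every window start 0..L-w (cumulative-sum trick).

    Returns (sums (m,6), counts (m,)) where m = n_steps - (w-1) + 1 window starts,
    i.e. one entry per start s with the window fully inside the sequence.
    """
    w = window_length
    n_steps = len(profile)
    per = w - 1  # steps owned by a window
    if per > n_steps:
        return np.zeros((0, 6)), np.zeros(0, dtype=int)
    cs = np.concatenate([np.zeros((1, 6)), np.cumsum(profile.values, axis=0)])
    cm = np.concatenate([[0], np.cumsum(profile.mask.astype(np.int64))])
    m = n_steps - per + 1
    sums = cs[per : per + m] - cs[:m]
    counts = cm[per : per + m] - cm[:m]
    return sums, counts


def window_average(
    profile: PhysicalProfile,
    window_length: int = 500,
    stride: int = 50,
    min_valid: float = 0.9,
) -> WindowedProfile:
    """Average the step series linearly over fixed-length windows.

    Windows start at multiples of ``stride`` and must fit entirely within the
    sequence; a window longer than the profile yields an empty result.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sums, counts = _window_sums(profile, window_length)
    starts = np.arange(0, len(sums), stride)
    sums, counts = sums[starts], counts[starts]
    per = window_length - 1
    frac = counts / per
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts[:, None]
    means[(frac < min_valid) | (counts == 0)] = np.nan
    return WindowedProfile(
        window_length=window_length,
        stride=stride,
        starts=starts,
        means=means,
        valid_fraction=frac,
        min_valid=min_valid,
        origin=profile.origin,
    )


def write_windowed_bedgraph(
    wp: WindowedProfile,
    chrom: str,
    out_prefix: str | Path,
    channels: Iterable[str] = CHANNELS,
) -> list[Path]:
    """Export window means as one bedGraph file per channel.

    Each record spans the window ``[start, start+window_length)``; invalid
    windows are omitted. Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    written = []
    for ch in channels:
        k = CHANNELS.index(ch)
        path = out_prefix.parent / f"{out_prefix.name}.{ch}.bedgraph"
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{ch} stiffness"\n')
            for s, mean, ok in zip(wp.starts, wp.means, wp.valid):
                if not ok:
                    continue
                fh.write(f"{chrom}\t{s}\t{s + wp.window_length}\t{mean[k]:.6g}\n")
        written.append(path)
    return written
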