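"""Intragenic promoter motif analysis: A-/B-box extraction from tRNA
alignments, position weight matrices, relative-score scanning and 2D
binned kernel motif-density maps.

The A box and B box are the internal Pol III promoter elements read by
TFIIIC; in a standard tRNA alignment coordinate system they occupy
alignment columns 9-21 and 75-85 (1-based inclusive).  Scanning uses a
log-odds PWM with relative-score thresholding: a window is a hit when
(score - min possible) / (max possible - min possible) >= min_score,
matching the seqPattern "minScore = 90%" convention.  Motif density over
a set of sequences is an unnormalised 2D Gaussian kernel sum (bandwidth
1 bp in both the position and sequence-index directions) on a 1-bp
grid; each sequence's maximum density summarises how concentrated its
hits are relative to the rest of the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PWM",
    "extract_boxes",
    "filter_gap_columns",
    "build_pwm",
    "scan",
    "density_map",
    "A_BOX_COLUMNS",
    "B_BOX_COLUMNS",
]

A_BOX_COLUMNS = (9, 21)   # 1-based inclusive alignment columns
B_BOX_COLUMNS = (75, 85)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def extract_boxes(
    aligned: list[str],
    a_box: tuple[int, int] = A_BOX_COLUMNS,
    b_box: tuple[int, int] = B_BOX_COLUMNS,
) -> tuple[list[str], list[str]]:
    """Slice A-box and B-box columns out of an alignment.

    All sequences must share one alignment coordinate system; gap
    characters are retained as-is.  Columns are 1-based inclusive.
    """
    if not aligned:
        return [], []
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("aligned sequences differ in length")
    needed = max(a_box[1], b_box[1])
    if width < needed:
        raise ValueError(f"alignment has {width} columns; need >= {needed}")
    a = [s[a_box[0] - 1 : a_box[1]].upper() for s in aligned]
    b = [s[b_box[0] - 1 : b_box[1]].upper() for s in aligned]
    return a, b


def filter_gap_columns(strings: list[str], max_gap_frac: float = 0.5) -> list[str]:
    """Drop alignment columns gapped in more than ``max_gap_frac`` of
    sequences, then drop sequences still containing gaps."""
    if not strings:
        return []
    arr = np.array([list(s.upper()) for s in strings])
    gap = np.isin(arr, ["-", "."])
    keep = gap.mean(axis=0) <= max_gap_frac
    arr = arr[:, keep]
    clean = ~np.isin(arr, ["-", "."]).any(axis=1)
    return ["".join(row) for row in arr[clean]]


@dataclass
class PWM:
    """Position probability matrix (4 x W, rows A/C/G/T) with a flat
    background; scores are log2 odds against the background."""

    probs: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A,C,G,T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))


def build_pwm(strings: list[str], pseudocount: float = 0.01) -> PWM:
    """PWM from equal-length ungapped strings:
    p = (count + pseudocount) / (n + 4*pseudocount) per column."""
    if not strings:
        raise ValueError("no input strings")
    w = len(strings[0])
    if any(len(s) != w for s in strings):
        raise ValueError("input strings have unequal lengths")
    counts = np.zeros((4, w))
    for s in strings:
        for j, ch in enumerate(s.upper()):
            if ch not in _BASE_INDEX:
                raise ValueError(f"non-ACGT character {ch!r}; degap the input first")
            counts[_BASE_INDEX[ch], j] += 1
    probs = (counts + pseudocount) / (len(strings) + 4 * pseudocount)
    return PWM(probs=probs, background=np.full(4, 0.25))


def scan(pwm: PWM, sequence: str, min_score: float = 0.90) -> list[int]:
    """All window start positions whose relative log-odds score reaches
    ``min_score``.

    relative = (score - min possible) / (max possible - min possible),
    where the extremes sum the per-column best/worst log-odds.  Windows
    containing non-ACGT characters never match.
    """
    seq = sequence.upper()
    W = pwm.width
    if len(seq) < W:
        raise ValueError("sequence shorter than PWM width")
    lo = pwm.log_odds
    smin = lo.min(axis=0).sum()
    smax = lo.max(axis=0).sum()
    span = smax - smin
    hits = []
    for start in range(len(seq) - W + 1):
        window = seq[start : start + W]
        try:
            score = sum(lo[_BASE_INDEX[ch], j] for j, ch in enumerate(window))
        except KeyError:
            continue
        rel = (score - smin) / span if span > 0 else 1.0
        if rel >= min_score - 1e-12:
            hits.append(start)
    return hits


def _gauss(offsets: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-0.5 * (offsets / bandwidth) ** 2)


def density_map(
    hits_per_sequence: list[list[int]],
    seq_length: int,
    bandwidth: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """2D binned Gaussian kernel density of motif hits on a 1-bp grid.

    The grid is (sequence index) x (position); each hit contributes unit
    mass through a separable Gaussian kernel (sd = ``bandwidth`` grid
    units in both directions), renormalised within the grid so boundary
    truncation does not lose mass.  Returns ``(grid, per_sequence_max)``
    where ``per_sequence_max[i]`` is the maximum grid value on sequence
    i's row.
    """
    n = len(hits_per_sequence)
    grid = np.zeros((n, seq_length))
    if n == 0:
        return grid, np.zeros(0)
    rows = np.arange(n)
    cols = np.arange(seq_length)
    for i, hits in enumerate(hits_per_sequence):
        for h in hits:
            if not 0 <= h < seq_length:
                raise ValueError(f"hit position {h} outside [0, {seq_length})")
            wy = _gauss(rows - i, bandwidth)
            wx = _gauss(cols - h, bandwidth)
            kern = np.outer(wy, wx)
            grid += kern / kern.sum()
    return grid, grid.max(axis=1)
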