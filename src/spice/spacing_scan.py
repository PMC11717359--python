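"""Primary-motif anchoring and secondary-motif spacing scans.

Windows are recentered and reoriented on the best primary-motif match so the
primary always reads 5'->3' at the window center; each secondary motif is then
scanned in the flanks and the single best non-overlapping placement per window
becomes a spacing observation: an orientation quadrant (same/opposite strand x
upstream/downstream) plus an edge-to-edge gap in bp (gap 0 = adjacent).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from ._seq import encode_many, revcomp
from .motif_io import PWM, BackgroundModel, log_odds, max_log_odds
from .peaks_windows import SequenceWindow

log = logging.getLogger(__name__)

__all__ = [
    "QUADRANTS",
    "MotifMatch",
    "SpacingObservation",
    "best_match",
    "default_min_score",
    "recenter_on_primary",
    "filter_primary",
    "primary_footprint",
    "scan_secondary",
]

#: Canonical quadrant order; also the tie-break order in the statistics stage.
QUADRANTS = ("same-down", "same-up", "opp-down", "opp-up")


@dataclass(frozen=True)
class MotifMatch:
    """A scored, stranded motif placement in window coordinates (match start)."""

    motif_id: str
    offset: int
    strand: str  # '+' or '-' relative to the stored window orientation
    score: float  # bits
    width: int


@dataclass(frozen=True)
class SpacingObservation:
    """Best secondary placement for one window, reduced to quadrant + gap."""

    window_id: str
    secondary_id: str
    quadrant: str
    gap: int
    score: float


def default_min_score(pwm: PWM, bg: BackgroundModel, fraction: float = 0.6) -> float:
    """Default match threshold: a fraction of the maximum achievable score."""
    return fraction * max_log_odds(pwm, bg)


def _best_interleaved(S_plus: np.ndarray, S_minus: np.ndarray):
    """Per-row best placement with ties broken by smallest offset, then '+'.

    Returns (scores, offsets, strand_is_minus) arrays. Candidates are
    interleaved (offset 0 '+', offset 0 '-', offset 1 '+', ...) so that
    numpy's first-argmax implements the tie-break exactly.
    """
    n, m = S_plus.shape
    C = np.empty((n, 2 * m))
    C[:, 0::2] = S_plus
    C[:, 1::2] = S_minus
    idx = np.argmax(C, axis=1)
    return C[np.arange(n), idx], idx // 2, (idx % 2).astype(bool)


def best_match(
    window: SequenceWindow,
    pwm: PWM,
    bg: BackgroundModel,
    min_score: float | None = None,
) -> MotifMatch | None:
    """The single highest-scoring placement over all offsets x both strands.

    Returns None when that score falls below ``min_score`` (default: 60% of
    the PWM's maximum achievable log-odds). N bases score 0 bits.
    """
    if len(pwm) > window.width:
        raise ValueError(f"PWM {pwm.id} wider than window {window.window_id}")
    if min_score is None:
        min_score = default_min_score(pwm, bg)
    lom = log_odds(pwm, bg)
    X = encode_many([window.seq])
    from ._seq import scores_both_strands

    S_plus, S_minus = scores_both_strands(X, lom)
    score, offset, minus = _best_interleaved(S_plus, S_minus)
    if score[0] < min_score:
        return None
    return MotifMatch(
        motif_id=pwm.id,
        offset=int(offset[0]),
        strand="-" if minus[0] else "+",
        score=float(score[0]),
        width=len(pwm),
    )


def recenter_on_primary(
    window: SequenceWindow, match: MotifMatch, out_width: int
) -> SequenceWindow | None:
    """Recenter (and reorient) a window on a primary-motif match.

    The new window has ``out_width`` bp with the primary footprint starting at
    offset (out_width - match.width) // 2, i.e. centered with rounding toward
    the lower offset. Minus-strand matches reverse-complement the sequence so
    the primary always reads 5'->3' on the stored strand. Returns None when
    the recentered span exceeds the available sequence.
    """
    W = window.width
    w = match.width
    if out_width < w:
        raise ValueError("out_width smaller than the primary footprint")
    if match.strand == "-":
        seq = revcomp(window.seq)
        offset = W - match.offset - w
        flipped = True
    else:
        seq = window.seq
        offset = match.offset
        flipped = False
    start = offset - (out_width - w) // 2
    if start < 0 or start + out_width > W:
        return None
    sub = seq[start : start + out_width]
    if flipped:
        # genomic start of the kept slice on the reference strand
        win_start = window.win_start + (W - (start + out_width))
    else:
        win_start = window.win_start + start
    return SequenceWindow(
        window_id=window.window_id,
        chrom=window.chrom,
        win_start=win_start,
        seq=sub,
        oriented_minus=window.oriented_minus ^ flipped,
        source_peak=window.source_peak,
    )


def filter_primary(
    windows: Sequence[SequenceWindow],
    primary: PWM,
    bg: BackgroundModel,
    min_score: float | None = None,
    out_width: int | None = None,
) -> tuple[list[SequenceWindow], int]:
    """Keep windows with a primary match >= min_score, recentered on the match.

    Returns (kept windows in input order, number dropped). Dropped counts both
    windows without a qualifying match and windows whose recentered span runs
    off the available sequence.
    """
    if min_score is None:
        min_score = default_min_score(primary, bg)
    if not windows:
        return [], 0
    if out_width is None:
        out_width = windows[0].width
    lom = log_odds(primary, bg)
    widths = {w.width for w in windows}
    kept: list[SequenceWindow] = []
    n_dropped = 0

    def process(batch: list[SequenceWindow]):
        nonlocal n_dropped
        from ._seq import scores_both_strands

        X = encode_many([w.seq for w in batch])
        S_plus, S_minus = scores_both_strands(X, lom)
        scores, offsets, minus = _best_interleaved(S_plus, S_minus)
        for i, win in enumerate(batch):
            if scores[i] < min_score:
                n_dropped += 1
                continue
            match = MotifMatch(
                motif_id=primary.id,
                offset=int(offsets[i]),
                strand="-" if minus[i] else "+",
                score=float(scores[i]),
                width=len(primary),
            )
            rec = recenter_on_primary(win, match, out_width)
            if rec is None:
                n_dropped += 1
            else:
                kept.append(rec)

    if len(widths) == 1:
        process(list(windows))
    else:
        for win in windows:
            process([win])
    if n_dropped:
        log.info("filter_primary: dropped %d of %d windows", n_dropped, len(windows))
    return kept, n_dropped


def primary_footprint(window_width: int, primary_width: int) -> tuple[int, int]:
    """Half-open [start, end) of the centered primary footprint."""
    p0 = (window_width - primary_width) // 2
    return p0, p0 + primary_width


def scan_secondary(
    windows: Sequence[SequenceWindow],
    secondary: PWM,
    bg: BackgroundModel,
    primary_width: int,
    min_score: float = 0.0,
    max_gap: int = 150,
) -> list[SpacingObservation]:
    """Best non-overlapping secondary placement per primary-centered window.

    Candidate placements must not overlap the primary footprint and must lie
    within ``max_gap`` bp edge-to-edge of it; among candidates the single
    best-scoring placement (both strands) wins, with ties broken by smallest
    offset then '+' strand. Windows whose best candidate scores below
    ``min_score`` (default 0 bits) contribute nothing; at most one observation
    is emitted per window.
    """
    if not windows:
        return []
    W = windows[0].width
    if any(w.width != W for w in windows):
        raise ValueError("recentered windows must share one width")
    ws = len(secondary)
    p0, p1 = primary_footprint(W, primary_width)
    m = W - ws + 1
    offsets = np.arange(m)
    up = offsets + ws <= p0
    down = offsets >= p1
    gap = np.where(up, p0 - (offsets + ws), np.where(down, offsets - p1, -1))
    allowed = (up | down) & (gap >= 0) & (gap <= max_gap)
    if not allowed.any():
        raise ValueError(
            f"secondary {secondary.id} (width {ws}) does not fit in the flanks "
            f"of {W} bp windows with a {primary_width} bp primary"
        )
    lom = log_odds(secondary, bg)
    from ._seq import scores_both_strands

    X = encode_many([w.seq for w in windows])
    S_plus, S_minus = scores_both_strands(X, lom)
    neg = -np.inf
    S_plus = np.where(allowed, S_plus, neg)
    S_minus = np.where(allowed, S_minus, neg)
    scores, offs, minus = _best_interleaved(S_plus, S_minus)

    obs: list[SpacingObservation] = []
    for i, win in enumerate(windows):
        if not np.isfinite(scores[i]) or scores[i] < min_score:
            continue
        o = int(offs[i])
        side = "down" if down[o] else "up"
        strand_cls = "opp" if minus[i] else "same"
        obs.append(
            SpacingObservation(
                window_id=win.window_id,
                secondary_id=secondary.id,
                quadrant=f"{strand_cls}-{side}",
                gap=int(gap[o]),
                score=float(scores[i]),
            )
        )
    return obs
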