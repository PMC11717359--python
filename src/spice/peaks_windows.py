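"""Peak files, summit-centered sequence windows, and peak-set overlap.

All interval arithmetic is 0-based half-open, matching narrowPeak/BED
natively; the overlap of [x, y) and [y, z) is empty.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import encode
from .motif_io import BackgroundModel

log = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "SequenceWindow",
    "OverlapSummary",
    "PeakParseError",
    "read_narrowpeak",
    "write_narrowpeak",
    "select_top_peaks",
    "extract_window",
    "estimate_background",
    "peak_overlap",
    "read_windows_fasta",
    "write_windows_fasta",
]


class PeakParseError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak interval with its summit offset relative to ``start``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    neglog10p: float = 0.0
    neglog10q: float = -1.0
    summit_offset: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if not 0 <= self.summit_offset < self.end - self.start:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit offset "
                f"{self.summit_offset} outside interval"
            )

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


@dataclass
class SequenceWindow:
    """A fixed-width sequence window, optionally reoriented to the minus strand.

    ``seq`` is stored uppercase over {A,C,G,T,N}. ``oriented_minus`` is True
    when ``seq`` is the reverse complement of the reference strand.
    """

    window_id: str
    chrom: str
    win_start: int
    seq: str
    oriented_minus: bool = False
    source_peak: Peak | None = field(default=None, repr=False)

    def __post_init__(self):
        self.seq = self.seq.upper()

    @property
    def width(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_a_overlapping_b: int

    @property
    def fraction_a(self) -> float:
        return self.n_a_overlapping_b / self.n_a if self.n_a else 0.0


# ---------------------------------------------------------------------------
# narrowPeak / BED I/O


def read_narrowpeak(path) -> list[Peak]:
    """Read narrowPeak (BED6+4) or plain BED; returns peaks in file order.

    When the 10th column (summit) is -1 or absent, the summit falls back to
    the interval midpoint floor((end - start) / 2).
    """
    peaks: list[Peak] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split()
        if len(f) < 3:
            raise PeakParseError(f"line {ln}: fewer than 3 columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise PeakParseError(f"line {ln}: non-integer coordinates") from None
        if start >= end:
            raise PeakParseError(f"line {ln}: start {start} >= end {end}")
        summit = -1
        if len(f) >= 10:
            try:
                summit = int(f[9])
            except ValueError:
                raise PeakParseError(f"line {ln}: non-integer summit column") from None
        if summit < 0 or summit >= end - start:
            summit = (end - start) // 2
        peaks.append(
            Peak(
                chrom=f[0],
                start=start,
                end=end,
                name=f[3] if len(f) > 3 else ".",
                score=float(f[4]) if len(f) > 4 else 0.0,
                strand=f[5] if len(f) > 5 else ".",
                signal=float(f[6]) if len(f) > 6 else 0.0,
                neglog10p=float(f[7]) if len(f) > 7 else 0.0,
                neglog10q=float(f[8]) if len(f) > 8 else -1.0,
                summit_offset=summit,
            )
        )
    return peaks


def write_narrowpeak(path, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}"
                f"\t{p.signal:g}\t{p.neglog10p:g}\t{p.neglog10q:g}\t{p.summit_offset}\n"
            )


def select_top_peaks(peaks: Sequence[Peak], n: int) -> list[Peak]:
    """The n peaks with largest -log10(p), descending; ties broken by
    (chrom, start) ascending. Returns all peaks when fewer than n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(peaks, key=lambda p: (-p.neglog10p, p.chrom, p.start))
    return ranked[:n]


# ---------------------------------------------------------------------------
# Window extraction


def _chrom_seq(genome, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Mapping):
        return genome[chrom][start:end]
    return str(genome[chrom][start:end])


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def _chrom_names(genome) -> list[str]:
    return list(genome.keys())


def extract_window(
    genome,
    chrom: str,
    center: int,
    width: int,
    window_id: str | None = None,
    source_peak: Peak | None = None,
) -> SequenceWindow | None:
    """Extract an uppercased window spanning [center - width/2, center + width/2).

    ``genome`` is a pyfaidx.Fasta or any mapping of chromosome name to string.
    Returns None (with a logged warning) when the span exceeds chromosome
    bounds; raises KeyError listing available names for unknown chromosomes.
    """
    if width < 50 or width % 2:
        raise ValueError("width must be even and >= 50")
    try:
        clen = _chrom_len(genome, chrom)
    except KeyError:
        raise KeyError(
            f"unknown chromosome {chrom!r}; available: {sorted(_chrom_names(genome))}"
        ) from None
    start = center - width // 2
    end = start + width
    if start < 0 or end > clen:
        log.warning(
            "window %s:%d-%d exceeds chromosome bounds (len %d); skipped",
            chrom, start, end, clen,
        )
        return None
    seq = _chrom_seq(genome, chrom, start, end).upper()
    return SequenceWindow(
        window_id=window_id or f"{chrom}:{start}-{end}",
        chrom=chrom,
        win_start=start,
        seq=seq,
        source_peak=source_peak,
    )


def estimate_background(
    windows: Sequence[SequenceWindow], floor: float = 1e-3
) -> BackgroundModel:
    """Strand-pooled mononucleotide frequencies (so A=T and C=G), ignoring N.

    Frequencies are floored at ``floor`` and renormalized so downstream
    log-odds stay finite even for degenerate inputs.
    """
    if not windows:
        raise ValueError("need at least one window")
    counts = np.zeros(5, dtype=np.int64)
    for w in windows:
        counts += np.bincount(encode(w.seq), minlength=5)
    counts = counts[:4]
    if counts.sum() == 0:
        raise ValueError("all-N input: cannot estimate background")
    pooled = (counts + counts[::-1]) / 2.0  # A<->T, C<->G strand pooling
    freqs = pooled / pooled.sum()
    freqs = np.maximum(freqs, floor)
    freqs = freqs / freqs.sum()
    return BackgroundModel(freqs)


# ---------------------------------------------------------------------------
# Peak overlap


def peak_overlap(a: Sequence[Peak], b: Sequence[Peak]) -> OverlapSummary:
    """Count peaks in ``a`` sharing >= 1 bp with any peak in ``b``.

    Each ``a`` peak is counted once regardless of how many ``b`` peaks it
    hits; intervals are half-open so touching intervals do not overlap.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in b:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:  # touching ([x,y) vs [y,z)) does not merge or overlap
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        starts.append(cur_s)
        ends.append(cur_e)
        merged[chrom] = (starts, ends)

    hits = 0
    for p in a:
        if p.chrom not in merged:
            continue
        starts, ends = merged[p.chrom]
        i = bisect_right(starts, p.end - 1) - 1  # last merged iv starting before p.end
        if i >= 0 and ends[i] > p.start:
            hits += 1
    return OverlapSummary(n_a=len(a), n_b=len(b), n_a_overlapping_b=hits)


# ---------------------------------------------------------------------------
# Window set persistence (plain FASTA with coordinate headers)


def write_windows_fasta(path, windows: Sequence[SequenceWindow]) -> None:
    with open(path, "w") as fh:
        for w in windows:
            strand = "-" if w.oriented_minus else "+"
            fh.write(f">{w.window_id} {w.chrom}:{w.win_start}:{strand}\n{w.seq}\n")


def read_windows_fasta(path) -> list[SequenceWindow]:
    windows: list[SequenceWindow] = []
    name = meta = None
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        chrom, start, strand = (meta.split(":") + ["0", "+"])[:3] if meta else ("?", "0", "+")
        windows.append(
            SequenceWindow(
                window_id=name,
                chrom=chrom,
                win_start=int(start),
                seq="".join(chunks),
                oriented_minus=strand == "-",
            )
        )

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith(">"):
            flush()
            toks = line[1:].split(None, 1)
            name = toks[0]
            meta = toks[1] if len(toks) > 1 else None
            chunks = []
        elif line:
            chunks.append(line)
    flush()
    return windows
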