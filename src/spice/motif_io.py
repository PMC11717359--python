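"""Position weight matrices and background models: parsing, construction, I/O.

Reads and writes the MEME minimal motif format and HOCOMOCO-style plain count
matrices. The alphabet order is fixed to (A, C, G, T); serialized files state
it in their header. A :class:`PWM` is the unit of both primary and secondary
motifs throughout the package.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._seq import BASES

log = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "BackgroundModel",
    "MotifParseError",
    "parse_meme_motifs",
    "write_meme_motifs",
    "parse_hocomoco_counts",
    "counts_to_pwm",
    "consensus_to_pwm",
    "log_odds",
    "max_log_odds",
    "revcomp_pwm",
]


class MotifParseError(ValueError):
    """Raised on malformed motif files; carries the offending line number."""


@dataclass(frozen=True)
class BackgroundModel:
    """Mononucleotide background frequencies over (A, C, G, T)."""

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=np.float64)
        object.__setattr__(self, "freqs", f)
        if f.shape != (4,):
            raise ValueError("background must be a 4-vector over (A,C,G,T)")
        if not np.all(f > 0):
            raise ValueError("background frequencies must all be > 0")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {f.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))


@dataclass(frozen=True)
class PWM:
    """A position probability matrix with identity metadata.

    ``probs`` has shape (L, 4) over (A, C, G, T); every column (row of the
    array) sums to 1 within 1e-6 and L >= 4. ``cluster`` is an optional family
    tag (e.g. "ETS") used to group redundant motifs; ``nsites`` is the source
    site count when known.
    """

    id: str
    probs: np.ndarray
    tf_name: str = ""
    cluster: str | None = None
    nsites: int | None = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: probs must be (L, 4), got {p.shape}")
        if p.shape[0] < 4:
            raise ValueError(f"PWM {self.id}: length {p.shape[0]} < 4")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError(f"PWM {self.id}: entries outside [0, 1]")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"PWM {self.id}: column {bad} sums to {sums[bad]:.8f}, not 1"
            )
        if not self.tf_name:
            object.__setattr__(self, "tf_name", self.id)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Per-column argmax bases (ties resolved toward A<C<G<T)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self, bg: BackgroundModel | None = None) -> np.ndarray:
        """Per-column relative-entropy IC in bits."""
        bg = bg or BackgroundModel.uniform()
        p = np.clip(self.probs, 1e-12, None)
        return (p * np.log2(p / bg.freqs)).sum(axis=1)


def counts_to_pwm(
    counts: np.ndarray,
    pseudocount: float = 0.1,
    id: str = "motif",
    tf_name: str = "",
    cluster: str | None = None,
) -> PWM:
    """Convert an L x 4 non-negative count matrix to a PWM.

    probs[i, b] = (counts[i, b] + pseudocount) / (rowsum_i + 4 * pseudocount).
    """
    c = np.asarray(counts, dtype=np.float64)
    if c.ndim != 2 or c.shape[1] != 4:
        raise ValueError(f"counts must be (L, 4), got {c.shape}")
    if np.any(c < 0):
        raise ValueError("negative count in matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rowsums = c.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError("every position must have at least one positive count")
    probs = (c + pseudocount) / (rowsums + 4 * pseudocount)[:, None]
    # renormalize exactly: floating division can be off in the last ulp
    probs /= probs.sum(axis=1, keepdims=True)
    nsites = int(round(rowsums.max()))
    return PWM(id=id, probs=probs, tf_name=tf_name, cluster=cluster, nsites=nsites)


def consensus_to_pwm(
    consensus: str,
    id: str = "consensus",
    match_prob: float = 0.85,
    tf_name: str = "",
    cluster: str | None = None,
) -> PWM:
    """Build a PWM from a consensus string; N columns are uniform.

    The consensus base gets ``match_prob``; the rest is split evenly.
    """
    consensus = consensus.upper()
    L = len(consensus)
    probs = np.full((L, 4), 0.25)
    off = (1.0 - match_prob) / 3.0
    for i, b in enumerate(consensus):
        if b == "N":
            continue
        if b not in BASES:
            raise ValueError(f"consensus base {b!r} not in {BASES}/N")
        probs[i] = off
        probs[i, BASES.index(b)] = match_prob
    return PWM(id=id, probs=probs, tf_name=tf_name or id, cluster=cluster)


def log_odds(pwm: PWM, bg: BackgroundModel) -> np.ndarray:
    """(L, 4) log2-odds score matrix in bits: log2(probs / bg).

    Raises if any probability is exactly zero; apply a pseudocount first
    (see :func:`counts_to_pwm`).
    """
    if np.any(pwm.probs <= 0):
        raise ValueError(
            f"PWM {pwm.id} contains zero probabilities; apply counts_to_pwm "
            "with a positive pseudocount before scoring"
        )
    return np.log2(pwm.probs / bg.freqs)


def max_log_odds(pwm: PWM, bg: BackgroundModel) -> float:
    """Maximum achievable placement score in bits (sum of per-column maxima)."""
    return float(log_odds(pwm, bg).max(axis=1).sum())


def revcomp_pwm(pwm: PWM) -> PWM:
    """Reverse-complement: position i -> L-1-i with A<->T, C<->G swapped."""
    return replace(pwm, probs=pwm.probs[::-1, ::-1].copy())


# ---------------------------------------------------------------------------
# MEME minimal format

_NUM_RE = re.compile(r"^[\s]*[-+0-9.eE]")


def _is_numeric_row(line: str) -> bool:
    s = line.strip()
    if not s:
        return False
    try:
        float(s.split()[0])
        return True
    except ValueError:
        return False


def _finish_motif(motif_id, alt, rows, nsites, start_line) -> PWM:
    if len(rows) < 4:
        raise MotifParseError(
            f"motif {motif_id} starting at line {start_line}: only "
            f"{len(rows)} matrix rows (need >= 4)"
        )
    probs = np.array(rows, dtype=np.float64)
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        log.warning(
            "motif %s: %d columns deviate from sum 1 by > 1e-3; renormalizing",
            motif_id,
            int(np.sum(np.abs(sums - 1.0) > 1e-3)),
        )
    probs = probs / sums[:, None]
    return PWM(id=motif_id, probs=probs, tf_name=alt or motif_id, nsites=nsites)


def parse_meme_motifs(path) -> tuple[list[PWM], BackgroundModel | None]:
    """Parse a MEME minimal motif file.

    Returns (motifs in file order, background model from the optional
    "Background letter frequencies" section, or None). Motif ids are preserved
    verbatim; a second word on the MOTIF line becomes ``tf_name``. Columns off
    from sum 1 by more than 1e-3 are renormalized with a logged warning;
    matrix rows without exactly 4 numeric fields raise
    :class:`MotifParseError` naming the line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    motifs: list[PWM] = []
    background: BackgroundModel | None = None

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        stripped = line.strip()
        if stripped.startswith("Background letter frequencies"):
            # pairs may span several lines: "A 0.25 C 0.25 G 0.25 T 0.25"
            freqs = {}
            i += 1
            while i < n and len(freqs) < 4:
                toks = lines[i].split()
                if not toks or toks[0].upper() == "MOTIF":
                    break
                for b, v in zip(toks[::2], toks[1::2]):
                    if b.upper() in BASES:
                        freqs[b.upper()] = float(v)
                i += 1
            if len(freqs) == 4:
                background = BackgroundModel(np.array([freqs[b] for b in BASES]))
            continue
        if stripped.upper().startswith("MOTIF"):
            toks = stripped.split()
            if len(toks) < 2:
                raise MotifParseError(f"line {i + 1}: MOTIF line without identifier")
            motif_id = toks[1]
            alt = toks[2] if len(toks) > 2 else ""
            start_line = i + 1
            nsites = None
            expect_w = None
            i += 1
            # optional URL / letter-probability header lines
            while i < n and not _is_numeric_row(lines[i]):
                hdr = lines[i].strip()
                if hdr.startswith("letter-probability matrix"):
                    m = re.search(r"w=\s*(\d+)", hdr)
                    if m:
                        expect_w = int(m.group(1))
                    m = re.search(r"nsites=\s*(\d+)", hdr)
                    if m:
                        nsites = int(m.group(1))
                elif hdr.upper().startswith("MOTIF"):
                    break
                i += 1
            rows = []
            while i < n and _is_numeric_row(lines[i]):
                fields = lines[i].split()
                try:
                    vals = [float(x) for x in fields]
                except ValueError:
                    raise MotifParseError(
                        f"line {i + 1}: non-numeric field in matrix row"
                    ) from None
                if len(vals) != 4:
                    raise MotifParseError(
                        f"line {i + 1}: matrix row has {len(vals)} fields, expected 4"
                    )
                rows.append(vals)
                i += 1
            if expect_w is not None and len(rows) != expect_w:
                raise MotifParseError(
                    f"motif {motif_id} at line {start_line}: header says w="
                    f"{expect_w} but {len(rows)} rows found"
                )
            motifs.append(_finish_motif(motif_id, alt, rows, nsites, start_line))
            continue
        i += 1
    return motifs, background


def write_meme_motifs(path, pwms, background: BackgroundModel | None = None) -> None:
    """Serialize motifs in MEME minimal format (alphabet ACGT, 10 decimals)."""
    bg = background or BackgroundModel.uniform()
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    out.append("Background letter frequencies")
    out.append(" ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg.freqs)))
    out.append("")
    for p in pwms:
        name = f"MOTIF {p.id}"
        if p.tf_name and p.tf_name != p.id:
            name += f" {p.tf_name}"
        out.append(name)
        hdr = f"letter-probability matrix: alength= 4 w= {len(p)}"
        if p.nsites is not None:
            hdr += f" nsites= {p.nsites}"
        hdr += " E= 0"
        out.append(hdr)
        for row in p.probs:
            out.append(" " + " ".join(f"{v:.10f}" for v in row))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# HOCOMOCO-style plain count matrices


def parse_hocomoco_counts(path, pseudocount: float = 0.1) -> list[PWM]:
    """Read HOCOMOCO-style records: '>ID' header then L rows of 4 counts.

    A second whitespace-separated word on the header line, if present, is
    stored as the cluster/family tag. ``tf_name`` is the part of the id before
    the first underscore (HOCOMOCO convention, e.g. JUN_HUMAN.H11MO.0.A ->
    JUN).
    """
    path = Path(path)
    pwms: list[PWM] = []
    header: str | None = None
    cluster: str | None = None
    rows: list[list[float]] = []
    header_line = 0

    def flush(line_no):
        nonlocal header, cluster, rows
        if header is None:
            return
        if len(rows) < 4:
            raise MotifParseError(
                f"record {header} at line {header_line}: {len(rows)} rows (need >= 4)"
            )
        tf = header.split("_")[0]
        pwms.append(
            counts_to_pwm(
                np.array(rows), pseudocount, id=header, tf_name=tf, cluster=cluster
            )
        )
        header, cluster, rows = None, None, []

    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(ln)
            toks = line[1:].split()
            header = toks[0]
            cluster = toks[1] if len(toks) > 1 else None
            header_line = ln
        else:
            fields = line.split()
            if len(fields) != 4:
                raise MotifParseError(
                    f"line {ln}: count row has {len(fields)} fields, expected 4"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError:
                raise MotifParseError(f"line {ln}: non-numeric count") from None
    flush(None)
    return pwms
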