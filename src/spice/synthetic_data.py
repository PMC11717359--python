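"""Self-contained synthetic fixtures: genome, peaks, motifs, and ground truth.

The generator emulates the data the pipeline consumes: peak-centered sequence
windows with a planted primary site near the summit and, in a controllable
fraction of windows, a planted secondary site at an exact edge-to-edge gap and
orientation quadrant, over a Markov-0 background of configurable GC content.
Planted sites are mutated per base so PWM scoring, not string matching, is
required to recover them, and whole windows are flipped to the minus strand at
random so recentering must reorient. Every fixture is byte-reproducible from
(spec, rng_seed).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import BASES, decode, revcomp
from .motif_io import PWM, BackgroundModel, consensus_to_pwm, write_meme_motifs
from .peaks_windows import Peak, SequenceWindow, write_narrowpeak

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "sample_site",
    "simulate_windows",
    "make_fixture",
    "null_fixture",
    "aice_demo_spec",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-composite-element fixture.

    Defaults are the AICE-style recovery conditions used throughout the test
    suite: an AP1-like 7-mer primary in every window, an IRF-half-site-like
    secondary planted same-strand downstream at a 4 bp gap in half the
    windows, 10% per-base mutation on planted sites, and a 10 bp sd between
    the peak summit and the primary-site center.
    """

    n_peaks: int = 400
    window_width: int = 500
    gc: float = 0.41
    primary: "str | PWM" = "TGACTCA"
    secondary: "str | PWM | None" = "TGAAAC"
    gap: "int | tuple[int, ...]" = 4
    quadrant: str = "same-down"
    planted_fraction: float = 0.5
    primary_fraction: float = 1.0
    summit_jitter_sd: float = 10.0
    mutation_rate: float = 0.1
    rng_seed: int = 1337
    pad: int = 300
    primary_strand: str = "both"  # 'both' (random flips) or '+'

    def gaps(self) -> tuple[int, ...]:
        return (self.gap,) if isinstance(self.gap, int) else tuple(self.gap)

    def primary_pwm(self) -> PWM:
        if isinstance(self.primary, PWM):
            return self.primary
        return consensus_to_pwm(self.primary, id="primary", match_prob=0.85)

    def secondary_pwm(self) -> PWM | None:
        if self.secondary is None:
            return None
        if isinstance(self.secondary, PWM):
            return self.secondary
        return consensus_to_pwm(self.secondary, id="secondary", match_prob=0.85)

    def validate(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.quadrant not in ("same-down", "same-up", "opp-down", "opp-up"):
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        wp = len(self._primary_len())
        ws = len(self._secondary_len() or "")
        slack = self._jitter_limit()
        p0 = (self.window_width - wp) // 2
        if self.secondary is not None:
            for g in self.gaps():
                if p0 - slack - g - ws < 0 or p0 + slack + wp + g + ws > self.window_width:
                    raise ValueError(
                        f"planted geometry (gap {g}, jitter +/-{slack}) does not "
                        f"fit inside a {self.window_width} bp window"
                    )
        elif p0 - slack < 0 or p0 + slack + wp > self.window_width:
            raise ValueError("primary site does not fit inside the window")

    def _primary_len(self) -> str:
        return (
            self.primary.consensus if isinstance(self.primary, PWM) else self.primary
        )

    def _secondary_len(self) -> str | None:
        if self.secondary is None:
            return None
        return (
            self.secondary.consensus
            if isinstance(self.secondary, PWM)
            else self.secondary
        )

    def _jitter_limit(self) -> int:
        return int(np.ceil(3 * self.summit_jitter_sd))


@dataclass
class GroundTruth:
    """Per-window truth records plus the spec and emitted file paths."""

    spec: FixtureSpec
    records: list[dict]
    paths: dict = field(default_factory=dict)

    @property
    def n_planted_secondary(self) -> int:
        return sum(1 for r in self.records if r["secondary_start"] is not None)


def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one site, each position independently from its column distribution."""
    idx = [rng.choice(4, p=col / col.sum()) for col in pwm.probs]
    return "".join(BASES[i] for i in idx)


def _plant_site(consensus_or_pwm, rate: float, rng: np.random.Generator) -> str:
    """Realize a planted site: PWM -> column sampling; consensus -> per-base
    mutation at ``rate`` to a uniformly chosen different base (N -> uniform)."""
    if isinstance(consensus_or_pwm, PWM):
        return sample_site(consensus_or_pwm, rng)
    out = []
    for b in consensus_or_pwm.upper():
        if b == "N":
            out.append(BASES[rng.integers(4)])
        elif rng.random() < rate:
            out.append(rng.choice([x for x in BASES if x != b]))
        else:
            out.append(b)
    return "".join(out)


def simulate_windows(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[list[SequenceWindow], list[dict]]:
    """Generate summit-centered windows with planted sites, plus truth records.

    Windows are built in the primary-plus frame (primary site at the window
    center offset by a clamped Gaussian jitter, secondary at the spec's gap
    and quadrant relative to it) and then, when ``primary_strand`` is
    ``'both'``, flipped whole to the reverse strand with probability 1/2.
    Truth coordinates are window-frame (post-flip); ``quadrant`` is recorded
    in the primary frame and is invariant under the whole-window flip.
    """
    spec.validate()
    rng = rng or np.random.default_rng(spec.rng_seed)
    W = spec.window_width
    bg_probs = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    X = rng.choice(4, size=(spec.n_peaks, W), p=bg_probs)
    jlim = spec._jitter_limit()

    windows: list[SequenceWindow] = []
    records: list[dict] = []
    for i in range(spec.n_peaks):
        seq = list(decode(X[i]))
        has_primary = rng.random() < spec.primary_fraction
        plant_secondary = (
            has_primary
            and spec.secondary is not None
            and rng.random() < spec.planted_fraction
        )
        rec = {
            "window_id": f"w{i:05d}",
            "primary_start": None,
            "primary_strand": None,
            "primary_site": None,
            "secondary_start": None,
            "secondary_strand": None,
            "secondary_site": None,
            "gap": None,
            "quadrant": None,
            "flipped": False,
        }
        if has_primary:
            psite = _plant_site(spec.primary, spec.mutation_rate, rng)
            wp = len(psite)
            jitter = int(np.clip(round(rng.normal(0, spec.summit_jitter_sd)), -jlim, jlim))
            p0 = (W - wp) // 2 + jitter
            seq[p0 : p0 + wp] = psite
            rec.update(primary_start=p0, primary_strand="+", primary_site=psite)
            if plant_secondary:
                ssite = _plant_site(spec.secondary, spec.mutation_rate, rng)
                ws = len(ssite)
                gap = int(rng.choice(spec.gaps()))
                strand_cls, side = spec.quadrant.split("-")
                s0 = p0 + wp + gap if side == "down" else p0 - gap - ws
                placed = ssite if strand_cls == "same" else revcomp(ssite)
                seq[s0 : s0 + ws] = placed
                rec.update(
                    secondary_start=s0,
                    secondary_strand="+" if strand_cls == "same" else "-",
                    secondary_site=placed,
                    gap=gap,
                    quadrant=spec.quadrant,
                )
        s = "".join(seq)
        if spec.primary_strand == "both" and rng.random() < 0.5:
            s = revcomp(s)
            rec["flipped"] = True
            for which in ("primary", "secondary"):
                if rec[f"{which}_start"] is not None:
                    L = len(rec[f"{which}_site"])
                    rec[f"{which}_start"] = W - rec[f"{which}_start"] - L
                    rec[f"{which}_site"] = revcomp(rec[f"{which}_site"])
                    rec[f"{which}_strand"] = "-" if rec[f"{which}_strand"] == "+" else "+"
        windows.append(
            SequenceWindow(window_id=rec["window_id"], chrom="chrSim", win_start=0, seq=s)
        )
        records.append(rec)
    return windows, records


def _decoy_motifs(spec: FixtureSpec, rng: np.random.Generator, n_decoys: int) -> list[PWM]:
    """Column-shuffled variants of the secondary, used as database padding."""
    sec = spec.secondary_pwm()
    if sec is None or n_decoys <= 0:
        return []
    decoys = []
    for d in range(n_decoys):
        perm = rng.permutation(len(sec))
        while decode(sec.probs[perm].argmax(axis=1)) == sec.consensus:
            perm = rng.permutation(len(sec))
        decoys.append(PWM(id=f"decoy{d + 1}", probs=sec.probs[perm].copy()))
    return decoys


def make_fixture(spec: FixtureSpec, out_dir, n_decoys: int = 3) -> GroundTruth:
    """Write a complete fixture: genome FASTA, narrowPeak, motif files, truth.

    The synthetic chromosome concatenates the windows separated by ``pad`` bp
    of background; each peak spans its window with the summit at the window
    center (the planted primary sits at the summit +/- the jitter). The motif
    database file holds the secondary motif plus ``n_decoys`` column-shuffled
    decoys. Raises before writing anything when the geometry cannot fit.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    windows, records = simulate_windows(spec, rng)
    W = spec.window_width
    bg_probs = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )

    chunks: list[str] = []
    peaks: list[Peak] = []
    pos = 0
    for i, win in enumerate(windows):
        pad_seq = decode(rng.choice(4, size=spec.pad, p=bg_probs))
        chunks.append(pad_seq)
        pos += spec.pad
        win_start = pos
        chunks.append(win.seq)
        pos += W
        records[i]["chrom_start"] = win_start
        nlp = float(np.round(rng.uniform(10, 100), 3))
        peaks.append(
            Peak(
                chrom="chrSim",
                start=win_start,
                end=win_start + W,
                name=win.window_id,
                score=min(1000.0, round(10 * nlp)),
                strand=".",
                signal=nlp / 2,
                neglog10p=nlp,
                neglog10q=nlp / 2,
                summit_offset=W // 2,
            )
        )
    chunks.append(decode(rng.choice(4, size=spec.pad, p=bg_probs)))
    chrom = "".join(chunks)

    genome_path = out_dir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(">chrSim\n")
        for i in range(0, len(chrom), 80):
            fh.write(chrom[i : i + 80] + "\n")
    peaks_path = out_dir / "peaks.narrowPeak"
    write_narrowpeak(peaks_path, peaks)

    bg = BackgroundModel(bg_probs)
    primary_path = out_dir / "primary.meme"
    write_meme_motifs(primary_path, [spec.primary_pwm()], bg)
    db_path = out_dir / "motif_db.meme"
    sec = spec.secondary_pwm()
    db = ([sec] if sec is not None else []) + _decoy_motifs(spec, rng, n_decoys)
    write_meme_motifs(db_path, db, bg)

    spec_echo = dataclasses.asdict(
        dataclasses.replace(
            spec,
            primary=spec._primary_len(),
            secondary=spec._secondary_len(),
        )
    )
    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps({"spec": spec_echo, "records": records}, indent=1) + "\n"
    )
    paths = {
        "genome": str(genome_path),
        "peaks": str(peaks_path),
        "primary_motif": str(primary_path),
        "motif_db": str(db_path),
        "truth": str(truth_path),
    }
    return GroundTruth(spec=spec, records=records, paths=paths)


def null_fixture(spec: FixtureSpec, out_dir, n_decoys: int = 3) -> GroundTruth:
    """A fixture with no planted secondary sites (type-I-error calibration)."""
    return make_fixture(
        dataclasses.replace(spec, planted_fraction=0.0), out_dir, n_decoys
    )


def aice_demo_spec(**overrides) -> FixtureSpec:
    """The canonical demo: AP1-like primary with the secondary planted at
    0 or 4 bp (split evenly), mirroring the classic AICE dual spacing."""
    kw = dict(gap=(0, 4), planted_fraction=0.6)
    kw.update(overrides)
    return FixtureSpec(**kw)
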