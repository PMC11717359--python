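"""End-to-end orchestration: peaks -> windows -> primary -> spacing -> matrix.

`run_pipeline` drives the whole analysis from a :class:`PipelineConfig`
(loadable from YAML) and writes TSV/JSON reports, figures, and a
:class:`RunManifest` with provenance metadata and per-stage conservation
counts. `spacing_analysis` is the library-level core shared by the pipeline,
the test-suite and the acceptance script.
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .denovo_motif import discover_primary
from .motif_io import (
    PWM,
    BackgroundModel,
    max_log_odds,
    parse_meme_motifs,
    write_meme_motifs,
)
from .peaks_windows import (
    SequenceWindow,
    estimate_background,
    extract_window,
    read_narrowpeak,
    select_top_peaks,
    write_windows_fasta,
)
from .spacing_scan import filter_primary, scan_secondary
from .spacing_stats import (
    SpacingHistogram,
    SpacingTestResult,
    build_histogram,
    build_matrix,
    evalue_across_db,
    filter_and_rank,
    group_redundant,
    significant_bins,
    test_secondary,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "ConfigError", "run_pipeline", "spacing_analysis"]

#: Defaults the source protocol states explicitly vs. choices this package made.
DEFAULT_PROVENANCE = {
    "window_width": "stated",
    "top_n": "stated",
    "alpha": "stated",
    "e_threshold": "stated",
    "max_gap": "unstated-in-paper",
    "primary_min_score_frac": "unstated-in-paper",
    "secondary_min_score": "unstated-in-paper",
    "widths": "unstated-in-paper",
    "n_seeds": "unstated-in-paper",
    "rng_seed": "unstated-in-paper",
    "recenter_slack": "unstated-in-paper",
    "max_n_frac": "unstated-in-paper",
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths, parameters and flags for one library's analysis."""

    genome: str
    peaks: str
    motif_db: str
    out_dir: str
    primary_motif: str | None = None  # skip de novo discovery when given
    library_id: str | None = None
    window_width: int = 500
    top_n: int = 1000
    max_gap: int = 150
    alpha: float = 0.01
    e_threshold: float = 1e-10
    primary_min_score_frac: float = 0.6
    secondary_min_score: float = 0.0
    widths: tuple[int, ...] = (8, 10, 12)
    n_seeds: int = 5
    rng_seed: int = 1337
    recenter_slack: int = 100
    max_n_frac: float = 0.5
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "widths" in raw:
            raw["widths"] = tuple(raw["widths"])
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("genome", "peaks", "motif_db"):
            p = getattr(self, attr)
            if not p or not Path(p).exists():
                raise ConfigError(f"{attr} path does not exist: {p!r}")
        if self.primary_motif is not None and not Path(self.primary_motif).exists():
            raise ConfigError(f"primary_motif path does not exist: {self.primary_motif!r}")
        if self.window_width < 50 or self.window_width % 2:
            raise ConfigError("window_width must be even and >= 50")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")


@dataclass
class RunManifest:
    """Provenance and conservation counts for one pipeline run."""

    config: dict
    version: str
    input_checksums: dict
    counts: dict
    outputs: dict
    primary_id: str
    started: str
    finished: str = ""
    defaults_provenance: dict = field(default_factory=lambda: dict(DEFAULT_PROVENANCE))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def spacing_analysis(
    kept_windows: list[SequenceWindow],
    primary: PWM,
    secondaries: list[PWM],
    bg: BackgroundModel,
    max_gap: int = 150,
    alpha: float = 0.01,
    secondary_min_score: float = 0.0,
    primary_id: str = "library",
) -> dict:
    """Scan every secondary motif over primary-centered windows and test spacing.

    Returns a dict with per-secondary observations, histograms, E-valued test
    results, the significant ranked subset, and grouped predictions. Secondary
    motifs too wide for the flanks are skipped with a logged warning.
    """
    observations = {}
    histograms: dict[str, SpacingHistogram] = {}
    results: list[SpacingTestResult] = []
    n_skipped = 0
    for sec in secondaries:
        try:
            obs = scan_secondary(
                kept_windows,
                sec,
                bg,
                primary_width=len(primary),
                min_score=secondary_min_score,
                max_gap=max_gap,
            )
        except ValueError as exc:
            log.warning("skipping secondary %s: %s", sec.id, exc)
            n_skipped += 1
            continue
        hist = build_histogram(obs, max_gap)
        hist.secondary_id = sec.id  # empty observation lists lose the id
        observations[sec.id] = obs
        histograms[sec.id] = hist
        results.append(test_secondary(hist, primary_id=primary_id))
    results = evalue_across_db(results, n_motifs_in_db=len(secondaries))
    significant = filter_and_rank(results, alpha)
    predictions = group_redundant(significant, {p.id: p for p in secondaries})
    return {
        "observations": observations,
        "histograms": histograms,
        "results": results,
        "significant": significant,
        "predictions": predictions,
        "n_secondary_skipped": n_skipped,
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis for one peak library.

    Stages: load and rank peaks, extract summit-centered windows (with
    recentering slack), discover or load the primary motif, keep and recenter
    windows on their best primary match, scan every database motif in the
    flanks, compute binomial spacing statistics and E-values, group redundant
    motifs, and emit reports, figures and the interaction matrix.
    """
    import pyfaidx

    config.validate()
    started = datetime.datetime.now().isoformat(timespec="seconds")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library_id = config.library_id or Path(config.peaks).stem

    peaks = read_narrowpeak(config.peaks)
    top = select_top_peaks(peaks, config.top_n)

    genome = pyfaidx.Fasta(str(config.genome))
    extract_width = config.window_width + 2 * config.recenter_slack
    windows: list[SequenceWindow] = []
    n_oob = 0
    n_nheavy = 0
    for i, p in enumerate(top):
        win = extract_window(
            genome, p.chrom, p.summit, extract_width,
            window_id=p.name if p.name != "." else f"peak{i:05d}",
            source_peak=p,
        )
        if win is None:
            n_oob += 1
            continue
        if win.seq.count("N") > config.max_n_frac * win.width:
            n_nheavy += 1
            continue
        windows.append(win)
    if not windows:
        raise RuntimeError("pipeline stage 'windows': no usable windows extracted")
    bg = estimate_background(windows)
    log.info("windows: %d extracted (%d out-of-bounds, %d N-heavy)",
             len(windows), n_oob, n_nheavy)

    if config.primary_motif:
        motifs, _ = parse_meme_motifs(config.primary_motif)
        if not motifs:
            raise RuntimeError(f"no motif found in {config.primary_motif}")
        primary = motifs[0]
        log.info("primary: loaded %s (w=%d)", primary.id, len(primary))
    else:
        model = discover_primary(
            windows, widths=config.widths, n_seeds=config.n_seeds,
            rng_seed=config.rng_seed, bg=bg,
        )
        primary = model.pwm
        log.info(
            "primary: discovered %s consensus %s (score %.1f)",
            primary.id, primary.consensus, model.selection_score,
        )
    write_meme_motifs(out / "primary_used.meme", [primary], bg)

    min_score = config.primary_min_score_frac * max_log_odds(primary, bg)
    kept, n_dropped = filter_primary(
        windows, primary, bg, min_score=min_score, out_width=config.window_width
    )
    if not kept:
        raise RuntimeError("pipeline stage 'filter_primary': no windows kept")
    write_windows_fasta(out / "windows_centered.fa", kept)

    db, _db_bg = parse_meme_motifs(config.motif_db)
    if not db:
        raise RuntimeError(f"no motifs in database {config.motif_db}")
    analysis = spacing_analysis(
        kept, primary, db, bg,
        max_gap=config.max_gap, alpha=config.alpha,
        secondary_min_score=config.secondary_min_score, primary_id=library_id,
    )

    # ----- reports -------------------------------------------------------
    obs_rows = [
        {"window_id": o.window_id, "secondary_id": o.secondary_id,
         "quadrant": o.quadrant, "gap": o.gap, "score": round(o.score, 4)}
        for obs in analysis["observations"].values() for o in obs
    ]
    pd.DataFrame(
        obs_rows, columns=["window_id", "secondary_id", "quadrant", "gap", "score"]
    ).to_csv(out / "observations.tsv", sep="\t", index=False)

    report_rows = []
    for r in analysis["significant"]:
        for b in significant_bins(
            analysis["histograms"][r.secondary_id], config.alpha, primary_id=library_id
        ):
            report_rows.append(
                {"primary_id": library_id, "secondary_id": b.secondary_id,
                 "quadrant": b.best_quadrant, "gap": b.best_gap, "k": b.k,
                 "n": b.n, "p_raw": b.p_raw, "p_adj": b.p_adj,
                 "e_value": b.p_adj * len(db)}
            )
    pd.DataFrame(
        report_rows,
        columns=["primary_id", "secondary_id", "quadrant", "gap", "k", "n",
                 "p_raw", "p_adj", "e_value"],
    ).to_csv(out / "spacing_report.tsv", sep="\t", index=False)

    pred_rows = [
        {"rank": p.rank, "cluster": p.cluster_name,
         "representative": p.representative.secondary_id,
         "best_quadrant": p.representative.best_quadrant,
         "best_gap": p.representative.best_gap,
         "k": p.representative.k, "n": p.representative.n,
         "p_raw": p.representative.p_raw, "p_adj": p.representative.p_adj,
         "e_value": p.representative.e_value,
         "members": ",".join(p.member_ids)}
        for p in analysis["predictions"]
    ]
    pd.DataFrame(
        pred_rows,
        columns=["rank", "cluster", "representative", "best_quadrant", "best_gap",
                 "k", "n", "p_raw", "p_adj", "e_value", "members"],
    ).to_csv(out / "predictions.tsv", sep="\t", index=False)

    matrix_full = build_matrix({library_id: analysis["results"]}, e_threshold=None)
    matrix_sig = matrix_full.filtered(config.e_threshold)
    matrix_full.to_neglog10_frame().to_csv(out / "matrix_neglog10e.tsv", sep="\t")
    (out / "matrix_significant.json").write_text(
        json.dumps(
            {"e_threshold": config.e_threshold,
             "primary_ids": matrix_sig.primary_ids,
             "secondary_ids": matrix_sig.secondary_ids,
             "cells": matrix_sig.to_records()},
            indent=1,
        ) + "\n"
    )

    outputs = {
        "primary_used": str(out / "primary_used.meme"),
        "windows_centered": str(out / "windows_centered.fa"),
        "observations": str(out / "observations.tsv"),
        "spacing_report": str(out / "spacing_report.tsv"),
        "predictions": str(out / "predictions.tsv"),
        "matrix_neglog10e": str(out / "matrix_neglog10e.tsv"),
        "matrix_significant": str(out / "matrix_significant.json"),
    }

    if config.make_figures:
        from .plots import render_heatmap, render_spacing_bars

        grid = render_heatmap(matrix_full, out / "heatmap.png")
        if grid is not None:
            outputs["heatmap"] = str(out / "heatmap.png")
        if analysis["predictions"]:
            rep = analysis["predictions"][0].representative
            render_spacing_bars(
                analysis["histograms"][rep.secondary_id], rep,
                out / "spacing_top.png", alpha=config.alpha,
            )
            outputs["spacing_top"] = str(out / "spacing_top.png")

    n_obs_total = sum(len(v) for v in analysis["observations"].values())
    counts = {
        "peaks_in": len(peaks),
        "peaks_top": len(top),
        "windows_oob": n_oob,
        "windows_nheavy": n_nheavy,
        "windows_extracted": len(windows),
        "windows_kept_primary": len(kept),
        "windows_dropped_primary": n_dropped,
        "secondary_motifs": len(db),
        "secondary_skipped": analysis["n_secondary_skipped"],
        "observations": n_obs_total,
        "significant_pairs": len(analysis["significant"]),
        "predicted_clusters": len(analysis["predictions"]),
    }
    manifest = RunManifest(
        config={**dataclasses.asdict(config)},
        version=__version__,
        input_checksums={
            "genome": _md5(config.genome),
            "peaks": _md5(config.peaks),
            "motif_db": _md5(config.motif_db),
        },
        counts=counts,
        outputs=outputs,
        primary_id=primary.id,
        started=started,
        finished=datetime.datetime.now().isoformat(timespec="seconds"),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
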