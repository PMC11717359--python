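"""Spacing enrichment statistics, motif clustering, and the interaction matrix.

Spacing observations are binned at 1 bp resolution into 4 x (max_gap + 1)
(quadrant, gap) bins. Under the null every observation falls into any bin with
equal probability 1/n_bins, so the count k in the most occupied bin is tested
with an upper-tail binomial p-value P(X >= k), X ~ Binomial(n, 1/n_bins),
Bonferroni-adjusted for the number of bins. Scaling the adjusted p-value by
the number of motifs in the secondary database gives the per-pair E-value
feeding the primary x secondary interaction matrix (default significance
filter: E < 1e-10).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, pearsonr

from .motif_io import PWM
from .spacing_scan import QUADRANTS, SpacingObservation

__all__ = [
    "SpacingHistogram",
    "SpacingTestResult",
    "CompositePrediction",
    "InteractionMatrix",
    "build_histogram",
    "binom_bin_pvalue",
    "test_secondary",
    "significant_bins",
    "evalue_across_db",
    "filter_and_rank",
    "pwm_similarity",
    "group_redundant",
    "build_matrix",
]


@dataclass
class SpacingHistogram:
    """Exact (quadrant, gap) counts for one secondary motif."""

    secondary_id: str
    counts: dict[tuple[str, int], int]
    max_gap: int
    n: int

    def count(self, quadrant: str, gap: int) -> int:
        return self.counts.get((quadrant, gap), 0)

    @property
    def n_bins(self) -> int:
        return 4 * (self.max_gap + 1)


@dataclass(frozen=True)
class SpacingTestResult:
    """Binomial spacing test for one (primary, secondary) pair's best bin."""

    primary_id: str
    secondary_id: str
    best_quadrant: str
    best_gap: int
    k: int
    n: int
    n_bins: int
    p_raw: float
    p_adj: float
    e_value: float = float("nan")
    no_data: bool = False


@dataclass(frozen=True)
class CompositePrediction:
    """A cluster of redundant secondary motifs with its best spacing result."""

    primary_id: str
    cluster_name: str
    member_ids: tuple[str, ...]
    representative: SpacingTestResult
    rank: int


@dataclass
class InteractionMatrix:
    """Sparse primary-library x secondary-motif table of E-values.

    When built with a significance threshold, stored cells all pass it and
    absence means "not significant"; built unfiltered it holds every tested
    pair for heatmap export.
    """

    primary_ids: list[str]
    secondary_ids: list[str]
    cells: dict[tuple[str, str], float] = field(default_factory=dict)

    def filtered(self, e_threshold: float) -> "InteractionMatrix":
        kept = {k: v for k, v in self.cells.items() if v < e_threshold}
        prim = [p for p in self.primary_ids if any(k[0] == p for k in kept)]
        sec = [s for s in self.secondary_ids if any(k[1] == s for k in kept)]
        return InteractionMatrix(prim, sec, kept)

    def to_neglog10_frame(self, cap: float | None = None) -> pd.DataFrame:
        """Dense -log10(E) grid: secondary motifs as rows, primaries as columns
        (the heatmap convention: primaries on x, secondaries on y). Missing
        cells are 0."""
        grid = pd.DataFrame(
            0.0, index=list(self.secondary_ids), columns=list(self.primary_ids)
        )
        for (p, s), e in self.cells.items():
            v = 300.0 if e <= 0 else -np.log10(e)
            if cap is not None:
                v = min(v, cap)
            grid.loc[s, p] = max(v, 0.0)
        return grid

    def to_records(self) -> list[dict]:
        return [
            {"primary_id": p, "secondary_id": s, "e_value": e}
            for (p, s), e in sorted(self.cells.items())
        ]


# ---------------------------------------------------------------------------


def build_histogram(
    observations: Sequence[SpacingObservation], max_gap: int
) -> SpacingHistogram:
    """Count observations per (quadrant, gap) bin; n = number of observations."""
    sec_ids = {o.secondary_id for o in observations}
    if len(sec_ids) > 1:
        raise ValueError(f"mixed secondary ids in one histogram: {sorted(sec_ids)}")
    counts: dict[tuple[str, int], int] = {}
    for o in observations:
        if o.gap > max_gap or o.gap < 0:
            raise ValueError(f"gap {o.gap} outside [0, {max_gap}]")
        key = (o.quadrant, o.gap)
        counts[key] = counts.get(key, 0) + 1
    return SpacingHistogram(
        secondary_id=sec_ids.pop() if sec_ids else "",
        counts=counts,
        max_gap=max_gap,
        n=len(observations),
    )


def binom_bin_pvalue(k: int, n: int, n_bins: int) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, 1/n_bins).

    Exactly 1.0 at k = 0; numerically stable in the far tail via the
    regularized incomplete beta survival function.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, 1.0 / n_bins))


def test_secondary(hist: SpacingHistogram, primary_id: str = "primary") -> SpacingTestResult:
    """Binomial test of the most occupied (quadrant, gap) bin.

    Ties go to the smaller gap, then to quadrant order same-down, same-up,
    opp-down, opp-up. p_adj is the Bonferroni adjustment min(1, p_raw *
    n_bins). An empty histogram yields p_adj = 1 flagged ``no_data``.
    """
    n_bins = hist.n_bins
    if hist.n == 0:
        return SpacingTestResult(
            primary_id, hist.secondary_id, QUADRANTS[0], 0, 0, 0, n_bins,
            1.0, 1.0, no_data=True,
        )
    qrank = {q: i for i, q in enumerate(QUADRANTS)}
    best_key = min(
        hist.counts.items(), key=lambda kv: (-kv[1], kv[0][1], qrank[kv[0][0]])
    )[0]
    k = hist.counts[best_key]
    p_raw = binom_bin_pvalue(k, hist.n, n_bins)
    return SpacingTestResult(
        primary_id=primary_id,
        secondary_id=hist.secondary_id,
        best_quadrant=best_key[0],
        best_gap=best_key[1],
        k=k,
        n=hist.n,
        n_bins=n_bins,
        p_raw=p_raw,
        p_adj=min(1.0, p_raw * n_bins),
    )


def significant_bins(
    hist: SpacingHistogram, alpha: float = 0.01, primary_id: str = "primary"
) -> list[SpacingTestResult]:
    """Every (quadrant, gap) bin individually passing p_adj < alpha.

    Preserves secondary optima (e.g. a dual 0 / 4 bp preference) that the
    single best-bin result collapses.
    """
    out = []
    qrank = {q: i for i, q in enumerate(QUADRANTS)}
    for (quadrant, gap), k in sorted(
        hist.counts.items(), key=lambda kv: (kv[0][1], qrank[kv[0][0]])
    ):
        p_raw = binom_bin_pvalue(k, hist.n, hist.n_bins)
        p_adj = min(1.0, p_raw * hist.n_bins)
        if p_adj < alpha:
            out.append(
                SpacingTestResult(
                    primary_id, hist.secondary_id, quadrant, gap, k, hist.n,
                    hist.n_bins, p_raw, p_adj,
                )
            )
    out.sort(key=lambda r: r.p_adj)
    return out


def evalue_across_db(
    results: Sequence[SpacingTestResult], n_motifs_in_db: int
) -> list[SpacingTestResult]:
    """Set e_value = p_adj x database size (uncapped, preserving the order)."""
    n_tested = len({r.secondary_id for r in results})
    if n_motifs_in_db < n_tested:
        raise ValueError(
            f"database size {n_motifs_in_db} smaller than {n_tested} tested motifs"
        )
    return [replace(r, e_value=r.p_adj * n_motifs_in_db) for r in results]


def filter_and_rank(
    results: Sequence[SpacingTestResult], alpha: float = 0.01
) -> list[SpacingTestResult]:
    """Results with p_adj < alpha, ascending p_adj (ties by secondary id)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    kept = [r for r in results if r.p_adj < alpha]
    kept.sort(key=lambda r: (r.p_adj, r.secondary_id))
    return kept


# ---------------------------------------------------------------------------
# Redundant-motif grouping


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 5) -> float:
    """Maximum ungapped column-correlation alignment over both orientations.

    For each offset with >= ``min_overlap`` overlapping columns, the mean
    Pearson correlation of the aligned 4-vectors; the maximum over all
    offsets and both orientations of ``b``. Zero-variance columns (uniform)
    contribute correlation 0.
    """

    def col_corr(u: np.ndarray, v: np.ndarray) -> float:
        if np.ptp(u) < 1e-12 or np.ptp(v) < 1e-12:
            return 0.0
        return float(pearsonr(u, v)[0])

    def best_over_offsets(pa: np.ndarray, pb: np.ndarray) -> float:
        la, lb = pa.shape[0], pb.shape[0]
        best = -np.inf
        for shift in range(-(lb - min_overlap), la - min_overlap + 1):
            lo_a = max(0, shift)
            hi_a = min(la, lb + shift)
            if hi_a - lo_a < min_overlap:
                continue
            cols = [
                col_corr(pa[i], pb[i - shift]) for i in range(lo_a, hi_a)
            ]
            best = max(best, float(np.mean(cols)))
        return best

    rc = b.probs[::-1, ::-1]
    return max(best_over_offsets(a.probs, b.probs), best_over_offsets(a.probs, rc))


def group_redundant(
    results: Sequence[SpacingTestResult],
    pwms: Mapping[str, PWM],
    sim_threshold: float = 0.8,
    min_overlap: int = 5,
) -> list[CompositePrediction]:
    """Single-linkage clustering of significant secondary motifs.

    Pairs with :func:`pwm_similarity` >= ``sim_threshold`` are linked; when
    both motifs carry cluster tags the tags override similarity (equal tags
    link, different tags never link). Each cluster is represented by its
    member with the smallest p_adj, and clusters are ranked by that value.
    """
    results = list(results)
    for r in results:
        if r.secondary_id not in pwms:
            raise KeyError(f"no PWM for secondary id {r.secondary_id}")
    ids = sorted({r.secondary_id for r in results})
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            ta, tb = pwms[x].cluster, pwms[y].cluster
            if ta is not None and tb is not None:
                if ta == tb:
                    union(x, y)
                continue
            if pwm_similarity(pwms[x], pwms[y], min_overlap) >= sim_threshold:
                union(x, y)

    best_by_id = {}
    for r in results:
        cur = best_by_id.get(r.secondary_id)
        if cur is None or r.p_adj < cur.p_adj:
            best_by_id[r.secondary_id] = r
    clusters: dict[str, list[str]] = {}
    for sid in ids:
        clusters.setdefault(find(sid), []).append(sid)

    preds = []
    for members in clusters.values():
        rep = min((best_by_id[m] for m in members), key=lambda r: (r.p_adj, r.secondary_id))
        tag = pwms[rep.secondary_id].cluster
        preds.append(
            (
                rep.p_adj,
                CompositePrediction(
                    primary_id=rep.primary_id,
                    cluster_name=tag or pwms[rep.secondary_id].tf_name,
                    member_ids=tuple(members),
                    representative=rep,
                    rank=0,
                ),
            )
        )
    preds.sort(key=lambda t: (t[0], t[1].cluster_name))
    return [replace(p, rank=i + 1) for i, (_, p) in enumerate(preds)]


# ---------------------------------------------------------------------------


def build_matrix(
    per_library: Mapping[str, Sequence[SpacingTestResult]],
    e_threshold: float | None = 1e-10,
) -> InteractionMatrix:
    """Assemble the primary x secondary E-value matrix across libraries.

    Cells are retained iff e_value < e_threshold; pass ``e_threshold=None``
    to keep every tested pair (the unfiltered export used for heatmaps).
    """
    primary_ids: list[str] = []
    secondary_ids: list[str] = []
    cells: dict[tuple[str, str], float] = {}
    for pid, results in per_library.items():
        if pid not in primary_ids:
            primary_ids.append(pid)
        for r in results:
            if np.isnan(r.e_value):
                raise ValueError(
                    f"result {pid}/{r.secondary_id} has no e_value; run "
                    "evalue_across_db first"
                )
            if e_threshold is not None and not r.e_value < e_threshold:
                continue
            if r.secondary_id not in secondary_ids:
                secondary_ids.append(r.secondary_id)
            cells[(pid, r.secondary_id)] = r.e_value
    return InteractionMatrix(primary_ids, secondary_ids, cells)
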