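"""De novo primary-motif discovery: k-mer seeding plus ZOOPS EM.

The ZOOPS model (zero or one occurrence per sequence) treats each window as
either pure background or background with a single motif site at one offset on
one strand. Seeds come from z-score-ranked k-mers; each seed initializes EM,
and the best model across seeds and widths is selected by a BIC-style
penalized log-likelihood ratio against the background-only model.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from ._seq import BASES, encode_many
from .motif_io import PWM, BackgroundModel
from .peaks_windows import SequenceWindow, estimate_background

log = logging.getLogger(__name__)

__all__ = [
    "SeedCandidate",
    "MotifModel",
    "NoPrimaryMotifError",
    "enumerate_seeds",
    "seed_to_pwm",
    "em_zoops",
    "discover_primary",
]


class NoPrimaryMotifError(RuntimeError):
    """No candidate model beat the background-only model."""


@dataclass(frozen=True)
class SeedCandidate:
    """An enriched k-mer: observed count of the k-mer/reverse-complement pair
    on the forward strands, with its Poisson z-score against the background
    expectation."""

    kmer: str
    zscore: float
    count: int


@dataclass
class MotifModel:
    """A fitted ZOOPS motif model.

    ``loglik`` is the data log-likelihood at the fitted parameters;
    ``objective_history`` tracks the Dirichlet-penalized objective EM
    maximizes (non-decreasing by construction). ``loglik_bg`` is the
    background-only (site prior = 0) log-likelihood of the same data, and
    ``selection_score`` the penalized LLR used for model selection.
    """

    pwm: PWM
    site_prob: float
    loglik: float
    n_sites_expected: float
    width: int
    loglik_bg: float = math.nan
    selection_score: float = math.nan
    seed: str = ""
    n_iter: int = 0
    objective_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Seeding


def _kmer_codes(X: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all k-mers on the forward strand; N-containing -> -1."""
    n, W = X.shape
    m = W - k + 1
    codes = np.zeros((n, m), dtype=np.int64)
    valid = np.ones((n, m), dtype=bool)
    for j in range(k):
        col = X[:, j : j + m].astype(np.int64)
        valid &= col < 4
        codes = codes * 4 + np.where(col < 4, col, 0)
    return codes[valid]


def _rc_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = rc * 4 + (3 - (code & 3))
        code >>= 2
    return rc


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def enumerate_seeds(
    windows: Sequence[SequenceWindow],
    k: int,
    n_seeds: int = 10,
    bg: BackgroundModel | None = None,
) -> list[SeedCandidate]:
    """Rank k-mers by z-score of observed vs Markov-0 expected count.

    A k-mer and its reverse complement are collapsed into one candidate whose
    count is the total forward-strand occurrences of either member; the
    reported ``kmer`` is the member seen more often on the forward strand.
    """
    if not 4 <= k <= 12:
        raise ValueError("k must be in [4, 12]")
    widths = [w.width for w in windows]
    if min(widths) < k:
        raise ValueError(f"k={k} larger than smallest window width {min(widths)}")
    bg = bg or estimate_background(windows)
    X = encode_many([w.seq for w in windows]) if len(set(widths)) == 1 else None
    if X is not None:
        observed = _kmer_codes(X, k)
    else:
        observed = np.concatenate(
            [_kmer_codes(encode_many([w.seq]), k) for w in windows]
        )
    total_positions = observed.size
    uniq, cnt = np.unique(observed, return_counts=True)
    counts = dict(zip(uniq.tolist(), cnt.tolist()))

    logp = np.log(bg.freqs)

    def kmer_logp(code: int) -> float:
        s = 0.0
        for _ in range(k):
            s += logp[code & 3]
            code >>= 2
        return s

    seen: set[int] = set()
    cands: list[SeedCandidate] = []
    for code in counts:
        rc = _rc_code(code, k)
        key = min(code, rc)
        if key in seen:
            continue
        seen.add(key)
        c_fwd = counts.get(code, 0)
        c_rc = counts.get(rc, 0) if rc != code else 0
        pair_count = c_fwd + c_rc
        p = math.exp(kmer_logp(code))
        expected = total_positions * (p if rc == code else p + math.exp(kmer_logp(rc)))
        z = (pair_count - expected) / math.sqrt(expected) if expected > 0 else 0.0
        rep_code = code if (c_fwd, -code) >= (c_rc, -rc) else rc
        cands.append(SeedCandidate(_code_to_kmer(rep_code, k), z, pair_count))
    cands.sort(key=lambda c: (-c.zscore, c.kmer))
    return cands[:n_seeds]


def seed_to_pwm(
    seed: str | SeedCandidate,
    width: int | None = None,
    match_prob: float = 0.7,
    bg: BackgroundModel | None = None,
) -> PWM:
    """Soft-seed PWM: 0.7 on the seed base, 0.1 elsewhere; padded to ``width``
    with background columns (centered, extra column on the right)."""
    kmer = seed.kmer if isinstance(seed, SeedCandidate) else seed
    bg = bg or BackgroundModel.uniform()
    k = len(kmer)
    width = width or k
    if width < k:
        raise ValueError("target width smaller than seed")
    off = (1.0 - match_prob) / 3.0
    core = np.full((k, 4), off)
    for i, b in enumerate(kmer.upper()):
        core[i, BASES.index(b)] = match_prob
    left = (width - k) // 2
    probs = np.vstack(
        [np.tile(bg.freqs, (left, 1)), core, np.tile(bg.freqs, (width - k - left, 1))]
    )
    return PWM(id=f"seed_{kmer}", probs=probs)


# ---------------------------------------------------------------------------
# ZOOPS EM


def _as_seed_probs(seed, width: int, bg: BackgroundModel) -> tuple[np.ndarray, str]:
    if isinstance(seed, PWM):
        probs = np.clip(seed.probs, 1e-3, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
        if probs.shape[0] != width:
            pwm = PWM(id=seed.id, probs=probs)
            pad = seed_to_pwm(pwm.consensus, width=width, bg=bg)
            return pad.probs.copy(), seed.id
        return probs, seed.id
    pwm = seed_to_pwm(seed, width=width, bg=bg)
    kmer = seed.kmer if isinstance(seed, SeedCandidate) else seed
    return pwm.probs.copy(), kmer


def em_zoops(
    windows: Sequence[SequenceWindow],
    seed,
    bg: BackgroundModel | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    pseudocount: float = 0.01,
    rng_seed: int = 1337,
    width: int | None = None,
    motif_id: str = "denovo",
) -> MotifModel:
    """Fit a ZOOPS motif model by EM from a seed (k-mer, SeedCandidate or PWM).

    E-step: per-sequence posterior over {no site} plus every offset x strand;
    both strands are handled by augmenting the offset space with
    reverse-complement placements, keeping at most one site per sequence.
    M-step: Dirichlet-smoothed PWM update (``pseudocount`` per cell) and
    site-prior MLE. Iterates until the penalized objective improves by less
    than ``tol`` or ``max_iter`` is reached; the penalized objective is
    non-decreasing within 1e-9 at every step.
    """
    seqs = [w.seq for w in windows]
    if not seqs:
        raise ValueError("no windows")
    X = encode_many(seqs)  # raises on unequal widths
    n, W = X.shape
    bg = bg or estimate_background(windows)
    if width is None:
        width = len(seed) if isinstance(seed, (str, PWM)) else len(seed.kmer)
    if width > W:
        raise ValueError(f"seed width {width} exceeds window width {W}")
    theta, seed_name = _as_seed_probs(seed, width, bg)
    w = width
    m = W - w + 1

    log_bg = np.log(bg.freqs)
    # per-sequence background log-likelihood (N positions contribute 0)
    lb5 = np.append(log_bg, 0.0)
    logp_bg_seq = lb5[X].sum(axis=1)

    # one-hot (n, W, 4); N rows are all-zero
    Xoh = np.zeros((n, W, 4), dtype=np.float64)
    for b in range(4):
        Xoh[:, :, b] = X == b
    Xoh_c = Xoh[:, :, ::-1]  # complemented bases

    lam = 0.5
    prev_obj = -np.inf
    history: list[float] = []
    loglik = -np.inf
    n_iter = 0

    for it in range(1, max_iter + 1):
        llr = np.log(theta) - log_bg  # (w, 4), natural log
        l5 = np.zeros((w, 5))
        l5[:, :4] = llr
        l5_rc = np.zeros((w, 5))
        l5_rc[:, :4] = llr[::-1, ::-1]

        S_plus = np.zeros((n, m))
        S_minus = np.zeros((n, m))
        for j in range(w):
            block = X[:, j : j + m]
            S_plus += l5[j][block]
            S_minus += l5_rc[j][block]

        log_site_prior = math.log(lam) - math.log(2 * m)
        logw = np.concatenate(
            [
                np.full((n, 1), math.log1p(-lam)),
                log_site_prior + S_plus,
                log_site_prior + S_minus,
            ],
            axis=1,
        )
        logZ = logsumexp(logw, axis=1)
        loglik = float(np.sum(logZ + logp_bg_seq))
        obj = loglik + pseudocount * float(np.sum(np.log(theta)))
        if not math.isfinite(obj):
            raise RuntimeError(f"non-finite log-likelihood at EM iteration {it}")
        if obj < prev_obj - 1e-9:
            raise RuntimeError(
                f"penalized objective decreased at iteration {it}: "
                f"{prev_obj} -> {obj}"
            )
        history.append(obj)
        n_iter = it
        if obj - prev_obj < tol and it > 1:
            break
        prev_obj = obj

        post = np.exp(logw - logZ[:, None])
        post_plus = post[:, 1 : m + 1]
        post_minus = post[:, m + 1 :]
        site_post = 1.0 - post[:, 0]

        C = np.zeros((w, 4))
        for j in range(w):
            C[j] += np.einsum("io,iob->b", post_plus, Xoh[:, j : j + m, :])
            C[j] += np.einsum(
                "io,iob->b", post_minus, Xoh_c[:, w - 1 - j : w - 1 - j + m, :]
            )
        theta = C + pseudocount
        theta /= theta.sum(axis=1, keepdims=True)
        lam = float(np.clip(site_post.mean(), 1e-6, 1 - 1e-6))

    pwm = PWM(id=motif_id, probs=theta / theta.sum(axis=1, keepdims=True))
    return MotifModel(
        pwm=pwm,
        site_prob=lam,
        loglik=loglik,
        n_sites_expected=lam * n,
        width=w,
        loglik_bg=float(np.sum(logp_bg_seq)),
        seed=seed_name,
        n_iter=n_iter,
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# Width/seed sweep and model selection


def discover_primary(
    windows: Sequence[SequenceWindow],
    widths: Iterable[int] = (8, 10, 12),
    n_seeds: int = 5,
    rng_seed: int = 1337,
    bg: BackgroundModel | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> MotifModel:
    """Discover the primary motif: EM from each top seed at each width.

    The winning model maximizes ``(loglik - loglik_bg) - width * log(total
    scanned positions)``, a BIC-style penalized log-likelihood ratio that
    plays the role a motif E-value ordering plays in discovery tools. Raises
    :class:`NoPrimaryMotifError` when nothing beats background (score <= 0);
    the pipeline stops there by design.
    """
    widths = sorted(set(widths))
    if not widths or widths[0] < 6 or widths[-1] > 20:
        raise ValueError("widths must be within [6, 20]")
    bg = bg or estimate_background(windows)
    W = min(w.width for w in windows)
    best: MotifModel | None = None
    for width in widths:
        if width > W:
            log.warning("skipping width %d > window width %d", width, W)
            continue
        k = min(width, 12)
        seeds = enumerate_seeds(windows, k=k, n_seeds=n_seeds, bg=bg)
        total_scanned = sum(2 * (w.width - width + 1) for w in windows)
        penalty = width * math.log(total_scanned)
        for seed in seeds:
            model = em_zoops(
                windows,
                seed,
                bg=bg,
                width=width,
                max_iter=max_iter,
                tol=tol,
                rng_seed=rng_seed,
                motif_id=f"denovo_w{width}",
            )
            model.selection_score = (model.loglik - model.loglik_bg) - penalty
            if best is None or model.selection_score > best.selection_score:
                best = model
    if best is None or best.selection_score <= 0:
        raise NoPrimaryMotifError("no primary motif found")
    return best
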