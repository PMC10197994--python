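"""EM-based motif discovery over protein sequences (MEME-style, ANR model).

Motifs are found sequentially: a two-component mixture model (motif vs
0-order background) is fitted by EM over all sequence windows of a given
width, sites are called wherever the posterior odds of the motif component
exceed a threshold (so a sequence may carry any number of repetitions),
and called sites are masked before the next motif is sought.  Width is
selected over a fixed grid by a BIC-like penalised log-likelihood-ratio
criterion, and the fitted motif is phase-refined by trying small column
shifts — EM's main failure mode on repeated patterns is convergence to a
register shifted by a residue or two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ProteinSequence

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_TO_IDX = {a: i for i, a in enumerate(AA)}
MASK_IDX = 20  # index used for X / masked residues

WIDTH_GRID = (6, 8, 10, 15, 20, 29, 50)

PSEUDOCOUNT = 0.05
MAX_ITER = 200
TOL = 1e-4
SITE_ODDS = 10.0
N_CANDIDATES = 300
N_SHORT = 3
SHORT_ITER = 20
MAX_SHIFT = 3


@dataclass
class Motif:
    """A position weight matrix with its called occurrence sites."""

    motif_id: int
    width: int
    pwm: np.ndarray  # (width, 20), columns sum to 1
    sites: list[tuple[str, int]]  # (protein id, 1-based start)
    log_likelihood_ratio: float

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.pwm.argmax(axis=1))


@dataclass
class _Windows:
    """All width-w windows of the working (maskable) sequence set."""

    seq_ids: list[str]
    seq_idx: np.ndarray  # (n_win,)
    pos: np.ndarray  # (n_win,) 0-based start within sequence
    residues: np.ndarray  # (n_win, w) residue indices (no masked windows)


def _encode(seqs: list[ProteinSequence]) -> list[np.ndarray]:
    return [
        np.array([_AA_TO_IDX.get(c, MASK_IDX) for c in s.residues], dtype=np.intp)
        for s in seqs
    ]


def _windows(encoded: list[np.ndarray], ids: list[str], w: int) -> _Windows | None:
    seq_idx, pos, rows = [], [], []
    for si, arr in enumerate(encoded):
        if len(arr) < w:
            continue
        view = np.lib.stride_tricks.sliding_window_view(arr, w)
        ok = ~(view == MASK_IDX).any(axis=1)
        where = np.flatnonzero(ok)
        seq_idx.append(np.full(where.size, si))
        pos.append(where)
        rows.append(view[where])
    if not rows or sum(r.shape[0] for r in rows) == 0:
        return None
    return _Windows(
        ids, np.concatenate(seq_idx), np.concatenate(pos), np.vstack(rows)
    )


def _background(encoded: list[np.ndarray]) -> np.ndarray:
    counts = np.full(20, PSEUDOCOUNT)
    for arr in encoded:
        valid = arr[arr < 20]
        counts += np.bincount(valid, minlength=20)
    return counts / counts.sum()


def _window_llr(win: _Windows, log_theta: np.ndarray, bg_scores: np.ndarray):
    w = log_theta.shape[0]
    s = np.zeros(win.residues.shape[0])
    for j in range(w):
        s += log_theta[j, win.residues[:, j]]
    return s - bg_scores


def _bg_window_scores(win: _Windows, log_bg: np.ndarray) -> np.ndarray:
    return log_bg[win.residues].sum(axis=1)


def _m_step(win: _Windows, z: np.ndarray, w: int) -> np.ndarray:
    theta = np.empty((w, 20))
    for j in range(w):
        theta[j] = np.bincount(
            win.residues[:, j], weights=z, minlength=20
        ) + PSEUDOCOUNT
    theta /= theta.sum(axis=1, keepdims=True)
    return theta


def _em(
    win: _Windows,
    theta0: np.ndarray,
    bg: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    trace: list[float] | None = None,
) -> tuple[np.ndarray, float]:
    """Two-component mixture EM; returns (pwm, gamma)."""
    n_win = win.residues.shape[0]
    w = theta0.shape[0]
    bg_scores = _bg_window_scores(win, np.log(bg))
    theta = theta0
    gamma = max(len(win.seq_ids) / n_win, 1e-4)
    for _ in range(max_iter):
        llr = _window_llr(win, np.log(theta), bg_scores)
        logit = llr + math.log(gamma) - math.log1p(-gamma)
        z = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
        if trace is not None:
            # the objective EM ascends: data log-likelihood (up to the
            # constant background sum) plus the Dirichlet pseudocount prior
            ll = float(
                np.logaddexp(math.log1p(-gamma), math.log(gamma) + llr).sum()
            )
            trace.append(ll + PSEUDOCOUNT * float(np.log(theta).sum()))
        new_theta = _m_step(win, z, w)
        gamma = float(np.clip(z.mean(), 1e-6, 0.3))
        if np.abs(new_theta - theta).max() < tol:
            theta = new_theta
            break
        theta = new_theta
    return theta, gamma


def _call_sites(
    win: _Windows, theta: np.ndarray, gamma: float, bg: np.ndarray,
    site_odds: float = SITE_ODDS,
) -> tuple[list[tuple[int, int]], float]:
    """ANR site calling: posterior odds >= threshold, greedy non-overlap."""
    w = theta.shape[0]
    bg_scores = _bg_window_scores(win, np.log(bg))
    llr = _window_llr(win, np.log(theta), bg_scores)
    log_odds = llr + math.log(gamma) - math.log1p(-gamma)
    hit = np.flatnonzero(log_odds >= math.log(site_odds))
    order = hit[np.argsort(-llr[hit], kind="stable")]
    taken: dict[int, list[tuple[int, int]]] = {}
    sites, total_llr = [], 0.0
    for idx in order:
        si, p = int(win.seq_idx[idx]), int(win.pos[idx])
        spans = taken.setdefault(si, [])
        if any(p < e and s < p + w for s, e in spans):
            continue
        spans.append((p, p + w))
        sites.append((si, p))
        total_llr += float(llr[idx])
    sites.sort()
    return sites, total_llr


def _criterion(total_llr: float, n_sites: int, w: int) -> float:
    """Penalised LLR: E-value-like model-complexity charge of 19 free
    parameters per column."""
    return total_llr - 0.5 * 19 * w * math.log(max(n_sites, 2))


def _seed_theta(window_row: np.ndarray, bg: np.ndarray, weight=0.7) -> np.ndarray:
    w = window_row.shape[0]
    theta = np.tile(bg * (1 - weight), (w, 1))
    theta[np.arange(w), window_row] += weight
    return theta


def _fit_width(
    win: _Windows, bg: np.ndarray, rng: np.random.Generator
) -> tuple[float, np.ndarray, float]:
    """Seed-select, short-EM and full-EM one width; returns
    (criterion, pwm, gamma)."""
    n_win = win.residues.shape[0]
    w = win.residues.shape[1]
    n_cand = min(N_CANDIDATES, n_win)
    cand = rng.choice(n_win, size=n_cand, replace=False)
    bg_scores = _bg_window_scores(win, np.log(bg))
    k = len(win.seq_ids)
    scores = np.empty(n_cand)
    for i, c in enumerate(cand):
        theta = _seed_theta(win.residues[c], bg)
        llr = _window_llr(win, np.log(theta), bg_scores)
        top = np.partition(llr, -k)[-k:] if llr.size > k else llr
        scores[i] = top[top > 0].sum()
    best = cand[np.argsort(-scores, kind="stable")[:N_SHORT]]
    short_results = []
    for c in best:
        theta, gamma = _em(
            win, _seed_theta(win.residues[c], bg), bg, max_iter=SHORT_ITER
        )
        sites, total_llr = _call_sites(win, theta, gamma, bg)
        short_results.append((_criterion(total_llr, len(sites), w), theta, gamma))
    crit, theta, gamma = max(short_results, key=lambda t: t[0])
    theta, gamma = _em(win, theta, bg)
    sites, total_llr = _call_sites(win, theta, gamma, bg)
    return _criterion(total_llr, len(sites), w), theta, gamma


def _phase_refine(
    win_by_width, theta: np.ndarray, gamma: float, bg: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Try small column shifts of the fitted PWM and re-run EM, keeping the
    best penalised criterion."""
    w = theta.shape[0]
    win = win_by_width(w)
    best = None
    for shift in range(-MAX_SHIFT, MAX_SHIFT + 1):
        if shift == 0:
            cand = theta
        elif shift > 0:
            cand = np.vstack([theta[shift:], np.tile(bg, (shift, 1))])
        else:
            cand = np.vstack([np.tile(bg, (-shift, 1)), theta[:shift]])
        t, g = _em(win, cand, bg, max_iter=50)
        sites, total_llr = _call_sites(win, t, g, bg)
        crit = _criterion(total_llr, len(sites), w)
        if best is None or crit > best[0]:
            best = (crit, t, g)
    return best


def discover_motifs(
    seqs: list[ProteinSequence],
    max_motifs: int = 10,
    w_min: int = 6,
    w_max: int = 50,
    seed: int = 0,
    site_odds: float = SITE_ODDS,
) -> list[Motif]:
    """Sequential EM motif discovery with site masking between motifs.

    Any number of occurrences per sequence is allowed (ANR); discovery
    stops early when no motif with a positive penalised criterion and at
    least two sites remains.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if all(s.length < w_min for s in seqs):
        raise ValueError(f"all sequences shorter than the minimum width {w_min}")
    if max_motifs <= 0:
        return []
    widths = [w for w in WIDTH_GRID if w_min <= w <= w_max]
    if not widths:
        widths = [w_min]
    rng = np.random.default_rng(seed)
    encoded = _encode(seqs)
    ids = [s.seq_id for s in seqs]
    bg = _background(encoded)
    motifs: list[Motif] = []
    for motif_id in range(1, max_motifs + 1):
        best = None
        for w in widths:
            win = _windows(encoded, ids, w)
            if win is None:
                continue
            crit, theta, gamma = _fit_width(win, bg, rng)
            if best is None or crit > best[0]:
                best = (crit, theta, gamma)
        if best is None:
            break
        _, theta, gamma = best
        crit, theta, gamma = _phase_refine(
            lambda w: _windows(encoded, ids, w), theta, gamma, bg
        )
        w = theta.shape[0]
        win = _windows(encoded, ids, w)
        sites_idx, total_llr = _call_sites(win, theta, gamma, bg, site_odds)
        if crit <= 0 or len(sites_idx) < 2:
            break
        sites = [(ids[si], p + 1) for si, p in sites_idx]
        motifs.append(Motif(motif_id, w, theta, sites, total_llr))
        for si, p in sites_idx:  # mask before the next round
            encoded[si][p : p + w] = MASK_IDX
    return motifs


def em_log_likelihood_trace(
    seqs: list[ProteinSequence], width: int, seed: int = 0, max_iter: int = 50
) -> list[float]:
    """Per-iteration EM objective (log-likelihood plus the Dirichlet
    pseudocount prior) of one run; EM must never decrease it."""
    rng = np.random.default_rng(seed)
    encoded = _encode(seqs)
    bg = _background(encoded)
    win = _windows(encoded, [s.seq_id for s in seqs], width)
    if win is None:
        raise ValueError("no window of the requested width")
    c = rng.integers(0, win.residues.shape[0])
    trace: list[float] = []
    _em(win, _seed_theta(win.residues[c], bg), bg, max_iter=max_iter, trace=trace)
    # add the constant background term so the trace is a true log-likelihood
    trace_const = float(_bg_window_scores(win, np.log(bg)).sum())
    return [t + trace_const for t in trace]


def occurrence_matrix(
    motifs: list[Motif], seqs: list[ProteinSequence]
) -> pd.DataFrame:
    """Per-protein occurrence counts of each motif (rows = proteins,
    columns = motif ids), tallied from the called sites."""
    mat = pd.DataFrame(
        0, index=[s.seq_id for s in seqs], columns=[m.motif_id for m in motifs]
    )
    for m in motifs:
        for sid, _ in m.sites:
            mat.loc[sid, m.motif_id] += 1
    return mat


def shared_motifs(matrix: pd.DataFrame) -> list[int]:
    """Motif ids present at least once in every protein."""
    if matrix.empty:
        raise ValueError("empty occurrence matrix")
    return [c for c in matrix.columns if (matrix[c] >= 1).all()]


def write_meme_minimal(motifs: list[Motif], bg: np.ndarray | None, path) -> None:
    """Write motifs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA + "\n\n")
        if bg is not None:
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{a} {f:.5f}" for a, f in zip(AA, bg)) + "\n\n"
            )
        for m in motifs:
            fh.write(f"MOTIF m{m.motif_id} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 20 w= {m.width} "
                f"nsites= {len(m.sites)} E= 0\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
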