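"""Copy-number estimation from windowed coverage via a Gaussian HMM.

Sequencing depth, normalized per sample so the diploid baseline sits at
1.0, is summarized in consecutive 300-bp windows.  Copy number is decoded
with a hidden Markov model over integer states 0..12 whose emissions are
Normal(CN/2, sigma) with a shared sigma, and whose transitions strongly
favour staying in the current state (stay probability 0.9999, remaining
mass spread uniformly over jumps) — copy-number breakpoints are rare at
the 300-bp scale.  The Viterbi path gives per-window states; a gene's
copy number is the modal state over the windows it overlaps (ties going
to the larger state), and a gene is amplified when its modal copy number
exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CoverageProfile

MAX_STATE = 12
STAY_PROB = 0.9999


def normalize_coverage(raw: np.ndarray, sample_ids: list[str], chrom: str,
                       window_starts: np.ndarray, window_bp: int = 300,
                       autosomal: np.ndarray | None = None
                       ) -> CoverageProfile:
    """Scale each sample's window counts by its autosomal median.

    ``autosomal`` flags the windows used for the median (default: all).
    A zero median is an error — the sample carries no usable signal.
    """
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("raw counts must be non-negative")
    sel = autosomal if autosomal is not None else np.ones(raw.shape[1], bool)
    med = np.median(raw[:, sel], axis=1)
    if (med <= 0).any():
        bad = [sample_ids[i] for i in np.nonzero(med <= 0)[0]]
        raise ValueError(f"zero median coverage for samples: {bad}")
    return CoverageProfile(chrom, np.asarray(window_starts), window_bp,
                           raw / med[:, None], list(sample_ids))


def viterbi_path(obs: np.ndarray, sigma: float, max_state: int = MAX_STATE,
                 stay_prob: float = STAY_PROB) -> np.ndarray:
    """Most probable copy-number state path for one coverage vector.

    Emissions are Normal(state/2, sigma); the prior over initial states
    is uniform.
    """
    if sigma <= 0:
        raise ValueError("emission sigma must be positive")
    obs = np.asarray(obs, dtype=float)
    states = np.arange(max_state + 1)
    means = states / 2.0
    n, k = len(obs), len(states)
    # log emission matrix (n x k); constant terms cancel in the argmax
    log_em = -0.5 * ((obs[:, None] - means[None, :]) / sigma) ** 2
    log_stay = np.log(stay_prob)
    log_jump = np.log((1.0 - stay_prob) / (k - 1))
    trans = np.full((k, k), log_jump)
    np.fill_diagonal(trans, log_stay)

    delta = log_em[0].copy()
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], states] + log_em[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def estimate_sigma(profile: CoverageProfile, lo: float = 0.75,
                   hi: float = 1.25) -> float:
    """Emission sigma from the spread of windows near the diploid baseline."""
    vals = profile.values[(profile.values >= lo) & (profile.values <= hi)]
    if vals.size < 10:
        raise ValueError("too few near-baseline windows to estimate sigma")
    return float(max(vals.std(), 1e-3))


def viterbi_copy_number(profile: CoverageProfile, sigma: float | None = None,
                        max_state: int = MAX_STATE,
                        stay_prob: float = STAY_PROB) -> np.ndarray:
    """Per-sample, per-window integer copy-number calls (samples x windows)."""
    if sigma is None:
        sigma = estimate_sigma(profile)
    return np.vstack([viterbi_path(row, sigma, max_state, stay_prob)
                      for row in profile.values])


def gene_window_range(profile: CoverageProfile, gene_start: int,
                      gene_end: int) -> slice:
    """Windows overlapping a 0-based half-open gene span."""
    w = profile.window_bp
    starts = profile.window_starts
    lo = int(np.searchsorted(starts + w, gene_start, side="right"))
    hi = int(np.searchsorted(starts, gene_end, side="left"))
    if hi <= lo:
        raise ValueError("gene span overlaps no coverage window")
    return slice(lo, hi)


def gene_modal_copy_number(calls: np.ndarray, window_range: slice
                           ) -> np.ndarray:
    """Modal copy-number state per sample over a gene's windows.

    Ties resolve to the larger state, so a half-amplified gene is called
    consistently rather than by array order.
    """
    seg = calls[:, window_range]
    out = np.empty(seg.shape[0], dtype=int)
    for i, row in enumerate(seg):
        states, counts = np.unique(row, return_counts=True)
        best = counts.max()
        out[i] = states[counts == best].max()
    return out


def amplification_frequency(modal_cn: dict[str, np.ndarray],
                            sample_sets: dict[str, np.ndarray]
                            ) -> pd.DataFrame:
    """Fraction of samples per sample set with modal copy number > 2.

    ``modal_cn`` maps gene name to per-sample modal states;
    ``sample_sets`` maps sample-set name to a boolean sample selector.
    """
    rows = []
    for gene, cn in modal_cn.items():
        for name, sel in sample_sets.items():
            sub = cn[sel]
            frac = float((sub > 2).mean()) if len(sub) else np.nan
            rows.append((gene, name, frac))
    return pd.DataFrame(rows, columns=["gene", "sample_set",
                                       "prop_amplified"])
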