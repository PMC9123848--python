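"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written without the estimator/library path it
checks: direct per-window DFT cross-products for coherency, exhaustive
pair counting for the AUC, and an explicit step-up loop for
Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np


def dft_coherency(
    x: np.ndarray, y: np.ndarray, fs: float,
    window_len: float = 1.0, overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Coherency per frequency bin via direct windowed DFT cross-products."""
    nper = int(round(window_len * fs))
    step = nper - int(nper * overlap)
    # periodic Hann window, written out explicitly
    k = np.arange(nper)
    win = 0.5 - 0.5 * np.cos(2 * np.pi * k / nper)
    sxx = syy = sxy = 0.0
    n_seg = 0
    start = 0
    while start + nper <= x.size:
        xs = x[start : start + nper]
        ys = y[start : start + nper]
        fx = np.fft.rfft((xs - xs.mean()) * win)
        fy = np.fft.rfft((ys - ys.mean()) * win)
        sxx = sxx + np.conj(fx) * fx
        syy = syy + np.conj(fy) * fy
        sxy = sxy + np.conj(fx) * fy
        n_seg += 1
        start += step
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    return freqs, (sxy / n_seg) / np.sqrt((sxx / n_seg).real * (syy / n_seg).real)


def dft_imcoh(x, y, fs, f_lo, f_hi, window_len=1.0, overlap=0.5) -> float:
    freqs, coh = dft_coherency(x, y, fs, window_len, overlap)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    return float(np.mean(np.abs(coh.imag[mask])))


def auc_pair_count(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive concordant-pair counting (ties = 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the explicit step-up rule."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)
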