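"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths of the package: the SPARC oracle
uses a naive direct DFT and an explicit arc-length loop instead of an FFT;
the aggregation oracles recompute pooled statistics sample by sample.
"""

import math

import numpy as np


def sparc_bruteforce(series, fps, amplitude_threshold=0.05,
                     max_cutoff_hz=10.0, padding_factor=4):
    """Spectral arc length via a naive DFT and an explicit polyline sum."""
    x = np.asarray(series, dtype=float)
    v = np.abs(np.gradient(x) * fps)
    nfft = int(padding_factor * 2 ** math.ceil(math.log2(len(v))))
    padded = np.zeros(nfft)
    padded[:len(v)] = v
    n = np.arange(nfft)
    spec = []
    for k in range(nfft // 2 + 1):
        spec.append(abs(np.sum(padded * np.exp(-2j * np.pi * k * n / nfft))))
    spec = np.array(spec)
    if spec[0] <= 0:
        return float("nan")
    freqs = np.arange(nfft // 2 + 1) * fps / nfft
    vhat = spec / spec[0]
    above = [i for i, s in enumerate(vhat) if s >= amplitude_threshold]
    cutoff = min(max_cutoff_hz, float(freqs[above[-1]]))
    sel = [i for i, f in enumerate(freqs) if f <= cutoff]
    total = 0.0
    for a, b in zip(sel[:-1], sel[1:]):
        df = (freqs[b] - freqs[a]) / cutoff
        ds = vhat[b] - vhat[a]
        total += math.sqrt(df * df + ds * ds)
    return -total


def pooled_mean_std(groups):
    """Sample-weighted pooled mean/std over lists of per-class values."""
    allv = [v for g in groups for v in g]
    m = sum(allv) / len(allv)
    if len(allv) > 1:
        s = math.sqrt(sum((v - m) ** 2 for v in allv) / (len(allv) - 1))
    else:
        s = 0.0
    return m, s, len(allv)


def rom_bruteforce(column):
    """Min/max over non-missing samples by explicit scan."""
    lo, hi = math.inf, -math.inf
    n_missing = 0
    for v in column:
        if not math.isfinite(v):
            n_missing += 1
            continue
        lo, hi = min(lo, v), max(hi, v)
    return (lo, hi), n_missing
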