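"""Independent brute-force oracles shared by unit and acceptance tests."""
import numpy as np


def brute_force_peaks_and_prominences(v):
    """Exhaustive scan: every strict local maximum of ``v`` and its
    prominence.

    For each peak, walk outward until a strictly higher sample (or the
    signal edge); each side's base is the minimum encountered, and the
    prominence is the peak height minus the higher of the two bases.
    Mirrors the standard topographic definition, computed without any
    library call.
    """
    peaks, proms = [], []
    for i in range(1, len(v) - 1):
        if not (v[i] > v[i - 1] and v[i] > v[i + 1]):
            continue
        left_base = v[i]
        j = i - 1
        while j >= 0 and v[j] <= v[i]:
            left_base = min(left_base, v[j])
            j -= 1
        right_base = v[i]
        j = i + 1
        while j < len(v) and v[j] <= v[i]:
            right_base = min(right_base, v[j])
            j += 1
        peaks.append(i)
        proms.append(v[i] - max(left_base, right_base))
    return np.array(peaks, dtype=int), np.array(proms, dtype=float)


def random_envelope(rng, n=200, span_db=30.0, floor_db=-50.0):
    """Smoothed random-walk envelope in dB, plateau-free."""
    x = np.convolve(np.cumsum(rng.standard_normal(n)), np.ones(7) / 7, "same")
    x = span_db * (x - x.min()) / (np.ptp(x) + 1e-12) + floor_db
    return x + rng.normal(0, 1e-9, n)  # break accidental ties
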