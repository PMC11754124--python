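"""Independent brute-force TMM oracle shared by the test modules."""

import numpy as np
from scipy.stats import rankdata


def tmm_bruteforce(obs, ref, N, Nr, logratio_trim=0.3, abundance_trim=0.05):
    """Trimmed precision-weighted mean of M values, written from the
    definition (independent of the package implementation)."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    pos = (obs > 0) & (ref > 0)
    y, yr = obs[pos], ref[pos]
    M = np.log2((y / N) / (yr / Nr))
    A = 0.5 * np.log2((y / N) * (yr / Nr))
    n = M.size

    def keep(v, tr):
        lo = np.floor(n * tr) + 1
        hi = n + 1 - lo
        r = rankdata(v)
        return (r >= lo) & (r <= hi)

    k = keep(M, logratio_trim) & keep(A, abundance_trim)
    w = 1.0 / ((N - y[k]) / (N * y[k]) + (Nr - yr[k]) / (Nr * yr[k]))
    return float(np.sum(w * M[k]) / np.sum(w))
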