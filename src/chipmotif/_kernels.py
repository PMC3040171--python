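"""Numba-compiled inner loops for window scoring and the ZOOPS E-step.

Sequences are encoded as int8: A=0, C=1, G=2, T=3, N=4. A window containing
an N scores -inf (masked). All kernels are deterministic and single-threaded.
"""

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def window_scores(codes, lens, score_mat, out):
    """Score every width-w window of every sequence with a (w, 4) matrix.

    codes: (n, Lmax) int8, padded with 4 beyond lens[s].
    out:   (n, Lmax - w + 1) float64, NEG_INF for invalid/N windows.
    """
    n, lmax = codes.shape
    w = score_mat.shape[0]
    nofs = lmax - w + 1
    for s in range(n):
        last = lens[s] - w
        for o in range(nofs):
            if o > last:
                out[s, o] = NEG_INF
                continue
            acc = 0.0
            ok = True
            for j in range(w):
                c = codes[s, o + j]
                if c > 3:
                    ok = False
                    break
                acc += score_mat[j, c]
            out[s, o] = acc if ok else NEG_INF
    return out


@njit(cache=True)
def zoops_estep(codes, lens, sp, sm, pi, weights, gamma, counts, stats):
    """One ZOOPS E-step: accumulate posterior-weighted letter counts.

    sp, sm: (n, nofs) log2 likelihood-ratio scores of the motif vs background
            for + windows and for − windows (motif on the reverse strand).
    pi:     (n, nofs) positional prior, rows summing to 1 over valid offsets.
    counts: (w, 4) output, posterior-weighted letter counts in motif orientation.
    stats:  length-3 output: [loglik (nats, relative), gamma_num, gamma_den].
    """
    n, nofs = sp.shape
    w = counts.shape[0]
    ln2 = 0.6931471805599453
    for s in range(n):
        wt = weights[s]
        if lens[s] < w or wt == 0.0:
            continue
        denom = 1.0 - gamma
        for o in range(nofs):
            p = pi[s, o]
            if p == 0.0:
                continue
            if sp[s, o] > NEG_INF * 0.5:
                denom += gamma * p * 0.5 * np.exp2(sp[s, o])
            if sm[s, o] > NEG_INF * 0.5:
                denom += gamma * p * 0.5 * np.exp2(sm[s, o])
        if denom <= 0.0:
            continue
        stats[0] += wt * np.log(denom)
        post_tot = 0.0
        for o in range(nofs):
            p = pi[s, o]
            if p == 0.0:
                continue
            if sp[s, o] > NEG_INF * 0.5:
                z = gamma * p * 0.5 * np.exp2(sp[s, o]) / denom
                if z > 0.0:
                    post_tot += z
                    zz = z * wt
                    for j in range(w):
                        counts[j, codes[s, o + j]] += zz
            if sm[s, o] > NEG_INF * 0.5:
                z = gamma * p * 0.5 * np.exp2(sm[s, o]) / denom
                if z > 0.0:
                    post_tot += z
                    zz = z * wt
                    for j in range(w):
                        # motif column j sits at sequence position o + w - 1 - j,
                        # base complemented
                        counts[j, 3 - codes[s, o + w - 1 - j]] += zz
        stats[1] += wt * post_tot
        stats[2] += wt
    return counts
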