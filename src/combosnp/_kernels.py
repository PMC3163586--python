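"""Numba kernels for exhaustive 3-combination counting over packed bitsets.

The enumeration space is C(S,3) * 27 genotype triples; each triple's carrier
set is the AND of three per-genotype bitsets.  Kernels work on word arrays
pre-masked to cases / controls so penetrance classification is two popcounts.
"""

import numpy as np
from numba import njit

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)


@njit(cache=True, inline="always")
def _pc64(x):
    x = x - ((x >> np.uint64(1)) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return (x * _H01) >> np.uint64(56)


@njit(cache=True)
def tally_k3(wc, wt, n_cases):
    """Classify every observed genotype triple by penetrance.

    Parameters: ``wc``/``wt`` are (S, 3, W) uint64 carrier words masked to
    cases / controls.  Returns (observed, common, control_only, patient_only,
    hist) where hist[j] counts patient-only triples carried by exactly j
    patients.
    """
    S, _, W = wc.shape
    observed = np.int64(0)
    common = np.int64(0)
    ctrl_only = np.int64(0)
    pat_only = np.int64(0)
    hist = np.zeros(n_cases + 1, dtype=np.int64)
    pc = np.empty(W, dtype=np.uint64)
    pt = np.empty(W, dtype=np.uint64)
    for i in range(S - 2):
        for gi in range(3):
            for j in range(i + 1, S - 1):
                for gj in range(3):
                    empty = True
                    for w in range(W):
                        pc[w] = wc[i, gi, w] & wc[j, gj, w]
                        pt[w] = wt[i, gi, w] & wt[j, gj, w]
                        if pc[w] != 0 or pt[w] != 0:
                            empty = False
                    if empty:
                        continue
                    for k in range(j + 1, S):
                        for gk in range(3):
                            nc = np.uint64(0)
                            nt = np.uint64(0)
                            for w in range(W):
                                nc += _pc64(pc[w] & wc[k, gk, w])
                                nt += _pc64(pt[w] & wt[k, gk, w])
                            if nc == 0 and nt == 0:
                                continue
                            observed += 1
                            if nc > 0 and nt > 0:
                                common += 1
                            elif nt > 0:
                                ctrl_only += 1
                            else:
                                pat_only += 1
                                hist[nc] += 1
    return observed, common, ctrl_only, pat_only, hist


@njit(cache=True)
def collect_patient_specific_k3(wc, wt, min_patients, max_out):
    """Collect genotype triples carried by >= min_patients cases and 0 controls.

    Returns (n_out, combos, carrier_words): ``combos`` rows are
    (snp1, g1, snp2, g2, snp3, g3); ``carrier_words`` rows are the packed
    case-carrier bitsets.  ``n_out`` is -1 when ``max_out`` overflows.
    """
    S, _, W = wc.shape
    mp = np.uint64(min_patients)
    combos = np.empty((max_out, 6), dtype=np.int64)
    bits = np.empty((max_out, W), dtype=np.uint64)
    n_out = 0
    pc = np.empty(W, dtype=np.uint64)
    pt = np.empty(W, dtype=np.uint64)
    tri = np.empty(W, dtype=np.uint64)
    for i in range(S - 2):
        for gi in range(3):
            for j in range(i + 1, S - 1):
                for gj in range(3):
                    npair = np.uint64(0)
                    for w in range(W):
                        pc[w] = wc[i, gi, w] & wc[j, gj, w]
                        pt[w] = wt[i, gi, w] & wt[j, gj, w]
                        npair += _pc64(pc[w])
                    if npair < mp:
                        continue
                    for k in range(j + 1, S):
                        for gk in range(3):
                            has_ctrl = False
                            for w in range(W):
                                if pt[w] & wt[k, gk, w] != 0:
                                    has_ctrl = True
                                    break
                            if has_ctrl:
                                continue
                            nc = np.uint64(0)
                            for w in range(W):
                                tri[w] = pc[w] & wc[k, gk, w]
                                nc += _pc64(tri[w])
                            if nc < mp:
                                continue
                            if n_out >= max_out:
                                return -1, combos, bits
                            combos[n_out, 0] = i
                            combos[n_out, 1] = gi
                            combos[n_out, 2] = j
                            combos[n_out, 3] = gj
                            combos[n_out, 4] = k
                            combos[n_out, 5] = gk
                            for w in range(W):
                                bits[n_out, w] = tri[w]
                            n_out += 1
    return n_out, combos, bits
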