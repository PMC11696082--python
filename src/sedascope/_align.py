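"""Numba kernels for semi-global (glocal) affine-gap alignment.

The read is aligned end-to-end; reference ends are free (leading/trailing
reference bases cost nothing), which is the right shape for placing a short
fragment on a long mitogenome. A gap of length L scores
``gap_open + L * gap_extend`` (the first gap base costs open+extend).

Two kernels: a two-row score scan over the full (doubled) reference, and a
full Gotoh with traceback restricted to a window around the optimal end
column found by the scan. Because the read must be fully aligned, any
alignment ending at column ``j`` starts within ``read_len + window margin``
columns of ``j`` unless it contains a reference-gap run long enough to score
worse than an all-mismatch alignment, so a margin of 32 columns is safe for
every hit the pipeline can retain.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**6)


@njit(cache=True)
def sg_score(read, ref, match, mismatch, go, ge):
    """Best semi-global score and its end column (exclusive) on ``ref``."""
    m = read.shape[0]
    n = ref.shape[0]
    Hp = np.zeros(n + 1, np.int32)
    Fp = np.full(n + 1, NEG, np.int32)
    Hc = np.empty(n + 1, np.int32)
    Fc = np.empty(n + 1, np.int32)
    for i in range(1, m + 1):
        Hc[0] = go + ge * i
        Fc[0] = go + ge * i
        E = NEG
        rc = read[i - 1]
        for j in range(1, n + 1):
            f = Fp[j] + ge
            f2 = Hp[j] + go + ge
            if f2 > f:
                f = f2
            Fc[j] = f
            s = match if (ref[j - 1] == rc and rc < 4) else mismatch
            d = Hp[j - 1] + s
            e = E + ge
            e2 = Hc[j - 1] + go + ge
            if e2 > e:
                e = e2
            E = e
            h = d
            if f > h:
                h = f
            if e > h:
                h = e
            Hc[j] = h
        Hp, Hc = Hc, Hp
        Fp, Fc = Fc, Fp
    best = Hp[0]
    bj = 0
    for j in range(1, n + 1):
        if Hp[j] > best:
            best = Hp[j]
            bj = j
    return best, bj


@njit(cache=True)
def sg_traceback(read, ref, match, mismatch, go, ge):
    """Full Gotoh with traceback on a small reference window.

    Returns (score, ref_start, ref_end, n_match, n_columns, ops, lens, n_ops)
    where ops are 0=M, 1=I (read-only), 2=D (ref-only), listed 5'→3' of the
    oriented read, and ref_start/ref_end are within the window.
    """
    m = read.shape[0]
    n = ref.shape[0]
    H = np.empty((m + 1, n + 1), np.int32)
    E = np.empty((m + 1, n + 1), np.int32)
    F = np.empty((m + 1, n + 1), np.int32)
    # pointers: for H, 0=diag, 1=from E, 2=from F; for E/F, 0=open, 1=extend
    PH = np.zeros((m + 1, n + 1), np.uint8)
    PE = np.zeros((m + 1, n + 1), np.uint8)
    PF = np.zeros((m + 1, n + 1), np.uint8)
    for j in range(n + 1):
        H[0, j] = 0
        E[0, j] = NEG
        F[0, j] = NEG
    for i in range(1, m + 1):
        H[i, 0] = go + ge * i
        F[i, 0] = go + ge * i
        E[i, 0] = NEG
        PH[i, 0] = 2  # column 0 is reachable only through the vertical state
        PF[i, 0] = 0 if i == 1 else 1
        for j in range(1, n + 1):
            fo = H[i - 1, j] + go + ge
            fx = F[i - 1, j] + ge
            if fo >= fx:
                F[i, j] = fo
                PF[i, j] = 0
            else:
                F[i, j] = fx
                PF[i, j] = 1
            eo = H[i, j - 1] + go + ge
            ex = E[i, j - 1] + ge
            if eo >= ex:
                E[i, j] = eo
                PE[i, j] = 0
            else:
                E[i, j] = ex
                PE[i, j] = 1
            rc = read[i - 1]
            s = match if (ref[j - 1] == rc and rc < 4) else mismatch
            d = H[i - 1, j - 1] + s
            h = d
            p = 0
            if E[i, j] > h:
                h = E[i, j]
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            H[i, j] = h
            PH[i, j] = p
    best = H[m, 0]
    bj = 0
    for j in range(1, n + 1):
        if H[m, j] > best:
            best = H[m, j]
            bj = j
    # traceback from (m, bj) in state H until i == 0
    ops = np.empty(2 * m + n + 2, np.uint8)
    lens = np.empty(2 * m + n + 2, np.int32)
    n_ops = 0
    n_match = 0
    n_cols = 0
    i = m
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                op = 0
                rc = read[i - 1]
                if j > 0 and ref[j - 1] == rc and rc < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
                continue
            else:
                state = 2
                continue
        elif state == 1:  # E: consume reference
            op = 2
            if PE[i, j] == 0:
                state = 0
            j -= 1
        else:  # F: consume read
            op = 1
            if PF[i, j] == 0:
                state = 0
            i -= 1
        n_cols += 1
        if n_ops > 0 and ops[n_ops - 1] == op:
            lens[n_ops - 1] += 1
        else:
            ops[n_ops] = op
            lens[n_ops] = 1
            n_ops += 1
    return best, j, bj, n_match, n_cols, ops, lens, n_ops


_OP_CHARS = ("M", "I", "D")


def traceback_window(read_codes, ref_codes, j_end, match, mismatch, go, ge, margin=32):
    """Run the traceback kernel on a window ending at ``j_end``.

    Returns (score, ref_start, ref_end, n_match, n_cols, cigar) with
    reference coordinates on the full ``ref_codes`` frame and the cigar
    ordered 5'→3' of the oriented read.
    """
    m = read_codes.shape[0]
    j0 = max(0, j_end - m - margin)
    score, ws, we, n_match, n_cols, ops, lens, n_ops = sg_traceback(
        read_codes, ref_codes[j0:j_end], match, mismatch, go, ge
    )
    # kernel emits ops end→start; reverse into read order
    cigar = [(_OP_CHARS[ops[k]], int(lens[k])) for k in range(n_ops - 1, -1, -1)]
    # drop leading/trailing reference-only runs (free ends, zero cost)
    rs, re = j0 + ws, j0 + we
    while cigar and cigar[0][0] == "D":
        rs += cigar[0][1]
        n_cols -= cigar[0][1]
        cigar = cigar[1:]
    while cigar and cigar[-1][0] == "D":
        re -= cigar[-1][1]
        n_cols -= cigar[-1][1]
        cigar = cigar[:-1]
    return int(score), rs, re, int(n_match), int(n_cols), cigar
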