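"""Numba-compiled dynamic-programming alignment kernels.

Two kernels back the whole package:

* :func:`sw_local` — Smith–Waterman local alignment with affine gaps and
  full traceback, used for gapped extension of seed matches.
* :func:`nw_profile` — global Needleman–Wunsch/Gotoh over *profiles*
  (per-column symbol frequency vectors), used for pairwise and progressive
  multiple alignment.  An optional diagonal band accelerates the
  near-identical homoeolog case without changing small-instance results.

Cost model (shared by every aligner and every brute-force oracle in the
test suite): a gap run of length L costs ``gap_open + gap_extend * L``,
i.e. the opening transition pays ``gap_open + gap_extend`` and each
further gap column pays ``gap_extend``.  This is the blastn "existence /
extension" convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Symbol order used by every profile: A C G T N -
N_SYMBOLS = 6
GAP_SYM = 5

_CODE = np.full(128, 4, dtype=np.int8)  # ambiguity codes -> N (mismatch-all)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
_CODE[ord("-")] = GAP_SYM


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A,C,G,T=0..3, other=N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def substitution_matrix(match: float, mismatch: float) -> np.ndarray:
    """6x6 symbol-pair score matrix: bases score match/mismatch, N always
    mismatches (even against N), and the gap symbol scores 0 against
    everything (gap costs are handled by the affine penalties)."""
    S = np.full((N_SYMBOLS, N_SYMBOLS), mismatch, dtype=np.float64)
    for i in range(4):
        S[i, i] = match
    S[GAP_SYM, :] = 0.0
    S[:, GAP_SYM] = 0.0
    return S


@njit(cache=True)
def sw_local(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap local alignment of code arrays ``a`` vs ``b``.

    Returns ``(score, a0, a1, b0, b1, n_ident, aln_len)`` where the
    intervals are 0-based half-open on each input and ``n_ident`` counts
    identical aligned base pairs over ``aln_len`` alignment columns.
    """
    la, lb = a.shape[0], b.shape[0]
    NEG = -(1 << 29)
    H = np.zeros((la + 1, lb + 1), np.int32)
    E = np.full(lb + 1, NEG, np.int32)
    Fv = np.full((la + 1, lb + 1), NEG, np.int32)
    # traceback bits: 0-1 H source (0 stop, 1 diag, 2 E, 3 F); 4 E-extends; 8 F-extends
    TB = np.zeros((la + 1, lb + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, la + 1):
        E[:] = NEG
        for j in range(1, lb + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[j - 1] - gap_extend
            if e_ext > e_open:
                E[j] = e_ext
                eflag = 4
            else:
                E[j] = e_open
                eflag = 0
            f_open = H[i - 1, j] - go
            f_ext = Fv[i - 1, j] - gap_extend
            if f_ext > f_open:
                Fv[i, j] = f_ext
                fflag = 8
            else:
                Fv[i, j] = f_open
                fflag = 0
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                d = H[i - 1, j - 1] + match
            else:
                d = H[i - 1, j - 1] + mismatch
            h = 0
            src = 0
            if d > h:
                h = d
                src = 1
            if E[j] > h:
                h = E[j]
                src = 2
            if Fv[i, j] > h:
                h = Fv[i, j]
                src = 3
            H[i, j] = h
            TB[i, j] = np.uint8(src | eflag | fflag)
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i, j = bi, bj
    n_ident = 0
    aln_len = 0
    state = 0  # 0=H, 2=E, 3=F
    while i > 0 and j > 0:
        tb = TB[i, j]
        if state == 0:
            src = tb & 3
            if src == 0:
                break
            state = src if src > 1 else 0
            if src == 1:
                aln_len += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    n_ident += 1
                i -= 1
                j -= 1
                state = 0
        elif state == 2:  # gap in a, consume b
            aln_len += 1
            cont = tb & 4
            j -= 1
            state = 2 if cont else 0
        else:  # gap in b, consume a
            aln_len += 1
            cont = tb & 8
            i -= 1
            state = 3 if cont else 0
    return best, i, bi, j, bj, n_ident, aln_len


@njit(cache=True)
def nw_profile(SA, FB, gap_open, gap_extend, band):  # pragma: no cover
    """Banded global affine-gap alignment of two profiles.

    ``SA[i] = freqA[i] @ S`` (pre-multiplied substitution scores for each
    column of profile A) and ``FB[j]`` is the frequency vector of column j
    of profile B, so the column-pair score is ``dot(SA[i], FB[j])``
    (sum-of-pairs average).  ``band < 0`` disables banding.  Returns an
    ops array over the optimal path, 5'->3': 1 = aligned column pair,
    2 = gap in A (consume B), 3 = gap in B (consume A).
    """
    la = SA.shape[0]
    lb = FB.shape[0]
    NEG = -1.0e18
    go = float(gap_open + gap_extend)
    ge = float(gap_extend)
    # rolling rows: only the traceback matrix is O(la*lb) (uint8)
    Hprev = np.empty(lb + 1, np.float64)
    Hcur = np.empty(lb + 1, np.float64)
    Fv = np.full(lb + 1, NEG, np.float64)
    TB = np.zeros((la + 1, lb + 1), np.uint8)
    Hprev[0] = 0.0
    for j in range(1, lb + 1):
        Hprev[j] = -(gap_open + gap_extend * j)
        TB[0, j] = np.uint8(2 | 4)
    if band < 0:
        lo_w = la if la > lb else lb
        hi_w = lo_w
    else:
        # straight band around the (0,0)-(la,lb) diagonal
        lo_w = band
        hi_w = band + (lb - la if lb > la else 0)
        if la > lb:
            lo_w = band + (la - lb)
    final = NEG
    for i in range(1, la + 1):
        jmin = i - lo_w
        if jmin < 1:
            jmin = 1
        jmax = i + hi_w
        if jmax > lb:
            jmax = lb
        for j in range(lb + 1):
            Hcur[j] = NEG
        Hcur[0] = -(gap_open + gap_extend * i)
        TB[i, 0] = np.uint8(3 | 8)
        e = NEG
        for j in range(jmin, jmax + 1):
            e_open = Hcur[j - 1] - go
            e_ext = e - ge
            if e_ext > e_open:
                e = e_ext
                eflag = 4
            else:
                e = e_open
                eflag = 0
            f_open = Hprev[j] - go
            f_ext = Fv[j] - ge
            if f_ext > f_open:
                Fv[j] = f_ext
                fflag = 8
            else:
                Fv[j] = f_open
                fflag = 0
            s = 0.0
            for k in range(SA.shape[1]):
                s += SA[i - 1, k] * FB[j - 1, k]
            d = Hprev[j - 1] + s
            h = d
            src = 1
            if e > h:
                h = e
                src = 2
            if Fv[j] > h:
                h = Fv[j]
                src = 3
            Hcur[j] = h
            TB[i, j] = np.uint8(src | eflag | fflag)
        for j in range(lb + 1):
            Hprev[j] = Hcur[j]
        if jmax < lb:
            # columns right of the band never get F values from this row
            Fv[jmax + 1] = NEG
    final = Hprev[lb]
    # traceback from (la, lb)
    ops = np.empty(la + lb, np.uint8)
    nops = 0
    i, j = la, lb
    state = 0
    while i > 0 or j > 0:
        tb = TB[i, j]
        if state == 0:
            src = tb & 3
        else:
            src = state
        if src == 1:
            ops[nops] = 1
            nops += 1
            i -= 1
            j -= 1
            state = 0
        elif src == 2:
            ops[nops] = 2
            nops += 1
            cont = tb & 4
            j -= 1
            state = 2 if cont and j > 0 else 0
        else:
            ops[nops] = 3
            nops += 1
            cont = tb & 8
            i -= 1
            state = 3 if cont and i > 0 else 0
    return final, ops[:nops][::-1].copy()
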