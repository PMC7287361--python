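"""Brute-force reference implementations for recurrence line metrics.

Deliberately naive (pure-Python, O(n^3)-ish) so they cannot share bugs with
the vectorised production code they check.
"""

import math


def brute_diagonal_runs(M):
    """All maximal diagonal runs of ones, scanned cell by cell."""
    n_r, n_c = len(M), len(M[0])
    runs = []
    for i0 in range(n_r):
        for j0 in range(n_c):
            if not M[i0][j0]:
                continue
            if i0 > 0 and j0 > 0 and M[i0 - 1][j0 - 1]:
                continue  # not the start of a run
            length = 0
            i, j = i0, j0
            while i < n_r and j < n_c and M[i][j]:
                length += 1
                i += 1
                j += 1
            runs.append(length)
    return runs


def brute_vertical_runs(M):
    n_r, n_c = len(M), len(M[0])
    runs = []
    for j in range(n_c):
        i = 0
        while i < n_r:
            if M[i][j]:
                length = 0
                while i < n_r and M[i][j]:
                    length += 1
                    i += 1
                runs.append(length)
            else:
                i += 1
    return runs


def brute_metrics(M, lmin=2, vmin=2):
    """RR/DET/LAM/maxL/rENTR from explicit run enumeration."""
    n_r, n_c = len(M), len(M[0])
    total = sum(sum(1 for v in row if v) for row in M)
    if total == 0:
        return dict(rr=0.0, det=0.0, lam=0.0, maxl=0, rentr=0.0)
    diag = brute_diagonal_runs(M)
    vert = brute_vertical_runs(M)
    det = sum(r for r in diag if r >= lmin) / total
    lam = sum(r for r in vert if r >= vmin) / total
    maxl = max(diag)
    long_runs = [r for r in diag if r >= lmin]
    counts = {}
    for r in long_runs:
        counts[r] = counts.get(r, 0) + 1
    if len(counts) > 1:
        n = sum(counts.values())
        entr = -sum((c / n) * math.log(c / n) for c in counts.values())
        rentr = entr / math.log(len(counts))
    else:
        rentr = 0.0
    return dict(rr=total / (n_r * n_c), det=det, lam=lam, maxl=maxl,
                rentr=rentr)
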