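"""Independent oracles used only by the test suite.

Deliberately coded from scratch against the same published conventions as the
package, but sharing none of its code paths: a plain Gotoh affine-gap dynamic
program that enumerates *all* co-optimal global alignments, and small
closed-form helpers.  The nearest-neighbor melting-temperature oracle is
Biopython's Tm_NN (an established independent summation of the same published
tables).
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_all_optimal(
    ref: str,
    qry: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -1,
    max_paths: int = 5000,
):
    """Global affine alignment: optimal score and every co-optimal variant set.

    Gap of length k costs gap_open + (k-1) * gap_extend (the first gapped base
    carries the open cost).  Returns (score, set of variant tuples), each
    variant set a tuple of (pos, ref_allele, alt_allele) with indels
    left-shifted through identical context.
    """
    n, m = len(ref), len(qry)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (deletion)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mi, Mi1, Xi, Xi1, Yi, Yi1 = M[i], M[i - 1], X[i], X[i - 1], Y[i], Y[i - 1]
        for j in range(1, m + 1):
            s = match if ref[i - 1] == qry[j - 1] else mismatch
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + s
            Xi[j] = max(Mi1[j] + gap_open, Xi1[j] + gap_extend, Yi1[j] + gap_open)
            Yi[j] = max(Mi[j - 1] + gap_open, Xi[j - 1] + gap_open, Yi[j - 1] + gap_extend)
    score = max(M[n][m], X[n][m], Y[n][m])

    # enumerate all co-optimal paths by backtracking every achieving transition
    paths: list[list[tuple[str, int, int]]] = []  # ops: ('M'|'X'|'Y', i, j)
    stack = []
    for state, val in (("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])):
        if val == score:
            stack.append((n, m, state, []))
    while stack and len(paths) < max_paths:
        i, j, state, ops = stack.pop()
        if i == 0 and j == 0:
            paths.append(list(reversed(ops)))
            continue
        if state == "M":
            s = match if ref[i - 1] == qry[j - 1] else mismatch
            target = M[i][j] - s
            for prev, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i - 1][j - 1] == target:
                    stack.append((i - 1, j - 1, prev, ops + [("M", i - 1, j - 1)]))
        elif state == "X":
            for prev, mat, cost in (("M", M, gap_open), ("X", X, gap_extend), ("Y", Y, gap_open)):
                if mat[i - 1][j] == X[i][j] - cost:
                    stack.append((i - 1, j, prev, ops + [("X", i - 1, j)]))
        else:  # Y
            for prev, mat, cost in (("M", M, gap_open), ("X", X, gap_open), ("Y", Y, gap_extend)):
                if mat[i][j - 1] == Y[i][j] - cost:
                    stack.append((i, j - 1, prev, ops + [("Y", i, j - 1)]))

    variant_sets = {tuple(_variants_from_ops(ops, ref, qry)) for ops in paths}
    return score, variant_sets


def _left_shift(pos: int, seq: str, ref: str):
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def _variants_from_ops(ops, ref: str, qry: str):
    variants = []
    run = None  # [kind, pos, chars]

    def flush():
        nonlocal run
        if run is not None:
            kind, pos, chars = run
            p, s = _left_shift(pos, "".join(chars), ref)
            variants.append((p, s, "") if kind == "del" else (p, "", s))
        run = None

    for op, i, j in ops:
        if op == "M":
            flush()
            if ref[i] != qry[j]:
                variants.append((i, ref[i], qry[j]))
        elif op == "X":  # deletion of ref[i]
            if run is not None and run[0] == "del" and run[1] + len(run[2]) == i:
                run[2].append(ref[i])
            else:
                flush()
                run = ["del", i, [ref[i]]]
        else:  # insertion of qry[j] before ref pos i
            if run is not None and run[0] == "ins" and run[1] == i:
                run[2].append(qry[j])
            else:
                flush()
                run = ["ins", i, [qry[j]]]
    flush()
    return sorted(variants)


def ols_slope_intercept(xs, ys):
    """Closed-form normal-equations least squares (independent of numpy.polyfit)."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
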