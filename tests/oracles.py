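"""Independent oracles for the test suite.

Each estimation oracle is a literal, loop-based transcription of the
published derivation of its rule (bin the training values, form the
explicit per-column fractions, add the pseudo-count, normalize), kept
free of the package's helper machinery so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def bin_counts(values, labels, median):
    """Active/inactive counts per class with the strict median tie rule."""
    a = b = c = d = 0
    for v, y in zip(values, labels):
        if y < 0:
            if v < median:
                c += 1
            else:
                a += 1
        else:
            if v < median:
                d += 1
            else:
                b += 1
    return a, b, c, d


def _smooth(columns):
    """+1 to every entry, then per-column normalization."""
    out = []
    for off, on in columns:
        off, on = off + 1.0, on + 1.0
        z = off + on
        out.append((off / z, on / z))
    return out


def oracle_sample_only(values, labels):
    med = float(np.median(values))
    a, b, c, d = bin_counts(values, labels, med)
    A, B = a + c, b + d
    pr_on_n = a / A if A else 0.0
    pr_on_t = b / B if B else 0.0
    cols = [
        (1.0 - pr_on_n if A else 0.0, pr_on_n),
        (1.0 - pr_on_t if B else 0.0, pr_on_t),
    ]
    return np.array(_smooth(cols)).T


def oracle_trcmplx_only(values, labels):
    # identical arithmetic, conditioning variable relabeled Off/On
    return oracle_sample_only(values, labels)


def oracle_sample_trcmplx(values, labels, p):
    med = float(np.median(values))
    a, b, c, d = bin_counts(values, labels, med)
    A, B = a + c, b + d
    cols = []
    for tr_on in (False, True):
        for tumor in (False, True):
            n = B if tumor else A
            act = b if tumor else a
            if n == 0:
                cols.append((0.0, 0.0))
            elif not tr_on:
                on = act * p / n
                cols.append((1.0 - on, on))
            else:
                off = (n - act) * (1 - p) / n
                cols.append((off, 1.0 - off))
    # order built (Sample fastest inside TRCMPLX blocks) == table order
    return np.array(_smooth(cols)).T


def oracle_sample_me_trcmplx(values, labels, p):
    med = float(np.median(values))
    a, b, c, d = bin_counts(values, labels, med)
    nN, nT = a + c, b + d
    A, B, C, D = nN + b, nT + a, nN + d, nT + c
    cols = []
    for w in (p, 1 - p):  # TRCMPLX off block, then on block
        for meth in (False, True):
            for tumor in (False, True):
                if not meth:
                    act, den = (b, B) if tumor else (a, A)
                    if den == 0:
                        cols.append((0.0, 0.0))
                    else:
                        on = act * w / den
                        cols.append((1.0 - on, on))
                else:
                    inact, den = (d, D) if tumor else (c, C)
                    if den == 0:
                        cols.append((0.0, 0.0))
                    else:
                        off = inact * w / den
                        cols.append((off, 1.0 - off))
    return np.array(_smooth(cols)).T


def oracle_sample_me(values, labels):
    med = float(np.median(values))
    a, b, c, d = bin_counts(values, labels, med)
    nN, nT = a + c, b + d
    A, B, C, D = nN + b, nT + a, nN + d, nT + c
    cols = []
    for meth in (False, True):
        for tumor in (False, True):
            if not meth:
                act, den = (b, B) if tumor else (a, A)
                if den == 0:
                    cols.append((0.0, 0.0))
                else:
                    on = act / den
                    cols.append((1.0 - on, on))
            else:
                inact, den = (d, D) if tumor else (c, C)
                if den == 0:
                    cols.append((0.0, 0.0))
                else:
                    off = inact / den
                    cols.append((off, 1.0 - off))
    return np.array(_smooth(cols)).T


def oracle_dact3(values, labels):
    med = float(np.median(values))
    a, b, c, d = bin_counts(values, labels, med)
    A, B = a + c, b + d
    cols = []
    for tumor in (False, True):  # Sample slowest
        act, n = (b, B) if tumor else (a, A)
        for k4 in (1, 2):
            for k27 in (1, 2):  # H3K27me3 fastest within each block
                if n == 0:
                    cols.append((0.0, 0.0))
                    continue
                on = act / n if (k27 == 1 and k4 == 2) else (n - act) / n
                cols.append((1.0 - on, on))
    return np.array(_smooth(cols)).T


def exhaustive_simple_paths(adjacency: dict[str, set[str]], a: str, b: str):
    """All simple paths in an undirected adjacency map, by recursive DFS."""
    paths = []

    def walk(node, path):
        if node == b:
            paths.append(list(path))
            return
        for nxt in sorted(adjacency[node]):
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    walk(a, [a])
    return paths
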