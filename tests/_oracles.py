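"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check:
``lcs_oracle`` enumerates common substrings via k-mer sets, and
``smith_waterman_oracle`` is a standalone Gotoh DP.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def lcs_oracle(seq_a: str, seq_b: str) -> int:
    """Longest common substring by exhaustive k-mer set enumeration.

    A common substring of length k exists iff the k-mer sets intersect;
    the property is monotone in k, so scan k upward. ``N`` is excluded
    from matching by stripping k-mers containing it.
    """

    def kmers(seq: str, k: int) -> set[str]:
        return {
            seq[i : i + k]
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        }

    best = 0
    k = 1
    while k <= min(len(seq_a), len(seq_b)):
        if kmers(seq_a, k) & kmers(seq_b, k):
            best = k
            k += 1
        else:
            break
    return best


def smith_waterman_oracle(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -3.0,
    gap_open: float = -1.0,
    gap_extend: float = -1.0,
) -> float:
    """Best local alignment score, affine gaps scoring open + k * extend.

    Row-vectorized Gotoh recursion; N matches nothing.
    """
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    n_code = ord("N")
    first_gap = gap_open + gap_extend

    m = len(b)
    best = 0.0
    prev_h = np.zeros(m + 1)
    prev_e = np.full(m + 1, NEG_INF)  # gap in a (consuming b)
    for ai in a:
        sub = np.where((b == ai) & (b != n_code), match, mismatch)
        h = np.zeros(m + 1)
        e = np.full(m + 1, NEG_INF)
        f = NEG_INF  # gap in b (consuming a), scalar carried along the row
        for j in range(1, m + 1):
            e[j] = max(prev_h[j] + first_gap, prev_e[j] + gap_extend)
            f = max(h[j - 1] + first_gap, f + gap_extend)
            h[j] = max(0.0, prev_h[j - 1] + sub[j - 1], e[j], f)
        best = max(best, float(h.max()))
        prev_h, prev_e = h, e
    return best


def needleman_wunsch_identity_oracle(
    seq_a: str,
    seq_b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal global alignment score (not identity) by plain Gotoh DP.

    Gap of length k costs open + (k-1) * extend, end gaps penalized.
    Used to confirm the aligner finds the optimal score.
    """
    a, b = seq_a, seq_b
    n, m = len(a), len(b)
    h = np.full((n + 1, m + 1), NEG_INF)
    e = np.full((n + 1, m + 1), NEG_INF)  # gap in a
    f = np.full((n + 1, m + 1), NEG_INF)  # gap in b
    h[0, 0] = 0.0
    for j in range(1, m + 1):
        e[0, j] = -(gap_open + (j - 1) * gap_extend)
        h[0, j] = e[0, j]
    for i in range(1, n + 1):
        f[i, 0] = -(gap_open + (i - 1) * gap_extend)
        h[i, 0] = f[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            e[i, j] = max(h[i, j - 1] - gap_open, e[i, j - 1] - gap_extend)
            f[i, j] = max(h[i - 1, j] - gap_open, f[i - 1, j] - gap_extend)
            h[i, j] = max(h[i - 1, j - 1] + s, e[i, j], f[i, j])
    return float(h[n, m])


def enumerate_global_alignments_identity(seq_a: str, seq_b: str, **scores) -> float:
    """Percent identity of the best-scoring global alignment by brute-force
    enumeration of all alignments (tiny inputs only)."""
    match = scores.get("match", 5.0)
    mismatch = scores.get("mismatch", -4.0)
    gap_open = scores.get("gap_open", 10.0)
    gap_extend = scores.get("gap_extend", 0.5)

    best = {"score": NEG_INF, "identity": 0.0}

    def gap_cost(run: int) -> float:
        return gap_open + (run - 1) * gap_extend if run else 0.0

    def recurse(i, j, score, columns, last):
        if i == len(seq_a) and j == len(seq_b):
            ident = 100.0 * sum(1 for c in columns if c == "M") / len(columns)
            if score > best["score"] or (
                score == best["score"] and ident > best["identity"]
            ):
                best["score"] = score
                best["identity"] = ident
            return
        if i < len(seq_a) and j < len(seq_b):
            s = match if seq_a[i] == seq_b[j] else mismatch
            recurse(i + 1, j + 1, score + s,
                    columns + [("M" if seq_a[i] == seq_b[j] else "X")], None)
        if i < len(seq_a):
            extra = gap_extend if last == "b" else gap_open
            recurse(i + 1, j, score - extra, columns + ["-"], "b")
        if j < len(seq_b):
            extra = gap_extend if last == "a" else gap_open
            recurse(i, j + 1, score - extra, columns + ["-"], "a")

    recurse(0, 0, 0.0, [], None)
    return best["identity"]
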