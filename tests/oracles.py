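"""Independent reference implementations used only to check the package.

These are deliberately naive (brute-force scans, dense pure-Python dynamic
programming, closed-form algebra) and share no code with the package paths
they verify.
"""

from __future__ import annotations

NEG = float("-inf")


def naive_find_all(text: str, query: str) -> list[int]:
    """Brute-force O(n*m) substring scan; N never matches."""
    if "N" in query:
        return []
    hits = []
    m = len(query)
    for i in range(len(text) - m + 1):
        window = text[i: i + m]
        if "N" in window:
            continue
        if window == query:
            hits.append(i)
    return hits


def global_affine_score(read: str, ref: str, match: int = 2, mismatch: int = -3,
                        gap_open: int = -6, gap_extend: int = -1) -> int:
    """Unconstrained full-DP optimal global affine-gap alignment score.

    Pure-Python three-state Gotoh recurrence; adjacent ins<->del transitions
    are disallowed (a substitution always scores better under the defaults).
    """
    n, m = len(read), len(ref)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0
    for j in range(1, m + 1):
        D[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        I[i][0] = gap_open + gap_extend * (i - 1)
    for i in range(1, n + 1):
        rb = read[i - 1]
        Hp, Ip, Dp = H[i - 1], I[i - 1], D[i - 1]
        Hc, Ic, Dc = H[i], I[i], D[i]
        for j in range(1, m + 1):
            cb = ref[j - 1]
            s = match if (rb == cb and rb != "N") else mismatch
            diag = max(Hp[j - 1], Ip[j - 1], Dp[j - 1])
            if diag > NEG:
                Hc[j] = diag + s
            Ic[j] = max(Hp[j] + gap_open, Ip[j] + gap_extend)
            Dc[j] = max(Hc[j - 1] + gap_open, Dc[j - 1] + gap_extend)
    return int(max(H[n][m], I[n][m], D[n][m]))


def pearson_chi2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


def mutate_sequence(seq: str, positions_to_base: dict[int, str]) -> str:
    out = list(seq)
    for pos, base in positions_to_base.items():
        out[pos] = base
    return "".join(out)
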