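"""Independent oracle implementations used to check the package.

These deliberately use the most naive possible algorithms (character
loops, all-pairs scans, full enumeration) and share no code with the
implementation they verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def oracle_scan(seq: str, word: str, both_strands: bool = True):
    """Character-by-character sliding-window scan.

    Returns a list of (start, end, strand) tuples, sorted by position.
    """
    k = len(word)
    rc = oracle_revcomp(word)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if window == word:
            hits.append((i, i + k, "+"))
        if both_strands and rc != word and window == rc:
            hits.append((i, i + k, "-"))
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits


def oracle_overlap_pairs(X, Y, min_bp: int = 1):
    """All-pairs O(n*m) overlap check on (chrom, start, end) triples."""
    pairs = []
    for i, (cx, sx, ex) in enumerate(X):
        for j, (cy, sy, ey) in enumerate(Y):
            if cx == cy and min(ex, ey) - max(sx, sy) >= min_bp:
                pairs.append((i, j))
    return pairs


def oracle_shrunken_t(Xf: np.ndarray, Xd: np.ndarray, lam: float) -> np.ndarray:
    """Textbook two-sample t with variance shrinkage, probe by probe."""
    nf, nd = Xf.shape[1], Xd.shape[1]
    pooled = []
    for i in range(Xf.shape[0]):
        vf = sum((x - Xf[i].mean()) ** 2 for x in Xf[i]) / (nf - 1)
        vd = sum((x - Xd[i].mean()) ** 2 for x in Xd[i]) / (nd - 1)
        pooled.append(((nf - 1) * vf + (nd - 1) * vd) / (nf + nd - 2))
    s0 = float(np.median(pooled))
    out = []
    for i in range(Xf.shape[0]):
        s2 = (1 - lam) * pooled[i] + lam * s0
        out.append((Xf[i].mean() - Xd[i].mean())
                   / math.sqrt(s2 * (1 / nf + 1 / nd)))
    return np.array(out)


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric
    distribution with the observed margins (sum of tables with
    probability <= that of the observed table)."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def log_comb(n_, k_):
        return (math.lgamma(n_ + 1) - math.lgamma(k_ + 1)
                - math.lgamma(n_ - k_ + 1))

    def prob(x):
        return math.exp(log_comb(col1, x) + log_comb(n - col1, row1 - x)
                        - log_comb(n, row1))

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def oracle_ranksum_exact(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    ranks = _midranks(pooled)
    obs = sum(ranks[i] for i in range(nx))
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        s = sum(ranks[i] for i in combo)
        total += 1
        if abs(s - nx * (n + 1) / 2) >= abs(obs - nx * (n + 1) / 2) - 1e-9:
            count += 1
    return count / total


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def oracle_nearest_tss(summit: int, tss_strand_pairs):
    """All-pairs nearest-TSS search with the documented tie-break
    (smaller absolute distance, then lower TSS coordinate)."""
    best = None
    for tss, strand in sorted(tss_strand_pairs, key=lambda t: t[0]):
        d = abs(summit - tss)
        if best is None or d < best[0]:
            best = (d, tss, strand)
    signed = summit - best[1]
    return -signed if best[2] == "-" else signed
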