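"""Interval-set algebra between a wild-type and a mutant factor.

Binding-peak sets of a wild-type and a mutant transcription factor are
compared by overlap (minimum 1 bp by default) and partitioned into:

* A — peaks unique to the wild type,
* B — peaks shared (reported per side: WT peaks overlapping the mutant
  set, and mutant peaks overlapping the WT set),
* C — peaks unique to the mutant ("off-targets").

Significance of an observed overlap is assessed against randomly
generated peak sets: null sets matched to the query in peak count and
individual peak lengths, placed uniformly within the probe-covered
territory (tiling arrays cover only a few percent of the genome, so
placement is territory-restricted). Gene-level set overlaps use the
Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import Peak, PeakSet
from .genome import Interval

__all__ = [
    "overlap_peaks",
    "OverlapResult",
    "decompose_sets",
    "SetDecomposition",
    "merge_intervals",
    "random_peak_null",
    "OverlapNull",
    "gene_set_fisher",
]


def _check_namespaces(X: Sequence[Interval], Y: Sequence[Interval]) -> None:
    cx = {iv.chrom for iv in X}
    cy = {iv.chrom for iv in Y}
    if cx and cy and not (cx & cy):
        raise ValueError(
            f"mismatched chromosome namespaces: {sorted(cx)[:3]} vs {sorted(cy)[:3]}"
        )


@dataclass
class OverlapResult:
    """Pairwise overlaps between two peak sets (many-to-many)."""

    pairs: list[tuple[int, int]]      # (index in X, index in Y)
    x_overlaps: np.ndarray            # bool per X peak: overlaps >=1 Y peak
    y_overlaps: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _intervals_of(ps) -> list[Interval]:
    if isinstance(ps, PeakSet):
        return ps.intervals()
    return list(ps)


def overlap_peaks(X, Y, min_bp: int = 1) -> OverlapResult:
    """All pairs (x, y) with overlap length >= min_bp (half-open arithmetic)."""
    ix = _intervals_of(X)
    iy = _intervals_of(Y)
    _check_namespaces(ix, iy)
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")

    # sorted sweep per chromosome; the scan window is bounded below using
    # the longest Y interval on the chromosome
    by_chrom_y: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(iy):
        by_chrom_y.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for chrom, lst in by_chrom_y.items():
        lst.sort()
        starts = np.array([c[0] for c in lst])
        ends = np.array([c[1] for c in lst])
        idx = np.array([c[2] for c in lst])
        index[chrom] = (starts, ends, idx, int((ends - starts).max()))

    pairs: list[tuple[int, int]] = []
    x_flags = np.zeros(len(ix), dtype=bool)
    y_flags = np.zeros(len(iy), dtype=bool)
    for i, iv in enumerate(ix):
        entry = index.get(iv.chrom)
        if entry is None:
            continue
        starts, ends, idx, max_len = entry
        # overlap >= min_bp needs start <= iv.end - min_bp and end >= iv.start + min_bp
        hi = int(np.searchsorted(starts, iv.end - min_bp, side="right"))
        lo = int(np.searchsorted(starts, iv.start + min_bp - max_len, side="left"))
        for k in range(lo, hi):
            if min(iv.end, int(ends[k])) - max(iv.start, int(starts[k])) >= min_bp:
                j = int(idx[k])
                pairs.append((i, j))
                x_flags[i] = True
                y_flags[j] = True
    return OverlapResult(pairs, x_flags, y_flags)


@dataclass
class SetDecomposition:
    """A/B/C partition of a WT / mutant peak-set pair."""

    A: PeakSet        # WT-only
    B_wt: PeakSet     # WT peaks overlapping >=1 mutant peak
    B_mut: PeakSet    # mutant peaks overlapping >=1 WT peak
    C: PeakSet        # mutant-only

    def summary(self) -> dict:
        n_wt = len(self.A) + len(self.B_wt)
        n_mut = len(self.B_mut) + len(self.C)
        return {
            "n_wt": n_wt,
            "n_mut": n_mut,
            "A": len(self.A),
            "B_wt": len(self.B_wt),
            "B_mut": len(self.B_mut),
            "C": len(self.C),
            "B_pct_of_wt": 100.0 * len(self.B_wt) / n_wt if n_wt else float("nan"),
            "B_pct_of_mut": 100.0 * len(self.B_mut) / n_mut if n_mut else float("nan"),
        }

    def to_bed(self, path: str | Path) -> None:
        """BED with a set-label column {A, B_wt, B_mut, C}."""
        rows = []
        for label, ps in (("A", self.A), ("B_wt", self.B_wt),
                          ("B_mut", self.B_mut), ("C", self.C)):
            for p in ps:
                rows.append((p.chrom, p.start, p.end,
                             p.interval.name or ".", 0, ".", label))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")


def decompose_sets(WT: PeakSet, MUT: PeakSet, min_bp: int = 1) -> SetDecomposition:
    """Partition WT into A | B_wt and MUT into B_mut | C by mutual overlap.

    Membership is per side: a WT peak overlapping two mutant peaks is one
    B_wt peak. Conservation holds on every input: |A|+|B_wt| = |WT| and
    |B_mut|+|C| = |MUT|.
    """
    if len(WT) == 0 and len(MUT) == 0:
        empty = lambda n: PeakSet(n, [])
        return SetDecomposition(empty("A"), empty("B_wt"), empty("B_mut"), empty("C"))
    if len(WT) == 0:
        return SetDecomposition(PeakSet("A", []), PeakSet("B_wt", []),
                                PeakSet("B_mut", []), PeakSet("C", list(MUT.peaks)))
    if len(MUT) == 0:
        return SetDecomposition(PeakSet("A", list(WT.peaks)), PeakSet("B_wt", []),
                                PeakSet("B_mut", []), PeakSet("C", []))
    res = overlap_peaks(WT, MUT, min_bp=min_bp)
    A = [p for p, f in zip(WT.peaks, res.x_overlaps) if not f]
    B_wt = [p for p, f in zip(WT.peaks, res.x_overlaps) if f]
    B_mut = [p for p, f in zip(MUT.peaks, res.y_overlaps) if f]
    C = [p for p, f in zip(MUT.peaks, res.y_overlaps) if not f]
    return SetDecomposition(PeakSet("A", A), PeakSet("B_wt", B_wt),
                            PeakSet("B_mut", B_mut), PeakSet("C", C))


def merge_intervals(intervals: Sequence[Interval],
                    gap: int = 0) -> list[Interval]:
    """Union of intervals as maximal non-overlapping blocks (strand ignored).

    Intervals separated by at most ``gap`` bp are merged into one block;
    with the default 0 only touching/overlapping intervals merge. A
    positive gap turns a probe tiling (e.g. 25 bp probes every 35 bp)
    into contiguous covered territory."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(Interval(chrom, cur_s, cur_e))
    return merged


@dataclass
class OverlapNull:
    """Observed overlap vs a null of randomly placed length-matched sets."""

    observed_count: int
    observed_fraction: float
    null_fractions: np.ndarray
    p_value: float      # (1 + #{null >= observed}) / (n_iter + 1)
    n_iter: int
    seed: int


def _sample_random_intervals(lengths: np.ndarray, territory: list[Interval],
                             rng: np.random.Generator) -> list[Interval]:
    """Place intervals of the given lengths uniformly over all valid start
    positions in territory blocks large enough to contain them."""
    block_chroms = np.array([b.chrom for b in territory])
    block_starts = np.array([b.start for b in territory])
    block_lens = np.array([len(b) for b in territory])
    out = []
    for L in lengths:
        capacity = np.maximum(0, block_lens - int(L) + 1)
        total = int(capacity.sum())
        if total <= 0:
            raise ValueError(
                f"no territory block can contain an interval of length {int(L)}"
            )
        r = int(rng.integers(total))
        k = int(np.searchsorted(np.cumsum(capacity), r, side="right"))
        offset = r - (int(np.cumsum(capacity)[k - 1]) if k > 0 else 0)
        s = int(block_starts[k]) + offset
        out.append(Interval(str(block_chroms[k]), s, s + int(L)))
    return out


def random_peak_null(reference: PeakSet, query: PeakSet,
                     territory: Sequence[Interval], n_iter: int = 1000,
                     seed: int = 0, min_bp: int = 1) -> OverlapNull:
    """Empirical null for the overlap of `reference` with `query`.

    Each iteration draws a random set matched to `query` in peak count
    and individual peak lengths, placed uniformly within territory
    blocks that can contain them; the statistic is the fraction of
    `reference` peaks overlapped (>= min_bp).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(reference) == 0 or len(query) == 0:
        raise ValueError("reference and query must be non-empty")
    territory = merge_intervals(territory)
    lengths = np.array([len(iv) for iv in query.intervals()])
    max_block = max(len(b) for b in territory)
    too_long = lengths[lengths > max_block]
    if too_long.size:
        raise ValueError(
            f"query peak of length {int(too_long.max())} exceeds every "
            f"territory block (max {max_block})"
        )

    obs = overlap_peaks(reference, query, min_bp=min_bp)
    observed_count = int(obs.x_overlaps.sum())
    observed_fraction = observed_count / len(reference)

    rng = np.random.default_rng(seed)
    null_fracs = np.empty(n_iter)
    ref_intervals = reference.intervals()
    for it in range(n_iter):
        rand = _sample_random_intervals(lengths, territory, rng)
        res = overlap_peaks(ref_intervals, rand, min_bp=min_bp)
        null_fracs[it] = res.x_overlaps.sum() / len(reference)

    p = (1 + int((null_fracs >= observed_fraction).sum())) / (n_iter + 1)
    return OverlapNull(observed_count, observed_fraction, null_fracs,
                       p, n_iter, seed)


def gene_set_fisher(genesA: set, genesB: set, universe: set) -> dict:
    """Fisher exact test for overlap of two gene sets within a universe.

    Returns the 2x2 table counts, an odds ratio (Haldane 0.5 correction
    when a cell is zero) and the exact hypergeometric two-sided p.
    """
    if not universe:
        raise ValueError("empty gene universe")
    genesA, genesB = set(genesA), set(genesB)
    if not genesA <= universe or not genesB <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(genesA & genesB)
    b = len(genesA - genesB)
    c = len(genesB - genesA)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {
        "overlap_count": a,
        "table": (a, b, c, d),
        "odds_ratio": float(odds),
        "p_two_sided": float(p),
    }
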