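"""Peak-to-gene assignment via basal-plus-extension regulatory domains.

Each gene gets a strand-aware basal domain around its TSS (6.5 kb
upstream, 2.5 kb downstream by default), extended outward on each side
up to a maximum (100 kb) but truncated at the nearest neighbouring
gene's basal domain and clipped at chromosome ends. A peak is assigned
to every gene whose extended domain it overlaps (>= 1 bp); summit-only
assignment is available as a mode.

Summit-to-TSS distances are signed in the gene's orientation: negative
means the peak summit lies upstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import Peak, PeakSet
from .genome import Interval

__all__ = [
    "RegulatoryDomain",
    "regulatory_domains",
    "assign_peaks",
    "tss_distance_profile",
    "TssDistanceProfile",
]


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal and extended regulatory domain of one gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    basal: Interval
    extended: Interval

    def __post_init__(self) -> None:
        if not (self.extended.start <= self.basal.start
                and self.basal.end <= self.extended.end):
            raise ValueError(f"basal not contained in extended for {self.gene_id}")


def regulatory_domains(genes: pd.DataFrame,
                       basal_up: int = 6500, basal_down: int = 2500,
                       ext_max: int = 100_000,
                       chrom_lengths: Mapping[str, int] | None = None,
                       ) -> list[RegulatoryDomain]:
    """Basal-plus-extension domains for a gene table (gene_id, chrom,
    strand, tss).

    The basal domain is assigned regardless of neighbours. Each side is
    then extended outward up to ``ext_max`` bp, truncated at the nearest
    neighbouring gene's basal-domain edge, and clipped at chromosome
    boundaries (position 0, and the chromosome length when
    ``chrom_lengths`` is given).
    """
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "gene_id"].tolist()[:5]
        raise ValueError(f"missing or invalid strand for genes {bad}")

    rows = []
    for g in genes.itertuples(index=False):
        tss = int(g.tss)
        if g.strand == "+":
            b_start, b_end = tss - basal_up, tss + basal_down
        else:
            b_start, b_end = tss - basal_down, tss + basal_up
        rows.append((g.gene_id, g.chrom, g.strand, tss,
                     max(0, b_start), b_end))
    basal = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                        "tss", "b_start", "b_end"])

    out: list[RegulatoryDomain] = []
    for chrom, grp in basal.groupby("chrom", sort=False):
        chrom_len = None if chrom_lengths is None else int(chrom_lengths[chrom])
        b_starts = grp["b_start"].to_numpy()
        b_ends = grp["b_end"].to_numpy()
        for i, g in enumerate(grp.itertuples(index=False)):
            left_mask = b_starts < g.b_start
            left_limit = int(b_ends[left_mask].max()) if left_mask.any() else 0
            right_mask = b_ends > g.b_end
            right_limit = (int(b_starts[right_mask].min())
                           if right_mask.any()
                           else (chrom_len if chrom_len is not None else g.b_end + ext_max))
            e_start = max(g.b_start - ext_max, left_limit, 0)
            e_start = min(e_start, g.b_start)
            e_end = min(g.b_end + ext_max, right_limit)
            if chrom_len is not None:
                e_end = min(e_end, chrom_len)
            e_end = max(e_end, g.b_end)
            out.append(RegulatoryDomain(
                gene_id=str(g.gene_id), chrom=str(chrom), strand=g.strand,
                tss=g.tss,
                basal=Interval(str(chrom), int(g.b_start), int(g.b_end), g.strand),
                extended=Interval(str(chrom), int(e_start), int(e_end), g.strand),
            ))
    return out


def _peak_items(peaks) -> list[tuple[str, Interval, int]]:
    """(name, interval, summit) triples from a PeakSet or interval list."""
    items = []
    if isinstance(peaks, PeakSet):
        for i, p in enumerate(peaks):
            items.append((p.interval.name or f"peak_{i + 1}", p.interval,
                          int(p.summit_bp)))
    else:
        for i, iv in enumerate(peaks):
            items.append((iv.name or f"peak_{i + 1}", iv,
                          int((iv.start + iv.end) // 2)))
    return items


def assign_peaks(peaks, domains: Sequence[RegulatoryDomain],
                 mode: str = "overlap") -> dict:
    """Assign peaks to genes whose extended domains they hit.

    ``mode='overlap'`` assigns a peak to every gene whose extended
    domain overlaps it by >= 1 bp; ``mode='summit'`` requires the peak
    summit to fall inside the extended domain. Returns the assignment
    table, the target-gene union and unassigned peak names.
    """
    if mode not in ("overlap", "summit"):
        raise ValueError("mode must be 'overlap' or 'summit'")
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)

    rows = []
    unassigned = []
    for name, iv, summit in _peak_items(peaks):
        hit = False
        for d in by_chrom.get(iv.chrom, []):
            if mode == "overlap":
                ok = min(iv.end, d.extended.end) - max(iv.start, d.extended.start) >= 1
            else:
                ok = d.extended.start <= summit < d.extended.end
            if ok:
                rows.append({"peak": name, "gene_id": d.gene_id,
                             "chrom": iv.chrom, "peak_start": iv.start,
                             "peak_end": iv.end})
                hit = True
        if not hit:
            unassigned.append(name)
    table = pd.DataFrame(rows, columns=["peak", "gene_id", "chrom",
                                        "peak_start", "peak_end"])
    return {
        "assignments": table,
        "target_genes": sorted(set(table["gene_id"])) if len(table) else [],
        "unassigned_peaks": unassigned,
    }


@dataclass
class TssDistanceProfile:
    """Signed summit-to-nearest-TSS distances plus their histogram."""

    distances: np.ndarray           # signed bp, one per peak
    nearest_gene: list[str]
    histogram: pd.DataFrame         # bin_left, bin_right, count
    bin_bp: int
    sign_convention: str = "negative = upstream of TSS in gene orientation"


def tss_distance_profile(peaks, genes: pd.DataFrame,
                         bin_bp: int = 250) -> TssDistanceProfile:
    """Signed distance of each peak summit to its nearest TSS.

    Nearest is by absolute distance; ties break to the lower-coordinate
    TSS. The sign is flipped for minus-strand genes so that negative
    always means upstream.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    by_chrom = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        grp = grp.sort_values("tss")
        by_chrom[chrom] = (grp["tss"].to_numpy(dtype=int),
                           grp["strand"].to_numpy(),
                           grp["gene_id"].to_numpy())

    dists, nearest = [], []
    for name, iv, summit in _peak_items(peaks):
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            continue
        tss_arr, strands, ids = entry
        j = int(np.searchsorted(tss_arr, summit))
        cands = [k for k in (j - 1, j) if 0 <= k < tss_arr.size]
        # nearest by |distance|, tie -> lower TSS coordinate
        best = min(cands, key=lambda k: (abs(summit - int(tss_arr[k])),
                                         int(tss_arr[k])))
        signed = summit - int(tss_arr[best])
        if strands[best] == "-":
            signed = -signed
        dists.append(signed)
        nearest.append(str(ids[best]))

    arr = np.asarray(dists, dtype=float)
    if arr.size:
        lo = int(np.floor(arr.min() / bin_bp)) * bin_bp
        hi = int(np.ceil((arr.max() + 1) / bin_bp)) * bin_bp
        edges = np.arange(lo, hi + bin_bp, bin_bp)
        counts, edges = np.histogram(arr, bins=edges)
        hist = pd.DataFrame({"bin_left": edges[:-1].astype(int),
                             "bin_right": edges[1:].astype(int),
                             "count": counts})
    else:
        hist = pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    return TssDistanceProfile(arr, nearest, hist, bin_bp)
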