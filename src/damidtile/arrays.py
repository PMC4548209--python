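"""From replicate probe intensities to called binding peaks.

The DamID contrast is Dam-fusion versus Dam-only log2 probe intensity.
The processing chain is:

1. quantile normalization across samples;
2. a per-probe shrunken two-sample t statistic (fusion minus Dam-only),
   with the pooled variance shrunk toward the across-probe median;
3. a centered moving average of the probe statistic along the tiling
   (windows never cross chromosome boundaries or gaps in probe
   coverage larger than ``max_gap_bp``);
4. region detection: maximal runs of >= ``min_probes`` consecutive
   probes with moving-average statistic >= ``ma_cutoff`` become peaks;
5. an empirical false discovery rate from balanced permutations of the
   fusion / Dam-only sample labels.

Defaults (>= 8 probes, moving average >= 3.5) reproduce the region
detection rule used for promoter tiling arrays with ~35 bp probe
spacing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Interval

__all__ = [
    "COORD_COLUMNS",
    "SampleDesign",
    "PeakCallParams",
    "Peak",
    "PeakSet",
    "load_intensity_table",
    "save_intensity_table",
    "validate_table",
    "quantile_normalize",
    "probe_statistic",
    "moving_average",
    "call_peaks",
    "run_peak_calling",
    "estimate_fdr",
    "FdrResult",
]

COORD_COLUMNS = ["probe_id", "chrom", "start", "end"]


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample column names to condition ('fusion' or 'dam_only')."""

    conditions: dict  # sample_id -> condition

    def __post_init__(self) -> None:
        bad = {s: c for s, c in self.conditions.items()
               if c not in ("fusion", "dam_only")}
        if bad:
            raise ValueError(f"conditions must be fusion/dam_only, got {bad}")

    @property
    def fusion_samples(self) -> list[str]:
        return [s for s, c in self.conditions.items() if c == "fusion"]

    @property
    def dam_samples(self) -> list[str]:
        return [s for s, c in self.conditions.items() if c == "dam_only"]

    def validate(self) -> None:
        if len(self.fusion_samples) < 2 or len(self.dam_samples) < 2:
            raise ValueError(
                "need >=2 replicates per condition for variance estimation: "
                f"fusion={len(self.fusion_samples)}, dam_only={len(self.dam_samples)}"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["sample_id"], df["condition"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.conditions),
             "condition": list(self.conditions.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PeakCallParams:
    """Region-detection parameters.

    min_probes / ma_cutoff are the published defaults (>=8 probes with a
    moving-average statistic >=3.5). ``shrinkage_weight`` is the weight
    lambda on the across-probe median pooled variance in the shrunken
    probe statistic. ``bridge_below_cutoff`` switches to the alternative
    reading of the region rule in which above-cutoff runs separated by
    sub-cutoff probes within ``max_gap_bp`` are merged and ``min_probes``
    counts all probes in the merged span.
    """

    min_probes: int = 8
    ma_cutoff: float = 3.5
    ma_window_probes: int = 5
    max_gap_bp: int = 300
    shrinkage_weight: float = 0.5
    n_permutations: int = 20
    seed: int = 0
    bridge_below_cutoff: bool = False

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.ma_window_probes % 2 != 1:
            raise ValueError("ma_window_probes must be odd (centered window)")
        if not (0.0 <= self.shrinkage_weight <= 1.0):
            raise ValueError("shrinkage_weight must be in [0, 1]")


@dataclass(frozen=True)
class Peak:
    """A called binding region: probe-defined span plus statistics."""

    interval: Interval
    n_probes: int
    max_ma_stat: float
    summit_bp: int  # median probe midpoint
    fdr: float = float("nan")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PeakSet:
    """A named collection of peaks for one factor."""

    name: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    def sorted(self) -> "PeakSet":
        return PeakSet(self.name,
                       sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.interval.name or f"{self.name}_peak{i + 1}"
                         for i, p in enumerate(self.peaks)],
                "n_probes": [p.n_probes for p in self.peaks],
                "max_ma_stat": [p.max_ma_stat for p in self.peaks],
                "summit_bp": [p.summit_bp for p in self.peaks],
                "fdr": [p.fdr for p in self.peaks],
            }
        )

    def to_bed(self, path: str | Path) -> None:
        """BED6+3: name, score 0, strand '.', then n_probes, max_ma_stat, fdr."""
        df = self.sorted().to_dataframe()
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t.\t"
                    f"{row.n_probes}\t{row.max_ma_stat:.4f}\t{row.fdr:.4g}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path, name: str = "") -> "PeakSet":
        peaks = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                pk_name = parts[3] if len(parts) > 3 else ""
                n_probes = int(parts[6]) if len(parts) > 6 else 0
                max_ma = float(parts[7]) if len(parts) > 7 else float("nan")
                fdr = float(parts[8]) if len(parts) > 8 else float("nan")
                peaks.append(
                    Peak(Interval(chrom, start, end, ".", pk_name),
                         n_probes, max_ma, (start + end) // 2, fdr)
                )
        return cls(name or Path(path).stem, peaks)


# ---------------------------------------------------------------------------
# intensity table I/O and validation
# ---------------------------------------------------------------------------

def load_intensity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table missing columns {missing}")
    return validate_table(df)


def save_intensity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in COORD_COLUMNS]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check sortedness, unique probe ids and numeric, complete intensities."""
    if table["probe_id"].duplicated().any():
        dups = table.loc[table["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicate probe_ids, e.g. {dups}")
    key = table[["chrom", "start"]]
    if not key.equals(key.sort_values(["chrom", "start"]).reset_index(drop=True)):
        table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
    samples = sample_columns(table)
    if not samples:
        raise ValueError("intensity table has no sample columns")
    vals = table[samples]
    bad_mask = ~np.isfinite(vals.apply(pd.to_numeric, errors="coerce")).all(axis=1)
    if bad_mask.any():
        bad = table.loc[bad_mask, "probe_id"].tolist()[:10]
        raise ValueError(f"non-numeric or missing intensities for probes {bad}")
    return table


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common per-rank mean distribution.

    After normalization the sorted value vector of every column is the
    cross-sample mean of sorted values. Ties within a column receive the
    mean of the reference values over their rank range.
    """
    table = validate_table(table)
    samples = sample_columns(table)
    if len(samples) < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = table[samples].to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.sort(X, axis=0).mean(axis=1)  # per-rank cross-sample mean

    out = np.empty_like(X)
    n = X.shape[0]
    rows = np.empty(n, dtype=int)
    for j in range(X.shape[1]):
        rows[order[:, j]] = np.arange(n)
        col = ref[rows]
        # ties: average the reference values assigned across the tie's ranks
        s = pd.Series(col).groupby(X[:, j]).transform("mean").to_numpy()
        out[:, j] = s
    result = table.copy()
    result[samples] = out
    return result


# ---------------------------------------------------------------------------
# probe statistic
# ---------------------------------------------------------------------------

def _shrunken_t(X_f: np.ndarray, X_d: np.ndarray, lam: float) -> np.ndarray:
    n_f, n_d = X_f.shape[1], X_d.shape[1]
    mean_f = X_f.mean(axis=1)
    mean_d = X_d.mean(axis=1)
    var_f = X_f.var(axis=1, ddof=1)
    var_d = X_d.var(axis=1, ddof=1)
    s_pooled2 = ((n_f - 1) * var_f + (n_d - 1) * var_d) / (n_f + n_d - 2)
    s0_2 = float(np.median(s_pooled2))
    s_tilde2 = (1.0 - lam) * s_pooled2 + lam * s0_2
    denom = np.sqrt(s_tilde2 * (1.0 / n_f + 1.0 / n_d))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_f - mean_d) / denom
    zero = s_tilde2 <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} probes have zero shrunken variance; "
                      "their statistic is set to 0")
        t[zero] = 0.0
    return t


def probe_statistic(table: pd.DataFrame, design: SampleDesign,
                    shrinkage_weight: float = 0.5) -> np.ndarray:
    """Per-probe shrunken two-sample t: fusion minus Dam-only.

    t_i = (mean_fusion,i - mean_dam,i) / sqrt(s~_i^2 (1/n_f + 1/n_d)),
    s~_i^2 = (1-lambda) s_pooled,i^2 + lambda s0^2 with s0^2 the median
    pooled variance over probes.
    """
    design.validate()
    X_f = table[design.fusion_samples].to_numpy(dtype=float)
    X_d = table[design.dam_samples].to_numpy(dtype=float)
    return _shrunken_t(X_f, X_d, shrinkage_weight)


# ---------------------------------------------------------------------------
# moving average and region detection (numpy internals shared with the FDR)
# ---------------------------------------------------------------------------

def _probe_segments(table: pd.DataFrame, max_gap_bp: int) -> list[tuple[int, int]]:
    """Half-open index ranges of probes not separated by chromosome
    boundaries or inter-probe gaps (next.start - prev.end) > max_gap_bp."""
    chroms = table["chrom"].to_numpy()
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    n = len(table)
    if n == 0:
        return []
    breaks = [0]
    for i in range(1, n):
        if chroms[i] != chroms[i - 1] or starts[i] - ends[i - 1] > max_gap_bp:
            breaks.append(i)
    breaks.append(n)
    return [(breaks[k], breaks[k + 1]) for k in range(len(breaks) - 1)]


def _moving_average_segmented(values: np.ndarray,
                              segments: Sequence[tuple[int, int]],
                              window: int) -> np.ndarray:
    """Centered moving mean within each segment; truncated at segment edges."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i0, i1 in segments:
        seg = values[i0:i1]
        m = seg.size
        cs = np.concatenate(([0.0], np.cumsum(seg)))
        idx = np.arange(m)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, m)
        out[i0:i1] = (cs[hi] - cs[lo]) / (hi - lo)
    return out


def moving_average(table: pd.DataFrame, t_stat: np.ndarray,
                   window: int = 5, max_gap_bp: int = 300) -> np.ndarray:
    """Centered moving average of the probe statistic along the tiling."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    segments = _probe_segments(table, max_gap_bp)
    return _moving_average_segmented(np.asarray(t_stat, dtype=float),
                                     segments, window)


def _find_runs(ma: np.ndarray, segments: Sequence[tuple[int, int]],
               cutoff: float, min_probes: int,
               bridge_below_cutoff: bool = False) -> list[tuple[int, int]]:
    """Maximal runs of probes with MA >= cutoff inside segments; runs with
    >= min_probes probes are returned as half-open index ranges."""
    runs: list[tuple[int, int]] = []
    above = ma >= cutoff
    for i0, i1 in segments:
        seg = above[i0:i1]
        if not seg.any():
            continue
        d = np.diff(seg.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if seg[0]:
            starts = np.concatenate(([0], starts))
        if seg[-1]:
            ends = np.concatenate((ends, [seg.size]))
        seg_runs = [(i0 + a, i0 + b) for a, b in zip(starts, ends)]
        if bridge_below_cutoff and len(seg_runs) > 1:
            # alternative region rule: bridge sub-cutoff probes within the
            # segment, min_probes then counts all probes in the merged span
            seg_runs = [(seg_runs[0][0], seg_runs[-1][1])]
        runs.extend((a, b) for a, b in seg_runs if b - a >= min_probes)
    return runs


def call_peaks(table: pd.DataFrame, ma: np.ndarray,
               params: PeakCallParams, name: str = "peaks") -> PeakSet:
    """Detect peaks: >= min_probes consecutive probes with MA >= ma_cutoff.

    The peak spans first-probe start to last-probe end; the summit is
    the median probe midpoint; max_ma_stat is the run maximum.
    """
    segments = _probe_segments(table, params.max_gap_bp)
    runs = _find_runs(np.asarray(ma), segments, params.ma_cutoff,
                      params.min_probes, params.bridge_below_cutoff)
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    chroms = table["chrom"].to_numpy()
    peaks = []
    for k, (a, b) in enumerate(runs):
        mids = (starts[a:b] + ends[a:b]) / 2.0
        peaks.append(
            Peak(
                interval=Interval(str(chroms[a]), int(starts[a]), int(ends[b - 1]),
                                  ".", f"{name}_{k + 1}"),
                n_probes=b - a,
                max_ma_stat=float(np.max(ma[a:b])),
                summit_bp=int(np.median(mids)),
            )
        )
    return PeakSet(name, peaks)


def run_peak_calling(table: pd.DataFrame, design: SampleDesign,
                     params: PeakCallParams, name: str = "peaks",
                     normalized: bool = False) -> PeakSet:
    """normalize -> probe statistic -> moving average -> region detection."""
    table = validate_table(table)
    if not normalized:
        table = quantile_normalize(table)
    t = probe_statistic(table, design, params.shrinkage_weight)
    ma = moving_average(table, t, params.ma_window_probes, params.max_gap_bp)
    return call_peaks(table, ma, params, name=name)


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    """Observed peaks annotated with per-peak FDR, plus the FDR curve."""

    peaks: PeakSet
    fdr_at_cutoff: float          # at params.ma_cutoff
    curve: pd.DataFrame           # columns: cutoff, n_observed, mean_null, fdr
    n_permutations_used: int


def _balanced_relabelings(samples: list[str], n_fusion: int,
                          n_max: int, seed: int) -> list[list[str]]:
    """All distinct assignments of n_fusion samples to 'fusion', excluding
    the identity, shuffled under the seed, truncated to n_max."""
    all_combos = [set(c) for c in itertools.combinations(samples, n_fusion)]
    identity = set(samples[:n_fusion])
    combos = [c for c in all_combos if c != identity]
    rng = np.random.default_rng(seed)
    rng.shuffle(combos)
    return [sorted(c) for c in combos[:n_max]]


def estimate_fdr(table: pd.DataFrame, design: SampleDesign,
                 params: PeakCallParams, name: str = "peaks") -> FdrResult:
    """Empirical FDR of peak calls by balanced label permutation.

    Condition labels are permuted across samples (all distinct balanced
    relabelings up to n_permutations, seeded); the statistic -> moving
    average -> region detection chain is re-run per permutation.
    FDR(cutoff) = mean permuted peak count at cutoff / observed count,
    capped at 1. Each observed peak is annotated with the FDR at its own
    max moving-average statistic.
    """
    if params.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    design.validate()
    table = validate_table(table)
    table = quantile_normalize(table)
    segments = _probe_segments(table, params.max_gap_bp)

    fusion = design.fusion_samples
    dam = design.dam_samples
    ordered = fusion + dam
    X = table[ordered].to_numpy(dtype=float)
    n_f = len(fusion)

    def peak_max_stats(cols_fusion: list[int]) -> np.ndarray:
        mask = np.zeros(len(ordered), dtype=bool)
        mask[cols_fusion] = True
        t = _shrunken_t(X[:, mask], X[:, ~mask], params.shrinkage_weight)
        ma = _moving_average_segmented(t, segments, params.ma_window_probes)
        runs = _find_runs(ma, segments, params.ma_cutoff, params.min_probes,
                          params.bridge_below_cutoff)
        return np.array([ma[a:b].max() for a, b in runs], dtype=float)

    observed = run_peak_calling(table, design, params, name=name,
                                normalized=True)
    obs_max = np.array([p.max_ma_stat for p in observed], dtype=float)

    relabelings = _balanced_relabelings(ordered, n_f,
                                        params.n_permutations, params.seed)
    if not relabelings:
        raise ValueError("no non-identity balanced relabelings possible")
    col_index = {s: i for i, s in enumerate(ordered)}
    null_max: list[np.ndarray] = []
    for combo in relabelings:
        null_max.append(peak_max_stats([col_index[s] for s in combo]))
    n_perm = len(relabelings)

    def fdr_at(cutoff: float) -> tuple[int, float, float]:
        n_obs = int((obs_max >= cutoff).sum())
        mean_null = float(np.mean([(nm >= cutoff).sum() for nm in null_max]))
        if n_obs == 0:
            fdr = 0.0 if mean_null == 0 else 1.0
        else:
            fdr = min(1.0, mean_null / n_obs)
        return n_obs, mean_null, fdr

    cutoffs = np.unique(np.concatenate(([params.ma_cutoff], obs_max)))
    rows = []
    for c in cutoffs:
        n_obs, mean_null, fdr = fdr_at(float(c))
        rows.append({"cutoff": float(c), "n_observed": n_obs,
                     "mean_null": mean_null, "fdr": fdr})
    curve = pd.DataFrame(rows)

    fdr_lookup = dict(zip(curve["cutoff"], curve["fdr"]))
    annotated = [replace(p, fdr=fdr_lookup[p.max_ma_stat]) for p in observed]
    _, _, fdr0 = fdr_at(params.ma_cutoff)
    return FdrResult(
        peaks=PeakSet(observed.name, annotated),
        fdr_at_cutoff=fdr0,
        curve=curve,
        n_permutations_used=n_perm,
    )
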