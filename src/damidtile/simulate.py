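"""Synthetic DamID promoter-array studies with recorded ground truth.

A simulated study emulates the real experimental design end to end:

* an i.i.d. uniform ACGT genome with gene models whose basal regulatory
  domains (6.5 kb upstream / 2.5 kb downstream of the TSS) do not
  overlap;
* probes of ~25 bp tiled every ~35 bp across promoter windows only
  (intergenic territory is probe-free, as on a promoter array, which
  exercises the max-gap logic in peak calling);
* planted binding peaks spanning at least 8 probes, organised as an
  A/B/C structure between a wild-type and a mutant factor (A: WT-only,
  B: overlapping-but-jittered shared peaks, C: mutant-only);
* exact motif words (e.g. the NKE, AAGTG) written into the genome
  inside a configurable fraction of each factor's true peaks;
* replicate log2 probe intensities: a per-probe baseline shared across
  samples plus the peak effect for Dam-fusion samples plus Gaussian
  noise; Dam-only samples carry baseline and noise but no signal.

The generator is fully deterministic under a fixed seed, and the truth
tables it records make every downstream stage testable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arrays import COORD_COLUMNS, Peak, PeakSet, SampleDesign, save_intensity_table
from .genome import GenomeSequence, Interval, MotifWord, read_fasta, reverse_complement, write_fasta

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genome",
    "plant_peaks",
    "simulate_intensities",
    "simulate_study",
    "write_study",
    "read_study",
]

DEFAULT_MOTIF_WORDS = {"NKE": "AAGTG", "GATA": "GATAA",
                       "NF1like": "TGCCAA", "HOXlike": "TAATC"}

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Stated world of a default synthetic study.

    Defaults follow the experimental design being emulated: ~35 bp probe
    spacing over 6.5 kb + 2.5 kb promoter windows, biological triplicate
    fusion and Dam-only samples, log2 effect size 2.0 with probe noise
    SD 0.5, peaks 400-1200 bp wide (>= 8 probes), an A/B/C plan totalling
    100 planted regions on a 2 Mb / 200 gene genome, and an NKE plant
    rate of 0.79 (the observed fraction of WT peaks carrying the word).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 200
    probe_spacing_bp: int = 35
    probe_length_bp: int = 25
    promoter_upstream_bp: int = 6500
    promoter_downstream_bp: int = 2500
    n_peaks_a: int = 40
    n_peaks_b: int = 30
    n_peaks_c: int = 30
    peak_width_min_bp: int = 400
    peak_width_max_bp: int = 1200
    min_probes_per_peak: int = 8
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.0
    n_replicates: int = 3
    motif_plant_rates: dict = field(default_factory=lambda: {"NKE": 0.79})
    motif_words: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_WORDS))
    signal_shape: str = "flat"  # or "triangular"
    wt_name: str = "WT"
    mut_name: str = "MUT"

    def __post_init__(self) -> None:
        if self.signal_shape not in ("flat", "triangular"):
            raise ValueError("signal_shape must be 'flat' or 'triangular'")
        for m in self.motif_plant_rates:
            if m not in self.motif_words:
                raise ValueError(f"plant rate given for unknown motif {m!r}")
        if self.peak_width_min_bp < self.min_probes_per_peak * self.probe_spacing_bp - self.probe_spacing_bp:
            raise ValueError("peak_width_min_bp too small to span min_probes_per_peak probes")

    @property
    def window_bp(self) -> int:
        return self.promoter_upstream_bp + self.promoter_downstream_bp


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus its ground truth."""

    config: SimulationConfig
    genome: GenomeSequence
    genes: pd.DataFrame          # gene_id, chrom, strand, tss, tes
    probes: pd.DataFrame         # probe_id, chrom, start, end
    intensities: dict            # factor -> intensity table (incl. dam_only cols)
    designs: dict                # factor -> SampleDesign
    truth: dict                  # factor -> PeakSet (peak names carry set label)
    truth_table: pd.DataFrame    # name, factor, set_label, chrom, start, end + planted_<motif>

    def probe_territory(self, gap: int = 300) -> list[Interval]:
        """Merged probe-covered blocks (the array's effective territory);
        probes within ``gap`` bp count as contiguous coverage."""
        from .peaksets import merge_intervals
        ivs = [Interval(r.chrom, int(r.start), int(r.end))
               for r in self.probes.itertuples(index=False)]
        return merge_intervals(ivs, gap=gap)


# ---------------------------------------------------------------------------
# genome + gene models + probe tiling
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return _LETTERS[rng.integers(0, 4, size=n)]


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[GenomeSequence, pd.DataFrame, dict]:
    """I.i.d. uniform ACGT genome plus non-overlapping promoter windows.

    Gene promoter windows (upstream + downstream around the TSS, equal to
    the basal regulatory domain at defaults) are placed per chromosome by
    random-gap allocation: window order is fixed, the slack outside the
    windows is split uniformly at random into inter-window gaps. This is
    robust at high packing density; if the windows cannot fit, an error
    suggests a longer genome.

    Returns the genome, the gene table and the raw per-chromosome byte
    arrays (kept mutable so peaks can plant motif words later).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    raw = {c: _random_sequence(rng, config.chrom_length_bp) for c in chrom_names}

    # spread genes over chromosomes as evenly as possible
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    W = config.window_bp
    rows = []
    gene_idx = 0
    for c, n_g in zip(chrom_names, per_chrom):
        slack = config.chrom_length_bp - n_g * W
        if slack < 0:
            raise ValueError(
                f"cannot place {n_g} promoter windows of {W} bp on a "
                f"{config.chrom_length_bp} bp chromosome; use a longer genome"
            )
        # split slack into n_g + 1 gaps uniformly at random
        if n_g == 0:
            continue
        cuts = np.sort(rng.integers(0, slack + 1, size=n_g))
        gaps = np.diff(np.concatenate(([0], cuts)))
        pos = 0
        for g in range(n_g):
            pos += int(gaps[g])
            w_start = pos
            pos += W
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss = w_start + config.promoter_upstream_bp
                tes = min(tss + int(rng.integers(2000, 10001)),
                          config.chrom_length_bp)
            else:
                tss = w_start + config.promoter_downstream_bp
                tes = max(tss - int(rng.integers(2000, 10001)), 0)
            gene_idx += 1
            rows.append({"gene_id": f"gene{gene_idx}", "chrom": c,
                         "strand": strand, "tss": tss, "tes": tes,
                         "window_start": w_start, "window_end": w_start + W})
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                        "tes", "window_start", "window_end"])
    genome = GenomeSequence({c: raw[c].tobytes().decode("ascii")
                             for c in chrom_names})
    return genome, genes, raw


def tile_probes(config: SimulationConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Tile probes across each promoter window at the configured spacing."""
    rows = []
    for g in genes.itertuples(index=False):
        pos = g.window_start
        while pos + config.probe_length_bp <= g.window_end:
            rows.append((f"p_{g.chrom}_{pos}", g.chrom, pos,
                         pos + config.probe_length_bp))
            pos += config.probe_spacing_bp
    probes = pd.DataFrame(rows, columns=COORD_COLUMNS)
    return probes.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# peak planting (A/B/C structure) and motif planting
# ---------------------------------------------------------------------------

def _scrub_word(raw: np.ndarray, word: str, start: int, end: int,
                rng: np.random.Generator, max_rounds: int = 100) -> None:
    """Remove every chance occurrence of `word` (both strands) from
    raw[start:end] by re-randomizing the middle base of each occurrence;
    iterates because a mutation can create a new occurrence."""
    k = len(word)
    rc = reverse_complement(word)
    lo = max(0, start - (k - 1))
    hi = min(raw.size, end + (k - 1))
    for _ in range(max_rounds):
        seg = raw[lo:hi].tobytes().decode("ascii")
        hits = []
        for w in {word, rc}:
            p = seg.find(w)
            while p != -1:
                hits.append(p)
                p = seg.find(w, p + 1)
        if not hits:
            return
        for p in hits:
            pos = lo + p + k // 2
            current = raw[pos]
            choices = _LETTERS[_LETTERS != current]
            raw[pos] = choices[rng.integers(0, choices.size)]
    raise RuntimeError("failed to scrub word occurrences after max rounds")


def _make_peak(name: str, chrom: str, start: int, end: int) -> Peak:
    return Peak(Interval(chrom, start, end, ".", name),
                n_probes=0, max_ma_stat=float("nan"),
                summit_bp=(start + end) // 2)


def plant_peaks(config: SimulationConfig, genes: pd.DataFrame,
                probes: pd.DataFrame, raw_genome: dict,
                rng: np.random.Generator | None = None
                ) -> tuple[dict, pd.DataFrame]:
    """Plant true binding peaks with an A/B/C structure and motif words.

    One planted region per randomly chosen gene window; B regions get a
    jittered-but-overlapping copy in the mutant set. Motif words are
    written into the genome (in the raw byte arrays, in place) inside a
    configured fraction of each factor's true peaks, at uniform-random
    offsets that avoid overlapping previously planted words; the planted
    strand is random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_total = config.n_peaks_a + config.n_peaks_b + config.n_peaks_c
    if n_total > len(genes):
        raise ValueError(
            f"cannot place {n_total} peaks in {len(genes)} gene windows "
            "without overlap; increase n_genes or reduce the peak plan"
        )
    win_idx = rng.choice(len(genes), size=n_total, replace=False)
    labels = (["A"] * config.n_peaks_a + ["B"] * config.n_peaks_b
              + ["C"] * config.n_peaks_c)

    probe_starts = {c: grp["start"].to_numpy()
                    for c, grp in probes.groupby("chrom")}
    probe_ends = {c: grp["end"].to_numpy()
                  for c, grp in probes.groupby("chrom")}

    def n_probes_covered(chrom: str, start: int, end: int) -> int:
        s, e = probe_starts[chrom], probe_ends[chrom]
        return int(np.sum((s < end) & (e > start)))

    wt_peaks: list[Peak] = []
    mut_peaks: list[Peak] = []
    records = []
    counters = {"A": 0, "B": 0, "C": 0}
    for gi, label in zip(win_idx, labels):
        g = genes.iloc[int(gi)]
        width = int(rng.integers(config.peak_width_min_bp,
                                 config.peak_width_max_bp + 1))
        width = min(width, int(g.window_end - g.window_start))
        start = int(rng.integers(g.window_start, g.window_end - width + 1))
        end = start + width
        assert n_probes_covered(g.chrom, start, end) >= config.min_probes_per_peak
        counters[label] += 1
        name = f"{label}_{counters[label]}"
        rec = {"name": name, "factor": "", "set_label": label,
               "chrom": g.chrom, "start": start, "end": end,
               "source_gene": g.gene_id}
        if label == "A":
            wt_peaks.append(_make_peak(name, g.chrom, start, end))
            records.append({**rec, "factor": config.wt_name})
        elif label == "C":
            mut_peaks.append(_make_peak(name, g.chrom, start, end))
            records.append({**rec, "factor": config.mut_name})
        else:  # B: overlapping pair, mutant copy jittered within the window
            wt_peaks.append(_make_peak(name, g.chrom, start, end))
            records.append({**rec, "factor": config.wt_name})
            max_shift = width // 3
            shift = int(rng.integers(-max_shift, max_shift + 1))
            m_start = max(int(g.window_start), start + shift)
            m_end = min(int(g.window_end), m_start + width)
            m_start = m_end - width
            if n_probes_covered(g.chrom, m_start, m_end) < config.min_probes_per_peak:
                m_start, m_end = start, end  # fall back to identical coords
            mut_peaks.append(_make_peak(name, g.chrom, m_start, m_end))
            records.append({**rec, "factor": config.mut_name,
                            "start": m_start, "end": m_end})

    truth_table = pd.DataFrame(records)

    # Motif planting with controlled presence: the configured rate is the
    # fraction of a factor's true peaks CONTAINING >= 1 occurrence of the
    # word, so chance occurrences of the word inside planted regions are
    # scrubbed first (short words occur by chance in most kb-scale
    # regions), then the word is written into a Bernoulli(rate) subset.
    # B pairs get a single draw, the word placed in the WT/mutant
    # intersection so both copies carry it.
    regions: list[dict] = []  # one entry per planted locus
    if truth_table.empty:
        truth_table = pd.DataFrame(columns=["name", "factor", "set_label",
                                            "chrom", "start", "end",
                                            "source_gene"])
        for motif_name in config.motif_plant_rates:
            truth_table[f"planted_{motif_name}"] = pd.Series(dtype=int)
        return ({config.wt_name: PeakSet(config.wt_name, []),
                 config.mut_name: PeakSet(config.mut_name, [])}, truth_table)
    for name, grp in truth_table.groupby("name", sort=False):
        chrom = grp["chrom"].iloc[0]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        regions.append({
            "name": name, "chrom": chrom,
            "span": (int(starts.min()), int(ends.max())),
            "core": (int(starts.max()), int(ends.min())),  # intersection
            "rows": grp.index.tolist(),
        })

    words = {m: config.motif_words[m] for m in config.motif_plant_rates}
    for reg in regions:
        for word in words.values():
            _scrub_word(raw_genome[reg["chrom"]], word,
                        reg["span"][0], reg["span"][1], rng)

    planted_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in raw_genome}
    for motif_name, rate in config.motif_plant_rates.items():
        word = words[motif_name]
        k = len(word)
        col = f"planted_{motif_name}"
        truth_table[col] = 0
        for reg in regions:
            if rng.random() >= rate:
                continue
            chrom = reg["chrom"]
            lo, hi = reg["core"]
            if hi - lo < k:
                lo, hi = reg["span"]
            placed = False
            for _ in range(50):
                off = int(rng.integers(lo, hi - k + 1))
                if any(off < e and off + k > s
                       for s, e in planted_spans[chrom]):
                    continue
                w = word if rng.random() < 0.5 else reverse_complement(word)
                raw_genome[chrom][off:off + k] = np.frombuffer(
                    w.encode("ascii"), dtype=np.uint8)
                planted_spans[chrom].append((off, off + k))
                placed = True
                break
            if placed:
                truth_table.loc[reg["rows"], col] = 1

    truth = {
        config.wt_name: PeakSet(config.wt_name, wt_peaks),
        config.mut_name: PeakSet(config.mut_name, mut_peaks),
    }
    return truth, truth_table


# ---------------------------------------------------------------------------
# replicate intensities
# ---------------------------------------------------------------------------

def _inpeak_weights(probes: pd.DataFrame, peaks: PeakSet,
                    shape: str) -> np.ndarray:
    """Per-probe signal weight: 1 inside a peak (flat) or a triangular
    ramp peaking at the peak centre."""
    w = np.zeros(len(probes))
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    mids = (starts + ends) / 2.0
    for p in peaks:
        mask = (chroms == p.chrom) & (starts < p.end) & (ends > p.start)
        if shape == "flat":
            w[mask] = np.maximum(w[mask], 1.0)
        else:
            centre = (p.start + p.end) / 2.0
            half = (p.end - p.start) / 2.0
            tri = np.clip(1.0 - np.abs(mids[mask] - centre) / half, 0.0, 1.0)
            w[mask] = np.maximum(w[mask], tri)
    return w


def simulate_intensities(config: SimulationConfig, probes: pd.DataFrame,
                         truth: dict,
                         rng: np.random.Generator | None = None
                         ) -> tuple[dict, dict]:
    """Log2 intensity tables per factor (fusion + shared Dam-only columns).

    log2 intensity = baseline(probe) + effect * inpeak(probe) + N(0, sd)
    for fusion samples; baseline + noise for Dam-only. The baseline is
    drawn once per probe and shared across all samples and factors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(probes)
    baseline = rng.normal(config.baseline_mean_log2,
                          config.baseline_sd_log2, size=n)
    dam_cols = {}
    for r in range(config.n_replicates):
        dam_cols[f"dam_only_{r + 1}"] = baseline + rng.normal(
            0.0, config.noise_sd_log2, size=n)

    tables, designs = {}, {}
    for factor, peaks in truth.items():
        w = _inpeak_weights(probes, peaks, config.signal_shape)
        table = probes.copy()
        cond = {}
        for r in range(config.n_replicates):
            col = f"{factor}_fusion_{r + 1}"
            table[col] = (baseline + config.effect_size_log2 * w
                          + rng.normal(0.0, config.noise_sd_log2, size=n))
            cond[col] = "fusion"
        for col, vals in dam_cols.items():
            table[col] = vals
            cond[col] = "dam_only"
        tables[factor] = table
        designs[factor] = SampleDesign(cond)
    return tables, designs


# ---------------------------------------------------------------------------
# orchestration and study I/O
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a full study: genome, genes, probes, truth, intensities."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genome, genes, raw = simulate_genome(config, rng)
    probes = tile_probes(config, genes)
    truth, truth_table = plant_peaks(config, genes, probes, raw, rng)
    # rebuild genome strings after in-place motif planting
    genome = GenomeSequence({c: raw[c].tobytes().decode("ascii") for c in raw})
    tables, designs = simulate_intensities(config, probes, truth, rng)
    return SimulatedStudy(config, genome, genes, probes, tables, designs,
                          truth, truth_table)


def write_study(study: SimulatedStudy, directory: str | Path) -> None:
    """Write the study to disk: FASTA, gene/probe/intensity/design tables,
    truth BED-like table and the generating configuration."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, d / "genome.fasta")
    study.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    study.probes.to_csv(d / "probes.bed", sep="\t", index=False, header=False,
                        columns=["chrom", "start", "end", "probe_id"])
    for factor, table in study.intensities.items():
        save_intensity_table(table, d / f"intensities_{factor}.tsv")
        study.designs[factor].to_tsv(d / f"design_{factor}.tsv")
    study.truth_table.to_csv(d / "truth.tsv", sep="\t", index=False)
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(study.config), fh, sort_keys=False)


def read_study(directory: str | Path) -> SimulatedStudy:
    """Re-read a study written by :func:`write_study`."""
    d = Path(directory)
    with open(d / "config.yaml") as fh:
        config = SimulationConfig(**yaml.safe_load(fh))
    genome = read_fasta(d / "genome.fasta")
    genes = pd.read_csv(d / "genes.tsv", sep="\t")
    probes = pd.read_csv(d / "probes.bed", sep="\t", header=None,
                         names=["chrom", "start", "end", "probe_id"])
    probes = probes[COORD_COLUMNS]
    truth_table = pd.read_csv(d / "truth.tsv", sep="\t")
    tables, designs, truth = {}, {}, {}
    for factor in (config.wt_name, config.mut_name):
        tables[factor] = pd.read_csv(d / f"intensities_{factor}.tsv", sep="\t")
        designs[factor] = SampleDesign.from_tsv(d / f"design_{factor}.tsv")
        sub = truth_table[truth_table["factor"] == factor]
        truth[factor] = PeakSet(factor, [
            _make_peak(str(rec["name"]), str(rec["chrom"]),
                       int(rec["start"]), int(rec["end"]))
            for rec in sub.to_dict("records")
        ])
    return SimulatedStudy(config, genome, genes, probes, tables, designs,
                          truth, truth_table)
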