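"""Seeded synthetic ATAC-seq time-course generator.

Emulates an 8-timepoint x 2-replicate differentiation experiment: a peak
universe whose accessibility follows planted temporal trajectories, a
matched expression matrix whose signature genes turn on a fixed lag after
chromatin opens, per-timepoint transposase-insertion tracks with footprint
protection inside bound motifs, a TF motif set with planted promoter
occurrences defining a ground-truth regulatory network, and a rising
NK-fraction phenotype trajectory.

Peak trajectory model (mean counts mu_p(t), before size factors):

* cluster I  — decreasing logistic, open early, closing at the interim stage;
* cluster II — increasing logistic with midpoint at ``onset_day_accessibility``;
* cluster III — flat low mean times a shared transient log2 bump peaking
  mid-course: elements transiently accessible in progenitors, whose
  accessibility varies between timepoints but not between replicates —
  the signature the intrinsic analysis selects for;
* stable     — flat high, the conserved-peak set;
* background — flat at baseline. The background majority mirrors real peak
  universes (differential peaks are a small minority) and is what makes
  median-of-ratios size factors identifiable: with mostly-changing peaks
  the median ratio tracks the trend instead of sequencing depth.

Logistic shapes are min-max rescaled over the day grid so the realized
fold between a peak's least and most accessible timepoints equals its
drawn fold.

Counts are negative binomial with Var = mu + alpha * mu^2, scaled by
per-sample size factors drawn log-uniform in [0.7, 1.4]. Each sample's
trajectories are evaluated at its nominal day plus a small pseudotime
jitter, modelling the asynchrony of replicate differentiation cultures;
without it, replicate pairs would be unrealistically tight relative to
adjacent timepoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from chromdyn.io import (
    CountMatrix,
    ExpressionMatrix,
    GenomicInterval,
    InsertionTrack,
    MotifHit,
    MotifSet,
    PWM,
    PeakSet,
    ValidationError,
    normalize_pfm,
    reverse_complement,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_jaspar,
    write_matrix,
)
from chromdyn.motifs import pwm_logodds

_BASES = np.array(list("ACGT"))

PEAK_WIDTH = 500
PEAK_SPACING = 800
GENE_SLOT = 2600
# keep embedded motifs (and their footprint windows) inside the peak
EMBED_MARGIN = 130


def logistic(t: np.ndarray | float, midpoint: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - midpoint) / scale))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study design."""

    seed: int = 0
    timepoints: tuple[int, ...] = (7, 14, 19, 21, 24, 26, 28, 35)
    n_replicates: int = 2
    n_diff_peaks: int = 640
    cluster_proportions: tuple[float, float, float] = (0.247, 0.697, 0.056)
    n_stable_peaks: int = 160
    n_background_peaks: int = 1600
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    fold_range: tuple[float, float] = (8.0, 64.0)
    onset_day_accessibility: float = 14.0
    expression_lag_days: float = 2.0
    phenotype_onset_day: float = 21.0
    n_tfs: int = 30
    n_decoy_tfs: int = 10
    n_planted_edges: int = 40
    motif_length_range: tuple[int, int] = (8, 12)
    footprint_protection: float = 0.4
    promoter_length: int = 2000
    # secondary knobs
    accessibility_steepness: float = 1.2      # days, cluster II logistic
    cluster_i_midpoint: float = 16.5
    cluster_i_steepness: float = 1.2
    cluster_iii_amplitude: float = 2.0        # log2 units, day-effect size
    cluster_iii_peak_day: float = 20.0
    cluster_iii_width: float = 4.0            # days
    cluster_iii_coherence: float = 0.8        # shared vs peak-specific variation
    cluster_iii_mean: float = 50.0
    sample_time_jitter_sd: float = 0.5        # days, replicate asynchrony
    stable_mean_factor: float = 2.0
    expression_noise_sd: float = 0.2          # log2 units
    expression_steepness: float = 2.0
    tf_bump_width: float = 2.0                # days
    phenotype_midpoint_offset: float = 5.5    # days past phenotype_onset_day
    phenotype_steepness: float = 2.2
    phenotype_noise_sd: float = 0.01
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    motif_embed_prob: float = 0.5
    n_signature_genes: int = 60
    n_background_genes: int = 60
    edge_same_day_frac: float = 0.6           # planted edges within one day's TFs

    def validate(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValidationError("cluster_proportions must sum to 1")
        t = self.timepoints
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if not (t[0] <= self.onset_day_accessibility <= t[-1]):
            raise ValidationError("onset_day_accessibility outside timepoint range")
        if not (t[0] <= self.phenotype_onset_day <= t[-1]):
            raise ValidationError("phenotype_onset_day outside timepoint range")
        for name in ("n_diff_peaks", "n_stable_peaks", "n_tfs", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.baseline_mean <= 0 or self.nb_dispersion < 0:
            raise ValidationError("baseline_mean must be > 0 and dispersion >= 0")
        if self.motif_length_range[1] > PEAK_WIDTH:
            raise ValidationError("motifs longer than peaks")
        if self.n_decoy_tfs >= self.n_tfs:
            raise ValidationError("need at least one non-decoy TF")
        if not (0 <= self.footprint_protection < 1):
            raise ValidationError("footprint_protection must be in [0, 1)")

    def cluster_sizes(self) -> tuple[int, int, int]:
        sizes = [round(self.n_diff_peaks * p) for p in self.cluster_proportions]
        sizes[-1] = self.n_diff_peaks - sum(sizes[:-1])
        return tuple(sizes)


@dataclass
class SyntheticDataset:
    """The generated fixture plus its ground truth."""

    config: SimulationConfig
    genome: dict[str, str]
    peaks: PeakSet
    counts: CountMatrix
    tss: PeakSet
    motifs: MotifSet
    motif_counts: dict[str, tuple[str, np.ndarray]]
    planted_hits: list[MotifHit]
    planted_network: list[tuple[str, str, str]]  # (source TF, target TF, pcc class)
    expression: ExpressionMatrix
    tracks: dict[int, InsertionTrack]
    phenotype: pd.Series
    truth: dict
    tf_gene_map: dict[str, str]

    def hits_for(self, motif_id: str, chrom: str | None = None) -> list[MotifHit]:
        return [
            h
            for h in self.planted_hits
            if h.motif_id == motif_id and (chrom is None or h.interval.chrom == chrom)
        ]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray("".join(_BASES[rng.integers(0, 4, n)]), "ascii")


def sample_negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB draw with Var = mu + alpha*mu^2 (gamma-Poisson); Poisson when alpha=0."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def _embed(
    seq: bytearray,
    region_start: int,
    region_end: int,
    word: str,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
) -> int | None:
    """Place ``word`` at a random non-overlapping offset; return its start."""
    L = len(word)
    if region_end - region_start < L:
        return None
    for _ in range(25):
        pos = int(rng.integers(region_start, region_end - L + 1))
        if all(pos + L <= s or pos >= e for s, e in occupied):
            seq[pos : pos + L] = bytes(word, "ascii")
            occupied.append((pos, pos + L))
            return pos
    return None


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset; all randomness flows from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    days = np.array(config.timepoints, dtype=float)
    n_t = len(days)

    # --- peak universe -----------------------------------------------------
    n_i, n_ii, n_iii = config.cluster_sizes()
    n_peaks = config.n_diff_peaks + config.n_stable_peaks + config.n_background_peaks
    labels = (
        ["I"] * n_i
        + ["II"] * n_ii
        + ["III"] * n_iii
        + ["stable"] * config.n_stable_peaks
        + ["background"] * config.n_background_peaks
    )
    order = rng.permutation(n_peaks)  # interleave clusters along the chromosome
    labels = [labels[i] for i in order]

    peak_ivs = []
    for i in range(n_peaks):
        start = 200 + i * PEAK_SPACING
        peak_ivs.append(
            GenomicInterval(
                "chrA", start, start + PEAK_WIDTH, f"peak_{i:04d}", ".", PEAK_WIDTH // 2
            )
        )
    peaks = PeakSet(peak_ivs)
    peak_names = [iv.name for iv in peak_ivs]
    label_by_peak = dict(zip(peak_names, labels))

    # --- trajectories ------------------------------------------------------
    lo, hi = config.fold_range
    folds = np.exp(rng.uniform(np.log(lo), np.log(hi), n_peaks))
    base = config.baseline_mean

    def _unit_over_grid(fn):
        vals = fn(days)
        vmin, vmax = vals.min(), vals.max()
        return lambda t: np.clip((fn(t) - vmin) / (vmax - vmin), 0.0, 1.0)

    rise = _unit_over_grid(
        lambda t: logistic(t, config.onset_day_accessibility, config.accessibility_steepness)
    )
    fall = _unit_over_grid(
        lambda t: 1.0 - logistic(t, config.cluster_i_midpoint, config.cluster_i_steepness)
    )

    def _bump(t):
        t = np.asarray(t, dtype=float)
        return np.exp(
            -((t - config.cluster_iii_peak_day) ** 2) / (2 * config.cluster_iii_width**2)
        )

    # orthogonalize the transient against the opening/closing programs on
    # the grid so the three planted temporal patterns stay distinguishable
    _design = np.column_stack([np.ones(n_t), rise(days), fall(days)])
    _bv = _bump(days)
    _coef, *_ = np.linalg.lstsq(_design, _bv, rcond=None)
    _resid = _bv - _design @ _coef
    _rm, _rs = _resid.mean(), _resid.std()

    def transient(t):
        raw = _bump(t) - np.stack([np.ones_like(np.asarray(t, dtype=float)), rise(t), fall(t)], axis=-1) @ _coef
        return (raw - _rm) / _rs

    lab_arr = np.array(labels)
    masks = {lab: lab_arr == lab for lab in ("I", "II", "III", "stable", "background")}

    # cluster III = coherent transient + peak-specific day effects: variation
    # between timepoints but not between replicates, only partly shared
    coh = config.cluster_iii_coherence
    own_iii = rng.normal(0.0, 1.0, (int(masks["III"].sum()), n_t))

    def mu_at(t: float) -> np.ndarray:
        """Noise-free mean counts of every peak at continuous time t."""
        nearest = int(np.argmin(np.abs(days - t)))
        out = np.empty(n_peaks)
        out[masks["I"]] = base * (1.0 + (folds[masks["I"]] - 1.0) * fall(t))
        out[masks["II"]] = base * (1.0 + (folds[masks["II"]] - 1.0) * rise(t))
        effect = coh * transient(t) + np.sqrt(1.0 - coh**2) * own_iii[:, nearest]
        out[masks["III"]] = config.cluster_iii_mean * 2.0 ** (
            config.cluster_iii_amplitude * effect
        )
        out[masks["stable"]] = config.stable_mean_factor * base
        out[masks["background"]] = base
        return out

    mu = np.column_stack([mu_at(d) for d in days])  # nominal-day means

    # --- counts ------------------------------------------------------------
    sample_names, sample_days = [], []
    for d in config.timepoints:
        for r in range(1, config.n_replicates + 1):
            sample_names.append(f"d{d}_R{r}")
            sample_days.append(d)
    sf_lo, sf_hi = config.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi), len(sample_names)))
    jitter = rng.normal(0.0, config.sample_time_jitter_sd, len(sample_names))
    counts = np.zeros((n_peaks, len(sample_names)), dtype=np.int64)
    for j, d in enumerate(sample_days):
        counts[:, j] = sample_negative_binomial(
            rng, size_factors[j] * mu_at(d + jitter[j]), config.nb_dispersion
        )
    meta = pd.DataFrame(
        {
            "sample": sample_names,
            "timepoint": sample_days,
            "replicate": [s.split("_")[1] for s in sample_names],
        }
    ).set_index("sample")
    count_matrix = CountMatrix(
        values=pd.DataFrame(counts, index=peak_names, columns=sample_names),
        sample_meta=meta,
    )

    # --- TFs and motifs ----------------------------------------------------
    n_planted = config.n_tfs - config.n_decoy_tfs
    tf_names = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    planted_tfs, decoy_tfs = tf_names[:n_planted], tf_names[n_planted:]
    early_days = [d for d in config.timepoints if d <= config.cluster_i_midpoint]
    late_days = [d for d in config.timepoints if d > config.cluster_i_midpoint]
    n_early = n_planted // 2
    tf_day = {}
    for i, tf in enumerate(planted_tfs[:n_early]):
        tf_day[tf] = early_days[i % len(early_days)]
    # pair late TFs on the boundary and terminal days first so every such
    # day can host same-day regulator/target pairs
    late_order = late_days[:2] + late_days[-2:] + late_days[2:-2] if len(late_days) > 4 else late_days
    for i, tf in enumerate(planted_tfs[n_early:]):
        tf_day[tf] = late_order[i % len(late_order)]
    early_tfs = planted_tfs[:n_early]
    late_tfs = planted_tfs[n_early:]

    motif_counts: dict[str, tuple[str, np.ndarray]] = {}
    pwms, motif_of_tf = [], {}
    lmin, lmax = config.motif_length_range
    for i, tf in enumerate(tf_names):
        L = int(rng.integers(lmin, lmax + 1))
        consensus_idx = rng.integers(0, 4, L)
        cnt = np.ones((4, L))
        cnt[consensus_idx, np.arange(L)] = 17.0  # sharp, near-consensus motif
        motif_id = f"M{i + 1:03d}"
        motif_counts[motif_id] = (tf, cnt)
        pwms.append(PWM(motif_id, tf, normalize_pfm(cnt)))
        motif_of_tf[tf] = motif_id
    motifs = MotifSet(pwms)
    max_scores = {
        p.motif_id: float(pwm_logodds(p).max(axis=0).sum()) for p in motifs
    }

    # --- genome with embedded motifs --------------------------------------
    chr_a_len = 200 + n_peaks * PEAK_SPACING
    seq_a = _random_seq(rng, chr_a_len)
    occupied_by_peak: dict[str, list[tuple[int, int]]] = {n: [] for n in peak_names}
    planted_hits: list[MotifHit] = []
    hit_counter = 0

    cluster_of_tf = {tf: ("I" if tf in early_tfs else "II") for tf in planted_tfs}
    for tf in planted_tfs:
        pwm = motifs[motif_of_tf[tf]]
        target_label = cluster_of_tf[tf]
        for iv in peak_ivs:
            if label_by_peak[iv.name] != target_label:
                continue
            if rng.random() >= config.motif_embed_prob:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            word = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
            pos = _embed(
                seq_a,
                iv.start + EMBED_MARGIN,
                iv.end - EMBED_MARGIN,
                word,
                occupied_by_peak[iv.name],
                rng,
            )
            if pos is None:
                continue
            planted_hits.append(
                MotifHit(
                    pwm.motif_id,
                    GenomicInterval(
                        "chrA", pos, pos + pwm.length, f"hit_{hit_counter:05d}", strand
                    ),
                    strand,
                    max_scores[pwm.motif_id],
                )
            )
            hit_counter += 1

    # --- genes, TSS, promoters ---------------------------------------------
    gene_names = (
        tf_names
        + [f"NKG{i + 1:02d}" for i in range(config.n_signature_genes)]
        + [f"BG{i + 1:02d}" for i in range(config.n_background_genes)]
    )
    chr_p_len = len(gene_names) * GENE_SLOT
    seq_p = _random_seq(rng, chr_p_len)
    tss_ivs, promoter_span = [], {}
    for i, g in enumerate(gene_names):
        slot = i * GENE_SLOT
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = slot + config.promoter_length
            promoter_span[g] = (tss - config.promoter_length, tss)
        else:
            tss = slot + GENE_SLOT - config.promoter_length - 1
            promoter_span[g] = (tss, tss + config.promoter_length)
        tss_ivs.append(GenomicInterval("chrP", tss, tss + 1, g, strand))
    tss_set = PeakSet(tss_ivs)

    # --- planted regulatory edges ------------------------------------------
    # bias toward same-day regulator/target pairs so each timepoint's strict
    # network carries the intra-stage interconnections seen in the data
    by_day: dict[int, list[str]] = {}
    for tf, d in tf_day.items():
        by_day.setdefault(d, []).append(tf)
    multi_days = [d for d, tfs in by_day.items() if len(tfs) >= 2]
    chosen: set[tuple[str, str]] = set()
    n_same = int(round(config.n_planted_edges * config.edge_same_day_frac))
    attempts = 0
    day_cycle = 0
    while len(chosen) < n_same and attempts < 20 * config.n_planted_edges:
        attempts += 1
        d = multi_days[day_cycle % len(multi_days)]
        day_cycle += 1
        a, b = rng.choice(by_day[d], size=2, replace=False)
        chosen.add((str(a), str(b)))
    all_pairs = [(a, b) for a in planted_tfs for b in planted_tfs if a != b]
    while len(chosen) < min(config.n_planted_edges, len(all_pairs)):
        chosen.add(all_pairs[int(rng.integers(len(all_pairs)))])
    planted_edges = sorted(chosen)
    occupied_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_names}
    for src, tgt in planted_edges:
        pwm = motifs[motif_of_tf[src]]
        strand = "+" if rng.random() < 0.5 else "-"
        word = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
        s, e = promoter_span[tgt]
        pos = _embed(seq_p, s, e, word, occupied_by_gene[tgt], rng)
        if pos is None:  # promoter full (never at default sizes); force at edge
            pos = s
            seq_p[pos : pos + pwm.length] = bytes(word, "ascii")
        planted_hits.append(
            MotifHit(
                pwm.motif_id,
                GenomicInterval(
                    "chrP", pos, pos + pwm.length, f"hit_{hit_counter:05d}", strand
                ),
                strand,
                max_scores[pwm.motif_id],
            )
        )
        hit_counter += 1

    genome = {"chrA": seq_a.decode(), "chrP": seq_p.decode()}

    # --- expression ---------------------------------------------------------
    expr_onset = config.onset_day_accessibility + config.expression_lag_days
    clean = {}
    for g in gene_names:
        if g in tf_day:
            d = tf_day[g]
            clean[g] = 6.0 + 3.0 * np.exp(-((days - d) ** 2) / (2 * config.tf_bump_width**2))
        elif g in decoy_tfs:
            clean[g] = np.full(n_t, 4.0)
        elif g.startswith("NKG"):
            clean[g] = 6.0 + 3.0 * logistic(days, expr_onset, config.expression_steepness)
        else:
            clean[g] = np.full(n_t, 6.0)
    clean_df = pd.DataFrame(clean, index=config.timepoints).T
    noise = rng.normal(0.0, config.expression_noise_sd, clean_df.shape)
    expression = ExpressionMatrix(
        values=clean_df + noise, tf_flags=frozenset(tf_names)
    )

    # edge sign truth from the noise-free profiles
    network_truth = []
    for src, tgt in planted_edges:
        pcc = float(np.corrcoef(clean[src], clean[tgt])[0, 1])
        cls = "positive" if pcc > 0.4 else ("negative" if pcc < -0.4 else "none")
        network_truth.append((src, tgt, cls))

    # --- insertion tracks ---------------------------------------------------
    activity_rise = logistic(days, config.cluster_i_midpoint, config.accessibility_steepness)
    tf_activity = {
        tf: (1.0 - activity_rise if tf in early_tfs else activity_rise)
        for tf in planted_tfs
    }
    tf_of_motif = {v: k for k, v in motif_of_tf.items()}
    peak_hits_a = [h for h in planted_hits if h.interval.chrom == "chrA"]
    peak_idx_by_name = {n: i for i, n in enumerate(peak_names)}
    tracks: dict[int, InsertionTrack] = {}
    for ti, d in enumerate(config.timepoints):
        rate = np.zeros(chr_a_len)
        for iv in peak_ivs:
            i = peak_idx_by_name[iv.name]
            rate[iv.start : iv.end] = mu[i, ti] / config.baseline_mean
        for h in peak_hits_a:
            act = tf_activity[tf_of_motif[h.motif_id]][ti]
            hs, he = h.interval.start, h.interval.end
            rate[hs:he] *= 1.0 - config.footprint_protection * act
        tracks[d] = InsertionTrack(
            label=f"d{d}",
            data={"chrA": rng.poisson(rate), "chrP": np.zeros(chr_p_len, dtype=np.int64)},
        )

    # --- phenotype ----------------------------------------------------------
    phen_mid = config.phenotype_onset_day + config.phenotype_midpoint_offset
    phen = logistic(days, phen_mid, config.phenotype_steepness)
    phen = np.clip(phen + rng.normal(0.0, config.phenotype_noise_sd, n_t), 0.0, 1.0)
    phenotype = pd.Series(phen, index=list(config.timepoints), name="nk_fraction")

    truth = {
        "cluster_labels": label_by_peak,
        "onset_accessibility_day": config.onset_day_accessibility,
        "expression_onset_day": expr_onset,
        "expression_lag_days": config.expression_lag_days,
        "phenotype_onset_day": config.phenotype_onset_day,
        "phenotype_midpoint_day": phen_mid,
        "tf_day": tf_day,
        "decoy_tfs": decoy_tfs,
        "planted_edges": network_truth,
        "folds": dict(zip(peak_names, folds.tolist())),
        "size_factors": dict(zip(sample_names, size_factors.tolist())),
        "sample_time_jitter": dict(zip(sample_names, jitter.tolist())),
        "motif_of_tf": motif_of_tf,
    }

    return SyntheticDataset(
        config=config,
        genome=genome,
        peaks=peaks,
        counts=count_matrix,
        tss=tss_set,
        motifs=motifs,
        motif_counts=motif_counts,
        planted_hits=planted_hits,
        planted_network=network_truth,
        expression=expression,
        tracks=tracks,
        phenotype=phenotype,
        truth=truth,
        tf_gene_map={tf: tf for tf in tf_names},
    )


def simulate_insertion_track(
    length: int,
    rate: float,
    hit_starts: list[int],
    motif_length: int,
    protection: float,
    rng: np.random.Generator,
    chrom: str = "chrA",
) -> InsertionTrack:
    """Uniform-rate insertion track with protected motif cores.

    A controlled version of the generator's footprint model: flank rate
    ``rate`` everywhere, ``rate * (1 - protection)`` inside each motif core.
    """
    r = np.full(length, float(rate))
    for s in hit_starts:
        r[s : s + motif_length] *= 1.0 - protection
    return InsertionTrack(label="uniform", data={chrom: rng.poisson(r)})


def export_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write every piece of the dataset in its external format plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    write_bed(dataset.peaks, outdir / "peaks.bed")
    paths["peaks"] = "peaks.bed"
    write_bed(dataset.tss, outdir / "tss.bed")
    paths["tss"] = "tss.bed"
    write_fasta(dataset.genome, outdir / "genome.fa")
    paths["genome"] = "genome.fa"
    write_matrix(dataset.counts.values, outdir / "counts.tsv")
    paths["counts"] = "counts.tsv"
    write_matrix(dataset.expression.values, outdir / "expression.tsv")
    paths["expression"] = "expression.tsv"
    write_jaspar(dataset.motif_counts, outdir / "motifs.jaspar")
    paths["motifs"] = "motifs.jaspar"
    dataset.phenotype.to_frame().to_csv(outdir / "phenotype.tsv", sep="\t")
    paths["phenotype"] = "phenotype.tsv"
    with open(outdir / "tf_gene_map.tsv", "w") as fh:
        fh.write("tf\tgene\n")
        for tf, g in dataset.tf_gene_map.items():
            fh.write(f"{tf}\t{g}\n")
    paths["tf_gene_map"] = "tf_gene_map.tsv"
    for d, track in dataset.tracks.items():
        name = f"insertions_d{d}.bedgraph"
        write_bedgraph(track, outdir / name)
        paths[f"track_d{d}"] = name
    hits = pd.DataFrame(
        [
            {
                "chrom": h.interval.chrom,
                "start": h.interval.start,
                "end": h.interval.end,
                "name": h.interval.name,
                "score": h.score,
                "strand": h.strand,
                "motif_id": h.motif_id,
            }
            for h in dataset.planted_hits
        ]
    )
    hits.to_csv(outdir / "planted_hits.tsv", sep="\t", index=False)
    paths["planted_hits"] = "planted_hits.tsv"
    truth = dict(dataset.truth)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    paths["truth"] = "truth.json"
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(dataset.config), fh, indent=1)
    paths["config"] = "config.json"
    return paths
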