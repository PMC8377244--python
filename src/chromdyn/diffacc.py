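"""Count normalization and differential accessibility.

Normalization follows the median-of-ratios scheme: each sample's size
factor is the median across peaks of its counts divided by the per-peak
geometric mean, computed over peaks with no zero count. Differential
testing is a per-peak negative-binomial Wald test between two timepoint
groups with a method-of-moments dispersion pooled within groups, plus an
"intrinsic" score that contrasts between-timepoint with between-replicate
variability and is standardized into a z-score over all peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chromdyn.io import CountMatrix, PeakSet

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
INTRINSIC_EPS = 0.01

DEFAULT_THRESHOLDS = {"p": 0.01, "abs_log2_fc": 5.0, "fdr": 0.01, "z": 1.0}


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one per sample."""
    x = counts.values.values.astype(float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no peak has nonzero counts in all samples; "
            "add a pseudocount or filter samples"
        )
    ref = np.exp(np.log(x[all_nonzero]).mean(axis=1))
    factors = np.median(x[all_nonzero] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.sample_names, name="size_factor")


def normalize(
    counts: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), peaks x samples."""
    if list(factors.index) != counts.sample_names:
        factors = factors.reindex(counts.sample_names)
        if factors.isna().any():
            raise ValueError("size factors do not cover all samples")
    return np.log2(counts.values / factors + pseudocount)


def normalized_linear(
    counts: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """count / size_factor + pseudocount on the linear scale."""
    return counts.values / factors.reindex(counts.sample_names) + pseudocount


def pairwise_differential(
    counts: CountMatrix,
    group_a: int,
    group_b: int,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """NB Wald test of group_b vs group_a (timepoints), per peak.

    log2_fc is the log2 ratio of size-factor-normalized group means (with
    pseudocount); its standard error comes from the NB variance
    Var = mu + alpha*mu^2 with a pooled method-of-moments dispersion.
    """
    if factors is None:
        factors = estimate_size_factors(counts)
    sa = counts.samples_at(group_a)
    sb = counts.samples_at(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"groups need >=2 replicates (day {group_a}: {len(sa)}, "
            f"day {group_b}: {len(sb)})"
        )
    norm = (counts.values / factors.reindex(counts.sample_names)).astype(float)
    xa, xb = norm[sa].values, norm[sb].values
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    log2_fc = np.log2(mb + pseudocount) - np.log2(ma + pseudocount)

    # pooled method-of-moments dispersion: alpha = (s^2 - mu) / mu^2
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (va - ma) / np.square(ma)
        alpha_b = (vb - mb) / np.square(mb)
    alpha = np.nanmean(np.stack([alpha_a, alpha_b]), axis=0)
    alpha = np.clip(np.nan_to_num(alpha, nan=DISPERSION_FLOOR), DISPERSION_FLOOR, None)

    # delta-method SE of log2 of a group mean under the NB model
    def se2_log2_mean(m: np.ndarray, n: int) -> np.ndarray:
        var = m + alpha * np.square(m)
        return var / (n * np.square(m + pseudocount) * LN2**2)

    se = np.sqrt(se2_log2_mean(ma, xa.shape[1]) + se2_log2_mean(mb, xb.shape[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2_fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": fdr,
            "mean_a": ma,
            "mean_b": mb,
            "dispersion": alpha,
        },
        index=counts.peak_names,
    )


def all_pairwise(
    counts: CountMatrix, factors: pd.Series | None = None
) -> dict[tuple[int, int], pd.DataFrame]:
    """Every pairwise comparison between the timepoint categories."""
    if factors is None:
        factors = estimate_size_factors(counts)
    out = {}
    for a, b in combinations(counts.timepoints, 2):
        out[(a, b)] = pairwise_differential(counts, a, b, factors)
    return out


def intrinsic_scores(normalized: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-peak intrinsic z-score from normalized (log2) signal.

    between = variance across timepoints of the replicate-mean signal;
    within = mean across timepoints of the replicate variance;
    score = log2((between + eps) / (within + eps)); z standardizes the
    scores over all peaks.
    """
    days = sorted(meta["timepoint"].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 timepoints")
    group_means, group_vars = [], []
    for d in days:
        cols = meta.index[meta["timepoint"] == d]
        if len(cols) < 2:
            raise ValueError(f"timepoint {d} has fewer than 2 replicates")
        sub = normalized[cols]
        group_means.append(sub.mean(axis=1))
        group_vars.append(sub.var(axis=1, ddof=1))
    between = pd.concat(group_means, axis=1).var(axis=1, ddof=1)
    within = pd.concat(group_vars, axis=1).mean(axis=1)
    score = np.log2((between + INTRINSIC_EPS) / (within + INTRINSIC_EPS))
    sd = score.std(ddof=0)
    z = (score - score.mean()) / sd if sd > 0 else score * 0.0
    return pd.DataFrame(
        {"between": between, "within": within, "score": score, "intrinsic_z": z}
    )


@dataclass
class DifferentialSelection:
    """Selected differential peaks plus per-criterion bookkeeping."""

    selected: list[str]
    passes_pairwise: pd.Series
    passes_intrinsic: pd.Series
    mode: str
    thresholds: dict
    n_pairwise: int
    n_intrinsic: int

    def subset(self, peaks: PeakSet) -> PeakSet:
        return peaks.subset(self.selected)


def select_differential_peaks(
    pairwise: dict[tuple[int, int], pd.DataFrame],
    intrinsic: pd.DataFrame,
    thresholds: dict | None = None,
    mode: str = "union",
) -> DifferentialSelection:
    """Combine the pairwise and intrinsic criteria into a differential set.

    A peak passes the pairwise criterion when, in at least one comparison,
    p < p_thr, |log2_fc| > fc_thr and fdr < fdr_thr simultaneously. The
    final set is the union (default) or intersection with the intrinsic
    criterion z > z_thr.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union or intersection, got {mode!r}")
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    index = next(iter(pairwise.values())).index
    passes_pair = pd.Series(False, index=index)
    for df in pairwise.values():
        passes_pair |= (
            (df["p_value"] < thr["p"])
            & (df["log2_fc"].abs() > thr["abs_log2_fc"])
            & (df["fdr"] < thr["fdr"])
        )
    passes_intr = intrinsic["intrinsic_z"].reindex(index) > thr["z"]
    combined = passes_pair | passes_intr if mode == "union" else passes_pair & passes_intr
    return DifferentialSelection(
        selected=list(index[combined]),
        passes_pairwise=passes_pair,
        passes_intrinsic=passes_intr,
        mode=mode,
        thresholds=thr,
        n_pairwise=int(passes_pair.sum()),
        n_intrinsic=int(passes_intr.sum()),
    )
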