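"""PWM scanning and signed hypergeometric motif enrichment.

Scanning scores every window on both strands with a log2-odds matrix and
keeps windows at or above a fraction of the motif's maximum score.
Enrichment compares, per motif, the fraction of target peaks carrying at
least one hit with the fraction in a background universe via the
hypergeometric tail; the signed score is -log10 p with positive sign for
enrichment and negative for depletion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from chromdyn.io import (
    ExpressionMatrix,
    GenomicInterval,
    MotifHit,
    MotifSet,
    PWM,
    PeakSet,
    reverse_complement,
)

LOGODDS_PSEUDOCOUNT = 1e-3
P_FLOOR = 1e-300

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_logodds(pwm: PWM, background: np.ndarray | None = None) -> np.ndarray:
    """4xL log2-odds matrix: log2((prob + pc) / (bg + pc)), pc = 1e-3."""
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    return np.log2(
        (pwm.matrix + LOGODDS_PSEUDOCOUNT) / (bg[:, None] + LOGODDS_PSEUDOCOUNT)
    )


def max_score(pwm: PWM) -> float:
    return float(pwm_logodds(pwm).max(axis=0).sum())


def _encode(seq: str) -> np.ndarray:
    """Map sequence to row indices; N (or anything else) becomes -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Score of every length-L window; windows containing N get -inf."""
    L = lom.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        c = codes[j : j + n_win]
        ok = c >= 0
        valid &= ok
        scores += lom[np.where(ok, c, 0), j] * ok
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    seq: str,
    pwm: PWM,
    threshold_frac: float = 0.8,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of ``seq``; report hits in forward coordinates.

    A window is a hit when its score is >= ``threshold_frac`` times the
    motif's maximum achievable score. Windows containing N are skipped.
    """
    seq = seq.upper()
    L = pwm.length
    if len(seq) < L:
        return []
    lom = pwm_logodds(pwm)
    thresh = threshold_frac * max_score(pwm)
    codes_fwd = _encode(seq)
    codes_rev = _encode(reverse_complement(seq))
    fwd = _window_scores(codes_fwd, lom)
    rev = _window_scores(codes_rev, lom)

    hits = []
    n = len(seq)
    for strand, scores in (("+", fwd), ("-", rev)):
        for i in np.flatnonzero(scores >= thresh):
            start = int(i) if strand == "+" else n - int(i) - L
            hits.append(
                MotifHit(
                    pwm.motif_id,
                    GenomicInterval(
                        chrom or "seq",
                        offset + start,
                        offset + start + L,
                        f"{pwm.motif_id}@{offset + start}{strand}",
                        strand,
                    ),
                    strand,
                    float(scores[i]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_peaks(
    peaks: PeakSet,
    genome: dict[str, str],
    motifs: MotifSet,
    threshold_frac: float = 0.8,
) -> dict[str, dict[str, list[MotifHit]]]:
    """Scan every peak with every motif: motif_id -> peak name -> hits."""
    seqs = peaks.sequences(genome)
    out: dict[str, dict[str, list[MotifHit]]] = {}
    for pwm in motifs:
        per_peak = {}
        for iv in peaks:
            hits = scan_sequence(
                seqs[iv.name], pwm, threshold_frac, chrom=iv.chrom, offset=iv.start
            )
            if hits:
                per_peak[iv.name] = hits
        out[pwm.motif_id] = per_peak
    return out


def enrich(
    target: PeakSet,
    universe: PeakSet,
    hits: dict[str, dict[str, list[MotifHit]]],
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of target peaks vs the universe.

    ``hits`` is the :func:`scan_peaks` output on universe sequences.
    Returns a DataFrame indexed by motif with n/k counts, the directional
    p-value, signed_score = sign * -log10(p), and BH FDR across motifs.
    """
    universe_names = set(universe.names)
    target_names = set(target.names)
    if not target_names <= universe_names:
        raise ValueError("target peaks must be a subset of the universe")
    N, n = len(universe_names), len(target_names)
    rows = []
    for motif_id, per_peak in hits.items():
        with_hit = set(per_peak) & universe_names
        K = len(with_hit)
        k = len(with_hit & target_names)
        p_enrich = float(hypergeom.sf(k - 1, N, K, n))
        p_deplete = float(hypergeom.cdf(k, N, K, n))
        enriched = (k / n if n else 0.0) >= (K / N if N else 0.0)
        p = p_enrich if enriched else p_deplete
        p = max(p, P_FLOOR)
        signed = (-np.log10(p)) * (1.0 if enriched else -1.0)
        rows.append(
            {
                "motif_id": motif_id,
                "n_target": n,
                "k_target": k,
                "n_background": N,
                "k_background": K,
                "p_value": p,
                "signed_score": signed,
            }
        )
    df = pd.DataFrame(rows).set_index("motif_id")
    df["fdr"] = multipletests(df["p_value"].clip(upper=1.0), method=fdr_method)[1]
    return df


def module_map(
    peak_sets: dict[str, PeakSet],
    universe: PeakSet,
    hits: dict[str, dict[str, list[MotifHit]]],
    cluster_rows: bool = True,
) -> pd.DataFrame:
    """Motif x sample matrix of signed enrichment scores (the module map).

    Empty peak sets yield a zero column (flagged via the ``attrs['empty']``
    list). Rows are ordered by hierarchical clustering of the matrix.
    """
    cols, empty = {}, []
    for name, pset in peak_sets.items():
        if len(pset) == 0:
            empty.append(name)
            cols[name] = pd.Series(0.0, index=list(hits))
        else:
            cols[name] = enrich(pset, universe, hits)["signed_score"]
    mat = pd.DataFrame(cols)
    if cluster_rows and len(mat) > 2 and mat.values.std() > 0:
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.corrcoef(mat.values)
        d = np.nan_to_num(d, nan=1.0)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        link = hierarchy.average(squareform(np.clip(d, 0, None), checks=False))
        order = hierarchy.leaves_list(link)
        mat = mat.iloc[order]
    mat.attrs["empty"] = empty
    return mat


def tf_bubble_table(
    enrichment: pd.DataFrame,
    expression: ExpressionMatrix,
    tf_gene_map: dict[str, str],
    motif_tf: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-TF enrichment significance with per-timepoint expression.

    One row per (TF, timepoint) with the TF's expression at that timepoint
    and the motif's -log10 p. TFs whose mapped gene is absent from the
    expression matrix are dropped with a warning.
    """
    rows = []
    dropped = []
    for motif_id, rec in enrichment.iterrows():
        tf = (motif_tf or {}).get(motif_id, str(motif_id))
        gene = tf_gene_map.get(tf)
        if gene is None or gene not in expression.values.index:
            dropped.append(tf)
            continue
        neg_log10_p = -np.log10(max(float(rec["p_value"]), P_FLOOR))
        for t in expression.timepoints:
            rows.append(
                {
                    "tf": tf,
                    "timepoint": t,
                    "expression": float(expression.values.loc[gene, t]),
                    "neg_log10_p": neg_log10_p,
                }
            )
    if dropped:
        warnings.warn(f"TFs without expression rows dropped: {sorted(set(dropped))}")
    if not rows:
        raise ValueError("no TF could be joined to the expression matrix")
    return pd.DataFrame(rows)
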