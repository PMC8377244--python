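"""Per-timepoint TF-TF regulatory network construction.

The promoter is the 2 kb upstream of each TSS. A directed edge A -> B means
TF A's motif occurs at least once in TF B's promoter; the edge's sign comes
from the Pearson correlation of the two expression time courses
(positive: PCC > 0.4; negative: PCC < -0.4; otherwise none). Each
timepoint's network keeps only the TFs relevant at that timepoint
(strictly: the timepoint-specific TFs; optionally any candidate expressed
then), with expression and enrichment significance as node attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from chromdyn.io import (
    ExpressionMatrix,
    GenomicInterval,
    MotifSet,
    PeakSet,
    ValidationError,
)
from chromdyn.motifs import scan_sequence
from chromdyn.cluster import stage_specific_elements

PCC_THRESHOLD = 0.4


def promoter_regions(
    tss: PeakSet,
    chrom_sizes: dict[str, int],
    upstream: int = 2000,
) -> dict[str, GenomicInterval]:
    """gene -> promoter interval, the ``upstream`` bases 5' of the TSS.

    A + strand TSS at x gives [x-upstream, x); a - strand TSS at x gives
    [x, x+upstream); both clipped to the chromosome. Clipped promoters are
    flagged via a ``clipped`` list on the result's attrs-like companion:
    the interval name gets a ``*`` suffix stripped by callers if needed.
    """
    out: dict[str, GenomicInterval] = {}
    for iv in tss:
        if iv.strand not in ("+", "-"):
            raise ValidationError(f"TSS {iv.name} lacks a strand")
        size = chrom_sizes[iv.chrom]
        if iv.strand == "+":
            start, end = max(0, iv.start - upstream), iv.start
        else:
            start, end = iv.start, min(size, iv.start + upstream)
        if end <= start:
            warnings.warn(f"promoter of {iv.name} fully clipped; skipped")
            continue
        out[iv.name] = GenomicInterval(iv.chrom, start, end, iv.name, iv.strand)
    return out


def expressed_threshold(expression: ExpressionMatrix, quantile: float = 0.5) -> float:
    """Default "expressed" cutoff: a quantile of all gene-timepoint values."""
    return float(np.quantile(expression.values.values, quantile))


def candidate_tfs(
    enrichment: dict[str, pd.DataFrame],
    expression: ExpressionMatrix,
    tf_gene_map: dict[str, str],
    motif_tf: dict[str, str],
    p: float = 0.05,
    expressed_cutoff: float | None = None,
) -> set[str]:
    """TFs enriched (p < threshold) in any provided peak set and expressed
    above the cutoff at >=1 timepoint."""
    if expressed_cutoff is None:
        expressed_cutoff = expressed_threshold(expression)
    enriched_tfs = set()
    for df in enrichment.values():
        sig = df[(df["p_value"] < p) & (df["signed_score"] > 0)]
        enriched_tfs.update(motif_tf.get(m, m) for m in sig.index)
    out = set()
    for tf in enriched_tfs:
        gene = tf_gene_map.get(tf)
        if gene is None or gene not in expression.values.index:
            continue
        if (expression.values.loc[gene] > expressed_cutoff).any():
            out.add(tf)
    return out


def stage_specific_tfs(
    expression: ExpressionMatrix,
    tfs: set[str],
    tf_gene_map: dict[str, str],
    fc: float = 1.5,
) -> dict[int, set[str]]:
    """Per-timepoint TF sets: TFs whose linear expression at one timepoint
    exceeds every other timepoint's by the fold-change threshold."""
    genes = [tf_gene_map[tf] for tf in tfs if tf_gene_map.get(tf) in expression.values.index]
    tf_of_gene = {
        tf_gene_map[tf]: tf for tf in tfs if tf_gene_map.get(tf) in expression.values.index
    }
    if not genes:
        return {t: set() for t in expression.timepoints}
    linear = 2.0 ** expression.values.loc[genes]
    design = {t: [t] for t in expression.timepoints}
    per_day = stage_specific_elements(linear, design, fc=fc)
    return {int(t): {tf_of_gene[g] for g in members} for t, members in per_day.items()}


def infer_edges(
    candidates: set[str],
    promoters: dict[str, GenomicInterval],
    genome: dict[str, str],
    motifs: MotifSet,
    tf_gene_map: dict[str, str],
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Directed edges A -> B from A's motif hits inside B's promoter.

    Promoters are scanned with the same PWM settings as peak scanning. TFs
    without a motif get a warning and no outgoing edges; self-loops are
    allowed but flagged.
    """
    rows = []
    no_motif = []
    for src in sorted(candidates):
        pwm = motifs.by_tf(src)
        if pwm is None:
            no_motif.append(src)
            continue
        for tgt in sorted(candidates):
            gene = tf_gene_map.get(tgt)
            if gene is None or gene not in promoters:
                continue
            prom = promoters[gene]
            seq = genome[prom.chrom][prom.start : prom.end]
            hits = scan_sequence(
                seq, pwm, threshold_frac, chrom=prom.chrom, offset=prom.start
            )
            if hits:
                rows.append(
                    {
                        "source": src,
                        "target": tgt,
                        "n_hits": len(hits),
                        "best_score": max(h.score for h in hits),
                        "self_loop": src == tgt,
                    }
                )
    if no_motif:
        warnings.warn(f"TFs without a motif (no outgoing edges): {no_motif}")
    return pd.DataFrame(
        rows, columns=["source", "target", "n_hits", "best_score", "self_loop"]
    )


def classify_edges(
    edges: pd.DataFrame,
    expression: ExpressionMatrix,
    tf_gene_map: dict[str, str],
    pcc_threshold: float = PCC_THRESHOLD,
) -> pd.DataFrame:
    """Attach PCC over the expression time course and the edge type.

    Type is positive iff pcc > threshold, negative iff pcc < -threshold,
    otherwise none (the interval [-thr, +thr] is closed, so pcc == 0.4 is
    "none"). Zero-variance profiles give an undefined PCC, typed none and
    flagged.
    """
    out = edges.copy()
    pccs, types, flags = [], [], []
    for _, row in edges.iterrows():
        ga, gb = tf_gene_map.get(row["source"]), tf_gene_map.get(row["target"])
        xa = expression.values.loc[ga].values.astype(float)
        xb = expression.values.loc[gb].values.astype(float)
        if xa.std() == 0 or xb.std() == 0:
            pccs.append(np.nan)
            types.append("none")
            flags.append(True)
            continue
        pcc = float(np.corrcoef(xa, xb)[0, 1])
        pccs.append(pcc)
        if pcc > pcc_threshold:
            types.append("positive")
        elif pcc < -pcc_threshold:
            types.append("negative")
        else:
            types.append("none")
        flags.append(False)
    out["pcc"] = pccs
    out["edge_type"] = types
    out["pcc_undefined"] = flags
    return out


@dataclass
class RegulatoryNetwork:
    """A directed TF graph for one timepoint."""

    timepoint: int
    graph: nx.DiGraph
    strict: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_timepoint_network(
    timepoint: int,
    candidates: set[str],
    stage_tfs: dict[int, set[str]],
    typed_edges: pd.DataFrame,
    expression: ExpressionMatrix,
    enrichment_p: dict[str, float],
    tf_gene_map: dict[str, str],
    strict: bool = True,
    expressed_cutoff: float | None = None,
) -> RegulatoryNetwork:
    """Assemble the network at one timepoint.

    strict: nodes are the timepoint-specific TFs only. Non-strict adds any
    candidate expressed at the timepoint (above the expressed cutoff).
    """
    if expressed_cutoff is None:
        expressed_cutoff = expressed_threshold(expression)
    nodes = set(stage_tfs.get(timepoint, set()))
    if not strict:
        for tf in candidates:
            gene = tf_gene_map.get(tf)
            if gene in expression.values.index and (
                expression.values.loc[gene, timepoint] > expressed_cutoff
            ):
                nodes.add(tf)
    notes = []
    if not nodes:
        notes.append(f"empty node set at day {timepoint}")
        warnings.warn(notes[-1])
    g = nx.DiGraph(timepoint=int(timepoint))
    for tf in sorted(nodes):
        gene = tf_gene_map.get(tf)
        expr = (
            float(expression.values.loc[gene, timepoint])
            if gene in expression.values.index
            else float("nan")
        )
        g.add_node(
            tf,
            expression=expr,
            neg_log10_p=float(enrichment_p.get(tf, 0.0)),
            stage_specific=tf in stage_tfs.get(timepoint, set()),
        )
    for _, row in typed_edges.iterrows():
        if row["source"] in nodes and row["target"] in nodes:
            g.add_edge(
                row["source"],
                row["target"],
                pcc=float(row["pcc"]) if pd.notna(row["pcc"]) else float("nan"),
                edge_type=str(row["edge_type"]),
                self_loop=bool(row.get("self_loop", row["source"] == row["target"])),
            )
    return RegulatoryNetwork(timepoint=int(timepoint), graph=g, strict=strict, notes=notes)
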