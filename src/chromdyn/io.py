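"""Domain types and fixed-dialect readers/writers.

Coordinates are 0-based half-open everywhere, matching BED. Matrices travel
as TSV with row IDs in the first column; motifs as JASPAR PFM text;
insertion signal as bedGraph; networks as edge-list TSV or GraphML.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

VALID_STRANDS = {"+", "-", "."}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


# ---------------------------------------------------------------------------
# intervals and peak sets


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``summit_offset`` is the distance from ``start`` to the peak summit,
    when known (ATAC peak callers report one); ``None`` otherwise.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval {self.name}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"interval {self.name}: bad strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValidationError(f"interval {self.name}: summit outside interval")

    def __len__(self) -> int:
        return self.end - self.start


class PeakSet:
    """An ordered collection of uniquely named intervals, sorted by position."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        names = [iv.name for iv in ivs]
        if len(set(names)) != len(names):
            dup = pd.Series(names).value_counts()
            raise ValidationError(
                f"duplicate interval names: {list(dup[dup > 1].index[:5])}"
            )
        self._intervals = ivs
        self._by_name = {iv.name: iv for iv in ivs}

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, name: str) -> GenomicInterval:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self._intervals]

    def subset(self, names: Iterable[str]) -> "PeakSet":
        wanted = set(names)
        missing = wanted - self._by_name.keys()
        if missing:
            raise KeyError(f"unknown peak names: {sorted(missing)[:5]}")
        return PeakSet(iv for iv in self._intervals if iv.name in wanted)

    def sequences(self, genome: Mapping[str, str]) -> dict[str, str]:
        """Extract each interval's sequence from a chrom->sequence mapping."""
        out = {}
        for iv in self._intervals:
            seq = genome[iv.chrom][iv.start : iv.end]
            out[iv.name] = seq.upper()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self._intervals == other._intervals


# ---------------------------------------------------------------------------
# matrices


@dataclass
class CountMatrix:
    """Peaks x samples integer fragment counts with a sample design.

    ``sample_meta`` is indexed by sample name with columns ``timepoint``
    (day integer) and ``replicate`` (e.g. R1/R2).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValidationError("count columns do not match sample_meta index")
        if (self.values.values < 0).any():
            raise ValidationError("negative counts")
        if "timepoint" not in self.sample_meta.columns:
            raise ValidationError("sample_meta needs a 'timepoint' column")

    @property
    def peak_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.sample_meta["timepoint"].unique().tolist())

    def samples_at(self, timepoint: int) -> list[str]:
        m = self.sample_meta["timepoint"] == timepoint
        return list(self.sample_meta.index[m])


@dataclass
class ExpressionMatrix:
    """Genes x timepoints continuous (log-scale) expression.

    ``tf_flags`` marks the subset of genes that encode transcription factors.
    """

    values: pd.DataFrame  # columns are day integers, strictly increasing
    tf_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        self.tf_flags = frozenset(self.tf_flags)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[int]:
        return [int(c) for c in self.values.columns]


@dataclass
class InsertionTrack:
    """Per-base transposase insertion counts for one sample/timepoint.

    Stored dense per chromosome; uncovered bases are zero.
    """

    label: str
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            if (arr < 0).any():
                raise ValidationError(f"negative insertion counts on {chrom}")

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.data[chrom]
        if start < 0 or end > len(arr):
            raise KeyError(f"{chrom}:{start}-{end} outside covered coordinates")
        return arr[start:end]


# ---------------------------------------------------------------------------
# motifs


@dataclass
class PWM:
    """Position probability matrix, rows in A,C,G,T order."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # 4 x L probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValidationError(f"{self.motif_id}: PWM must have 4 rows")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValidationError(f"{self.motif_id}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


class MotifSet:
    """Ordered collection of PWMs keyed by motif_id."""

    def __init__(self, pwms: Iterable[PWM]):
        self._pwms = list(pwms)
        ids = [p.motif_id for p in self._pwms]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate motif IDs")
        self._by_id = {p.motif_id: p for p in self._pwms}

    def __len__(self) -> int:
        return len(self._pwms)

    def __iter__(self) -> Iterator[PWM]:
        return iter(self._pwms)

    def __getitem__(self, motif_id: str) -> PWM:
        return self._by_id[motif_id]

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [p.motif_id for p in self._pwms]

    def by_tf(self, tf_name: str) -> PWM | None:
        for p in self._pwms:
            if p.tf_name == tf_name:
                return p
        return None


@dataclass(frozen=True)
class MotifHit:
    """A strand-aware scored motif occurrence in forward coordinates."""

    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> PeakSet:
    """Read BED (>=3 columns) into a PeakSet.

    Column 4 is the name (rows without one are auto-named ``peak_<i>``),
    column 6 the strand, and optional column 7 a summit offset.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            summit = None
            if len(fields) > 6 and fields[6] not in ("", "."):
                summit = int(fields[6])
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, strand, summit)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, "0", iv.strand]
            if iv.summit_offset is not None:
                fields.append(str(iv.summit_offset))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence dict."""
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks).upper()
    if not genome:
        raise ParseError(f"{path}: no sequences")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM

JASPAR_PSEUDOCOUNT = 0.8


def normalize_pfm(counts: np.ndarray, pseudocount: float = JASPAR_PSEUDOCOUNT) -> np.ndarray:
    """Column-normalize a 4xL count matrix after adding pseudocount/4 per cell."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative motif counts")
    padded = counts + pseudocount / 4.0
    return padded / padded.sum(axis=0, keepdims=True)


def read_jaspar(path: str | Path, pseudocount: float = JASPAR_PSEUDOCOUNT) -> MotifSet:
    """Read JASPAR PFM text (">ID NAME" header, 4 count rows) into a MotifSet.

    Counts become probabilities by adding ``pseudocount/4`` to every cell and
    normalizing each column.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = bio_motifs.parse(_io.StringIO(text), "jaspar")
    except Exception as exc:  # biopython raises bare Exceptions on bad input
        raise ParseError(f"{path}: not parseable as JASPAR PFM: {exc}") from exc
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        if counts.shape[0] != 4:
            raise ParseError(f"{path}: motif {m.matrix_id}: expected 4 base rows")
        pwms.append(
            PWM(
                motif_id=m.matrix_id or m.name,
                tf_name=m.name or m.matrix_id,
                matrix=normalize_pfm(counts, pseudocount),
            )
        )
    if not pwms:
        raise ParseError(f"{path}: no motifs found")
    return MotifSet(pwms)


def write_jaspar(counts_by_motif: Mapping[str, tuple[str, np.ndarray]], path: str | Path) -> None:
    """Write raw count matrices as JASPAR PFM text.

    ``counts_by_motif`` maps motif_id -> (tf_name, 4xL count matrix).
    """
    with open(path, "w") as fh:
        for motif_id, (tf_name, counts) in counts_by_motif.items():
            fh.write(f">{motif_id}\t{tf_name}\n")
            for base, row in zip("ACGT", np.asarray(counts)):
                vals = " ".join(f"{v:.0f}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# matrices (TSV)


def read_matrix(path: str | Path, kind: str) -> CountMatrix | ExpressionMatrix:
    """Read a TSV matrix (first column row IDs).

    kind="counts": header is sample names; requires a companion design via
    :func:`read_design` to build a CountMatrix — here sample metadata is
    parsed from column names of the form ``d<day>_R<rep>``.
    kind="expression": header is day integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate row IDs")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing cell")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(f"{path}: non-numeric cell in column {col}")
    if kind == "counts":
        arr = df.values
        if not np.allclose(arr, np.round(arr)):
            raise ParseError(f"{path}: fractional value in a count matrix")
        df = df.astype(np.int64)
        meta = design_from_sample_names(df.columns)
        return CountMatrix(values=df, sample_meta=meta)
    if kind == "expression":
        df.columns = [int(c) for c in df.columns]
        return ExpressionMatrix(values=df.astype(float))
    raise ValueError(f"unknown matrix kind {kind!r}")


def design_from_sample_names(names: Iterable[str]) -> pd.DataFrame:
    """Parse ``d<day>_R<rep>`` sample names into a design table."""
    rows = []
    for name in names:
        try:
            day_part, rep_part = name.split("_")
            day = int(day_part.lstrip("d"))
        except ValueError as exc:
            raise ParseError(
                f"sample name {name!r} not of the form d<day>_R<rep>"
            ) from exc
        rows.append({"sample": name, "timepoint": day, "replicate": rep_part})
    return pd.DataFrame(rows).set_index("sample")


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: InsertionTrack, path: str | Path) -> None:
    """Write nonzero runs of an insertion track as bedGraph."""
    frames = []
    for chrom in track.data:
        arr = np.asarray(track.data[chrom])
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        values = arr[starts]
        keep = values != 0
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts[keep], "end": ends[keep], "value": values[keep]}
            )
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=["chrom", "start", "end", "value"])
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], label: str = ""
) -> InsertionTrack:
    data = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not parseable as bedGraph: {exc}") from exc
    if df.empty:
        return InsertionTrack(label=label, data=data)
    unknown = set(df["chrom"]) - set(data)
    if unknown:
        raise ParseError(f"{path}: unknown chrom(s) {sorted(unknown)}")
    for chrom, grp in df.groupby("chrom", sort=False):
        lengths = (grp["end"] - grp["start"]).values
        if (lengths <= 0).any():
            raise ParseError(f"{path}: interval with end <= start on {chrom}")
        # vectorized fill: positions of every covered base, runs expanded
        idx = np.repeat(grp["start"].values, lengths) + _within_run_offsets(lengths)
        data[chrom][idx] = np.repeat(grp["value"].values.astype(np.int64), lengths)
    return InsertionTrack(label=label, data=data)


def _within_run_offsets(lengths: np.ndarray) -> np.ndarray:
    """[0..l0-1, 0..l1-1, ...] for run lengths, without a Python loop."""
    total = int(lengths.sum())
    offsets = np.arange(total)
    run_starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    return offsets - np.repeat(run_starts, lengths)


# ---------------------------------------------------------------------------
# networks


def write_network(network, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a RegulatoryNetwork as an edge-list TSV (+node table) or GraphML.

    For ``edge_tsv``, ``path`` is a prefix: ``<path>.edges.tsv`` and
    ``<path>.nodes.tsv`` are written.
    """
    import networkx as nx

    g = network if isinstance(network, nx.Graph) else network.graph
    if format == "edge_tsv":
        path = Path(path)
        edges = pd.DataFrame(
            [
                {
                    "source": u,
                    "target": v,
                    "pcc": d.get("pcc", float("nan")),
                    "edge_type": d.get("edge_type", "none"),
                }
                for u, v, d in g.edges(data=True)
            ],
            columns=["source", "target", "pcc", "edge_type"],
        )
        nodes = pd.DataFrame(
            [
                {
                    "tf": n,
                    "expression": d.get("expression", float("nan")),
                    "neg_log10_p": d.get("neg_log10_p", float("nan")),
                }
                for n, d in g.nodes(data=True)
            ],
            columns=["tf", "expression", "neg_log10_p"],
        )
        edges.to_csv(str(path) + ".edges.tsv", sep="\t", index=False)
        nodes.to_csv(str(path) + ".nodes.tsv", sep="\t", index=False)
    elif format == "graphml":
        # drop non-scalar attributes GraphML cannot encode
        h = nx.DiGraph()
        h.add_nodes_from(
            (n, {k: v for k, v in d.items() if isinstance(v, (str, int, float, bool))})
            for n, d in g.nodes(data=True)
        )
        h.add_edges_from(
            (u, v, {k: w for k, w in d.items() if isinstance(w, (str, int, float, bool))})
            for u, v, d in g.edges(data=True)
        )
        nx.write_graphml(h, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")
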