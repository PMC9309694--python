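"""Readers, writers and the raw-read QC filter.

File formats used by the pipeline:

* FASTQ (4-line records, Phred+33) for raw reads;
* TSV for count matrices (feature-id column + one column per sample, optional
  ``length`` column in bp), sample sheets (``sample``, ``group``), miRNA
  target tables and differential-expression tables;
* GMT for gene-set collections (set id TAB description TAB members...);
* SIF / GraphML / node-and-edge TSV for network export (Cytoscape-compatible).

All readers validate rather than silently coerce: duplicate ids, unknown group
labels, negative counts and malformed records raise with a description of the
offending input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GROUP_CASE = "A-ED"
GROUP_CONTROL = "NC"
VALID_GROUPS = (GROUP_CASE, GROUP_CONTROL)
RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")


class ValidationError(ValueError):
    """Raised when an input object or file violates its invariants."""


class FastqParseError(ValidationError):
    """Raised for malformed FASTQ input; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"FASTQ record {record_index}: {message}")
        self.record_index = record_index


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: id, IUPAC nucleotide string, per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValidationError(f"read {self.id!r}: empty sequence")
        if len(self.sequence) != len(self.qualities):
            raise ValidationError(
                f"read {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise ValidationError(f"read {self.id!r}: negative Phred score")


@dataclass
class QCReport:
    """Per-rule failure tallies from :func:`filter_reads`.

    Failures are attributed to the first failing rule in the order the rules
    are applied: adapter content, then N content, then low-quality content.
    """

    n_total: int = 0
    n_kept: int = 0
    fail_adapter: int = 0
    fail_n_content: int = 0
    fail_low_quality: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "fail_adapter": self.fail_adapter,
            "fail_n_content": self.fail_n_content,
            "fail_low_quality": self.fail_low_quality,
        }


def filter_reads(
    reads: Iterable[ReadRecord],
    adapters: Sequence[str],
    max_n_fraction: float = 0.10,
    low_quality_q: int = 20,
    max_low_quality_fraction: float = 0.50,
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the three raw-read inclusion rules.

    A read is kept iff (1) it contains no adapter as an exact substring,
    (2) its fraction of ``N`` bases does not exceed ``max_n_fraction`` and
    (3) its fraction of bases with Phred quality <= ``low_quality_q`` does not
    exceed ``max_low_quality_fraction``.  Boundaries are kept: "more than" is
    read strictly, so a read with exactly 10% N survives.  Reads are kept or
    dropped whole (no trimming) and order is preserved.
    """
    adapters = [a for a in adapters if a]
    if not adapters:
        raise ValidationError("adapter list must contain at least one non-empty string")
    kept: list[ReadRecord] = []
    report = QCReport()
    for read in reads:
        report.n_total += 1
        if any(a in read.sequence for a in adapters):
            report.fail_adapter += 1
            continue
        L = len(read.sequence)
        seq = read.sequence.upper()
        if seq.count("N") / L > max_n_fraction:
            report.fail_n_content += 1
            continue
        n_low = sum(1 for q in read.qualities if q <= low_quality_q)
        if n_low / L > max_low_quality_fraction:
            report.fail_low_quality += 1
            continue
        report.n_kept += 1
        kept.append(read)
    return kept, report


def read_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from a 4-line FASTQ file (Phred+33)."""
    with open(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(str(exc), index) from exc
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
            index += 1


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> int:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with open(path, "w") as handle:
        return SeqIO.write(records, handle, "fastq")


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionMatrix:
    """Integer counts for one RNA class over named, group-labelled samples.

    ``counts`` is features x samples; ``groups`` maps sample id to "A-ED" or
    "NC"; ``lengths`` (bp) is optional and only needed for FPKM.
    """

    counts: pd.DataFrame
    groups: pd.Series
    rna_class: str
    lengths: pd.Series | None = None

    def __post_init__(self):
        if self.rna_class not in RNA_CLASSES:
            raise ValidationError(
                f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}"
            )
        dup_f = self.counts.index[self.counts.index.duplicated()].unique().tolist()
        if dup_f:
            raise ValidationError(f"duplicate feature ids: {dup_f}")
        dup_s = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        if set(self.groups.index) != set(self.counts.columns):
            raise ValidationError("sample sheet does not match count matrix columns")
        self.groups = self.groups.reindex(self.counts.columns)
        bad = sorted(set(self.groups.unique()) - set(VALID_GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        if len(set(self.groups.unique())) < 2:
            raise ValidationError("both groups (A-ED, NC) must be represented")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset(self, features: Iterable[str]) -> "ExpressionMatrix":
        idx = [f for f in self.counts.index if f in set(features)]
        return ExpressionMatrix(
            counts=self.counts.loc[idx].copy(),
            groups=self.groups.copy(),
            rna_class=self.rna_class,
            lengths=None if self.lengths is None else self.lengths.loc[idx].copy(),
        )


def write_counts(
    matrix: ExpressionMatrix,
    counts_path: str | os.PathLike,
    samples_path: str | os.PathLike,
) -> None:
    out = matrix.counts.copy()
    out.insert(0, "feature_id", out.index)
    if matrix.lengths is not None:
        out["length"] = matrix.lengths.values
    out.to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame({"sample": matrix.groups.index, "group": matrix.groups.values}).to_csv(
        samples_path, sep="\t", index=False
    )


def read_counts(
    counts_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    rna_class: str,
) -> ExpressionMatrix:
    df = pd.read_csv(counts_path, sep="\t")
    if df.columns[0] != "feature_id":
        raise ValidationError(
            f"{counts_path}: first column must be 'feature_id', got {df.columns[0]!r}"
        )
    df = df.set_index("feature_id")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length")
    sheet = pd.read_csv(samples_path, sep="\t")
    if list(sheet.columns[:2]) != ["sample", "group"]:
        raise ValidationError(f"{samples_path}: expected columns 'sample', 'group'")
    dup = sheet["sample"][sheet["sample"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate sample ids in sheet: {dup}")
    groups = pd.Series(sheet["group"].values, index=sheet["sample"].values)
    counts = df[list(sheet["sample"])]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"{counts_path}: counts must be integers")
    return ExpressionMatrix(
        counts=counts.astype(np.int64),
        groups=groups,
        rna_class=rna_class,
        lengths=lengths,
    )


# ---------------------------------------------------------------------------
# miRNA target tables

TARGET_COLUMNS = ["mirna", "target", "target_class", "tools"]


@dataclass
class TargetTable:
    """Predicted miRNA -> target pairs with per-tool provenance votes.

    One row per (miRNA, target) pair after merging; ``tools`` holds the set of
    prediction sources that voted for the pair (never empty).
    """

    pairs: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TARGET_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValidationError(f"target table missing columns: {missing}")
        dup = self.pairs.duplicated(subset=["mirna", "target"])
        if dup.any():
            rows = self.pairs.loc[dup, ["mirna", "target"]].values.tolist()
            raise ValidationError(f"duplicate (miRNA, target) rows: {rows[:5]}")
        bad_cls = set(self.pairs["target_class"]) - {"lncRNA", "mRNA"}
        if bad_cls:
            raise ValidationError(f"unknown target classes: {sorted(bad_cls)}")
        if any(len(t) == 0 for t in self.pairs["tools"]):
            raise ValidationError("every pair must carry at least one tool vote")
        # canonical row order makes serialization deterministic
        self.pairs = self.pairs.sort_values(["mirna", "target"], kind="mergesort")
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def restrict(self, mirnas: Iterable[str], targets: Iterable[str]) -> "TargetTable":
        m, t = set(mirnas), set(targets)
        sub = self.pairs[
            self.pairs["mirna"].isin(m) & self.pairs["target"].isin(t)
        ].copy()
        return TargetTable(sub)

    def pairs_for_class(self, target_class: str) -> pd.DataFrame:
        return self.pairs[self.pairs["target_class"] == target_class]


def merge_target_tables(tables: Mapping[str, pd.DataFrame]) -> TargetTable:
    """Union per-tool (mirna, target, target_class) frames, tracking votes."""
    votes: dict[tuple[str, str, str], set[str]] = {}
    for tool, df in tables.items():
        for mirna, target, cls in df[["mirna", "target", "target_class"]].itertuples(
            index=False
        ):
            votes.setdefault((mirna, target, cls), set()).add(tool)
    rows = [
        {"mirna": m, "target": t, "target_class": c, "tools": frozenset(v)}
        for (m, t, c), v in sorted(votes.items())
    ]
    return TargetTable(pd.DataFrame(rows, columns=TARGET_COLUMNS))


def read_target_table(paths: Mapping[str, str | os.PathLike]) -> TargetTable:
    """Read and merge one TSV per prediction tool (keyed by tool name).

    Each file needs columns ``mirna``, ``target``, ``target_class``; a merged
    file written by :func:`write_target_table` may be re-read by passing it as
    the single entry (its own ``tools`` column is unioned with the key).
    """
    frames: dict[str, pd.DataFrame] = {}
    merged: dict[tuple[str, str, str], set[str]] = {}
    for tool, path in paths.items():
        df = pd.read_csv(path, sep="\t")
        need = ["mirna", "target", "target_class"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        if "tools" in df.columns:
            for mirna, target, cls, tools in df[need + ["tools"]].itertuples(index=False):
                for t in str(tools).split(","):
                    merged.setdefault((mirna, target, cls), set()).add(t)
        else:
            frames[tool] = df
    for tool, df in frames.items():
        for mirna, target, cls in df[["mirna", "target", "target_class"]].itertuples(
            index=False
        ):
            merged.setdefault((mirna, target, cls), set()).add(tool)
    rows = [
        {"mirna": m, "target": t, "target_class": c, "tools": frozenset(v)}
        for (m, t, c), v in sorted(merged.items())
    ]
    return TargetTable(pd.DataFrame(rows, columns=TARGET_COLUMNS))


def write_target_table(table: TargetTable, path: str | os.PathLike) -> None:
    out = table.pairs.copy()
    out["tools"] = [",".join(sorted(t)) for t in out["tools"]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets: set id -> (description, frozenset of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            sid, desc, members = parts[0], parts[1], parts[2:]
            if sid in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {sid!r} has no members")
            sets[sid] = (desc, frozenset(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# network export

SIF_INTERACTIONS = {
    ("lncRNA", "miRNA"): "sponge",
    ("miRNA", "mRNA"): "represses",
}


def _edge_interaction(G: nx.Graph, u: str, v: str) -> tuple[str, str, str]:
    cu, cv = G.nodes[u]["rna_class"], G.nodes[v]["rna_class"]
    if (cu, cv) in SIF_INTERACTIONS:
        return u, SIF_INTERACTIONS[(cu, cv)], v
    if (cv, cu) in SIF_INTERACTIONS:
        return v, SIF_INTERACTIONS[(cv, cu)], u
    raise ValidationError(f"edge {u}--{v} joins classes {cu}/{cv}: not tripartite")


def write_network(G: nx.Graph, path: str | os.PathLike, fmt: str = "graphml") -> None:
    """Export a ceRNA network as GraphML, SIF, or node/edge attribute TSVs.

    For ``fmt="tsv"``, ``path`` is used as a prefix and two files are written:
    ``<path>.nodes.tsv`` and ``<path>.edges.tsv``.
    """
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(G.edges()):
                a, rel, b = _edge_interaction(G, u, v)
                fh.write(f"{a}\t{rel}\t{b}\n")
    elif fmt == "tsv":
        nodes = pd.DataFrame(
            [
                {"id": n, "rna_class": d["rna_class"], "direction": d["direction"]}
                for n, d in sorted(G.nodes(data=True))
            ]
        )
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, **{k: d[k] for k in sorted(d)}}
                for u, v, d in sorted(G.edges(data=True))
            ]
        )
        nodes.to_csv(f"{path}.nodes.tsv", sep="\t", index=False)
        edges.to_csv(f"{path}.edges.tsv", sep="\t", index=False)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")


def read_network(path: str | os.PathLike, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValidationError(f"reading format {fmt!r} is not supported")
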