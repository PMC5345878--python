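"""Gene models, splice-boundary anchors, and exon classification.

Gene structures are read from GTF or BED12 and normalised to a single
0-based half-open coordinate convention.  From them we derive the three
landmark kinds every downstream profile is anchored on:

``tss``
    The transcription start site (first transcribed base).
``intron_exon``
    The splice-acceptor side of an internal exon; ``pos`` is the first
    exonic base in transcript orientation.
``exon_intron``
    The splice-donor side of an internal exon; ``pos`` is the first
    intronic base in transcript orientation.

First and last exons carry no splice boundaries, so boundary anchors
exist only at internal exon edges.  Exons are further partitioned into
cassette (alternatively spliced, with an inclusion fraction a.k.a. PSI)
and constitutive sets; cassette calls are an external input produced by
a splicing caller.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "Anchor",
    "ExonRecord",
    "ParseError",
    "load_gene_models",
    "write_bed12",
    "extract_anchors",
    "classify_exons",
    "bin_by_inclusion",
    "read_cassette_calls",
    "INCLUSION_CLASSES",
]

ANCHOR_KINDS = ("tss", "intron_exon", "exon_intron")

#: inclusion classes in increasing order; bins are right-closed:
#: (0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 1.0]; inclusion 0 folds into very_low
INCLUSION_CLASSES = ("very_low", "low", "medium", "high")
_INCLUSION_EDGES = (0.2, 0.4, 0.6)


class ParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""


@dataclass(frozen=True)
class GeneModel:
    """One gene, represented by its canonical transcript.

    ``exons`` are 0-based half-open genomic intervals, sorted by start and
    non-overlapping regardless of strand.  ``expression`` is the host-gene
    TPM and may be attached after construction via :meth:`with_expression`.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise ValueError(f"{self.gene_id}: exon [{start},{end}) has length < 1")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def tss(self) -> int:
        """First transcribed base (0-based)."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def with_expression(self, tpm: float) -> "GeneModel":
        return replace(self, expression=float(tpm))


@dataclass(frozen=True)
class Anchor:
    """A strand-oriented genomic landmark owned by one gene.

    ``exon_index`` is the genomic (start-sorted) index of the exon whose
    boundary this is; -1 for TSS anchors.
    """

    kind: str
    chrom: str
    pos: int
    strand: str
    gene_id: str
    exon_index: int = -1


@dataclass(frozen=True)
class ExonRecord:
    """An internal exon labelled cassette or constitutive.

    ``inclusion`` (PSI, in [0, 1]) is present iff the exon is cassette.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_class: str
    inclusion: float | None = None
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.exon_class not in ("cassette", "constitutive"):
            raise ValueError(f"unknown exon_class {self.exon_class!r}")
        if (self.inclusion is not None) != (self.exon_class == "cassette"):
            raise ValueError("inclusion must be present iff exon_class == 'cassette'")
        if self.inclusion is not None and not 0.0 <= self.inclusion <= 1.0:
            raise ValueError(f"inclusion {self.inclusion} outside [0, 1]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: Path) -> list[GeneModel]:
    # transcript_id -> (gene_id, chrom, strand, [exons])
    transcripts: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                # GTF is 1-based inclusive; internal convention 0-based half-open
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = dict(_GTF_ATTR.findall(attrs))
            try:
                gene_id, tx_id = attr["gene_id"], attr["transcript_id"]
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: missing gene_id/transcript_id") from exc
            rec = transcripts.setdefault(tx_id, (gene_id, chrom, strand, []))
            rec[3].append(iv)

    # one canonical transcript per gene: longest summed exon length,
    # ties broken by lexicographically smallest transcript id
    by_gene: dict[str, tuple[tuple[int, str], GeneModel]] = {}
    for tx_id, (gene_id, chrom, strand, exons) in transcripts.items():
        exons.sort()
        model = GeneModel(gene_id, chrom, strand, tuple(exons))
        length = sum(e - s for s, e in exons)
        key = (-length, tx_id)
        if gene_id not in by_gene or key < by_gene[gene_id][0]:
            by_gene[gene_id] = (key, model)
    return [entry[1] for _, entry in sorted(by_gene.items())]


def _parse_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(fields)}")
            try:
                chrom, start, _end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED12 fields") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = tuple((start + off, start + off + size) for off, size in zip(starts, sizes))
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def load_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from a GTF or BED12 file.

    ``fmt`` is inferred from the suffix when omitted (``.gtf`` / anything
    else is treated as BED12).  Coordinates come back 0-based half-open,
    one canonical transcript per gene.  Raises :class:`ParseError` on
    malformed lines (with line number) and ``ValueError`` if no gene
    survives parsing.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed12"
    if fmt == "gtf":
        models = _parse_gtf(path)
    elif fmt == "bed12":
        models = _parse_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if not models:
        raise ValueError(f"{path}: no gene models parsed")
    return models


def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12; exact round-trip partner of the reader."""
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons)
            offsets = ",".join(str(s - m.start) for s, _ in m.exons)
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\t"
                f"{m.start}\t{m.end}\t0\t{m.n_exons}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def extract_anchors(models: Sequence[GeneModel], kind: str) -> list[Anchor]:
    """Derive strand-oriented anchors of one ``kind`` from gene models.

    For a + strand gene the splice acceptor (``intron_exon``) of genomic
    exon *i* (i >= 1) sits at its start; the donor (``exon_intron``) of
    exon *i* (i <= n-2) at its end.  On the - strand the biological roles
    swap ends: the acceptor is the genomic *end* of exons 0..n-2 (pos is
    the last genomic base, i.e. the first exonic base read 5'->3') and
    the donor is ``start - 1`` of exons 1..n-1.  Single-exon genes yield
    no boundary anchors.
    """
    if kind not in ANCHOR_KINDS:
        raise ValueError(f"unknown anchor kind {kind!r}; expected one of {ANCHOR_KINDS}")
    anchors: list[Anchor] = []
    for m in models:
        if kind == "tss":
            anchors.append(Anchor("tss", m.chrom, m.tss, m.strand, m.gene_id, -1))
            continue
        n = m.n_exons
        if n < 2:
            continue
        if m.strand == "+":
            if kind == "intron_exon":
                idx = range(1, n)
                positions = (m.exons[i][0] for i in idx)
            else:
                idx = range(0, n - 1)
                positions = (m.exons[i][1] for i in idx)
        else:
            if kind == "intron_exon":
                idx = range(0, n - 1)
                positions = (m.exons[i][1] - 1 for i in idx)
            else:
                idx = range(1, n)
                positions = (m.exons[i][0] - 1 for i in idx)
        for i, pos in zip(idx, positions):
            anchors.append(Anchor(kind, m.chrom, pos, m.strand, m.gene_id, i))
    return anchors


# ---------------------------------------------------------------------------
# exon classification
# ---------------------------------------------------------------------------


def read_cassette_calls(path: str | Path) -> pd.DataFrame:
    """Read a cassette-exon call table (chrom, start, end, strand, gene_id, inclusion)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "strand", "gene_id", "inclusion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cassette table missing columns {sorted(missing)}")
    return df


def classify_exons(
    models: Sequence[GeneModel],
    cassette_calls: pd.DataFrame | None,
    expression: Mapping[str, float] | None = None,
) -> list[ExonRecord]:
    """Partition internal exons into cassette and constitutive records.

    Every internal exon of every gene appears exactly once.  Cassette
    calls are matched on (chrom, start, end); duplicates in the call
    table are collapsed.  Calls that match no annotated internal exon are
    kept as cassette-only records with a warning, mirroring the way an
    external splicing caller can report events missing from the canonical
    annotation.
    """
    calls: dict[tuple[str, int, int], tuple[str, str, float]] = {}
    if cassette_calls is not None and len(cassette_calls):
        for row in cassette_calls.itertuples(index=False):
            key = (str(row.chrom), int(row.start), int(row.end))
            calls[key] = (str(row.gene_id), str(row.strand), float(row.inclusion))

    records: list[ExonRecord] = []
    seen: set[tuple[str, int, int]] = set()
    for m in models:
        expr = m.expression
        if expr is None and expression is not None:
            expr = expression.get(m.gene_id)
        for i in range(1, m.n_exons - 1):
            start, end = m.exons[i]
            key = (m.chrom, start, end)
            seen.add(key)
            if key in calls:
                records.append(
                    ExonRecord(m.gene_id, m.chrom, start, end, m.strand,
                               "cassette", calls[key][2], expr)
                )
            else:
                records.append(
                    ExonRecord(m.gene_id, m.chrom, start, end, m.strand,
                               "constitutive", None, expr)
                )
    orphans = set(calls) - seen
    for key in sorted(orphans):
        gene_id, strand, inclusion = calls[key]
        warnings.warn(
            f"cassette call {key} not found among annotated internal exons; "
            "keeping as cassette-only record"
        )
        expr = expression.get(gene_id) if expression is not None else None
        records.append(ExonRecord(gene_id, key[0], key[1], key[2], strand,
                                  "cassette", inclusion, expr))
    return records


def inclusion_class(value: float) -> str:
    """Map an inclusion fraction to its class; right-closed bins, 0 -> very_low."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"inclusion {value} outside [0, 1]")
    for name, edge in zip(INCLUSION_CLASSES, _INCLUSION_EDGES):
        if value <= edge:
            return name
    return INCLUSION_CLASSES[-1]


def bin_by_inclusion(records: Iterable[ExonRecord]) -> dict[str, list[ExonRecord]]:
    """Group cassette exons into the four inclusion classes.

    Bins are right-closed — (0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 1.0] —
    with inclusion exactly 0 folded into ``very_low``.  Classes without
    members are omitted from the mapping.
    """
    out: dict[str, list[ExonRecord]] = {}
    for rec in records:
        if rec.exon_class != "cassette":
            raise ValueError("bin_by_inclusion expects cassette records only")
        out.setdefault(inclusion_class(rec.inclusion), []).append(rec)
    return out
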