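"""Readers and writers for the SNP-table, header and annotation dialects.

The SNP-table dialect is deliberately minimal: tab-delimited text with NO
header row, column 1 the chromosome label, column 2 the 1-based position,
and columns 3+ one genotype token per sample, the first of which is the
reference genome.  Sample names travel separately, in a small XML header
file (``<dataset name="..."><sample>NAME</sample>...</dataset>``) or a
plain-text one-name-per-line fallback.  One file holds one chromosome.

The human-facing outputs (region report, distance matrix) DO carry header
rows; they are different formats from the input dialect.
"""

from __future__ import annotations

import gzip
import io as _stdio
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    DataError,
    DistanceMatrix,
    GeneModel,
    HaploTree,
    InvalidTokenError,
    Region,
    SNPMatrix,
    TreeNode,
    normalize_symbol,
    slice_region,
)

__all__ = [
    "ParseError",
    "read_snp_table",
    "write_snp_table",
    "read_sample_header",
    "write_sample_header",
    "read_annotation",
    "write_annotation",
    "annotate_position",
    "write_region_report",
    "write_distance_matrix",
    "read_distance_matrix",
    "to_newick",
    "write_newick",
]


class ParseError(DataError):
    """Malformed input file; the message names file and line."""


def _open_text(path: str | Path):
    p = Path(path)
    if p.suffix == ".gz":
        return _stdio.TextIOWrapper(gzip.open(p, "rb"), encoding="utf-8")
    return open(p, "r", encoding="utf-8", newline=None)


def read_snp_table(path: str | Path, sample_names: Sequence[str]) -> SNPMatrix:
    """Parse a tab-delimited SNP table into a matrix.

    ``sample_names`` must match the file's sample columns (column count
    minus the chromosome and position columns); the first name denotes
    the reference.  Rows are sorted by position; duplicate positions and
    mixed chromosome labels are rejected.  Windows line endings and
    trailing blank lines are tolerated.
    """
    names = list(sample_names)
    if not names:
        raise DataError("sample_names must be non-empty")
    chrom: Optional[str] = None
    positions: list[int] = []
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 + len(names):
                raise ParseError(
                    f"{path}:{lineno}: expected {2 + len(names)} columns "
                    f"({len(names)} samples), found {len(fields)}"
                )
            this_chrom = fields[0].strip()
            if chrom is None:
                chrom = this_chrom
            elif this_chrom != chrom:
                raise ParseError(
                    f"{path}:{lineno}: chromosome {this_chrom!r} differs "
                    f"from {chrom!r}; a file holds one chromosome at a time"
                )
            try:
                pos = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: position {fields[1]!r} is not an "
                    "integer"
                ) from None
            symbols = []
            for col, token in enumerate(fields[2:], start=3):
                try:
                    symbols.append(str(normalize_symbol(token)))
                except InvalidTokenError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: column {col}: {exc}"
                    ) from None
            positions.append(pos)
            rows.append(symbols)
    if chrom is None:
        raise ParseError(f"{path}: file holds no data lines")
    order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable")
    sorted_pos = np.asarray(positions, dtype=np.int64)[order]
    dups = sorted_pos[:-1][np.diff(sorted_pos) == 0]
    if dups.size:
        raise ParseError(
            f"{path}: duplicate position {int(dups[0])} on {chrom}"
        )
    calls = np.asarray(rows, dtype="<U1")[order]
    return SNPMatrix(
        chromosome=chrom, positions=sorted_pos, samples=tuple(names),
        calls=calls,
    )


def write_snp_table(m: SNPMatrix, path: str | Path) -> None:
    """Write a matrix back in the input dialect (no header row)."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in range(m.n_positions):
            fields = [m.chromosome, str(int(m.positions[row]))]
            fields.extend(m.calls[row, :])
            fh.write("\t".join(fields) + "\n")


def read_sample_header(path: str | Path) -> list[str]:
    """Read ordered sample names from an XML header or plain-text file.

    XML schema: a root ``<dataset name="...">`` holding ordered
    ``<sample>`` elements whose text (or ``name`` attribute) is the
    sample name.  Files not starting with ``<`` are read as plain text,
    one name per line.  The first name is the reference.
    """
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("<"):
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise ParseError(f"{path}: malformed XML: {exc}") from None
        names = []
        for el in root.iter("sample"):
            name = (el.text or "").strip() or el.attrib.get("name", "").strip()
            if not name:
                raise ParseError(f"{path}: <sample> element without a name")
            names.append(name)
    else:
        names = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not names:
        raise ParseError(f"{path}: header file lists no sample names")
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ParseError(f"{path}: duplicate sample name {dup!r}")
    return names


def write_sample_header(names: Sequence[str], path: str | Path,
                        dataset: str = "dataset") -> None:
    root = ET.Element("dataset", attrib={"name": dataset})
    for name in names:
        el = ET.SubElement(root, "sample")
        el.text = name
    ET.ElementTree(root).write(path, encoding="unicode")


def read_annotation(path: str | Path, id_attribute: str = "ID") -> list[GeneModel]:
    """Read gene models from a GFF3/GFF2/GTF file.

    Features are grouped by the value of ``id_attribute`` (e.g. ``ID``,
    ``locus_id``, ``gene_id``): gene/mRNA records set the span and
    strand, exon records (or CDS records when a group has no exons)
    supply the exon list.  Models are returned sorted by span start.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    seen_keys: set[str] = set()
    for feat in db.all_features():
        seen_keys.update(feat.attributes.keys())
        values = feat.attributes.get(id_attribute)
        if not values:
            continue
        key = values[0]
        ftype = feat.featuretype.lower()
        if ftype in ("gene", "mrna", "transcript"):
            prev = spans.get(key)
            if prev is None:
                spans[key] = (feat.seqid, feat.strand, feat.start, feat.end)
            else:
                spans[key] = (
                    prev[0], prev[1],
                    min(prev[2], feat.start), max(prev[3], feat.end),
                )
        elif ftype == "exon":
            exons.setdefault(key, []).append((feat.start, feat.end))
        elif ftype == "cds":
            cdss.setdefault(key, []).append((feat.start, feat.end))
    if not spans and not exons and not cdss:
        raise DataError(
            f"attribute {id_attribute!r} absent from every record in "
            f"{path}; available attribute keys: {sorted(seen_keys)}"
        )
    models = []
    keys = set(spans) | set(exons) | set(cdss)
    for key in keys:
        parts = exons.get(key) or cdss.get(key) or []
        parts = sorted(parts)
        if key in spans:
            seqid, strand, start, end = spans[key]
        else:
            seqid, strand = "", "+"
            start = min(p[0] for p in parts)
            end = max(p[1] for p in parts)
        span = Region(chromosome=seqid or "", start=start, end=end)
        exon_regions = tuple(
            Region(chromosome=span.chromosome, start=s, end=e)
            for s, e in parts
        )
        models.append(
            GeneModel(name=key, strand=strand if strand in "+-" else "+",
                      span=span, exons=exon_regions)
        )
    models.sort(key=lambda g: (g.span.start, g.name))
    return models


def write_annotation(models: Sequence[GeneModel], path: str | Path,
                     id_attribute: str = "ID") -> None:
    """Write gene models as GFF3 (gene + exon records)."""
    lines = ["##gff-version 3"]
    for g in models:
        attrs = f"{id_attribute}={g.name}"
        lines.append(
            f"{g.span.chromosome}\thaploclust\tgene\t{g.span.start}\t"
            f"{g.span.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for exon in g.exons:
            lines.append(
                f"{exon.chromosome}\thaploclust\texon\t{exon.start}\t"
                f"{exon.end}\t.\t{g.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def annotate_position(
    position: int, models: Sequence[GeneModel]
) -> tuple[str, str, str]:
    """(gene name, exon label, strand) for a SNP position, or blanks.

    The first model (by span start) covering the position wins; the exon
    label is ``exon<k>`` (1-based) when the position falls in an exon,
    ``intron`` when inside the span but outside every exon.
    """
    for g in models:
        if position in g.span:
            k = g.exon_index_at(position)
            return g.name, f"exon{k}" if k else "intron", g.strand
    return "", "", ""


def write_region_report(
    m: SNPMatrix,
    r: Region,
    models: Optional[Sequence[GeneModel]] = None,
    path: str | Path = "report.tsv",
    sample_order: Optional[Sequence[str]] = None,
) -> None:
    """Tab-delimited per-position report over a region.

    One data row per SNP position: chromosome, position, then each
    sample's symbol (in ``sample_order`` if given, e.g. the tree's leaf
    order), plus gene/exon/strand annotation columns when models are
    supplied.  A header row is always written.
    """
    sub = slice_region(m, r)
    order = list(sample_order) if sample_order is not None else list(m.samples)
    if set(order) != set(m.samples):
        raise DataError("sample_order must be a permutation of the samples")
    cols = [m.sample_index(s) for s in order]
    header = ["chromosome", "position", *order]
    if models is not None:
        header += ["gene", "exon", "strand"]
    lines = ["\t".join(header)]
    for row in range(sub.n_positions):
        pos = int(sub.positions[row])
        fields = [sub.chromosome, str(pos)]
        fields.extend(sub.calls[row, c] for c in cols)
        if models is not None:
            fields.extend(annotate_position(pos, models))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square tab-delimited matrix with labels; 6-decimal values."""
    lines = ["\t".join(["", *dm.samples])]
    for i, name in enumerate(dm.samples):
        values = (f"{dm.d[i, j]:.6f}" for j in range(dm.n_samples))
        lines.append("\t".join([name, *values]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Re-read a written distance matrix (compared counts are not stored)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty distance matrix file")
    samples = lines[0].split("\t")[1:]
    n = len(samples)
    d = np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise ParseError(f"{path}: ragged row {i + 2}")
        d[i, :] = [float(x) for x in fields[1:]]
    d = (d + d.T) / 2.0  # absorb printed-precision asymmetry
    np.fill_diagonal(d, 0.0)
    compared = np.zeros((n, n), dtype=np.int64)
    return DistanceMatrix(samples=tuple(samples), d=d, compared=compared)


def to_newick(t: HaploTree) -> str:
    """Newick string with branch lengths = parent height - child height."""

    def fmt(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{length:.10g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{length:.10g}"

    root = t.root
    if root.is_leaf:
        return f"{root.name};"
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(t: HaploTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(t) + "\n")
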