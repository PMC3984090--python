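"""Causative-SNP allele calling, deletion-signature scanning and codon math.

The registry maps each candidate gene to one or more causative SNPs: a
chromosome position whose reference-genome state names one allele and
whose alternative base names the other.  The built-in registry ships the
classical soybean maturity and stem-growth loci as characterized against
the Williams 82 reference: *E1/e1-as* (Williams 82 carries the earlier
maturing *e1-as* missense allele), *E2/e2*, and the four missense *dt1*
alleles of *Dt1*.  *E3* and *E4* variants are structural (deletions and a
retrotransposon insertion) and have no causative SNP, which is why the
deletion-signature scan exists: a long run of missing calls at the right
place is *consistent with* a deletion, and is reported strictly as a
candidate.

Codon arithmetic operates on 1-based coding-sequence (CDS) positions
only; mapping genomic coordinates to CDS coordinates through exon
structures is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CALL_HETEROZYGOUS,
    CALL_NO_DATA,
    CALL_UNKNOWN,
    AlleleDef,
    DataError,
    DeletionSignature,
    GenotypeCall,
    GenotypeSymbol,
    Region,
    SNPMatrix,
    slice_region,
)

__all__ = [
    "AlleleRegistry",
    "BUILTIN_REGISTRY",
    "haplotype_window",
    "call_allele",
    "deletion_signature",
    "affected_codon",
    "frameshift_intact_length",
    "interval_length",
    "genotype_table",
]

#: Default flank added on each side of a gene span for haplotype analysis.
DEFAULT_FLANK_BP = 3500

#: Deletion-signature defaults: flag a sample when at least this fraction
#: of the scanned SNP sites is missing, over at least this many sites.
DEFAULT_MISSING_THRESHOLD = 0.9
DEFAULT_MIN_SITES = 3


@dataclass(frozen=True)
class AlleleRegistry:
    """An ordered collection of causative-SNP definitions."""

    entries: tuple[AlleleDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        keys = [(e.gene, e.chromosome, e.position) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise DataError("registry entries must have unique (gene, site)")

    @property
    def genes(self) -> list[str]:
        """Gene names in first-appearance order."""
        seen: list[str] = []
        for e in self.entries:
            if e.gene not in seen:
                seen.append(e.gene)
        return seen

    def for_gene(self, gene: str) -> list[AlleleDef]:
        return [e for e in self.entries if e.gene == gene]

    @classmethod
    def from_file(cls, path: str | Path) -> "AlleleRegistry":
        """Load a registry from a tab-delimited config.

        Columns: gene, chromosome, position, ref symbol, alt symbol,
        ref allele name, alt allele name.  Lines starting with ``#`` and
        blank lines are ignored.
        """
        entries = []
        for lineno, raw in enumerate(
            Path(path).read_text().splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise DataError(
                    f"{path}:{lineno}: expected 7 tab-delimited fields, "
                    f"got {len(parts)}"
                )
            gene, chrom, pos, ref, alt, ref_name, alt_name = parts
            try:
                position = int(pos)
            except ValueError:
                raise DataError(
                    f"{path}:{lineno}: position {pos!r} is not an integer"
                ) from None
            entries.append(
                AlleleDef(
                    gene=gene,
                    chromosome=chrom,
                    position=position,
                    ref_symbol=GenotypeSymbol(ref.upper()),
                    alt_symbol=GenotypeSymbol(alt.upper()),
                    ref_allele_name=ref_name,
                    alt_allele_name=alt_name,
                )
            )
        if not entries:
            raise DataError(f"registry file {path} holds no entries")
        return cls(entries=tuple(entries))

    def to_file(self, path: str | Path) -> None:
        lines = ["#gene\tchrom\tpos\tref\talt\tref_name\talt_name"]
        for e in self.entries:
            lines.append(
                f"{e.gene}\t{e.chromosome}\t{e.position}\t{e.ref_symbol}"
                f"\t{e.alt_symbol}\t{e.ref_allele_name}\t{e.alt_allele_name}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


#: Causative SNPs of the soybean maturity/growth-habit loci, expressed
#: against the Williams 82 reference genome.  Williams 82 itself carries
#: e1-as (hence ref C at Gm06:20007173 names e1-as and alt G names the
#: functional E1), functional E2 (ref A at Gm10:44732850; alt T is the
#: e2 nonsense allele) and indeterminate Dt1 (four missense dt1 sites).
#: dt1 (R130K) is included for completeness although it is rarely seen.
BUILTIN_REGISTRY = AlleleRegistry(
    entries=(
        AlleleDef(
            gene="E1", chromosome="Gm06", position=20007173,
            ref_symbol=GenotypeSymbol("C"), alt_symbol=GenotypeSymbol("G"),
            ref_allele_name="e1-as", alt_allele_name="E1",
        ),
        AlleleDef(
            gene="E2", chromosome="Gm10", position=44732850,
            ref_symbol=GenotypeSymbol("A"), alt_symbol=GenotypeSymbol("T"),
            ref_allele_name="E2", alt_allele_name="e2",
        ),
        AlleleDef(
            gene="Dt1", chromosome="Gm19", position=44981190,
            ref_symbol=GenotypeSymbol("C"), alt_symbol=GenotypeSymbol("A"),
            ref_allele_name="Dt1", alt_allele_name="dt1 (R62S)",
        ),
        AlleleDef(
            gene="Dt1", chromosome="Gm19", position=44980245,
            ref_symbol=GenotypeSymbol("G"), alt_symbol=GenotypeSymbol("A"),
            ref_allele_name="Dt1", alt_allele_name="dt1 (P113L)",
        ),
        AlleleDef(
            gene="Dt1", chromosome="Gm19", position=44980194,
            ref_symbol=GenotypeSymbol("C"), alt_symbol=GenotypeSymbol("T"),
            ref_allele_name="Dt1", alt_allele_name="dt1 (R130K)",
        ),
        AlleleDef(
            gene="Dt1", chromosome="Gm19", position=44980087,
            ref_symbol=GenotypeSymbol("T"), alt_symbol=GenotypeSymbol("A"),
            ref_allele_name="Dt1", alt_allele_name="dt1 (R166W)",
        ),
    )
)


def haplotype_window(gene_span: Region, flank: int = DEFAULT_FLANK_BP) -> Region:
    """Extend a gene span by ``flank`` bp on each side (clamped at 1)."""
    if flank < 0:
        raise DataError("flank must be non-negative")
    return Region(
        chromosome=gene_span.chromosome,
        start=max(1, gene_span.start - flank),
        end=gene_span.end + flank,
    )


def call_allele(m: SNPMatrix, adef: AlleleDef) -> list[GenotypeCall]:
    """Assign an allele to every sample at one causative SNP.

    Per sample: the ref symbol gives the ref allele name, the alt symbol
    the alt allele name; a missing symbol gives ``no_data``; the IUPAC
    code whose expansion is exactly {ref, alt} gives ``heterozygous``;
    anything else gives ``unknown_variant``.  If the site is absent from
    the matrix entirely, every sample is called with the ref allele name
    and the ``assumed_reference`` flag set (absence from a variant-only
    matrix means "no variant reported").
    """
    if m.chromosome.strip() != adef.chromosome.strip():
        raise DataError(
            f"chromosome mismatch: matrix is {m.chromosome!r}, allele "
            f"site is on {adef.chromosome!r}"
        )
    row = m.position_index(adef.position)
    if row is None:
        return [
            GenotypeCall(
                sample=s,
                call=adef.ref_allele_name,
                observed=adef.ref_symbol,
                assumed_reference=True,
            )
            for s in m.samples
        ]
    het_bases = frozenset(
        {str(adef.ref_symbol), str(adef.alt_symbol)}
    )
    calls = []
    for col, sample in enumerate(m.samples):
        sym = GenotypeSymbol(m.calls[row, col])
        if sym.is_missing:
            call = CALL_NO_DATA
        elif sym == adef.ref_symbol:
            call = adef.ref_allele_name
        elif sym == adef.alt_symbol:
            call = adef.alt_allele_name
        elif sym.bases == het_bases:
            call = CALL_HETEROZYGOUS
        else:
            call = CALL_UNKNOWN
        calls.append(GenotypeCall(sample=sample, call=call, observed=sym))
    return calls


def deletion_signature(
    m: SNPMatrix,
    sample: str,
    scan: Region,
    threshold: float = DEFAULT_MISSING_THRESHOLD,
    min_sites: int = DEFAULT_MIN_SITES,
) -> DeletionSignature:
    """Scan one sample for a run of missing calls consistent with a deletion.

    Counts missing symbols among the SNP positions inside ``scan``; the
    sample is flagged as a deletion *candidate* when the missing fraction
    reaches ``threshold`` over at least ``min_sites`` sites.  The flag is
    heuristic evidence, not an allele call — confirming a deletion needs
    an orthogonal assay.
    """
    sub = slice_region(m, scan)
    column = sub.column(sample)
    missing = np.isin(column, _MISSING_ARR)
    n_sites = int(column.size)
    n_missing = int(missing.sum())
    longest = run = 0
    for flag in missing:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    flagged = (
        n_sites >= min_sites and n_sites > 0
        and n_missing / n_sites >= threshold
    )
    return DeletionSignature(
        sample=sample,
        region=scan,
        n_sites=n_sites,
        n_missing=n_missing,
        longest_run=longest,
        flagged=flagged,
    )


_MISSING_ARR = np.array(["N", "-"], dtype="<U1")


def affected_codon(cds_pos: int) -> int:
    """1-based codon index containing a 1-based CDS position."""
    if cds_pos < 1:
        raise DataError("CDS position must be >= 1")
    return math.ceil(cds_pos / 3)


def frameshift_intact_length(cds_del_pos: int) -> int:
    """N-terminal residues untouched by a frameshift at a CDS position.

    A single-base deletion at CDS position *p* disrupts codon
    ``affected_codon(p)``; every earlier codon still translates
    normally, so ``affected_codon(p) - 1`` residues remain intact.
    """
    return affected_codon(cds_del_pos) - 1


def interval_length(start: int, end: int) -> int:
    """Length of an interval under the coordinate-difference convention.

    Deletion sizes in the allele literature are quoted as ``end - start``
    (not ``end - start + 1``); this helper pins that convention down in
    one place.
    """
    if end < start:
        raise DataError(f"end {end} precedes start {start}")
    return end - start


def _combine_gene_calls(calls: list[GenotypeCall], entries: list[AlleleDef]) -> str:
    """Collapse one sample's per-site calls for a gene into one label.

    Priority: an alt allele observed at any site wins (several alts are
    joined with '+'); then heterozygous; then unknown_variant; a sample
    missing data at every site is no_data; otherwise the (shared) ref
    allele name.  Missing data at *some* sites does not block a ref call
    when the remaining sites are reference — only an observed alt
    positively renames the allele.
    """
    alt_names = [e.alt_allele_name for e in entries]
    hits = [c.call for c in calls if c.call in alt_names]
    if hits:
        return "+".join(dict.fromkeys(hits))
    states = {c.call for c in calls}
    if CALL_HETEROZYGOUS in states:
        return CALL_HETEROZYGOUS
    if CALL_UNKNOWN in states:
        return CALL_UNKNOWN
    if states == {CALL_NO_DATA}:
        return CALL_NO_DATA
    return entries[0].ref_allele_name


def genotype_table(
    m: SNPMatrix,
    registry: AlleleRegistry = BUILTIN_REGISTRY,
    e3_scan: Optional[Region] = None,
    threshold: float = DEFAULT_MISSING_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample allele calls for every registry gene on this chromosome.

    Rows are the non-reference samples; columns are the registry genes
    whose causative sites lie on the matrix chromosome.  Genes whose
    sites are absent from the matrix get assumed-reference calls plus a
    ``<gene>:assumed_reference`` flag column.  With ``e3_scan`` given, a
    ``deletion_candidate`` column reports the missing-data scan
    (``candidate`` / ``-``), for structural alleles that have no
    causative SNP.
    """
    if not registry.entries:
        raise DataError("registry is empty")
    chrom = m.chromosome.strip()
    genes = [
        g for g in registry.genes
        if all(e.chromosome.strip() == chrom for e in registry.for_gene(g))
    ]
    samples = list(m.samples[1:])
    data: dict[str, list[str]] = {}
    flags: dict[str, bool] = {}
    for gene in genes:
        entries = registry.for_gene(gene)
        per_site = [call_allele(m, e) for e in entries]
        assumed = all(cs[0].assumed_reference for cs in per_site)
        flags[gene] = assumed
        column = []
        for si, sample in enumerate(samples, start=1):
            calls = [cs[si] for cs in per_site]
            column.append(_combine_gene_calls(calls, entries))
        data[gene] = column
    table = pd.DataFrame(data, index=pd.Index(samples, name="sample"))
    for gene in genes:
        if flags[gene]:
            table[f"{gene}:assumed_reference"] = True
    if e3_scan is not None:
        table["deletion_candidate"] = [
            "candidate"
            if deletion_signature(m, s, e3_scan, threshold=threshold).flagged
            else "-"
            for s in samples
        ]
    return table
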