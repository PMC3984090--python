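"""Core domain types for region-based SNP haplotype analysis.

The central object is the :class:`SNPMatrix`: one chromosome's variant
positions (rows) by ordered samples (columns), where the first sample is
the reference genome all calls are expressed against.  Cells hold single
IUPAC nucleotide symbols; heterozygous genotypes entered as two-letter
tokens are collapsed to the corresponding ambiguity code at parse time
(:func:`normalize_symbol`).

Coordinates are 1-based and both ends of a :class:`Region` are inclusive
throughout the public API; there is no half-open convention anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "IUPAC_ALPHABET",
    "MISSING_SYMBOLS",
    "AMBIGUITY_SYMBOLS",
    "CODE_TO_BASES",
    "GenotypeSymbol",
    "InvalidTokenError",
    "DataError",
    "normalize_symbol",
    "Region",
    "SNPMatrix",
    "slice_region",
    "DistanceMatrix",
    "TreeNode",
    "HaploTree",
    "HaplogroupPartition",
    "GeneModel",
    "AlleleDef",
    "GenotypeCall",
    "DeletionSignature",
]

#: The 16-symbol alphabet: 4 bases, 10 ambiguity codes, 2 missing markers.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Symbols denoting no data / missing data.  '.' is deliberately NOT
#: accepted as missing; it is rejected as an invalid token.
MISSING_SYMBOLS = frozenset("N-")

#: The 10 ambiguity codes (2-, 3- and 4-base).
AMBIGUITY_SYMBOLS = frozenset("RYSWKMBDHV")

#: Expansion of every non-missing symbol to its base set.
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
}

_PAIR_TO_CODE: dict[frozenset[str], str] = {
    bases: code for code, bases in CODE_TO_BASES.items() if len(bases) == 2
}


class DataError(ValueError):
    """Invalid data content (as opposed to a usage/configuration error)."""


class InvalidTokenError(DataError):
    """A genotype token outside the accepted single/double-nucleotide dialect."""


class GenotypeSymbol(str):
    """A single validated IUPAC genotype symbol.

    Behaves as its one-character string; construction enforces membership
    in the 16-symbol alphabet.
    """

    __slots__ = ()

    def __new__(cls, code: str) -> "GenotypeSymbol":
        if len(code) != 1 or code not in IUPAC_ALPHABET:
            raise InvalidTokenError(
                f"invalid genotype symbol {code!r}: expected one of "
                f"{''.join(sorted(IUPAC_ALPHABET))}"
            )
        return super().__new__(cls, code)

    @property
    def is_missing(self) -> bool:
        return self in MISSING_SYMBOLS

    @property
    def is_ambiguous(self) -> bool:
        return self in AMBIGUITY_SYMBOLS

    @property
    def bases(self) -> frozenset[str]:
        """Base set this symbol may represent (empty for missing symbols)."""
        return CODE_TO_BASES.get(str(self), frozenset())


def normalize_symbol(token: str) -> GenotypeSymbol:
    """Normalize a raw genotype token to a single IUPAC symbol.

    Single-character tokens (bases, ambiguity codes, ``N``, ``-``) pass
    through case-folded.  Two-character tokens of plain bases map
    order-insensitively to the ambiguity code of the pair; an identical
    pair collapses to the base itself (``"TT"`` -> ``T``).

    Raises
    ------
    InvalidTokenError
        For empty tokens, tokens longer than two characters, characters
        outside the alphabet, or double tokens containing non-ACGT
        characters (e.g. ``"AN"``).
    """
    tok = token.strip().upper()
    if len(tok) == 1:
        return GenotypeSymbol(tok)
    if len(tok) == 2:
        a, b = tok[0], tok[1]
        if a not in "ACGT" or b not in "ACGT":
            raise InvalidTokenError(
                f"invalid double-nucleotide token {token!r}: both characters "
                "must be plain bases (A/C/G/T)"
            )
        if a == b:
            return GenotypeSymbol(a)
        return GenotypeSymbol(_PAIR_TO_CODE[frozenset((a, b))])
    raise InvalidTokenError(
        f"invalid genotype token {token!r}: expected 1 or 2 characters"
    )


@dataclass(frozen=True)
class Region:
    """A 1-based, both-ends-inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise DataError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise DataError(
                f"region start {self.start} exceeds end {self.end}"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def span_bp(self) -> int:
        """Number of bases covered (inclusive of both ends)."""
        return self.end - self.start + 1


def _as_symbol_array(calls: np.ndarray) -> np.ndarray:
    arr = np.asarray(calls, dtype="<U1")
    bad = ~np.isin(arr, sorted(IUPAC_ALPHABET))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"invalid genotype symbol {arr[i, j]!r} at cell ({i}, {j})"
        )
    return arr


@dataclass(frozen=True)
class SNPMatrix:
    """Variant positions x ordered samples for one chromosome.

    ``samples[0]`` is the reference genome.  ``calls`` is a dense
    ``(n_positions, n_samples)`` grid of single IUPAC symbols.
    """

    chromosome: str
    positions: np.ndarray
    samples: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "samples", tuple(self.samples))
        if not self.samples:
            raise DataError("SNPMatrix requires at least one sample")
        if len(set(self.samples)) != len(self.samples):
            raise DataError("sample names must be unique")
        if pos.ndim != 1:
            raise DataError("positions must be a 1-D sequence")
        if pos.size and (np.diff(pos) <= 0).any():
            raise DataError("positions must be strictly increasing")
        calls = _as_symbol_array(self.calls)
        if calls.shape != (pos.size, len(self.samples)):
            raise DataError(
                f"calls shape {calls.shape} does not match "
                f"({pos.size} positions, {len(self.samples)} samples)"
            )
        object.__setattr__(self, "calls", calls)

    @property
    def n_positions(self) -> int:
        return int(self.positions.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def reference(self) -> str:
        """Name of the reference sample (first column)."""
        return self.samples[0]

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise DataError(f"unknown sample {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        """Symbol column for one sample, ordered by position."""
        return self.calls[:, self.sample_index(name)]

    def position_index(self, position: int) -> Optional[int]:
        """Row index of ``position``, or None if absent."""
        i = int(np.searchsorted(self.positions, position))
        if i < self.n_positions and self.positions[i] == position:
            return i
        return None

    def equals(self, other: "SNPMatrix") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.samples == other.samples
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.calls, other.calls)
        )


def slice_region(m: SNPMatrix, r: Region) -> SNPMatrix:
    """Restrict a matrix to positions within ``r`` (inclusive bounds).

    The result may hold zero positions; samples are unchanged.
    Chromosome labels must match exactly (after trimming).
    """
    if m.chromosome.strip() != r.chromosome.strip():
        raise DataError(
            f"chromosome mismatch: matrix is {m.chromosome!r}, "
            f"region is {r.chromosome!r}"
        )
    lo = int(np.searchsorted(m.positions, r.start, side="left"))
    hi = int(np.searchsorted(m.positions, r.end, side="right"))
    return SNPMatrix(
        chromosome=m.chromosome,
        positions=m.positions[lo:hi],
        samples=m.samples,
        calls=m.calls[lo:hi, :],
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise identity distances in [0, 1].

    ``compared[i, j]`` counts the positions informative for the pair
    (neither symbol missing); the diagonal counts each sample's
    non-missing cells.
    """

    samples: tuple[str, ...]
    d: np.ndarray
    compared: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        d = np.asarray(self.d, dtype=float)
        c = np.asarray(self.compared, dtype=np.int64)
        n = len(self.samples)
        if d.shape != (n, n) or c.shape != (n, n):
            raise DataError("distance/compared grids must be n x n")
        if not np.allclose(d, d.T):
            raise DataError("distance matrix must be symmetric")
        if (np.diag(d) != 0.0).any():
            raise DataError("distance diagonal must be exactly zero")
        if ((d < 0) | (d > 1)).any():
            raise DataError("distances must lie in [0, 1]")
        if (c < 0).any():
            raise DataError("compared counts must be non-negative")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "compared", c)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted ultrametric tree.

    Leaves carry a sample ``name`` and height 0; internal nodes carry the
    merge height (half the merge distance) and exactly two ordered
    children.
    """

    height: float
    children: tuple["TreeNode", ...] = ()
    name: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        """Leaves in left-to-right order."""
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]  # type: ignore[misc]


@dataclass(frozen=True)
class HaploTree:
    """Rooted binary ultrametric tree over the sample set."""

    root: TreeNode
    samples: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        names = self.root.leaf_names()
        if len(set(names)) != len(names):
            raise DataError("tree leaf names must be unique")
        if not self.samples:
            object.__setattr__(self, "samples", tuple(names))
        elif set(self.samples) != set(names):
            raise DataError("tree leaf set does not match the sample set")

    def leaf_order(self) -> list[str]:
        """Left-to-right display order of the leaves."""
        return self.root.leaf_names()

    def contains(self, name: str) -> bool:
        return name in set(self.root.leaf_names())


@dataclass(frozen=True)
class HaplogroupPartition:
    """Haplogroups from cutting the tree at a branching tier.

    Tier 1 yields the two root-child clades: a reference-like group (the
    one holding the reference sample) and its complement.
    """

    tier: int
    groups: tuple[frozenset[str], ...]
    reference_group_index: int

    def __post_init__(self) -> None:
        if self.tier < 1:
            raise DataError("tier must be a positive integer")
        all_members: set[str] = set()
        for g in self.groups:
            if all_members & g:
                raise DataError("haplogroups must be disjoint")
            all_members |= g
        if not 0 <= self.reference_group_index < len(self.groups):
            raise DataError("reference_group_index out of range")

    @property
    def reference_group(self) -> frozenset[str]:
        return self.groups[self.reference_group_index]


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand and sorted non-overlapping exons."""

    name: str
    strand: str
    span: Region
    exons: tuple[Region, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = None
        for exon in self.exons:
            if exon.start < self.span.start or exon.end > self.span.end:
                raise DataError(
                    f"exon {exon.start}-{exon.end} outside gene span of "
                    f"{self.name}"
                )
            if prev_end is not None and exon.start <= prev_end:
                raise DataError(
                    f"exons of {self.name} must be sorted and non-overlapping"
                )
            prev_end = exon.end

    def exon_index_at(self, position: int) -> Optional[int]:
        """1-based index of the exon covering ``position``, else None."""
        for i, exon in enumerate(self.exons, start=1):
            if position in exon:
                return i
        return None


@dataclass(frozen=True)
class AlleleDef:
    """A causative SNP defining a functional vs variant allele of a gene.

    ``ref_symbol`` is the state of the reference genome at the site and
    carries ``ref_allele_name``; ``alt_symbol`` carries
    ``alt_allele_name``.
    """

    gene: str
    chromosome: str
    position: int
    ref_symbol: GenotypeSymbol
    alt_symbol: GenotypeSymbol
    ref_allele_name: str
    alt_allele_name: str

    def __post_init__(self) -> None:
        ref = GenotypeSymbol(self.ref_symbol)
        alt = GenotypeSymbol(self.alt_symbol)
        if ref.is_missing or alt.is_missing:
            raise DataError("allele symbols may not be missing symbols")
        if ref == alt:
            raise DataError("ref and alt symbols must differ")
        object.__setattr__(self, "ref_symbol", ref)
        object.__setattr__(self, "alt_symbol", alt)


#: Call categories beyond the two allele names.
CALL_NO_DATA = "no_data"
CALL_HETEROZYGOUS = "heterozygous"
CALL_UNKNOWN = "unknown_variant"


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample allele assignment at one causative SNP.

    ``assumed_reference`` marks calls made because the site was absent
    from a variant-only matrix: absence is taken as evidence of the
    reference state, but the flag keeps that weaker inference distinct
    from an observed base.
    """

    sample: str
    call: str
    observed: GenotypeSymbol
    assumed_reference: bool = False

    def __post_init__(self) -> None:
        obs = GenotypeSymbol(self.observed)
        object.__setattr__(self, "observed", obs)
        if (self.call == CALL_NO_DATA) != obs.is_missing:
            raise DataError(
                "call must be 'no_data' exactly when the observed symbol "
                "is missing"
            )


@dataclass(frozen=True)
class DeletionSignature:
    """Run of missing calls in one sample consistent with a deletion.

    A heuristic candidate only: a contiguous stretch of no-data SNP
    positions is what a genomic deletion looks like in a reference-aligned
    SNP matrix, but it is never a definitive allele call.
    """

    sample: str
    region: Region
    n_sites: int
    n_missing: int
    longest_run: int
    flagged: bool

    def __post_init__(self) -> None:
        if not 0 <= self.n_missing <= self.n_sites:
            raise DataError("need 0 <= n_missing <= n_sites")
        if self.longest_run > self.n_missing:
            raise DataError("longest_run cannot exceed n_missing")

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_sites if self.n_sites else 0.0
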