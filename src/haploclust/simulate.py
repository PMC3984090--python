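"""Seeded generator of SNP matrices with planted haplogroup structure.

The generator emulates the structure of reference-aligned resequencing
panels: a few tens of samples drawn from a small number of founder
haplotypes, one of which is the reference itself, with per-cell
sequencing noise, missing calls (as produced by low-coverage mapping),
and contiguous all-missing runs mimicking genomic deletions.  It makes
no attempt at coalescent realism — no recombination, no linkage
disequilibrium — because the planted two-cluster model is exactly what
the downstream operations (identity distance, UPGMA, tier-1
partitioning, deletion scanning) need to be exercised against, with the
truth known by construction.

Reproducibility contract: one global integer seed drives a named
pseudo-random stream per stage, in the fixed order ``positions``,
``reference``, ``founders``, ``assignment``, ``noise``, ``missing``.
Changing, say, the missing rate therefore never perturbs the founder
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    AlleleDef,
    DataError,
    GeneModel,
    Region,
    SNPMatrix,
)

__all__ = [
    "FixtureSpec",
    "generate_matrix",
    "generate_annotation",
    "plant_allele",
    "write_truth_labels",
]

_BASES = np.array(list("ACGT"), dtype="<U1")

#: Stream order of the per-stage random generators (part of the contract).
STREAMS = ("positions", "reference", "founders", "assignment", "noise",
           "missing")


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(
            np.random.SeedSequence(entropy=seed,
                                   spawn_key=(STREAMS.index(name),))
        )
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-haplogroup SNP panel.

    Defaults mirror a low-coverage resequencing panel: ~30 samples plus
    the reference over a gene-sized window, two founder haplotypes
    diverged at 10% of the variant sites, 1% per-cell noise and 5%
    per-cell missing data.
    """

    n_samples: int = 32
    n_sites: int = 300
    region: Region = field(
        default_factory=lambda: Region("Gm06", 20003428, 20011314)
    )
    founders: int = 2
    divergence: float = 0.1
    noise: float = 0.01
    missing: float = 0.05
    deletion_runs: tuple[tuple[tuple[str, ...], Region], ...] = ()
    assignment: Optional[dict[str, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for rate, label in (
            (self.divergence, "divergence"),
            (self.noise, "noise"),
            (self.missing, "missing"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise DataError(f"{label} rate must lie in [0, 1]")
        if self.founders < 1:
            raise DataError("need at least one founder")
        if self.founders > self.n_samples:
            raise DataError("founders cannot exceed n_samples")
        if self.n_samples < 1:
            raise DataError("need at least one sample (the reference)")
        if self.n_sites > self.region.span_bp:
            raise DataError(
                f"{self.n_sites} sites do not fit in a "
                f"{self.region.span_bp} bp region"
            )
        for _, sub in self.deletion_runs:
            if sub.start < self.region.start or sub.end > self.region.end:
                raise DataError("deletion run outside the fixture region")

    @property
    def sample_names(self) -> tuple[str, ...]:
        return ("Ref",) + tuple(
            f"S{i:02d}" for i in range(1, self.n_samples)
        )


def generate_matrix(spec: FixtureSpec) -> tuple[SNPMatrix, dict[str, int]]:
    """Generate a planted-structure matrix and its truth labels.

    The reference column is drawn uniformly from {A,C,G,T}; founder 1 is
    the reference haplotype, and each further founder differs from it at
    a seeded ``divergence``-fraction site set (alternative base drawn
    from the three non-reference bases).  Non-reference samples copy
    their assigned founder, then receive per-cell noise mutations, then
    per-cell missing calls (``N``), then any deletion runs (``-``).  The
    reference column itself stays pristine.  Returns the matrix and a
    ``sample -> founder`` map (1-based founder indices; reference = 1).
    """
    region = spec.region
    offsets = _stream(spec.seed, "positions").choice(
        region.span_bp, size=spec.n_sites, replace=False
    )
    positions = np.sort(offsets.astype(np.int64)) + region.start

    ref = _stream(spec.seed, "reference").choice(_BASES, size=spec.n_sites)

    rng_f = _stream(spec.seed, "founders")
    founder_seqs = [ref]
    for _ in range(spec.founders - 1):
        n_div = int(round(spec.divergence * spec.n_sites))
        sites = rng_f.choice(spec.n_sites, size=n_div, replace=False)
        seq = ref.copy()
        for s in sites:
            others = _BASES[_BASES != ref[s]]
            seq[s] = rng_f.choice(others)
        founder_seqs.append(seq)

    names = spec.sample_names
    if spec.assignment is not None:
        unknown = set(spec.assignment) - set(names[1:])
        if unknown:
            raise DataError(f"assignment names unknown samples: {unknown}")
        labels = [spec.assignment.get(nm, 1) for nm in names[1:]]
        if any(not 1 <= lab <= spec.founders for lab in labels):
            raise DataError("assignment founder index out of range")
    else:
        rng_a = _stream(spec.seed, "assignment")
        labels = list(
            rng_a.integers(1, spec.founders + 1, size=spec.n_samples - 1)
        )

    calls = np.empty((spec.n_sites, spec.n_samples), dtype="<U1")
    calls[:, 0] = ref
    for col, lab in enumerate(labels, start=1):
        calls[:, col] = founder_seqs[int(lab) - 1]

    if spec.n_samples > 1:
        rng_n = _stream(spec.seed, "noise")
        hit = rng_n.random((spec.n_sites, spec.n_samples - 1)) < spec.noise
        for row, col in np.argwhere(hit):
            current = calls[row, col + 1]
            others = _BASES[_BASES != current]
            calls[row, col + 1] = rng_n.choice(others)

        rng_m = _stream(spec.seed, "missing")
        gone = rng_m.random((spec.n_sites, spec.n_samples - 1)) < spec.missing
        calls[:, 1:][gone] = "N"

    for run_samples, sub in spec.deletion_runs:
        rows = (positions >= sub.start) & (positions <= sub.end)
        for nm in run_samples:
            col = names.index(nm)
            if col == 0:
                raise DataError("cannot blank the reference column")
            calls[rows, col] = "-"

    matrix = SNPMatrix(
        chromosome=region.chromosome,
        positions=positions,
        samples=names,
        calls=calls,
    )
    truth = {names[0]: 1}
    truth.update({nm: int(lab) for nm, lab in zip(names[1:], labels)})
    return matrix, truth


def generate_annotation(
    region: Region, n_genes: int, seed: int = 0
) -> list[GeneModel]:
    """Random non-overlapping gene models with 1-5 exons inside a region."""
    if n_genes < 0:
        raise DataError("n_genes must be >= 0")
    if n_genes == 0:
        return []
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    slot = region.span_bp // n_genes
    if slot < 12:
        raise DataError("region too small for the requested gene count")
    models = []
    for g in range(n_genes):
        slot_start = region.start + g * slot
        lo = int(slot_start + rng.integers(0, slot // 4 + 1))
        hi = int(slot_start + slot - 1 - rng.integers(0, slot // 4 + 1))
        span = Region(region.chromosome, lo, hi)
        max_exons = min(5, (hi - lo + 1) // 2)
        n_exons = int(rng.integers(1, max_exons + 1))
        coords = np.sort(
            rng.choice(hi - lo + 1, size=2 * n_exons, replace=False)
        ) + lo
        exons = tuple(
            Region(region.chromosome, int(coords[2 * k]),
                   int(coords[2 * k + 1]))
            for k in range(n_exons)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(name=f"gene{g + 1}", strand=strand, span=span,
                      exons=exons)
        )
    return models


def plant_allele(
    matrix: SNPMatrix, adef: AlleleDef, carriers: Sequence[str]
) -> SNPMatrix:
    """Plant a causative SNP: carriers get the alt symbol at the site.

    If the site is absent, a new row is inserted with the ref symbol
    everywhere first.  The reference sample may not be a carrier.
    """
    carrier_set = set(carriers)
    if matrix.reference in carrier_set:
        raise DataError("the reference sample cannot carry the alt allele")
    unknown = carrier_set - set(matrix.samples)
    if unknown:
        raise DataError(f"unknown carrier samples: {sorted(unknown)}")
    if matrix.chromosome.strip() != adef.chromosome.strip():
        raise DataError(
            f"allele site on {adef.chromosome!r} but matrix is "
            f"{matrix.chromosome!r}"
        )
    row = matrix.position_index(adef.position)
    if row is None:
        insert_at = int(np.searchsorted(matrix.positions, adef.position))
        positions = np.insert(matrix.positions, insert_at, adef.position)
        new_row = np.full(matrix.n_samples, str(adef.ref_symbol), dtype="<U1")
        calls = np.insert(matrix.calls, insert_at, new_row, axis=0)
        row = insert_at
    else:
        positions = matrix.positions.copy()
        calls = matrix.calls.copy()
    for nm in carrier_set:
        calls[row, matrix.sample_index(nm)] = str(adef.alt_symbol)
    return SNPMatrix(
        chromosome=matrix.chromosome,
        positions=positions,
        samples=matrix.samples,
        calls=calls,
    )


def write_truth_labels(truth: dict[str, int], path: str | Path) -> None:
    """Tab-delimited ``sample<TAB>founder`` sidecar for a fixture."""
    lines = ["sample\tfounder"]
    lines.extend(f"{nm}\t{lab}" for nm, lab in truth.items())
    Path(path).write_text("\n".join(lines) + "\n")
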