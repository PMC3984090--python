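"""Merging reference-aligned SNP datasets into one matrix.

Datasets called against the same reference genome can be combined even
when they report different position sets: a position absent from one
dataset but present in another is filled in with the *reference* symbol
for that dataset's samples.  In a variant-only matrix, "no row" means
"no variant reported", so reference fill-in is the faithful merge rule —
but note it biases samples of sparser datasets toward reference-likeness
at positions they never assayed, which in turn shrinks their distances
to the reference.  This is documented behaviour, not an accident.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DataError, SNPMatrix

__all__ = ["DatasetBundle", "MergeConflictError", "merge_datasets"]

log = logging.getLogger(__name__)

#: Soft limit on the number of datasets merged at once; more are allowed
#: but warned about (merging very many panels rarely makes a readable plot).
SOFT_BUNDLE_LIMIT = 3


@dataclass(frozen=True)
class DatasetBundle:
    """A named SNP matrix plus its provenance."""

    name: str
    matrix: SNPMatrix
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise DataError("dataset name must be non-empty")


class MergeConflictError(DataError):
    """Reference symbols disagree at a position shared by two datasets."""


def merge_datasets(
    bundles: Sequence[DatasetBundle],
    on_ref_conflict: str = "error",
) -> SNPMatrix:
    """Merge datasets sharing a chromosome and a reference genome.

    Positions become the sorted union.  Sample order follows bundle
    order with each bundle's internal order preserved; the merged
    reference column is emitted once, from the first bundle, extended to
    the union.  Later bundles' reference columns are dropped when they
    carry the same name as the merged reference (logged), and kept as
    ordinary samples otherwise.  Name collisions across bundles are
    resolved by suffixing ``@<dataset>`` with a warning.

    ``on_ref_conflict``: ``"error"`` (default) raises
    :class:`MergeConflictError` when two bundles disagree on the
    reference symbol at a shared position; ``"prefer_first"`` keeps the
    first bundle's symbol and logs a warning.
    """
    if not bundles:
        raise DataError("merge requires at least one dataset")
    if on_ref_conflict not in ("error", "prefer_first"):
        raise DataError(
            f"on_ref_conflict must be 'error' or 'prefer_first', "
            f"got {on_ref_conflict!r}"
        )
    chromosomes = {b.matrix.chromosome.strip() for b in bundles}
    if len(chromosomes) > 1:
        raise DataError(
            f"cannot merge datasets from different chromosomes: "
            f"{sorted(chromosomes)}"
        )
    if len(bundles) > SOFT_BUNDLE_LIMIT:
        warnings.warn(
            f"merging {len(bundles)} datasets (more than the advisory "
            f"limit of {SOFT_BUNDLE_LIMIT})",
            UserWarning,
            stacklevel=2,
        )

    union = np.unique(np.concatenate([b.matrix.positions for b in bundles]))
    pos_index = {int(p): k for k, p in enumerate(union)}

    # Consolidated reference symbols over the union, first-bundle-wins
    # ordering with agreement checks at shared positions.
    ref_syms = np.empty(union.size, dtype="<U1")
    ref_from = [""] * union.size
    for b in bundles:
        m = b.matrix
        for row, p in enumerate(m.positions):
            k = pos_index[int(p)]
            sym = m.calls[row, 0]
            if not ref_from[k]:
                ref_syms[k] = sym
                ref_from[k] = b.name
            elif ref_syms[k] != sym:
                if on_ref_conflict == "error":
                    raise MergeConflictError(
                        f"reference symbols disagree at position {int(p)}: "
                        f"{ref_syms[k]!r} in dataset {ref_from[k]!r} vs "
                        f"{sym!r} in dataset {b.name!r}"
                    )
                log.warning(
                    "reference conflict at %d: keeping %r from %r, "
                    "ignoring %r from %r",
                    int(p), str(ref_syms[k]), ref_from[k], str(sym), b.name,
                )

    # Assemble sample order and resolve name collisions.
    ref_name = bundles[0].matrix.samples[0]
    out_names: list[str] = [ref_name]
    # (bundle index, column index) backing each output column; the merged
    # reference column is virtual (filled from ref_syms below).
    col_sources: list[tuple[int, int]] = [(-1, -1)]
    seen = {ref_name}
    for bi, b in enumerate(bundles):
        for ci, name in enumerate(b.matrix.samples):
            if bi == 0 and ci == 0:
                continue
            if ci == 0 and name == ref_name:
                log.info(
                    "dropping duplicate reference column %r from dataset %r",
                    name, b.name,
                )
                continue
            out = name
            if out in seen:
                out = f"{name}@{b.name}"
                warnings.warn(
                    f"sample name collision: {name!r} renamed to {out!r}",
                    UserWarning,
                    stacklevel=2,
                )
                if out in seen:
                    raise DataError(
                        f"sample name {out!r} still collides after suffixing"
                    )
            seen.add(out)
            out_names.append(out)
            col_sources.append((bi, ci))

    calls = np.empty((union.size, len(out_names)), dtype="<U1")
    calls[:, 0] = ref_syms
    for out_col, (bi, ci) in enumerate(col_sources):
        if bi < 0:
            continue
        m = bundles[bi].matrix
        column = np.array(ref_syms, copy=True)  # reference fill-in
        rows = np.array([pos_index[int(p)] for p in m.positions], dtype=int)
        column[rows] = m.calls[:, ci]
        calls[:, out_col] = column

    return SNPMatrix(
        chromosome=bundles[0].matrix.chromosome,
        positions=union,
        samples=tuple(out_names),
        calls=calls,
    )
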