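"""Count-table normalization ahead of diversity and network analyses.

Rarefaction (random subsampling without replacement to an even depth),
dominant-OTU selection, presence/absence and relative-abundance transforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable

log = logging.getLogger(__name__)


class RarefactionError(ValueError):
    """A sample is too shallow to be rarefied to the requested depth."""


@dataclass
class RarefiedTable:
    table: OtuTable
    depth: int
    seed: object

    def __post_init__(self) -> None:
        totals = self.table.counts.sum(axis=1)
        if not (totals == self.depth).all():
            raise ValueError("rarefied sample totals must all equal depth")


def rarefy(table: OtuTable, depth: int, seed=None,
           with_replacement: bool = False,
           drop_empty_otus: bool = True) -> RarefiedTable:
    """Randomly subsample every sample to exactly ``depth`` reads.

    Subsampling is without replacement (multivariate hypergeometric), the
    convention of the amplicon literature; ``with_replacement=True`` switches
    to a multinomial draw. Samples shallower than ``depth`` raise — never a
    silent drop. OTUs left with zero counts in *all* samples are removed when
    ``drop_empty_otus`` is set.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = table.counts
    totals = counts.sum(axis=1)
    too_shallow = [sid for sid, tot in zip(table.sample_ids, totals) if tot < depth]
    if too_shallow:
        raise RarefactionError(
            f"samples below depth {depth}: {too_shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if totals[i] == depth:
            out[i] = row
        elif with_replacement:
            out[i] = rng.multinomial(depth, row / totals[i])
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=table.sample_ids, columns=table.otu_ids)
    if drop_empty_otus:
        keep = df.columns[(df > 0).any(axis=0)]
        n_dropped = df.shape[1] - len(keep)
        if n_dropped:
            log.info("rarefy: dropped %d OTUs empty in all samples", n_dropped)
        df = df[keep]
    return RarefiedTable(table=OtuTable(df), depth=depth, seed=seed)


def top_k_otus(table: OtuTable, k: int) -> OtuTable:
    """Keep the ``k`` most dominant OTUs.

    Dominance is the summed raw count across the table's samples; ties are
    broken lexicographically by OTU id so the result is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(table.otu_ids)
    if k >= n:
        if k > n:
            log.warning("top_k_otus: k=%d exceeds %d OTUs; keeping all", k, n)
        return OtuTable(table.data.copy())
    totals = table.data.sum(axis=0)
    ranked = sorted(table.otu_ids, key=lambda o: (-totals[o], o))
    keep = ranked[:k]
    return OtuTable(table.data[keep].copy())


def _check_no_empty_samples(table: OtuTable) -> None:
    totals = table.counts.sum(axis=1)
    empty = [sid for sid, tot in zip(table.sample_ids, totals) if tot == 0]
    if empty:
        raise ValueError(f"all-zero samples: {empty}")


def to_presence_absence(table: OtuTable) -> pd.DataFrame:
    """Binary samples × OTUs matrix (1 where count > 0)."""
    _check_no_empty_samples(table)
    return (table.data > 0).astype(np.int8)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-normalized relative abundances f_ik; every row sums to 1."""
    _check_no_empty_samples(table)
    counts = table.data.astype(float)
    return counts.div(counts.sum(axis=1), axis=0)
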