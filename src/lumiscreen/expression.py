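"""Expression prefilter: keep genes whose median read count across
samples strictly exceeds a threshold, then restrict a screened library
to that expressed set."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


def filter_expressed(
    counts: pd.DataFrame, min_median: float = 20.0
) -> tuple[set[str], pd.DataFrame]:
    """Return the expressed gene set and a per-gene median report.

    A gene is retained iff median(counts across samples) > min_median
    (strict: a median of exactly ``min_median`` is excluded). The
    median over an even number of samples is the mean of the two
    central values.
    """
    if counts.shape[1] < 1:
        raise ValidationError("count table has no sample columns")
    if counts.index.duplicated().any():
        raise ValidationError("duplicate gene ids in count table")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts")
    if counts.empty:
        logger.warning("filter_expressed: empty count table, returning empty set")
        report = pd.DataFrame(columns=["gene_id", "median_count", "expressed"])
        return set(), report

    medians = counts.median(axis=1)
    expressed_mask = medians > min_median
    report = pd.DataFrame(
        {
            "gene_id": counts.index,
            "median_count": medians.to_numpy(),
            "expressed": expressed_mask.to_numpy(),
        }
    ).sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    return set(counts.index[expressed_mask]), report


def restrict_to_expressed(
    screen_genes, expressed: set[str]
) -> tuple[list[str], list[str]]:
    """Split screened genes into (kept, dropped) by expressed membership.

    Matching is case-insensitive (both sides uppercased), the
    convention used when mapping symbols between libraries. The two
    lists partition the input: kept + dropped == screen genes.
    """
    expressed_uc = {g.upper() for g in expressed}
    kept, dropped = [], []
    for gene in screen_genes:
        (kept if gene.upper() in expressed_uc else dropped).append(gene)
    if not kept:
        logger.warning("restrict_to_expressed: no screened gene is expressed")
    return kept, dropped
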