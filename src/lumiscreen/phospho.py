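"""Phosphosite table filtering and differential-regulation testing.

Mirrors a Perseus-style chain on a wide TMT phosphosite table:
decoy/contaminant removal with strict confidence cutoffs, per-sample
log2 + median centering, a two-sample t test per site between
stimulated and control replicate groups, and the dual significance rule
p <= p_max AND |difference| >= min_abs_diff (both inclusive). No
multiple-testing correction enters the significance call; a BH column
is emitted for information only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError
from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "gene", "protein_id", "position", "residue",
    "localization_prob", "score_diff", "reverse", "contaminant",
]

P_FLOOR = np.finfo(float).tiny  # p for zero-variance, unequal-mean degenerate case


def site_id(gene: str, position: int) -> str:
    """Canonical site label: gene symbol with the residue position in parentheses."""
    return f"{gene}({int(position)})"


def filter_sites(
    table: pd.DataFrame,
    min_score_diff: float = 5.0,
    min_localization_prob: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop decoy/contaminant/low-confidence sites.

    Retained iff: not reverse, not contaminant, score_diff strictly
    greater than ``min_score_diff`` and localization_prob strictly
    greater than ``min_localization_prob`` (values exactly at either
    cutoff are removed). Returns (filtered table, exclusion report
    counting each removed row once, by first failing reason).
    """
    for col in META_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"phosphosite table missing column {col!r}")
    reverse = table["reverse"].astype(bool)
    contaminant = table["contaminant"].astype(bool)
    low_score = table["score_diff"] <= min_score_diff
    low_prob = table["localization_prob"] <= min_localization_prob

    reason = np.select(
        [reverse, ~reverse & contaminant,
         ~reverse & ~contaminant & low_score,
         ~reverse & ~contaminant & ~low_score & low_prob],
        ["reverse", "contaminant", "score_diff", "localization_prob"],
        default="",
    )
    kept = table[reason == ""].reset_index(drop=True)
    report = pd.DataFrame(
        {
            "reason": ["reverse", "contaminant", "score_diff", "localization_prob"],
            "n_removed": [
                int((reason == r).sum())
                for r in ("reverse", "contaminant", "score_diff", "localization_prob")
            ],
        }
    )
    return kept, report


def normalize_log(
    table: pd.DataFrame,
    intensity_cols: list[str],
    order: str = "log-then-center",
) -> pd.DataFrame:
    """Transform intensity columns to median-centered log2 values.

    ``order="log-then-center"`` (default, the standard workflow): log2
    each column then subtract that column's median, so every sample
    column has median 0 afterwards. ``"center-then-log"`` divides by the
    column median first, then logs (medians end up 0 either way).
    Idempotent on already-centered log2 data only in the default order.
    """
    if order not in ("log-then-center", "center-then-log"):
        raise ValidationError(f"unknown normalization order {order!r}")
    out = table.copy()
    for col in intensity_cols:
        if col not in out.columns:
            raise SchemaError(f"missing intensity column {col!r}")
        x = out[col].astype(float)
        finite = x.notna()
        if (x[finite] <= 0).any() and order == "center-then-log":
            raise ValidationError(f"nonpositive intensity in column {col!r}")
        if order == "log-then-center":
            if (x[finite] <= 0).any():
                raise ValidationError(f"nonpositive intensity in column {col!r}")
            logged = np.log2(x)
            out[col] = logged - logged[finite].median()
        else:
            centered = x / x[finite].median()
            out[col] = np.log2(centered)
    return out


def site_ttest(group_a, group_b, test: str = "student") -> tuple[float, float]:
    """Two-tailed two-sample t test on centered log2 intensities.

    Returns (difference, p) with difference = mean(a) - mean(b).
    ``test="student"`` pools variances; ``"welch"`` does not. Zero
    variance in both groups: p = 1 if the means agree, else p is set to
    the smallest positive float and logged.
    """
    if test not in ("student", "welch"):
        raise ValidationError(f"unknown test {test!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 finite values per group")
    difference = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if difference == 0:
            return 0.0, 1.0
        logger.warning("site_ttest: zero variance with unequal means; p floored")
        return difference, float(P_FLOOR)
    _, p = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return difference, float(p)


def analyze_sites(
    table: pd.DataFrame,
    stimulated_cols: list[str],
    control_cols: list[str],
    test: str = "student",
    p_max: float = 0.05,
    min_abs_diff: float = 0.2,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-site differential regulation on a normalized, filtered table.

    Significance rule (inclusive on both sides): p <= p_max and
    |difference| >= min_abs_diff. Sites with fewer than
    ``min_per_group`` finite intensities in either group are excluded
    and counted in ``result.attrs["n_excluded_missing"]``.
    """
    if min_per_group < 2:
        raise ValidationError("min_per_group must be >= 2")
    rows = []
    n_excluded = 0
    for row in table.itertuples(index=False):
        a = np.asarray([getattr(row, c) for c in stimulated_cols], dtype=float)
        b = np.asarray([getattr(row, c) for c in control_cols], dtype=float)
        if np.isfinite(a).sum() < min_per_group or np.isfinite(b).sum() < min_per_group:
            n_excluded += 1
            continue
        difference, p = site_ttest(a, b, test=test)
        rows.append(
            {
                "site_id": site_id(row.gene, row.position),
                "gene": row.gene,
                "protein_id": row.protein_id,
                "position": int(row.position),
                "residue": row.residue,
                "difference": difference,
                "p": p,
            }
        )
    if n_excluded:
        logger.warning("analyze_sites: excluded %d site(s) with too many missing values",
                       n_excluded)
    result = pd.DataFrame(
        rows, columns=["site_id", "gene", "protein_id", "position", "residue",
                       "difference", "p"]
    )
    if len(result):
        result["p_adj_info"] = bh_adjust(result["p"])
        result["significant"] = (result["p"] <= p_max) & (
            result["difference"].abs() >= min_abs_diff
        )
        result["direction"] = np.where(result["difference"] >= 0, "up", "down")
    else:
        result["p_adj_info"] = []
        result["significant"] = pd.Series([], dtype=bool)
        result["direction"] = []
    result.attrs["n_excluded_missing"] = n_excluded
    return result


def annotate_sites(
    results: pd.DataFrame,
    gobp_map: pd.DataFrame | None = None,
    regulatory_sites: set[str] | None = None,
) -> pd.DataFrame:
    """Attach GOBP category booleans and a known-regulatory-site flag.

    ``gobp_map`` has columns gene, category (one row per membership);
    ``regulatory_sites`` is a set of site ids like ``"GENE(123)"``.
    Unmatched entries get False and are counted in a log line.
    """
    out = results.copy()
    categories = []
    if gobp_map is not None and len(gobp_map):
        for col in ("gene", "category"):
            if col not in gobp_map.columns:
                raise SchemaError(f"GOBP map missing column {col!r}")
        categories = sorted(gobp_map["category"].unique())
        gene_uc = out["gene"].str.upper()
        for cat in categories:
            members = set(gobp_map.loc[gobp_map["category"] == cat, "gene"].str.upper())
            out[f"gobp_{cat.replace(' ', '_')}"] = gene_uc.isin(members)
    if categories:
        annotated = out[[f"gobp_{c.replace(' ', '_')}" for c in categories]].any(axis=1)
        logger.info("annotate_sites: %d / %d site(s) matched a GOBP category",
                    int(annotated.sum()), len(out))
    out["known_regulatory_site"] = (
        out["site_id"].isin(regulatory_sites) if regulatory_sites else False
    )
    return out


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready export: difference vs -log10 p plus flags, sorted by site."""
    if results.empty:
        return pd.DataFrame(
            columns=["site_id", "difference", "neg_log10_p", "significant", "direction"]
        )
    out = pd.DataFrame(
        {
            "site_id": results["site_id"],
            "difference": results["difference"],
            "neg_log10_p": -np.log10(results["p"]),
            "significant": results["significant"],
            "direction": results["direction"],
        }
    )
    for col in results.columns:
        if col.startswith("gobp_") or col == "known_regulatory_site":
            out[col] = results[col]
    return out.sort_values("site_id", kind="mergesort").reset_index(drop=True)
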