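"""Plate normalization, Z-scoring and activator/inhibitor hit calling.

Stage order for one screen:

1. Each plate of each replicate is normalized by the median raw signal
   of its negative-control wells, so every test well becomes a fold of
   the plate's null luminescence (controls' normalized median = 1).
2. Within each replicate, test wells are standardized:
   z = (x - mean) / sd, with the sample (n-1) standard deviation taken
   over all test wells of that replicate (controls excluded).
3. Per-gene z values are averaged across replicates (unweighted mean;
   genes observed in fewer than ``min_replicates`` replicates are
   excluded with a counted warning, never imputed).
4. Genes are classified by the strict rule: activator if mean_z < -t,
   inhibitor if mean_z > +t (silencing an activator lowers the
   luminescent signal). Values exactly at +/-t are not hits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .io import ScreenDataset

logger = logging.getLogger(__name__)

HIT_CLASSES = ("activator", "inhibitor", "none")


def normalize_plate(raw: pd.Series, control_values: np.ndarray, min_controls: int = 3) -> pd.Series:
    """Divide one plate's raw wells by the median of its negative controls."""
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size < min_controls:
        raise DegenerateDataError(
            f"plate has {control_values.size} negative controls, need >= {min_controls}"
        )
    if (control_values <= 0).any():
        raise ValidationError("nonpositive control RLU")
    ctl_median = float(np.median(control_values))
    if ctl_median <= 0:
        raise DegenerateDataError("nonpositive control median")
    return raw / ctl_median


def normalize_screen(dataset: ScreenDataset, min_controls: int = 3) -> pd.DataFrame:
    """Normalize every (plate, replicate) against its own controls.

    Returns a long table over occupied wells: plate_id, well, replicate,
    role, gene_id, normalized.
    """
    pm = dataset.platemap[["plate_id", "well", "role", "gene_id"]]
    df = dataset.measurements.merge(pm, on=["plate_id", "well"], how="left", validate="m:1")
    if df["role"].isna().any():
        raise ValidationError("measurement well missing from plate map")
    if (df["rlu"] <= 0).any():
        raise ValidationError("nonpositive RLU in measurements")

    out = []
    for (plate, rep), grp in df.groupby(["plate_id", "replicate"], sort=True):
        controls = grp.loc[grp["role"] == "negative_control", "rlu"].to_numpy()
        if controls.size < min_controls:
            raise DegenerateDataError(
                f"plate {plate} replicate {rep}: {controls.size} negative controls, "
                f"need >= {min_controls}"
            )
        normalized = normalize_plate(grp["rlu"], controls, min_controls=min_controls)
        out.append(grp.assign(normalized=normalized))
    res = pd.concat(out, ignore_index=True)
    return res[["plate_id", "well", "replicate", "role", "gene_id", "normalized"]]


def zscore(values) -> np.ndarray:
    """Standardize: (x - mean) / sample standard deviation (divisor n-1).

    Deviations are re-centered after the first pass so the output mean
    is 0 to machine precision even for nearly-constant inputs.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateDataError("zscore needs >= 2 distinct values")
    d = x - x.mean()
    d -= d.mean()
    sd = np.sqrt((d * d).sum() / (x.size - 1))
    if sd == 0:
        raise DegenerateDataError("zero standard deviation")
    return d / sd


def zscore_replicates(
    normalized: pd.DataFrame,
    log2: bool = False,
    scope: str = "replicate",
    include_controls: bool = False,
) -> pd.DataFrame:
    """Compute per-well z-scores of test wells.

    ``scope`` selects the population over which the mean and standard
    deviation are taken: ``"replicate"`` (default: all test wells of one
    replicate, after plate normalization) or ``"plate"`` (each plate of
    each replicate separately). ``include_controls`` adds control wells
    to that population; z values are still reported for test wells only.
    ``log2`` standardizes log2(normalized) instead of the natural scale.
    """
    if scope not in ("replicate", "plate"):
        raise ValidationError(f"unknown z-score scope {scope!r}")
    df = normalized[normalized["role"].isin(["test", "negative_control"])].copy()
    signal = np.log2(df["normalized"]) if log2 else df["normalized"]
    df["signal"] = signal

    group_cols = ["replicate"] if scope == "replicate" else ["replicate", "plate_id"]
    pieces = []
    for _, grp in df.groupby(group_cols, sort=True):
        pop = grp if include_controls else grp[grp["role"] == "test"]
        pop_vals = pop["signal"].to_numpy(dtype=float)
        zscore(pop_vals)  # degenerate-input checks
        mu = pop_vals.mean()
        mu += (pop_vals - mu).mean()  # two-pass centering, see zscore()
        sd = np.sqrt(((pop_vals - mu) ** 2).sum() / (pop_vals.size - 1))
        tests = grp[grp["role"] == "test"].copy()
        tests["z"] = (tests["signal"].to_numpy(dtype=float) - mu) / sd
        pieces.append(tests[["gene_id", "plate_id", "well", "replicate", "z"]])
    return pd.concat(pieces, ignore_index=True)


def aggregate_replicates(ztable: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Average per-gene z across replicates.

    Input: long table with gene_id, replicate, z. Genes with fewer than
    ``min_replicates`` finite z values are excluded with a logged,
    counted warning. Output: one row per gene with z_rep<i> columns,
    mean_z and n_replicates_used, sorted by gene_id.
    """
    if min_replicates < 1:
        raise ValidationError("min_replicates must be >= 1")
    t = ztable[np.isfinite(ztable["z"])]
    wide = t.pivot_table(index="gene_id", columns="replicate", values="z", aggfunc="mean")
    wide.columns = [f"z_rep{int(r)}" for r in wide.columns]
    n_used = wide.notna().sum(axis=1)
    excluded = sorted(wide.index[n_used < min_replicates])
    if excluded:
        logger.warning(
            "aggregate_replicates: excluded %d gene(s) with < %d replicates: %s",
            len(excluded), min_replicates, ", ".join(excluded[:10]),
        )
    kept = wide[n_used >= min_replicates].copy()
    kept["mean_z"] = kept.filter(like="z_rep").mean(axis=1)
    kept["n_replicates_used"] = n_used[kept.index].astype(int)
    kept = kept.sort_index().reset_index()
    kept.attrs["n_excluded"] = len(excluded)
    kept.attrs["excluded_genes"] = excluded
    return kept


def call_hits(gene_table: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Classify genes by replicate-mean z with strict +/- threshold.

    activator: mean_z < -threshold (silencing decreased the signal);
    inhibitor: mean_z > +threshold; otherwise none. Values exactly at
    the threshold are not hits.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if not np.isfinite(gene_table["mean_z"]).all():
        raise ValidationError("non-finite mean_z")
    out = gene_table.copy()
    out["hit_class"] = np.select(
        [out["mean_z"] < -threshold, out["mean_z"] > threshold],
        ["activator", "inhibitor"],
        default="none",
    )
    return out


def annotate_viability(
    gene_table: pd.DataFrame, viability: pd.DataFrame, min_ratio: float = 0.7
) -> pd.DataFrame:
    """Flag genes whose silencing dropped viability below ``min_ratio``.

    ``viability`` has columns gene_id, ratio (silenced / control, > 0).
    Annotation only: hit classes are never changed. Genes absent from
    the viability table keep a missing flag and are counted in a
    warning.
    """
    if (viability["ratio"] <= 0).any():
        raise ValidationError("viability ratios must be > 0")
    ratios = viability.set_index("gene_id")["ratio"]
    if ratios.index.duplicated().any():
        raise ValidationError("duplicate gene_id in viability table")
    out = gene_table.copy()
    mapped = out["gene_id"].map(ratios)
    out["viability_flag"] = (mapped < min_ratio).where(mapped.notna(), other=pd.NA)
    n_missing = int(mapped.isna().sum())
    if n_missing:
        logger.warning("annotate_viability: %d gene(s) missing from viability table", n_missing)
    return out


def score_screen(
    dataset: ScreenDataset,
    threshold: float = 2.0,
    min_replicates: int = 2,
    log2: bool = False,
    scope: str = "replicate",
    include_controls: bool = False,
    min_controls: int = 3,
    viability: pd.DataFrame | None = None,
    min_viability_ratio: float = 0.7,
) -> pd.DataFrame:
    """Full screen scoring: normalize -> z -> aggregate -> call hits."""
    normalized = normalize_screen(dataset, min_controls=min_controls)
    ztable = zscore_replicates(
        normalized, log2=log2, scope=scope, include_controls=include_controls
    )
    gene_table = aggregate_replicates(ztable, min_replicates=min_replicates)
    gene_table = call_hits(gene_table, threshold=threshold)
    if viability is not None:
        gene_table = annotate_viability(gene_table, viability, min_ratio=min_viability_ratio)
    return gene_table


def hit_summary(gene_table: pd.DataFrame) -> dict:
    """Totals per class; activators and inhibitors partition the hits."""
    counts = gene_table["hit_class"].value_counts()
    n_act = int(counts.get("activator", 0))
    n_inh = int(counts.get("inhibitor", 0))
    return {
        "genes_scored": int(len(gene_table)),
        "genes_excluded": int(gene_table.attrs.get("n_excluded", 0)),
        "hits": n_act + n_inh,
        "activators": n_act,
        "inhibitors": n_inh,
    }
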