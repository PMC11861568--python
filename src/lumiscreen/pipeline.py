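"""End-to-end orchestration of the analysis stages.

Each runner executes its stages in a fixed order, logs per-stage
in/out counts to stderr via :mod:`logging`, asserts count conservation
at every filter, and writes deterministic TSV/JSON outputs stamped with
a config hash and seed, so reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import enrichment, expression, hits, phospho
from . import io as sio
from .errors import ValidationError

logger = logging.getLogger(__name__)


def _log_stage(stage: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall_s=%.2f %s", stage, time.monotonic() - t0, extras)


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_screen_pipeline(
    platemap_path,
    measurements_path,
    out_dir,
    counts_path=None,
    min_median: float = 20.0,
    threshold: float = 2.0,
    min_replicates: int = 2,
    log2: bool = False,
    scope: str = "replicate",
    include_controls: bool = False,
    viability_path=None,
    min_viability_ratio: float = 0.7,
    seed: int | None = None,
) -> dict:
    """Expression filter -> plate normalization -> Z -> hit calling.

    Writes hits.tsv, summary.json (plus medians.tsv / expressed_genes.txt
    when a count table is supplied) and a metadata sidecar; returns the
    summary dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = dict(
        platemap=str(platemap_path), measurements=str(measurements_path),
        counts=str(counts_path), min_median=min_median, threshold=threshold,
        min_replicates=min_replicates, log2=log2, scope=scope,
        include_controls=include_controls, viability=str(viability_path),
        min_viability_ratio=min_viability_ratio,
    )

    t0 = time.monotonic()
    dataset = sio.read_screen(platemap_path, measurements_path)
    library_genes = dataset.genes
    _log_stage("read_screen", t0, wells=len(dataset.measurements), genes=len(library_genes))

    kept, dropped = library_genes, []
    if counts_path is not None:
        t0 = time.monotonic()
        counts = sio.read_counts(counts_path)
        expressed, medians = expression.filter_expressed(counts, min_median=min_median)
        kept, dropped = expression.restrict_to_expressed(library_genes, expressed)
        if len(kept) + len(dropped) != len(library_genes):
            raise AssertionError("expression filter broke count conservation")
        if not kept:
            raise ValidationError("no genes after expression filter")
        sio.write_table(medians, out_dir / "medians.tsv", sort_by=["gene_id"])
        sio.write_gene_list(sorted(kept), out_dir / "expressed_genes.txt")
        keep_set = set(kept)
        pm = dataset.platemap.copy()
        drop_mask = (pm["role"] == "test") & ~pm["gene_id"].isin(keep_set)
        pm.loc[drop_mask, ["role", "gene_id"]] = ["empty", ""]
        dropped_wells = set(
            zip(dataset.platemap.loc[drop_mask, "plate_id"], dataset.platemap.loc[drop_mask, "well"])
        )
        ms = dataset.measurements
        ms = ms[~pd.Series(list(zip(ms["plate_id"], ms["well"]))).isin(dropped_wells).to_numpy()]
        dataset = sio.ScreenDataset(platemap=pm, measurements=ms.reset_index(drop=True))
        _log_stage("expression_filter", t0, genes_in=len(library_genes),
                   genes_kept=len(kept), genes_dropped=len(dropped))

    viability = None
    if viability_path is not None:
        viability = pd.read_csv(viability_path, sep="\t")

    t0 = time.monotonic()
    gene_table = hits.score_screen(
        dataset, threshold=threshold, min_replicates=min_replicates, log2=log2,
        scope=scope, include_controls=include_controls,
        viability=viability, min_viability_ratio=min_viability_ratio,
    )
    summary_counts = hits.hit_summary(gene_table)
    _log_stage("score_screen", t0, **summary_counts)
    if summary_counts["genes_scored"] + summary_counts["genes_excluded"] != len(kept):
        raise AssertionError("scoring broke count conservation")

    sio.write_table(gene_table, out_dir / "hits.tsv", sort_by=["gene_id"])
    summary = {
        "config_hash": sio.config_hash(params),
        "seed": seed,
        "genes_in_library": len(library_genes),
        "genes_expressed": len(kept),
        "genes_dropped_not_expressed": len(dropped),
        **summary_counts,
    }
    _write_json(summary, out_dir / "summary.json")
    sio.write_run_metadata(out_dir, "screen_pipeline", params, seed=seed)
    return summary


def run_enrichment(
    query_path,
    gmt_paths,
    out_dir,
    universe_path=None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Over-representation of a query list against one or more GMT files.

    Libraries are concatenated; duplicate term names get a file-index
    suffix. The universe defaults to the union of the query and all
    library genes when no universe file is supplied (a screen-wide
    universe file is the recommended input).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = dict(query=str(query_path), gmt=[str(p) for p in gmt_paths],
                  universe=str(universe_path), alpha=alpha,
                  n_permutations=n_permutations)

    t0 = time.monotonic()
    query = sio.read_gene_list(query_path)
    library: dict[str, list[str]] = {}
    for i, path in enumerate(gmt_paths):
        for term, genes in sio.read_gmt(path).items():
            name = term if term not in library else f"{term}|{i}"
            library[name] = genes
    if universe_path is not None:
        universe = sio.read_gene_list(universe_path)
    else:
        universe = sorted({g.upper() for g in query}
                          | {g.upper() for gs in library.values() for g in gs})
        logger.warning("run_enrichment: no universe supplied; using query + library union "
                       "(%d genes)", len(universe))
    results = enrichment.enrich(
        query, library, universe, alpha=alpha, n_permutations=n_permutations, seed=seed
    )
    _log_stage("enrich", t0, terms=len(results),
               significant=int(results["significant"].sum()))
    results.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    sio.write_run_metadata(out_dir, "enrichment", params, seed=seed)
    return results


def run_phospho_pipeline(
    table_path,
    out_dir,
    stimulated_cols: list[str] | None = None,
    control_cols: list[str] | None = None,
    test: str = "student",
    order: str = "log-then-center",
    p_max: float = 0.05,
    min_abs_diff: float = 0.2,
    min_score_diff: float = 5.0,
    min_localization_prob: float = 0.5,
    gobp_path=None,
    regulatory_path=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Filter -> normalize -> per-site t test -> annotate -> export.

    Channel-to-condition mapping is explicit: ``stimulated_cols`` /
    ``control_cols`` name the intensity columns of each group. When
    omitted, columns named ``stimulated_*`` / ``control_*`` are used.
    Writes phospho_results.tsv, exclusions.tsv and volcano.tsv.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(table_path, sep="\t")
    if stimulated_cols is None:
        stimulated_cols = sorted(c for c in table.columns if c.startswith("stimulated_"))
    if control_cols is None:
        control_cols = sorted(c for c in table.columns if c.startswith("control_"))
    if not stimulated_cols or not control_cols:
        raise ValidationError("no stimulated/control intensity columns identified")
    params = dict(table=str(table_path), stimulated=stimulated_cols,
                  control=control_cols, test=test, order=order, p_max=p_max,
                  min_abs_diff=min_abs_diff, min_score_diff=min_score_diff,
                  min_localization_prob=min_localization_prob)

    t0 = time.monotonic()
    filtered, report = phospho.filter_sites(
        table, min_score_diff=min_score_diff, min_localization_prob=min_localization_prob
    )
    if len(filtered) + int(report["n_removed"].sum()) != len(table):
        raise AssertionError("site filter broke count conservation")
    _log_stage("filter_sites", t0, sites_in=len(table), sites_kept=len(filtered))

    t0 = time.monotonic()
    normalized = phospho.normalize_log(filtered, stimulated_cols + control_cols, order=order)
    results = phospho.analyze_sites(
        normalized, stimulated_cols, control_cols, test=test,
        p_max=p_max, min_abs_diff=min_abs_diff,
    )
    _log_stage("analyze_sites", t0, sites=len(results),
               significant=int(results["significant"].sum()) if len(results) else 0)

    gobp_map = pd.read_csv(gobp_path, sep="\t") if gobp_path is not None else None
    regulatory = set(sio.read_gene_list(regulatory_path)) if regulatory_path else None
    results = phospho.annotate_sites(results, gobp_map=gobp_map, regulatory_sites=regulatory)

    sio.write_table(results, out_dir / "phospho_results.tsv", sort_by=["site_id"])
    sio.write_table(report, out_dir / "exclusions.tsv")
    sio.write_table(phospho.volcano_table(results), out_dir / "volcano.tsv")
    sio.write_run_metadata(out_dir, "phospho_pipeline", params, seed=seed)
    return results
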