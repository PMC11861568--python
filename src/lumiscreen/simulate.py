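"""Seeded generators for synthetic screens, count tables, gene-set
libraries and phosphosite tables, with ground-truth records for
recovery testing.

The screen generator follows a multiplicative model: each well's raw
luminescence is

    rlu = plate_factor(plate, replicate) * baseline * gene_fold * noise

where ``plate_factor`` is lognormal with median 1, ``gene_fold`` is 1
for negative controls and unplanted genes and the configured fold for
planted activators/inhibitors, and ``noise`` is lognormal with mean 1
and coefficient of variation ``noise_cv``. Plate normalization against
the negative-control median therefore cancels the plate factor exactly.

All generators are deterministic functions of their configuration,
including the seed: equal configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import CapacityError, ValidationError
from .io import ScreenDataset, format_well

CONTROL_TYPE_CYCLE = ("GFP", "Scrambled", "AllStars")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Design and generative parameters of a simulated arrayed screen."""

    n_genes: int
    n_plates_per_replicate: int
    n_controls_per_plate: int
    n_replicates: int = 3
    plate_rows: int = 16
    plate_cols: int = 24
    baseline_rlu: float = 10_000.0
    plate_factor_sd: float = 0.15
    noise_cv: float = 0.10
    activator_genes: int = 0
    activator_effect: float = 0.5
    inhibitor_genes: int = 0
    inhibitor_effect: float = 2.0
    edge_gradient: float = 0.0  # optional additive row/column trend, off by default
    seed: int = 0

    @property
    def wells_per_plate(self) -> int:
        return self.plate_rows * self.plate_cols

    @property
    def test_capacity(self) -> int:
        return self.n_plates_per_replicate * (self.wells_per_plate - self.n_controls_per_plate)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_plates_per_replicate < 1 or self.n_replicates < 1:
            raise ValidationError("plate and replicate counts must be >= 1")
        if self.n_controls_per_plate < 0 or self.n_controls_per_plate >= self.wells_per_plate:
            raise ValidationError("n_controls_per_plate must be in [0, wells_per_plate)")
        if self.noise_cv <= 0:
            raise ValidationError("noise_cv must be > 0")
        if self.plate_factor_sd < 0:
            raise ValidationError("plate_factor_sd must be >= 0")
        if self.baseline_rlu <= 0:
            raise ValidationError("baseline_rlu must be > 0")
        if not 0 < self.activator_effect < 1:
            raise ValidationError("activator_effect must be in (0, 1)")
        if not self.inhibitor_effect > 1:
            raise ValidationError("inhibitor_effect must be > 1")
        if self.activator_genes < 0 or self.inhibitor_genes < 0:
            raise ValidationError("planted gene counts must be >= 0")
        if self.activator_genes + self.inhibitor_genes > self.n_genes:
            raise ValidationError("planted genes exceed n_genes")
        if self.n_genes > self.test_capacity:
            raise CapacityError(
                f"{self.n_genes} genes do not fit in "
                f"{self.n_plates_per_replicate} plates x "
                f"{self.wells_per_plate - self.n_controls_per_plate} test wells "
                f"(capacity {self.test_capacity})"
            )


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # lognormal with E[X] = 1 and CV = cv
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_screen(config: ScreenSimConfig) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a full multi-plate, multi-replicate screen.

    Returns the dataset plus a truth table with one row per gene
    (``gene_id``, ``planted_class`` in {activator, inhibitor, null},
    ``planted_fold``). The plate map (including randomized control
    positions) is shared by all replicates, mirroring a fixed library
    layout screened in replicate plate sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)
    classes = np.full(config.n_genes, "null", dtype=object)
    folds = np.ones(config.n_genes)
    classes[order[: config.activator_genes]] = "activator"
    folds[order[: config.activator_genes]] = config.activator_effect
    n_act = config.activator_genes
    classes[order[n_act: n_act + config.inhibitor_genes]] = "inhibitor"
    folds[order[n_act: n_act + config.inhibitor_genes]] = config.inhibitor_effect
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "planted_class": classes, "planted_fold": folds}
    )
    fold_by_gene = dict(zip(gene_ids, folds))

    wells = [
        format_well(r, c)
        for r in range(config.plate_rows)
        for c in range(config.plate_cols)
    ]
    pm_rows = []
    next_gene = 0
    for p in range(config.n_plates_per_replicate):
        plate_id = f"P{p + 1:02d}"
        control_idx = set(
            rng.choice(config.wells_per_plate, size=config.n_controls_per_plate, replace=False)
        )
        n_ctl = 0
        for w, well in enumerate(wells):
            if w in control_idx:
                ctype = CONTROL_TYPE_CYCLE[n_ctl % len(CONTROL_TYPE_CYCLE)]
                pm_rows.append((plate_id, well, "negative_control", "", ctype))
                n_ctl += 1
            elif next_gene < config.n_genes:
                pm_rows.append((plate_id, well, "test", gene_ids[next_gene], ""))
                next_gene += 1
            else:
                pm_rows.append((plate_id, well, "empty", "", ""))
    platemap = pd.DataFrame(
        pm_rows, columns=["plate_id", "well", "role", "gene_id", "control_type"]
    )

    occupied = platemap[platemap["role"] != "empty"].reset_index(drop=True)
    well_fold = np.array(
        [
            fold_by_gene[g] if role == "test" else 1.0
            for role, g in zip(occupied["role"], occupied["gene_id"])
        ]
    )
    row_idx = occupied["well"].str.extract(r"^([A-P])", expand=False).map(
        lambda ch: ord(ch) - ord("A")
    ).to_numpy()
    col_idx = occupied["well"].str.extract(r"([0-9]+)$", expand=False).astype(int).to_numpy() - 1
    edge = config.edge_gradient * config.baseline_rlu * (
        row_idx / max(config.plate_rows - 1, 1) + col_idx / max(config.plate_cols - 1, 1) - 1.0
    )

    plate_ids = sorted(platemap["plate_id"].unique())
    frames = []
    for rep in range(1, config.n_replicates + 1):
        plate_factors = dict(
            zip(plate_ids, rng.lognormal(0.0, config.plate_factor_sd, size=len(plate_ids)))
        )
        noise = _lognormal_mean_one(rng, config.noise_cv, len(occupied))
        rlu = (
            occupied["plate_id"].map(plate_factors).to_numpy()
            * config.baseline_rlu
            * well_fold
            * noise
            + edge
        )
        if (rlu <= 0).any():
            raise ValidationError("edge_gradient drove a well nonpositive; reduce it")
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": occupied["plate_id"],
                    "well": occupied["well"],
                    "replicate": rep,
                    "rlu": rlu,
                }
            )
        )
    measurements = pd.concat(frames, ignore_index=True)
    return ScreenDataset(platemap=platemap, measurements=measurements), truth


def generate_counts(
    n_genes: int,
    n_samples: int = 3,
    expressed_fraction: float = 0.5,
    expressed_mean: float = 500.0,
    expressed_dispersion: float = 10.0,
    unexpressed_mean: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Simulate a gene x sample read-count table.

    Expressed genes draw negative-binomial counts with mean
    ``expressed_mean`` (well above the median-20 boundary); unexpressed
    genes draw Poisson counts with mean ``unexpressed_mean`` (well
    below). Returns the table (index gene_id) and the truth set of
    expressed genes.
    """
    if not 0 <= expressed_fraction <= 1:
        raise ValidationError("expressed_fraction must be in [0, 1]")
    if n_genes < 0 or n_samples < 1:
        raise ValidationError("n_genes >= 0 and n_samples >= 1 required")
    if expressed_mean <= 20 <= unexpressed_mean or expressed_mean <= unexpressed_mean:
        raise ValidationError("count means must straddle the median-20 boundary")
    rng = np.random.default_rng(seed)
    gene_ids = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    n_expressed = int(round(expressed_fraction * n_genes))
    expressed = set(rng.choice(gene_ids, size=n_expressed, replace=False)) if n_genes else set()
    counts = np.empty((n_genes, n_samples), dtype=int)
    # negative binomial parametrised by mean m and size r: p = r / (r + m)
    r = expressed_dispersion
    p = r / (r + expressed_mean)
    for i, gene in enumerate(gene_ids):
        if gene in expressed:
            counts[i] = rng.negative_binomial(r, p, size=n_samples)
        else:
            counts[i] = rng.poisson(unexpressed_mean, size=n_samples)
    table = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                         columns=[f"sample_{j + 1}" for j in range(n_samples)])
    return table, expressed


def generate_gmt(
    n_terms: int,
    term_size_range: tuple[int, int],
    universe: list[str],
    query: list[str] | None = None,
    enriched_overlap: int = 0,
    enriched_term: str = "TERM_PLANTED",
    seed: int = 0,
) -> dict[str, list[str]]:
    """Simulate a gene-set library over ``universe``.

    If ``query`` and ``enriched_overlap`` are given, the designated term
    ``enriched_term`` contains exactly ``enriched_overlap`` genes of the
    query (the rest drawn outside it), so that it is enriched in the
    query by construction. Remaining terms are uniform draws from the
    universe.
    """
    lo, hi = term_size_range
    if not 1 <= lo <= hi:
        raise ValidationError("term_size_range must satisfy 1 <= lo <= hi")
    if hi > len(universe):
        raise ValidationError("term size exceeds universe size")
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    library: dict[str, list[str]] = {}

    if query is not None and enriched_overlap > 0:
        query = list(query)
        if enriched_overlap > len(query):
            raise ValidationError("enriched_overlap exceeds query size")
        size = int(rng.integers(lo, hi + 1))
        size = max(size, enriched_overlap)
        inside = list(rng.choice(query, size=enriched_overlap, replace=False))
        outside_pool = [g for g in universe if g not in set(query)]
        n_out = size - enriched_overlap
        if n_out > len(outside_pool):
            raise ValidationError("universe too small for the requested planted term")
        outside = list(rng.choice(outside_pool, size=n_out, replace=False))
        library[enriched_term] = sorted(inside + outside)

    i = 0
    while len(library) < n_terms:
        i += 1
        name = f"TERM{i:04d}"
        if name in library:
            continue
        size = int(rng.integers(lo, hi + 1))
        library[name] = sorted(rng.choice(universe, size=size, replace=False))
    return library


@dataclass(frozen=True)
class PhosphoSimConfig:
    """Generative parameters for a synthetic TMT phosphosite table."""

    n_sites: int
    n_regulated: int
    n_replicates: int = 4
    group_difference: float = 1.0  # planted |log2 stimulated - control|
    within_group_sd: float = 0.2
    frac_reverse: float = 0.0
    frac_contaminant: float = 0.0
    loc_prob_beta: tuple[float, float] = (8.0, 1.0)  # Beta params on [0, 1]
    score_diff_gamma: tuple[float, float] = (4.0, 5.0)  # shape, scale (nonnegative)
    base_log2_mean: float = 20.0
    base_log2_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if not 0 <= self.n_regulated <= self.n_sites:
            raise ValidationError("n_regulated must be in [0, n_sites]")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.within_group_sd <= 0:
            raise ValidationError("within_group_sd must be > 0")
        for frac, name in ((self.frac_reverse, "frac_reverse"),
                           (self.frac_contaminant, "frac_contaminant")):
            if not 0 <= frac <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if min(self.loc_prob_beta) <= 0 or min(self.score_diff_gamma) <= 0:
            raise ValidationError("distribution parameters must be positive")


RESIDUES = ("S", "T", "Y")


def generate_phospho(config: PhosphoSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a wide phosphosite intensity table plus its truth table.

    Regulated sites carry a planted stimulated-minus-control group-mean
    log2 difference of +/- ``group_difference`` (sign alternating at
    random); all sites get within-group gaussian log2 noise. Reverse and
    contaminant flags are assigned independently at the configured
    fractions. Columns: site metadata plus ``stimulated_1..n`` and
    ``control_1..n`` raw intensities.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, nrep = config.n_sites, config.n_replicates

    genes = [f"PGENE{i + 1:05d}" for i in range(n)]
    proteins = [f"PROT{i + 1:05d}" for i in range(n)]
    positions = rng.integers(1, 1000, size=n)
    residues = rng.choice(RESIDUES, size=n, p=(0.75, 0.2, 0.05))
    loc_prob = rng.beta(*config.loc_prob_beta, size=n)
    score_diff = rng.gamma(config.score_diff_gamma[0], config.score_diff_gamma[1], size=n)
    reverse = rng.random(n) < config.frac_reverse
    contaminant = rng.random(n) < config.frac_contaminant

    regulated_idx = rng.choice(n, size=config.n_regulated, replace=False)
    delta = np.zeros(n)
    signs = np.where(rng.random(config.n_regulated) < 0.5, -1.0, 1.0)
    delta[regulated_idx] = signs * config.group_difference

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    ctl = base[:, None] + rng.normal(0.0, config.within_group_sd, size=(n, nrep))
    stim = (base + delta)[:, None] + rng.normal(0.0, config.within_group_sd, size=(n, nrep))

    table = pd.DataFrame(
        {
            "gene": genes,
            "protein_id": proteins,
            "position": positions,
            "residue": residues,
            "localization_prob": loc_prob,
            "score_diff": score_diff,
            "reverse": reverse,
            "contaminant": contaminant,
        }
    )
    for j in range(nrep):
        table[f"stimulated_{j + 1}"] = np.exp2(stim[:, j])
    for j in range(nrep):
        table[f"control_{j + 1}"] = np.exp2(ctl[:, j])

    truth = pd.DataFrame(
        {
            "site_id": [f"{g}({p})" for g, p in zip(genes, positions)],
            "regulated": delta != 0.0,
            "planted_difference": delta,
        }
    )
    return table, truth


def config_dict(config) -> dict:
    """Flatten a sim config dataclass for metadata sidecars."""
    return asdict(config)
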