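"""Resampling-ensemble prognostic screen.

Training samples are randomized into "virtual cohorts" for a configurable
number of testing cycles (default 20), each containing roughly 70% of
patients drawn without replacement.  Within a cycle every gene receives a
prognostic score — by default the Wald statistic of its univariate Cox fit
on the cycle's samples — and the genes are ranked; membership of the
per-cycle top list (default top 200) is tallied across cycles.  A gene is
selected into the signature when it recurs in the top list in at least
``recurrence_min`` cycles AND its aggregate prognostic rating (median Wald
across the cycles where it ranked) exceeds ``wald_floor_frac`` (default
half) of the maximum rating in the screen.  The signature then defines a
combined prognostic rating model: a per-sample risk score that is the
rating-weighted, direction-signed sum of the signature genes' z-scores.

Two scoring modes exist.  ``univariate`` (default): a gene's score within
any random gene subset is just its univariate Wald on the cycle's samples,
which does not depend on the subset — so the random-subset loop collapses
analytically and each gene is scored once per cycle (this also makes the
screen's output independent of the input gene order).  ``component``: each
random gene subset is fit with a latent-component partial Cox model and a
member gene is scored by the Wald of its coefficient when added on top of
the subset's combined component risk score (as a fixed offset), measuring
prognostic value in the context of the subset fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from math import ceil

import numpy as np
import pandas as pd

from .cox import fit_cox_univariate_many, fit_partial_cox
from .io_norm import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 1000


@dataclass
class VirtualCohortParams:
    """Knobs of the ensemble screen (defaults follow the discovery design)."""

    n_cycles: int = 20
    sample_fraction: float = 0.70
    top_rank: int = 200
    genes_per_draw: int = 50
    n_draws_per_cycle: int | None = None  # default: expected >= 20 draws per gene
    recurrence_min: int = 15
    wald_floor_frac: float = 0.5
    seed: int = 0
    mode: str = "univariate"  # or "component"
    n_components: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must lie in (0, 1]")
        if self.recurrence_min > self.n_cycles:
            raise ValueError("recurrence_min cannot exceed n_cycles")
        if not 0 <= self.wald_floor_frac <= 1:
            raise ValueError("wald_floor_frac must lie in [0, 1]")
        if self.mode not in ("univariate", "component"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")

    def resolve_draws(self, n_genes: int) -> int:
        if self.n_draws_per_cycle is not None:
            return self.n_draws_per_cycle
        per_draw = min(self.genes_per_draw, n_genes)
        return ceil(20 * n_genes / per_draw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EnsembleRanking:
    """Aggregate of the ensemble screen.

    ``table`` is indexed by gene id with columns ``recurrence`` (number of
    cycles in the top list), ``rating`` (median Wald across those cycles; 0
    if never ranked), and ``direction`` (sign of the median Cox coefficient),
    sorted by (recurrence, rating) descending with gene id as tie-break.
    """

    table: pd.DataFrame
    params: VirtualCohortParams
    cycle_top: list[list[str]]
    n_samples: int

    @property
    def n_cycles(self) -> int:
        return self.params.n_cycles


@dataclass
class GeneSignature:
    """Selected prognostic genes with their ratings and risk directions."""

    gene_ids: list[str]
    ratings: pd.Series
    directions: pd.Series

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "ratings": {g: float(self.ratings[g]) for g in self.gene_ids},
            "directions": {g: int(self.directions[g]) for g in self.gene_ids},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSignature":
        genes = list(d["gene_ids"])
        return cls(
            gene_ids=genes,
            ratings=pd.Series({g: d["ratings"][g] for g in genes}, dtype=float),
            directions=pd.Series({g: d["directions"][g] for g in genes}, dtype=int),
        )


def _draw_cycle_samples(rng: np.random.Generator, n: int, frac: float,
                        event: np.ndarray) -> np.ndarray:
    """Sample a virtual cohort without replacement, redrawing until >= 2 events."""
    size = ceil(frac * n)
    for attempt in range(_MAX_REDRAWS):
        idx = rng.choice(n, size=size, replace=False)
        if event[idx].sum() >= 2:
            if attempt:
                logger.info("virtual cohort redrawn %d time(s) to reach 2 events", attempt)
            return np.sort(idx)
    raise ValueError("could not draw a virtual cohort with >= 2 events")


def _score_cycle_univariate(Z: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = fit_cox_univariate_many(Z.T, time, event)
    return res["wald"], res["beta"]


def _score_cycle_component(Z: np.ndarray, time: np.ndarray, event: np.ndarray,
                           gene_ids: list[str], sample_ids: list[str],
                           rng: np.random.Generator, params: VirtualCohortParams) -> tuple[np.ndarray, np.ndarray]:
    g = Z.shape[0]
    per_draw = min(params.genes_per_draw, g)
    n_draws = params.resolve_draws(g)
    wald = np.full(g, np.nan)
    beta = np.full(g, np.nan)
    clin = ClinicalTable(pd.DataFrame({"time": time, "event": event},
                                      index=pd.Index(sample_ids, name="sample_id")))
    for _d in range(n_draws):
        draw = rng.choice(g, size=per_draw, replace=False)
        sub = ExpressionMatrix(
            pd.DataFrame(Z[draw], index=[gene_ids[i] for i in draw], columns=sample_ids),
            mode="zscore",
        )
        try:
            model = fit_partial_cox(sub, clin, K=min(params.n_components, len(sample_ids) - 1))
            offset = model.risk_score()
        except ValueError:
            offset = None
        res = fit_cox_univariate_many(Z[draw].T, time, event, offset=offset)
        better = np.isnan(wald[draw]) | (res["wald"] > wald[draw])
        wald[draw] = np.where(better, res["wald"], wald[draw])
        beta[draw] = np.where(better, res["beta"], beta[draw])
    return wald, beta


def run_virtual_cohorts(X: ExpressionMatrix, surv: ClinicalTable,
                        params: VirtualCohortParams | None = None) -> EnsembleRanking:
    """Run the resampled ensemble screen and aggregate per-gene recurrence/rating."""
    params = params or VirtualCohortParams()
    if X.mode != "zscore":
        raise ValueError(f"screen expects z-scored expression, got mode {X.mode!r}")
    surv = surv.aligned_to(X)
    Z = X.values.to_numpy(dtype=float)
    gene_ids = np.array(X.gene_ids)
    n = X.n_samples
    time, event = surv.time, surv.event
    top_rank = min(params.top_rank, X.n_genes)

    master = np.random.default_rng(params.seed)
    cycle_seeds = master.integers(0, 2**31 - 1, size=params.n_cycles)

    walds = np.zeros((X.n_genes, params.n_cycles))
    betas = np.zeros((X.n_genes, params.n_cycles))
    in_top = np.zeros((X.n_genes, params.n_cycles), dtype=bool)
    cycle_top: list[list[str]] = []

    # gene id order used for deterministic tie-breaks, independent of row order
    id_rank = pd.Series(np.argsort(np.argsort(gene_ids)), index=gene_ids)

    for c in range(params.n_cycles):
        rng = np.random.default_rng(int(cycle_seeds[c]))
        idx = _draw_cycle_samples(rng, n, params.sample_fraction, event)
        Zc, tc, ec = Z[:, idx], time[idx], event[idx]
        sids = [X.sample_ids[i] for i in idx]
        if params.mode == "univariate":
            w, b = _score_cycle_univariate(Zc, tc, ec)
        else:
            w, b = _score_cycle_component(Zc, tc, ec, list(gene_ids), sids, rng, params)
        scored = ~np.isnan(w)
        walds[:, c] = np.where(scored, w, 0.0)
        betas[:, c] = np.where(scored, b, 0.0)
        # rank scored genes by Wald desc, gene id asc
        order = np.lexsort((id_rank[gene_ids].to_numpy(), -np.where(scored, w, -np.inf)))
        order = order[scored[order]]
        top = order[:top_rank]
        in_top[top, c] = True
        cycle_top.append(sorted(gene_ids[top]))

    recurrence = in_top.sum(axis=1)
    rating = np.zeros(X.n_genes)
    direction = np.zeros(X.n_genes, dtype=int)
    for i in range(X.n_genes):
        sel = in_top[i]
        ref = sel if sel.any() else np.ones(params.n_cycles, dtype=bool)
        if sel.any():
            rating[i] = np.median(walds[i, sel])
        med_beta = np.median(betas[i, ref])
        direction[i] = int(np.sign(med_beta))

    table = pd.DataFrame(
        {"recurrence": recurrence, "rating": rating, "direction": direction},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    table = table.sort_values(["recurrence", "rating", "gene_id"],
                              ascending=[False, False, True],
                              kind="mergesort")
    return EnsembleRanking(table=table, params=params, cycle_top=cycle_top, n_samples=n)


def select_signature(ranking: EnsembleRanking) -> GeneSignature:
    """Apply the recurrence and Wald-floor criteria to an ensemble ranking."""
    p = ranking.params
    t = ranking.table
    max_rating = float(t["rating"].max()) if len(t) else 0.0
    mask = t["recurrence"] >= p.recurrence_min
    if p.wald_floor_frac > 0:
        mask &= t["rating"] > p.wald_floor_frac * max_rating
    selected = t.loc[mask]
    if selected.empty:
        warnings.warn("signature selection produced an empty gene set", stacklevel=2)
    return GeneSignature(
        gene_ids=list(selected.index),
        ratings=selected["rating"].copy(),
        directions=selected["direction"].astype(int).copy(),
    )


def prognostic_risk_score(sig: GeneSignature, X: ExpressionMatrix) -> pd.Series:
    """Combined prognostic rating model: rating-weighted, direction-signed z-sum.

    Higher scores predict worse outcome.  An empty signature yields all-zero
    scores; a signature gene absent from the matrix raises with the missing
    gene ids listed.
    """
    if not sig.gene_ids:
        return pd.Series(0.0, index=X.sample_ids, name="risk_score")
    sub = X.restrict_genes(sig.gene_ids)  # raises listing missing genes
    w = (sig.directions.astype(float) * sig.ratings).loc[sig.gene_ids].to_numpy()
    score = w @ sub.values.to_numpy(dtype=float)
    return pd.Series(score, index=X.sample_ids, name="risk_score")
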