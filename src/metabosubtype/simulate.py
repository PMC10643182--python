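"""Synthetic tumor-expression cohorts with known prognostic ground truth.

The generator emulates the structure of a deconvolved tumor-compartment
RNA-seq cohort: negative-binomial counts with sample-specific sequencing
depth, a planted set of prognostic genes whose latent expression shifts
between two hidden subtypes ("aggressive" vs "indolent"), and overall
survival drawn from a Weibull proportional-hazards model driven by those
genes, with uniform administrative censoring calibrated to a target
censored fraction.

Each gene g has a latent standardized expression ``x_gs ~ N(0, 1)``;
aggressive samples are shifted by ``+subtype_shift`` standard deviations on
risk-increasing planted genes and ``-subtype_shift`` on protective ones, so
the clustering structure and the survival signal are coupled.  The linear
predictor is ``eta_s = sum_j beta_j x_js`` over planted genes (beta = +/-
``effect_size``, split evenly between signs), and event times follow
``T = scale * (-log U / exp(eta))**(1/shape)``.  Counts are
``NB(mean = depth_s * mu_g * exp(sigma_x * x_gs), dispersion)`` so the
observable matrix is a noisy read-out of the latent signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_norm import ClinicalTable, ExpressionMatrix, write_clinical, write_expression, write_json

AGGRESSIVE = "aggressive"
INDOLENT = "indolent"


@dataclass
class SyntheticConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults describe the package's reference study conditions: a cohort of
    300 patients, 500 screened genes of which 10 are prognostic at a
    log-hazard of 0.8 per SD, an aggressive subtype comprising 27% of
    patients shifted by 2 SD on the planted genes, and ~30% censoring under
    a Weibull baseline with shape 1.2 and scale 24 (months).
    """

    n_samples: int = 300
    n_genes: int = 500
    n_prognostic: int = 10
    effect_size: float = 0.8          # log-hazard per 1 SD of latent expression
    subtype_fraction: float = 0.27    # fraction of samples in the aggressive subtype
    subtype_shift: float = 2.0        # SD shift of planted genes in aggressive samples
    weibull_shape: float = 1.2
    weibull_scale: float = 24.0
    censor_target: float = 0.30       # expected censored fraction
    depth_range: tuple[float, float] = (0.5, 2.0)
    dispersion: float = 0.1           # NB dispersion: var = mu + dispersion * mu^2
    seed: int = 0
    design_seed: int = 0              # fixes WHICH genes are prognostic (shared across replicate cohorts)
    base_log_mean: float = 4.5        # log-scale mean of per-gene baseline expression
    base_log_sd: float = 1.0
    signal_log_sd: float = 0.5        # count-scale amplitude of the latent signal

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0 <= self.n_prognostic <= self.n_genes:
            raise ValueError("n_prognostic must lie in [0, n_genes]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not 0 < self.subtype_fraction < 1:
            raise ValueError("subtype_fraction must lie in (0, 1)")
        if not 0 <= self.censor_target < 1:
            raise ValueError("censor_target must lie in [0, 1)")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be 0 < min <= max")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depth_range"] = list(d["depth_range"])
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: which genes drive survival and how."""

    prognostic_gene_ids: list[str]
    true_betas: dict[str, float]
    true_subtype: pd.Series  # per-sample, values in {aggressive, indolent}
    censor_horizon: float | None = None

    def to_dict(self) -> dict:
        return {
            "prognostic_gene_ids": self.prognostic_gene_ids,
            "true_betas": self.true_betas,
            "true_subtype": self.true_subtype.to_dict(),
            "censor_horizon": self.censor_horizon,
        }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with mean mu and variance mu + dispersion*mu^2 (Poisson limit at 0)."""
    if dispersion < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def _calibrate_censor_horizon(event_times: np.ndarray, target: float) -> float:
    """Solve for c so that C ~ U(0, c) censors the given latent event times at rate ~target.

    With C uniform on (0, c), P(censored | T) = min(T, c) / c, so the expected
    censored fraction is mean(min(T, c)) / c — decreasing in c from 1 to 0.
    """
    t = np.asarray(event_times, dtype=float)

    def frac(c: float) -> float:
        return float(np.minimum(t, c).mean() / c)

    lo = t.min() * 1e-6
    hi = t.max()
    while frac(hi) > target:
        hi *= 2.0
        if hi > t.max() * 1e12:  # pragma: no cover - target ~0 handled by caller
            break
    return brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-10 * hi)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Generate a counts matrix, clinical table and ground truth from a config.

    Deterministic: the same config (including seed) yields byte-identical
    output.  With ``effect_size == 0`` no gene truly influences survival and
    the truth lists an empty prognostic set.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    gene_ids = [f"G{i + 1:04d}" for i in range(g)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # hidden subtype: fixed composition, random placement
    n_aggr = int(round(config.subtype_fraction * n))
    n_aggr = min(max(n_aggr, 1), n - 1)
    subtype = np.array([AGGRESSIVE] * n_aggr + [INDOLENT] * (n - n_aggr))
    rng.shuffle(subtype)
    aggressive = subtype == AGGRESSIVE

    # planted genes and their log-hazard coefficients (signs alternate);
    # drawn from design_seed, not seed, so replicate cohorts of one study
    # design share the same prognostic genes
    design_rng = np.random.default_rng(config.design_seed)
    prog_idx = np.sort(design_rng.choice(g, size=config.n_prognostic, replace=False))
    signs = np.where(np.arange(config.n_prognostic) % 2 == 0, 1.0, -1.0)
    betas = signs * config.effect_size

    # latent standardized expression; subtype shift couples clusters to risk
    x = rng.standard_normal((g, n))
    for gi, b in zip(prog_idx, betas):
        direction = 1.0 if b >= 0 else -1.0
        x[gi, aggressive] += direction * config.subtype_shift

    eta = betas @ x[prog_idx] if config.n_prognostic else np.zeros(n)

    # Weibull proportional hazards by inversion
    u = rng.uniform(size=n)
    t_event = config.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.weibull_shape)

    if config.censor_target > 0:
        c_max = _calibrate_censor_horizon(t_event, config.censor_target)
        c = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        c_max = None
        time = t_event
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-8)

    # negative-binomial read-out of the latent expression
    depth = rng.uniform(config.depth_range[0], config.depth_range[1], size=n)
    base = np.exp(rng.normal(config.base_log_mean, config.base_log_sd, size=g))
    mu = depth[None, :] * base[:, None] * np.exp(config.signal_log_sd * x)
    counts = _nb_draw(rng, mu, config.dispersion)

    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), mode="counts"
    )
    age = np.round(rng.normal(65.0, 10.0, size=n), 1)
    sex = rng.choice(["F", "M"], size=n)
    clin = ClinicalTable(pd.DataFrame(
        {"time": time, "event": event, "age": age, "sex": sex},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    planted = config.effect_size != 0.0
    truth = SyntheticTruth(
        prognostic_gene_ids=[gene_ids[i] for i in prog_idx] if planted else [],
        true_betas={gene_ids[i]: float(b) for i, b in zip(prog_idx, betas)} if planted else {},
        true_subtype=pd.Series(subtype, index=sample_ids, name="true_subtype"),
        censor_horizon=c_max,
    )
    return expr, clin, truth


def write_cohort(outdir: str | Path, expr: ExpressionMatrix, clin: ClinicalTable,
                 truth: SyntheticTruth, config: SyntheticConfig | None = None) -> dict[str, Path]:
    """Write expression/clinical TSVs and truth (+config) JSON under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(expr, paths["expression"])
    write_clinical(clin, paths["clinical"])
    write_json(truth.to_dict(), paths["truth"])
    if config is not None:
        paths["config"] = outdir / "config.json"
        write_json(config.to_dict(), paths["config"])
    return paths
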