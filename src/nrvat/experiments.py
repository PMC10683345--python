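"""Scripted simulation experiments: type-I error, power, multiple testing.

The default study design is 120 families — 40 parent-parent-child trios,
40 two-parent/two-child families and 40 three-generation octets (two
grandparents, their two children each with a married-in spouse, and two
first cousins) — for N = 600 subjects (320 founders, 280 nonfounders,
240 males, 360 females).  Each region holds 20 linked SNPs with MAF drawn
from Uniform(0.003, 0.01) and adjacent-SNP squared correlation d2 = 0.16;
covariates are X1 ~ U(0,1) and X2 ~ Bernoulli(0.2) with effects
gamma = (-2, 1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import RegionSpec, simulate_genotypes
from .kernels import KERNEL_KINDS
from .core import nrvat_test_multi
from .pedigree import Family, Individual, Pedigree
from .phenotypes import (DEFAULT_GAMMA, EffectModel, draw_beta,
                         simulate_chisq_copula, simulate_covariates,
                         simulate_gaussian_copula, simulate_glmm,
                         simulate_t_copula)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "default_pedigree_set",
    "simulate_dataset",
    "run_type1_experiment",
    "run_power_experiment",
    "summarize_multiple_testing",
    "wilson_interval",
]

SETTINGS = ("copula_gaussian", "glmm", "copula_t", "copula_chisq")


def default_pedigree_set(n_trio: int = 40, n_quad: int = 40,
                         n_octet: int = 40) -> Pedigree:
    """The standard simulation pedigree collection (see module docstring)."""
    fams: list[Family] = []
    fid = 0

    def I(i, fa=None, mo=None, sex="unknown"):
        return Individual(str(i), fa, mo, sex)

    for _ in range(n_trio):
        fid += 1
        fams.append(Family(f"F{fid:03d}", [
            I(1, sex="male"), I(2, sex="female"),
            I(3, "1", "2", sex="male"),
        ]))
    for _ in range(n_quad):
        fid += 1
        fams.append(Family(f"F{fid:03d}", [
            I(1, sex="male"), I(2, sex="female"),
            I(3, "1", "2", sex="female"), I(4, "1", "2", sex="female"),
        ]))
    for _ in range(n_octet):
        fid += 1
        fams.append(Family(f"F{fid:03d}", [
            I(1, sex="male"), I(2, sex="female"),          # grandparents
            I(3, "1", "2", sex="male"), I(4, sex="female"),   # son + spouse
            I(5, "1", "2", sex="female"), I(6, sex="male"),   # daughter + spouse
            I(7, "3", "4", sex="female"),                     # cousin 1
            I(8, "6", "5", sex="female"),                     # cousin 2
        ]))
    return Pedigree(fams)


@dataclass
class ExperimentConfig:
    """Parameters of one simulation experiment.

    setting: phenotype dependence mechanism; tau = 0 gives a null (type-I)
    run, tau > 0 an alternative with n_causal randomly chosen causal SNPs
    whose effects are drawn N(0, tau * w_l) per replicate.
    """

    setting: str = "copula_gaussian"
    h2: float = 0.5
    tau: float = 0.0
    n_replicates: int = 2000
    seed: int = 2024
    kernels: tuple = ("linear",)
    alphas: tuple = (0.05, 0.01)
    n_snps: int = 20
    maf_range: tuple = (0.003, 0.01)
    d2: float = 0.16
    gamma: tuple = tuple(DEFAULT_GAMMA)
    n_causal: int = 5
    n_trio: int = 40
    n_quad: int = 40
    n_octet: int = 40
    h2_fit: str | float = "auto"
    b_mode: str = "model"
    t_df: float = 3.0
    chisq_a: float = 1.0

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alpha levels must lie in (0, 1)")
        bad = set(self.kernels) - set(KERNEL_KINDS)
        if bad:
            raise ValueError(f"unknown kernels {bad}")


@dataclass
class ExperimentReport:
    """Per-kernel p-values, rejection rates with Wilson CIs, run manifest."""

    pvalues: pd.DataFrame          # one row per replicate, one column per kernel
    rates: pd.DataFrame            # kernel x alpha rejection rates + Wilson 99% CI
    h2_hats: np.ndarray
    manifest: dict

    def qq_data(self, kernel: str) -> pd.DataFrame:
        """Expected vs observed -log10 p for QQ plotting (TSV-friendly)."""
        p = np.sort(self.pvalues[kernel].to_numpy())
        n = p.size
        expected = (np.arange(1, n + 1) - 0.5) / n
        return pd.DataFrame({
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(p),
        })


def wilson_interval(k: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def simulate_dataset(cfg: ExperimentConfig, ped: Pedigree, rng,
                     beta: np.ndarray | None = None):
    """One replicate of (Y, X, G) under the configured setting."""
    rng = np.random.default_rng(rng)
    region = RegionSpec.uniform_rare(cfg.n_snps, *cfg.maf_range, d2=cfg.d2,
                                     rng=rng)
    G = simulate_genotypes(ped, region, rng)
    X = simulate_covariates(ped, rng)
    gamma = np.asarray(cfg.gamma, dtype=float)
    if beta is None and cfg.tau > 0:
        from .kernels import maf_weights

        effect = EffectModel.random_causal(
            cfg.tau, maf_weights(region.maf).weights, cfg.n_causal, rng
        )
        beta = draw_beta(effect, rng)
    dos = G.dosages
    if cfg.setting == "copula_gaussian":
        Y = simulate_gaussian_copula(ped, X, dos, gamma, beta, cfg.h2, rng)
    elif cfg.setting == "glmm":
        Y = simulate_glmm(ped, X, dos, gamma, beta, cfg.h2, rng)
    elif cfg.setting == "copula_t":
        Y = simulate_t_copula(ped, X, dos, gamma, beta, cfg.h2, rng, df=cfg.t_df)
    else:
        Y = simulate_chisq_copula(ped, X, dos, gamma, beta, cfg.h2, rng,
                                  a=cfg.chisq_a)
    return Y, X, G


def _run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    import warnings as _warnings

    ped = default_pedigree_set(cfg.n_trio, cfg.n_quad, cfg.n_octet)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)
    pvals = {k: np.empty(cfg.n_replicates) for k in cfg.kernels}
    h2s = np.empty(cfg.n_replicates)
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        Y, X, G = simulate_dataset(cfg, ped, rng)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = nrvat_test_multi(Y, X, G, ped, kernels=list(cfg.kernels),
                                   h2=cfg.h2_fit, b_mode=cfg.b_mode,
                                   set_id=f"rep{b}")
        for k in cfg.kernels:
            pvals[k][b] = res[k].p_value
        h2s[b] = next(iter(res.values())).h2_hat

    pdf = pd.DataFrame(pvals)
    rows = []
    for k in cfg.kernels:
        for alpha in cfg.alphas:
            nrej = int((pdf[k] <= alpha).sum())
            lo, hi = wilson_interval(nrej, cfg.n_replicates)
            rows.append({"kernel": k, "alpha": alpha,
                         "rate": nrej / cfg.n_replicates,
                         "wilson99_low": lo, "wilson99_high": hi})
    manifest = {"config": asdict(cfg), "n_replicates": cfg.n_replicates,
                "seed": cfg.seed}
    return ExperimentReport(pvalues=pdf, rates=pd.DataFrame(rows),
                            h2_hats=h2s, manifest=manifest)


def run_type1_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Null-hypothesis replicates (beta = 0): empirical type-I error rates."""
    if cfg.tau != 0:
        raise ValueError("type-I experiment requires tau = 0")
    return _run_experiment(cfg)


def run_power_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Alternative-hypothesis replicates: causal effects redrawn per replicate."""
    if cfg.tau < 0:
        raise ValueError("tau must be >= 0")
    return _run_experiment(cfg)


def summarize_multiple_testing(p_table: pd.DataFrame, alpha: float = 0.05,
                               scheme: str = "bonferroni_per_trait"):
    """Bonferroni-significant sets from a table with columns set_id, trait, p_value.

    "bonferroni_per_trait": threshold alpha / m_t within each trait;
    "bonferroni_overall": alpha / (total number of tests) across all traits.
    Returns (significant_table, thresholds_by_trait).
    """
    if p_table.empty:
        raise ValueError("empty p-value table")
    df = p_table.copy()
    if "trait" not in df.columns:
        df["trait"] = "trait"
    if scheme == "bonferroni_per_trait":
        thresholds = {t: alpha / len(g) for t, g in df.groupby("trait")}
    elif scheme == "bonferroni_overall":
        thr = alpha / len(df)
        thresholds = {t: thr for t in df["trait"].unique()}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    df["threshold"] = df["trait"].map(thresholds)
    sig = df[df["p_value"] <= df["threshold"]].reset_index(drop=True)
    return sig, thresholds
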