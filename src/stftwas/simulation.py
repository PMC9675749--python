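"""Null-calibration and power studies for the sTF-TWAS pipeline.

Two alternative-hypothesis scenarios are simulated under an additive
architecture f(X) = sum_i beta_i x_i with effects drawn from N(0, 1):

* **causality** — genotype acts on the trait through expression:
  z = f(X) + eps scaled to the expression heritability, y = z + eps scaled
  to the local trait heritability;
* **pleiotropy** — genotype acts on trait and expression independently:
  the trait's genetic component reuses the causal variants with freshly
  drawn effects, and its noise is rescaled by the *expression* heritability
  (the scenario's defining rule).

Noise is always solved from the realized genetic variance via
``s2_e = s2_g (1 - h2) / h2``, so the heritability of every simulated
quantity equals its target in expectation.

The power study compares three variant-selection protocols on identical
per-replicate data (paired seeds): the prioritized set (causal variants
plus decoys), all cis candidates, and a random set matched in size to the
prioritized one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_models import _enet_cv_weights, _pearson_r2
from .lmm import fit_random_intercept
from .synthetic_data import (FixtureSpec, _block_sizes, linear_gwas,
                             logistic_score_gwas, sample_dosages)
from .twas_association import zscore_from_weights

PROTOCOLS = ("stf", "all_cis", "random_matched")


@dataclass
class ArchitectureSpec:
    """One cell of the simulation grid."""

    n_local: int = 200
    n_causal: int = 10
    h2_expr: float = 0.3
    h2_trait: float = 0.1
    scenario: str = "causality"
    maf_min: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_local:
            raise ValueError("n_causal exceeds n_local")
        for h2 in (self.h2_expr, self.h2_trait):
            if not 0.0 <= h2 <= 1.0:
                raise ValueError("heritability must lie in [0, 1]")
        if self.scenario not in ("causality", "pleiotropy"):
            raise ValueError(f"unknown scenario {self.scenario}")


@dataclass
class SimulatedStudy:
    """One simulated gene: reference expression + cohort phenotype."""

    causal_idx: np.ndarray
    beta: np.ndarray
    z1: np.ndarray               # expression, reference panel
    z2: np.ndarray               # expression, cohort
    y2: np.ndarray               # phenotype, cohort
    sigma_g2_expr: float
    sigma_e2_expr: float
    sigma_g2_trait: float
    sigma_e2_trait: float
    beta_pleio: np.ndarray | None = None


def rescaled_noise_variance(sigma_g2: float, h2: float) -> float:
    """Noise variance giving the genetic component heritability ``h2``."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1] for rescaling")
    return sigma_g2 * (1.0 - h2) / h2


def _scaled(genetic: np.ndarray, h2: float, rng) -> tuple[np.ndarray, float, float]:
    """(signal + noise, sigma_g2, sigma_e2) under the rescaling rule."""
    if h2 <= 0.0:
        return rng.standard_normal(len(genetic)), 0.0, 1.0
    s2_g = float(np.var(genetic))
    if h2 >= 1.0 or s2_g == 0.0:
        return genetic.copy(), s2_g, 0.0
    s2_e = rescaled_noise_variance(s2_g, h2)
    return genetic + rng.normal(0.0, np.sqrt(s2_e), len(genetic)), s2_g, s2_e


def simulate_expression_and_trait(spec: ArchitectureSpec, X1: np.ndarray,
                                  X2: np.ndarray,
                                  rng: np.random.Generator | None = None
                                  ) -> SimulatedStudy:
    """Simulate one gene's expression (both panels) and cohort phenotype.

    ``X1``/``X2`` are reference/cohort dosage matrices over the same
    ``n_local`` candidate variants.  Causal variants are sampled among
    candidates passing the MAF filter.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("panels must share the candidate variant set")
    maf1 = np.minimum(X1.mean(axis=0) / 2.0, 1.0 - X1.mean(axis=0) / 2.0)
    eligible = np.where(maf1 >= spec.maf_min)[0]
    if len(eligible) < spec.n_causal:
        raise ValueError(f"only {len(eligible)} variants pass the MAF "
                         f"filter; need {spec.n_causal}")
    causal = np.sort(rng.choice(eligible, size=spec.n_causal, replace=False))
    beta = rng.standard_normal(spec.n_causal)

    f1 = X1[:, causal] @ beta
    f2 = X2[:, causal] @ beta
    z1, s2g_e, s2e_e = _scaled(f1, spec.h2_expr, rng)
    z2, _, _ = _scaled(f2, spec.h2_expr, rng)

    beta_pleio = None
    if spec.scenario == "causality":
        y2, s2g_t, s2e_t = _scaled(z2, spec.h2_trait, rng)
    else:  # pleiotropy: fresh effects, noise rescaled by h2_expr
        beta_pleio = rng.standard_normal(spec.n_causal)
        gp = X2[:, causal] @ beta_pleio
        y2, s2g_t, s2e_t = _scaled(gp, spec.h2_expr, rng)
    return SimulatedStudy(causal_idx=causal, beta=beta, z1=z1, z2=z2, y2=y2,
                          sigma_g2_expr=s2g_e, sigma_e2_expr=s2e_e,
                          sigma_g2_trait=s2g_t, sigma_e2_trait=s2e_t,
                          beta_pleio=beta_pleio)


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------

def _train_and_test(X1, z1, X2_gwas_z, candidates, seed, folds=10,
                    r2_min=0.01):
    """Elastic net on the candidate set; returns (TWAS z, cv_r2) or
    (nan, cv_r2) when the model fails the retention filter or degenerates.

    ``X2_gwas_z`` holds the per-variant GWAS z-scores aligned with X1's
    columns; the reference covariance comes from X1 itself.
    """
    Xc = X1[:, candidates]
    preds, w, _alpha = _enet_cv_weights(Xc, z1, folds=folds, seed=seed,
                                        nested=False)
    r2 = _pearson_r2(preds, z1)
    if r2 <= r2_min:
        return np.nan, r2
    nz = w != 0
    if not nz.any():
        return np.nan, r2
    sub = np.asarray(candidates)[nz]
    gamma = np.atleast_2d(np.cov(X1[:, sub], rowvar=False, ddof=1))
    try:
        z = zscore_from_weights(w[nz], gamma, X2_gwas_z[sub])
    except ZeroDivisionError:
        return np.nan, r2
    return z, r2


def _simulation_panels(fixture: FixtureSpec, n_ref, n_cohort, rng):
    """Raw dosage matrices + integer block codes for simulation loops."""
    mafs = rng.uniform(*fixture.maf_range, size=fixture.n_variants)
    sizes = _block_sizes(fixture.n_variants, fixture.n_blocks)
    X1 = sample_dosages(n_ref, mafs, sizes, fixture.within_block_correlation,
                        rng)
    X2 = sample_dosages(n_cohort, mafs, sizes,
                        fixture.within_block_correlation, rng)
    blocks = np.repeat(np.arange(fixture.n_blocks), sizes)
    return X1, X2, blocks


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    pvalues: np.ndarray
    rejection_rates: dict
    qq: pd.DataFrame             # expected vs observed -log10 quantiles
    n_gene_replicates: int
    n_trained: int
    n_batches: int
    n_tf_draws: int


def rejection_rates(pvalues, alphas=(0.05, 0.01)) -> dict:
    """Empirical fraction of p-values below each alpha."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return {a: np.nan for a in alphas}
    return {a: float((p < a).mean()) for a in alphas}


def qq_table(pvalues, n_points: int = 100) -> pd.DataFrame:
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    idx = np.unique(np.linspace(0, n - 1, min(n_points, n)).astype(int))
    expected = (idx + 0.5) / n
    return pd.DataFrame({
        "expected_logp": -np.log10(expected),
        "observed_logp": -np.log10(np.maximum(p[idx], 1e-300)),
    })


def run_null_calibration(n_genes: int = 2000,
                         panels: tuple | None = None,
                         seed: int = 0,
                         fixture: FixtureSpec | None = None,
                         genes_per_batch: int = 10,
                         tf_fraction: float = 0.2,
                         h2_expr: float = 0.3,
                         n_causal: int = 5,
                         window_variants: int = 150,
                         gwas_test: str = "logistic",
                         alphas: tuple = (0.05, 0.01),
                         prior_alpha: float = 0.05,
                         max_tf_draws: int = 500,
                         r2_min: float = 0.01) -> CalibrationResult:
    """Type-I error of the full pipeline under a null binary phenotype.

    Each batch draws a random 0/1 phenotype independent of genotype, runs a
    per-variant GWAS (logistic score test, or linear with
    ``gwas_test="linear"``), then draws random TF occupancy assignments of
    ``tf_fraction`` of the variants until the mixed-model occupancy slope
    has two-sided P < ``prior_alpha`` — mimicking prioritization on pure
    noise.  The TF-occupied variants become the prioritized set; expression
    for ``genes_per_batch`` genes (heritable in the reference panel, so
    models pass the R^2 filter at a realistic rate, but unrelated to the
    phenotype) is trained and tested.  Runs batches until ``n_genes``
    retained gene-replicates have produced TWAS p-values.
    """
    import warnings as _warnings

    if n_genes < 100:
        _warnings.warn("fewer than 100 gene-replicates: calibration is "
                       "unstable")
    rng = np.random.default_rng(seed)
    fixture = fixture or FixtureSpec()
    if panels is None:
        X1, X2, blocks = _simulation_panels(fixture, fixture.n_ref_samples,
                                            1000, rng)
    else:
        X1, X2, blocks = panels
    n_variants = X1.shape[1]
    n_occupied = max(2, int(round(tf_fraction * n_variants)))

    # fixed gene windows tiling the panel
    centers = np.linspace(window_variants // 2,
                          n_variants - window_variants // 2 - 1,
                          genes_per_batch).astype(int)
    windows = [np.arange(max(0, c - window_variants // 2),
                         min(n_variants, c + window_variants // 2))
               for c in centers]

    pvals = []
    n_trained = n_batches = n_draws = 0
    ones = np.ones(n_variants)
    while len(pvals) < n_genes:
        n_batches += 1
        y = (rng.random(X2.shape[0]) < 0.5).astype(float)
        if y.min() == y.max():  # astronomically unlikely; redraw
            continue
        if gwas_test == "logistic":
            gz, chi2, _ = logistic_score_gwas(X2, y)
        else:
            beta, se, _ = linear_gwas(X2, y)
            gz = beta / se
            chi2 = gz ** 2

        occupied = None
        for _ in range(max_tf_draws):
            n_draws += 1
            cand = np.zeros(n_variants, dtype=bool)
            cand[rng.choice(n_variants, size=n_occupied, replace=False)] = True
            X = np.column_stack([ones, cand.astype(float)])
            fit = fit_random_intercept(chi2, X, blocks, reml=True)
            if fit.converged and fit.wald_p[1] < prior_alpha:
                occupied = cand
                break
        if occupied is None:
            continue

        for win in windows:
            prioritized = win[occupied[win]]
            if len(prioritized) < 2:
                continue
            pool = prioritized if len(prioritized) >= n_causal else win
            causal = rng.choice(pool, size=min(n_causal, len(pool)),
                                replace=False)
            beta_e = rng.standard_normal(len(causal))
            z1, _, _ = _scaled(X1[:, causal] @ beta_e, h2_expr, rng)
            n_trained += 1
            z, _r2 = _train_and_test(X1, z1, gz, prioritized,
                                     seed=int(rng.integers(2 ** 31)),
                                     r2_min=r2_min)
            if np.isfinite(z):
                pvals.append(2.0 * stats.norm.sf(abs(z)))
            if len(pvals) >= n_genes:
                break
    p = np.asarray(pvals)
    return CalibrationResult(
        pvalues=p, rejection_rates=rejection_rates(p, alphas),
        qq=qq_table(p), n_gene_replicates=len(p), n_trained=n_trained,
        n_batches=n_batches, n_tf_draws=n_draws)


# ---------------------------------------------------------------------------
# Power study
# ---------------------------------------------------------------------------

@dataclass
class PowerResult:
    protocol: str
    scenario: str
    n_causal: int
    h2_expr: float
    h2_trait: float
    reps: int
    successes: int
    success_vector: np.ndarray = field(repr=False, default=None)

    @property
    def power(self) -> float:
        return self.successes / self.reps if self.reps else np.nan


def run_power_experiment(spec: ArchitectureSpec,
                         protocols: tuple = PROTOCOLS,
                         reps: int = 300,
                         n_ref: int = 500,
                         n_cohort: int = 2000,
                         decoys_per_causal: int = 1,
                         bonferroni_n: int | None = None,
                         alpha: float = 0.05,
                         seed: int = 0,
                         fixture: FixtureSpec | None = None
                         ) -> dict[str, PowerResult]:
    """Power of each protocol over ``reps`` paired replicates.

    Every replicate simulates fresh genotypes over ``spec.n_local``
    candidate variants, one gene and one cohort phenotype; all protocols
    see the same data, so power differences are attributable to variant
    selection only.  Success = TWAS p below ``alpha / bonferroni_n``
    (default denominator: ``reps``, the genes tested per batch).
    """
    import warnings as _warnings

    if reps < 50:
        _warnings.warn("fewer than 50 replicates: power estimates are noisy")
    unknown = set(protocols) - set(PROTOCOLS)
    if unknown:
        raise ValueError(f"unknown protocols: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    fixture = fixture or FixtureSpec(
        n_variants=spec.n_local,
        n_blocks=max(2, spec.n_local // 20),
    )
    if fixture.n_variants != spec.n_local:
        raise ValueError("fixture n_variants must equal spec.n_local")
    thr = alpha / (bonferroni_n if bonferroni_n else reps)
    z_thr = stats.norm.isf(thr / 2.0)

    success = {p: np.zeros(reps, dtype=bool) for p in protocols}
    for r in range(reps):
        X1, X2, _blocks = _simulation_panels(fixture, n_ref, n_cohort, rng)
        rep_spec = ArchitectureSpec(
            n_local=spec.n_local, n_causal=spec.n_causal,
            h2_expr=spec.h2_expr, h2_trait=spec.h2_trait,
            scenario=spec.scenario, maf_min=spec.maf_min)
        study = simulate_expression_and_trait(rep_spec, X1, X2, rng)
        beta, se, _ = linear_gwas(X2, study.y2)
        gz = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)

        n_stf = min(spec.n_local,
                    spec.n_causal * (1 + decoys_per_causal))
        non_causal = np.setdiff1d(np.arange(spec.n_local), study.causal_idx)
        decoys = rng.choice(non_causal, size=n_stf - spec.n_causal,
                            replace=False)
        sets = {
            "stf": np.sort(np.concatenate([study.causal_idx, decoys])),
            "all_cis": np.arange(spec.n_local),
            "random_matched": np.sort(rng.choice(spec.n_local, size=n_stf,
                                                 replace=False)),
        }
        enet_seed = int(rng.integers(2 ** 31))
        for proto in protocols:
            z, _r2 = _train_and_test(X1, study.z1, gz, sets[proto],
                                     seed=enet_seed)
            success[proto][r] = np.isfinite(z) and abs(z) > z_thr

    return {
        proto: PowerResult(
            protocol=proto, scenario=spec.scenario, n_causal=spec.n_causal,
            h2_expr=spec.h2_expr, h2_trait=spec.h2_trait, reps=reps,
            successes=int(success[proto].sum()),
            success_vector=success[proto])
        for proto in protocols
    }


def paired_exact_test(success_a: np.ndarray, success_b: np.ndarray) -> float:
    """One-sided exact sign test that protocol *a* succeeds more often than
    *b* on paired replicates (binomial on discordant pairs)."""
    a = np.asarray(success_a, dtype=bool)
    b = np.asarray(success_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired success vectors differ in length")
    n_ab = int((a & ~b).sum())
    n_ba = int((~a & b).sum())
    if n_ab + n_ba == 0:
        return 1.0
    return float(stats.binomtest(n_ab, n_ab + n_ba, 0.5,
                                 alternative="greater").pvalue)


def power_table(results: dict[str, dict[str, PowerResult]]) -> pd.DataFrame:
    """Tidy table over a {cell_label: {protocol: PowerResult}} grid."""
    rows = []
    for label, cell in results.items():
        for proto, res in cell.items():
            rows.append({
                "cell": label, "scenario": res.scenario,
                "h2_expr": res.h2_expr, "h2_trait": res.h2_trait,
                "n_causal": res.n_causal, "protocol": proto,
                "reps": res.reps, "power": res.power,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summary-vs-individual consistency (the Z-score approximation check)
# ---------------------------------------------------------------------------

def summary_vs_individual(n_genes: int = 200, n_ref: int = 500,
                          n_cohort: int = 2000, seed: int = 0,
                          spec: ArchitectureSpec | None = None,
                          fixture: FixtureSpec | None = None,
                          gamma_from: str = "cohort"):
    """Per-gene summary-statistics Z versus individual-level association Z.

    For each simulated gene the summary Z combines GWAS z-scores with
    elastic-net weights; the individual-level Z regresses the cohort
    phenotype on the predicted expression directly.  Returns a DataFrame
    with both (the two should agree almost perfectly).

    ``gamma_from`` selects the variance/covariance panel entering the
    summary formula: ``"cohort"`` (default) matches the panel behind the
    individual-level regression, so the comparison isolates the combining
    approximation itself; ``"reference"`` additionally exposes the
    reference-vs-cohort LD sampling noise present in real applications.
    """
    rng = np.random.default_rng(seed)
    spec = spec or ArchitectureSpec(n_local=200, n_causal=10, h2_expr=0.3,
                                    h2_trait=0.1)
    fixture = fixture or FixtureSpec(n_variants=spec.n_local,
                                     n_blocks=max(2, spec.n_local // 20))
    rows = []
    while len(rows) < n_genes:
        X1, X2, _ = _simulation_panels(fixture, n_ref, n_cohort, rng)
        study = simulate_expression_and_trait(spec, X1, X2, rng)
        beta, se, _ = linear_gwas(X2, study.y2)
        gz = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
        n_stf = min(spec.n_local, 2 * spec.n_causal)
        non_causal = np.setdiff1d(np.arange(spec.n_local), study.causal_idx)
        decoys = rng.choice(non_causal, size=n_stf - spec.n_causal,
                            replace=False)
        cand = np.sort(np.concatenate([study.causal_idx, decoys]))
        Xc = X1[:, cand]
        preds, w, _a = _enet_cv_weights(Xc, study.z1, folds=10,
                                        seed=int(rng.integers(2 ** 31)),
                                        nested=False)
        nz = w != 0
        if not nz.any():
            continue
        sub = cand[nz]
        Xg = X2 if gamma_from == "cohort" else X1
        gamma = np.atleast_2d(np.cov(Xg[:, sub], rowvar=False, ddof=1))
        try:
            z_summary = zscore_from_weights(w[nz], gamma, gz[sub])
        except ZeroDivisionError:
            continue
        pred_expr = X2[:, sub] @ w[nz]
        b, s, _p = linear_gwas(pred_expr[:, None], study.y2)
        if not (np.isfinite(s[0]) and s[0] > 0):
            continue
        rows.append({"z_summary": z_summary, "z_individual": b[0] / s[0]})
    return pd.DataFrame(rows)
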