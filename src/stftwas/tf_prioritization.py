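"""Susceptible-TF screening and prioritized variant set compilation.

Each candidate TF (or TF pair) is tested by regressing per-variant GWAS
chi-squared values on binding occupancy with an LD-block random intercept.
The analysis set for every test is the occupied variants plus the variants
occupied by *none* of the investigated TFs (the shared control group).  TFs
whose occupancy slope survives Bonferroni correction are "susceptible";
variants they occupy are ranked by the largest qualifying coefficient and
truncated to the requested top-K set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import fit_random_intercept

logger = logging.getLogger(__name__)


@dataclass
class TFAssociationResult:
    """Mixed-model association between occupancy and GWAS chi-squared.

    For a single TF the ranking coefficient ``beta`` is the occupancy slope
    (the mean chi-squared difference between occupancy states); for a pair
    it is the interaction coefficient, with main effects kept alongside.
    """

    unit: str
    kind: str                      # "single" | "pair"
    beta0: float
    beta: float                    # ranking coefficient (slope / interaction)
    se: float
    wald_z: float
    p: float
    block_variance: float
    residual_variance: float
    n_variants_used: int
    converged: bool
    beta1: float = np.nan          # pair main effects
    beta2: float = np.nan
    p_bonf: float = np.nan
    significant: bool = False
    tf_names: tuple = ()


@dataclass
class PrioritizedVariantSet:
    """Top-K variants ranked by susceptible-TF coefficients."""

    table: pd.DataFrame            # variant_id, score, source_unit, rank
    k: int
    n_eligible: int = 0

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def __len__(self) -> int:
        return len(self.table)


def _analysis_mask(binding: pd.DataFrame, occupied: np.ndarray) -> np.ndarray:
    """Occupied variants plus variants occupied by no investigated TF."""
    any_tf = binding.to_numpy().sum(axis=1) > 0
    return occupied | ~any_tf


def _align(chi2: pd.Series, binding: pd.DataFrame, blocks: pd.Series):
    ids = chi2.index.intersection(binding.index).intersection(blocks.index)
    if len(ids) == 0:
        raise ValueError("no variants shared by chi2, binding and blocks")
    return chi2.loc[ids], binding.loc[ids], blocks.loc[ids]


def fit_single_tf_model(chi2: pd.Series, tf_name: str,
                        binding: pd.DataFrame,
                        blocks: pd.Series, reml: bool = True) -> TFAssociationResult:
    """Fit ``chi2 = b0 + b1*TF + V_block + eps`` for one TF.

    ``chi2``, ``binding`` and ``blocks`` are indexed by variant id and are
    aligned on their intersection.
    """
    chi2, binding, blocks = _align(chi2, binding, blocks)
    occ = binding[tf_name].to_numpy() > 0
    if not occ.any():
        raise ValueError(f"TF {tf_name}: no occupied variants")
    mask = _analysis_mask(binding, occ)
    if not (~occ & mask).any():
        raise ValueError(f"TF {tf_name}: empty control group "
                         "(every variant is occupied by some TF)")
    y = chi2.to_numpy()[mask]
    tf_col = occ[mask].astype(float)
    if tf_col.min() == tf_col.max():
        raise ValueError(f"TF {tf_name}: occupancy constant on analysis set")
    g = blocks.to_numpy()[mask]
    if len(np.unique(g)) < 2:
        raise ValueError("need >= 2 LD blocks on the analysis set")
    X = np.column_stack([np.ones_like(tf_col), tf_col])
    try:
        fit = fit_random_intercept(y, X, g, reml=reml)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(f"TF {tf_name}: model fit failed: {exc}") from exc
    p = float(fit.wald_p[1]) if fit.converged else np.nan
    return TFAssociationResult(
        unit=tf_name, kind="single", beta0=float(fit.coef[0]),
        beta=float(fit.coef[1]), se=float(fit.se[1]),
        wald_z=float(fit.wald_z[1]), p=p,
        block_variance=fit.sigma2_b, residual_variance=fit.sigma2_e,
        n_variants_used=int(mask.sum()), converged=fit.converged,
        tf_names=(tf_name,),
    )


def fit_tf_pair_model(chi2: pd.Series, tf1: str, tf2: str,
                      binding: pd.DataFrame,
                      blocks: pd.Series, reml: bool = True) -> TFAssociationResult:
    """Fit the two-TF model with interaction; the Wald test is on the
    interaction coefficient (co-occupancy effect beyond the main effects)."""
    if tf1 == tf2:
        raise ValueError("TF pair must involve two distinct TFs")
    chi2, binding, blocks = _align(chi2, binding, blocks)
    occ1 = binding[tf1].to_numpy() > 0
    occ2 = binding[tf2].to_numpy() > 0
    if np.array_equal(occ1, occ2):
        raise ValueError(f"{tf1} and {tf2} have identical occupancy "
                         "(collinear)")
    mask = _analysis_mask(binding, occ1 | occ2)
    x1 = occ1[mask].astype(float)
    x2 = occ2[mask].astype(float)
    x12 = x1 * x2
    if x12.sum() == 0:
        raise ValueError(f"{tf1} and {tf2} never co-occupy a variant; "
                         "interaction inestimable")
    y = chi2.to_numpy()[mask]
    g = blocks.to_numpy()[mask]
    X = np.column_stack([np.ones_like(x1), x1, x2, x12])
    fit = fit_random_intercept(y, X, g, reml=reml)
    p = float(fit.wald_p[3]) if fit.converged else np.nan
    return TFAssociationResult(
        unit=f"{tf1}:{tf2}", kind="pair", beta0=float(fit.coef[0]),
        beta=float(fit.coef[3]), se=float(fit.se[3]),
        wald_z=float(fit.wald_z[3]), p=p,
        block_variance=fit.sigma2_b, residual_variance=fit.sigma2_e,
        n_variants_used=int(mask.sum()), converged=fit.converged,
        beta1=float(fit.coef[1]), beta2=float(fit.coef[2]),
        tf_names=(tf1, tf2),
    )


def screen_tfs(chi2: pd.Series, binding: pd.DataFrame, blocks: pd.Series,
               tf_alpha: float = 0.05,
               pairs: str = "significant-only") -> list[TFAssociationResult]:
    """Fit all single-TF models, Bonferroni-correct, then fit pair models.

    ``pairs`` is ``"significant-only"`` (unordered pairs of Bonferroni-
    significant single TFs; default, bounds the quadratic cost), ``"all"``,
    or ``"none"``.  Inestimable units are skipped with a log message.
    """
    singles: list[TFAssociationResult] = []
    for tf in binding.columns:
        try:
            singles.append(fit_single_tf_model(chi2, tf, binding, blocks))
        except ValueError as exc:
            logger.info("skipping TF %s: %s", tf, exc)
    _bonferroni(singles, tf_alpha)

    results = list(singles)
    if pairs != "none":
        if pairs == "significant-only":
            pool = [r.unit for r in singles if r.significant]
        elif pairs == "all":
            pool = [r.unit for r in singles]
        else:
            raise ValueError(f"unknown pairs mode: {pairs}")
        pair_results: list[TFAssociationResult] = []
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                try:
                    pair_results.append(
                        fit_tf_pair_model(chi2, pool[i], pool[j], binding,
                                          blocks))
                except ValueError as exc:
                    logger.info("skipping pair %s:%s: %s", pool[i], pool[j],
                                exc)
        _bonferroni(pair_results, tf_alpha)
        results.extend(pair_results)
    return results


def _bonferroni(results: list[TFAssociationResult], alpha: float) -> None:
    tested = [r for r in results if r.converged and np.isfinite(r.p)]
    for r in tested:
        r.p_bonf = min(1.0, r.p * len(tested))
        r.significant = r.p_bonf < alpha


def compile_prioritized_set(results: list[TFAssociationResult],
                            binding: pd.DataFrame, k: int,
                            tf_alpha: float = 0.05,
                            variants: pd.DataFrame | None = None,
                            positive_only: bool = True,
                            recorrect: bool = True) -> PrioritizedVariantSet:
    """Rank variants occupied by susceptible units and keep the top *k*.

    Significance is Bonferroni within each family (singles, pairs) unless
    the supplied results already carry flags and ``recorrect`` is False.
    A variant's score is the largest qualifying coefficient over the
    significant units occupying it (pair occupancy = co-occupancy); with
    ``positive_only`` (default) only risk-inflating positive coefficients
    qualify, otherwise units rank by absolute coefficient.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    converged = [r for r in results if r.converged and np.isfinite(r.p)]
    if not converged:
        raise ValueError("no converged TF association results")
    if recorrect:
        _bonferroni([r for r in converged if r.kind == "single"], tf_alpha)
        _bonferroni([r for r in converged if r.kind == "pair"], tf_alpha)
    units = [r for r in converged if r.significant]
    if positive_only:
        units = [r for r in units if r.beta > 0]
    if not units:
        warnings.warn("no significant susceptible TFs/pairs; prioritized set "
                      "is empty")
        empty = pd.DataFrame(columns=["variant_id", "score", "source_unit",
                                      "rank"])
        return PrioritizedVariantSet(table=empty, k=k, n_eligible=0)

    # deterministic unit order: score rule is a max, so order cannot matter,
    # but tie-broken provenance should not depend on input order either
    units = sorted(units, key=lambda r: (-abs(r.beta), r.unit))
    score = pd.Series(np.nan, index=binding.index)
    source = pd.Series("", index=binding.index)
    for r in units:
        if r.kind == "single":
            occ = binding[r.unit].to_numpy() > 0
        else:
            tf1, tf2 = r.tf_names
            occ = (binding[tf1].to_numpy() > 0) & (binding[tf2].to_numpy() > 0)
        magnitude = r.beta if positive_only else abs(r.beta)
        better = occ & (score.isna().to_numpy()
                        | (np.nan_to_num(score.to_numpy(), nan=-np.inf)
                           < magnitude))
        score.iloc[np.where(better)[0]] = magnitude
        source.iloc[np.where(better)[0]] = r.unit

    eligible = score.dropna()
    n_eligible = len(eligible)
    if k > n_eligible:
        warnings.warn(f"requested k={k} exceeds {n_eligible} eligible "
                      "variants; returning all of them")
    tbl = pd.DataFrame({
        "variant_id": eligible.index,
        "score": eligible.to_numpy(),
        "source_unit": source.loc[eligible.index].to_numpy(),
    })
    if variants is not None:
        pos = variants.set_index("id")[["chrom", "pos"]]
        tbl["chrom"] = pos.reindex(tbl["variant_id"])["chrom"].to_numpy()
        tbl["pos"] = pos.reindex(tbl["variant_id"])["pos"].to_numpy()
        tbl = tbl.sort_values(["score", "chrom", "pos"],
                              ascending=[False, True, True],
                              kind="mergesort")
        tbl = tbl.drop(columns=["chrom", "pos"])
    else:
        tbl = tbl.sort_values(["score", "variant_id"],
                              ascending=[False, True], kind="mergesort")
    tbl = tbl.head(k).reset_index(drop=True)
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return PrioritizedVariantSet(table=tbl, k=k, n_eligible=n_eligible)
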