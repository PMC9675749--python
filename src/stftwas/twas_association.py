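"""Summary-statistics gene–trait association and enrichment testing.

The per-gene score combines elastic-net weights with GWAS single-variant
z-scores,

    Z_g = sum_l w_lg (sigma_l / sigma_g) (beta_l / se_l),

where sigma_l is the reference-panel dosage standard deviation of variant
*l* and sigma_g^2 = w' Gamma w is the variance of the predicted expression
under the reference LD (covariance) matrix Gamma.  Model variants absent
from the GWAS are dropped and sigma_g recomputed on the remainder, with the
retained weight fraction reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypePanel
from .expression_models import GeneModel


@dataclass
class ReferenceCovariance:
    """Variant–variant dosage covariance for one gene's model variants."""

    variant_ids: list[str]
    gamma: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma, dtype=float)
        self.gamma = g.reshape(len(self.variant_ids), len(self.variant_ids))
        if not np.allclose(self.gamma, self.gamma.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")

    @classmethod
    def from_panel(cls, panel: GenotypePanel, variant_ids) -> "ReferenceCovariance":
        idx = pd.Index(panel.variants["id"])
        locs = [idx.get_loc(v) for v in variant_ids]
        sub = panel.dosages[:, locs]
        gamma = np.atleast_2d(np.cov(sub, rowvar=False, ddof=1))
        return cls(variant_ids=list(variant_ids), gamma=gamma)

    def restrict(self, ids) -> "ReferenceCovariance":
        pos = [self.variant_ids.index(v) for v in ids]
        return ReferenceCovariance(list(ids),
                                   self.gamma[np.ix_(pos, pos)])


@dataclass
class TWASResult:
    trait_id: str
    z: float
    p: float
    n_variants_used: int
    n_variants_missing_from_gwas: int
    weight_fraction_retained: float = 1.0
    p_bonf: float = np.nan
    significant: bool = False
    reason: str = ""


def zscore_from_weights(weights: np.ndarray, gamma: np.ndarray,
                        gwas_z: np.ndarray) -> float:
    """Core combination rule on aligned arrays.

    ``weights`` and ``gwas_z`` are per-variant; ``gamma`` is the reference
    covariance of the same variants.  Raises on sigma_g = 0.
    """
    w = np.asarray(weights, dtype=float)
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    sigma_l = np.sqrt(np.clip(np.diag(gamma), 0.0, None))
    sigma_g2 = float(w @ gamma @ w)
    if sigma_g2 <= 0:
        raise ZeroDivisionError("predicted-expression variance sigma_g^2 is "
                                "zero; Z undefined")
    return float(np.sum(w * sigma_l * np.asarray(gwas_z, dtype=float))
                 / np.sqrt(sigma_g2))


def gene_zscore(model: GeneModel, gwas: pd.DataFrame,
                refcov: ReferenceCovariance) -> TWASResult:
    """Association Z-score for one gene from harmonized GWAS statistics.

    Degenerate cases (no overlapping variants, zero predicted-expression
    variance) yield an NA result carrying the reason, not an exception.
    """
    gwas_idx = gwas.set_index("variant_id")
    present = [v for v in model.variant_ids if v in gwas_idx.index]
    n_missing = len(model.variant_ids) - len(present)
    if not present:
        return TWASResult(model.trait_id, np.nan, np.nan, 0,
                          n_missing, 0.0, reason="no model variant in GWAS")
    w_all = model.as_series()
    w = w_all.loc[present].to_numpy()
    total_w = float(np.abs(w_all).sum())
    retained = float(np.abs(w).sum() / total_w) if total_w > 0 else 0.0
    sub = refcov.restrict(present)
    zl = (gwas_idx.loc[present, "beta"].to_numpy(dtype=float)
          / gwas_idx.loc[present, "se"].to_numpy(dtype=float))
    try:
        z = zscore_from_weights(w, sub.gamma, zl)
    except ZeroDivisionError as exc:
        return TWASResult(model.trait_id, np.nan, np.nan, len(present),
                          n_missing, retained, reason=str(exc))
    p = 2.0 * stats.norm.sf(abs(z))
    return TWASResult(model.trait_id, z, p, len(present), n_missing, retained)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Familywise significance threshold alpha / n."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def run_twas(models: list[GeneModel], gwas: pd.DataFrame,
             refcovs: dict[str, ReferenceCovariance],
             alpha: float = 0.05) -> list[TWASResult]:
    """One result per model; Bonferroni over the traits actually tested
    (those yielding a finite Z) in this run."""
    results = [gene_zscore(m, gwas, refcovs[m.trait_id]) for m in models]
    tested = [r for r in results if np.isfinite(r.z)]
    if tested:
        thr = bonferroni_threshold(alpha, len(tested))
        for r in tested:
            r.p_bonf = min(1.0, r.p * len(tested))
            r.significant = r.p < thr
    return results


def results_table(results: list[TWASResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"trait": r.trait_id, "z": r.z, "p": r.p,
         "n_used": r.n_variants_used,
         "n_missing": r.n_variants_missing_from_gwas,
         "p_bonf": r.p_bonf, "significant": r.significant,
         "reason": r.reason}
        for r in results
    ])


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

#: protein-coding gene universe (GENCODE v26 annotation)
DEFAULT_GENE_UNIVERSE = 19_291


def enrichment_test(m: int, k: int, q: int,
                    N: int = DEFAULT_GENE_UNIVERSE,
                    inclusive: bool = False) -> float:
    """Hypergeometric enrichment of disease-database genes among hits.

    Draw *k* significant genes from a universe of *N* containing *m*
    database genes and observe *q* database hits.  Returns the strict upper
    tail P(X > q) — the convention used throughout this pipeline — or
    P(X >= q) when ``inclusive`` (the textbook enrichment p; the two differ
    by the point mass at q).
    """
    m, k, q, N = int(m), int(k), int(q), int(N)
    if not (0 <= m <= N and 0 <= k <= N):
        raise ValueError("require 0 <= m, k <= N")
    if q < 0 or q > min(m, k):
        raise ValueError(f"q={q} outside [0, min(m, k)={min(m, k)}]")
    return float(stats.hypergeom.sf(q - 1 if inclusive else q, N, m, k))
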