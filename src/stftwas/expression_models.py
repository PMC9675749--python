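"""Per-gene elastic-net expression prediction from prioritized cis-variants.

Traits (gene expression levels or intron-usage splicing ratios — the two are
treated identically) are first residualized on covariates, then regressed on
standardized effect-allele dosages of the prioritized variants inside the
cis window with an elastic net (mixing parameter 0.5, the TWAS convention).
Model quality is the squared Pearson correlation between pooled out-of-fold
predictions and the observed trait over a deterministic 10-fold split; only
models with CV R^2 > 0.01 are retained downstream.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .data_io import GenotypePanel

logger = logging.getLogger(__name__)

L1_RATIO = 0.5  # established TWAS elastic-net mixing parameter


class GeneSkipped(Exception):
    """Raised when a trait cannot be modeled (reason in ``args[0]``)."""


@dataclass
class GeneModel:
    """Elastic-net prediction model for one molecular trait."""

    trait_id: str
    cis_window: tuple            # (chrom, start, end), 1-based inclusive span
    variant_ids: list[str]       # variants with nonzero weight
    weights: np.ndarray          # on the original dosage scale
    cv_r2: float
    n_train: int
    alpha: float                 # selected penalty strength
    l1_ratio: float = L1_RATIO
    training_variant_universe: str = ""
    n_candidates: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.variant_ids,
                         name=self.trait_id)


# ---------------------------------------------------------------------------
# Covariate residualization
# ---------------------------------------------------------------------------

def _collinear_columns(C: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns linearly dependent on earlier ones."""
    bad = []
    kept: list[int] = []
    for j in range(C.shape[1]):
        sub = C[:, kept + [j]]
        if np.linalg.matrix_rank(sub) <= len(kept):
            bad.append(names[j])
        else:
            kept.append(j)
    return bad


def residualize_traits(values: pd.DataFrame,
                       covariates: pd.DataFrame | None = None,
                       drop_constant: bool = True) -> pd.DataFrame:
    """Replace each trait by its residual from an OLS projection on the
    covariates plus an intercept (traits are centered if no covariates).

    Trait columns whose residual is (numerically) constant are dropped.
    Raises on rank-deficient covariates, naming the offending columns.
    """
    Y = values.to_numpy(dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        design = np.ones((len(values), 1))
    else:
        if list(covariates.index) != list(values.index):
            covariates = covariates.loc[values.index]
        C = covariates.to_numpy(dtype=float)
        keep = C.std(axis=0) > 0
        C = C[:, keep]
        names = [n for n, k in zip(covariates.columns, keep) if k]
        design = np.column_stack([np.ones(len(values)), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = _collinear_columns(design[:, 1:], names)
            raise ValueError(f"collinear covariate columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    out = pd.DataFrame(resid, index=values.index, columns=values.columns)
    if drop_constant:
        scale = np.abs(Y).std(axis=0) + 1e-12
        const = (out.std(axis=0).to_numpy() / scale) < 1e-8
        if const.any():
            logger.info("dropping %d traits constant after residualization: %s",
                        int(const.sum()),
                        list(out.columns[const][:5]))
            out = out.loc[:, ~const]
    return out


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

def _hash_order(sample_ids, seed: int) -> np.ndarray:
    """Canonical sample order from a hash of (seed, sample id) — depends
    only on the ID set, never on input order."""
    digests = np.array([
        int.from_bytes(
            hashlib.blake2b(f"{seed}:{s}".encode(), digest_size=8).digest(),
            "big")
        for s in sample_ids
    ], dtype=np.uint64)
    return np.argsort(digests, kind="stable")


def fold_assignment(sample_ids, folds: int, seed: int) -> np.ndarray:
    """Balanced deterministic folds from a hash of (seed, sample id).

    Depends only on the set of IDs, so any consistent permutation of
    samples yields the same per-sample fold — CV R^2 is order-invariant.
    """
    order = _hash_order(sample_ids, seed)
    fold = np.empty(len(order), dtype=int)
    fold[order] = np.arange(len(order)) % folds
    return fold


def _pearson_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation, floored at 0 for anticorrelated
    predictions.

    Pooled out-of-fold predictions of a null model anticorrelate with the
    observations (every fold's intercept is its training-fold mean, which
    excludes the held-out samples); squaring that artifact would spuriously
    pass null models through the R^2 filter, so negative correlations count
    as no predictive ability.
    """
    if np.std(pred) < 1e-12 or np.std(obs) < 1e-12:
        return 0.0
    r = float(np.corrcoef(pred, obs)[0, 1])
    return r ** 2 if r > 0 else 0.0


def _sse_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return 0.0
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _enet_cv_weights(X: np.ndarray, y: np.ndarray, folds: int, seed: int,
                     nested: bool, n_alphas: int = 30, sample_ids=None,
                     alpha_override: float | None = None):
    """Out-of-fold predictions + full-data weights on the standardized scale.

    ``nested=True`` reselects the penalty inside every training fold (no
    selection leakage into CV R^2); ``nested=False`` selects it once on the
    full data, the cheap variant used inside large simulation loops.
    When ``sample_ids`` is given, all data are put in hash-canonical sample
    order first, so every downstream quantity is invariant to the order the
    samples arrived in.
    """
    n = len(y)
    order = _hash_order(sample_ids if sample_ids is not None
                        else np.arange(n), seed)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    X, y = X[order], y[order]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    fold = np.arange(n) % folds

    def fit_fixed(Xtr, ytr, alpha):
        m = ElasticNet(alpha=alpha, l1_ratio=L1_RATIO, max_iter=5000,
                       tol=1e-5)
        m.fit(Xtr, ytr)
        return m

    def fit_cv(Xtr, ytr):
        if alpha_override is not None:
            return fit_fixed(Xtr, ytr, alpha_override)
        cv = KFold(n_splits=min(5, max(2, len(ytr) // 10)), shuffle=True,
                   random_state=seed & 0x7FFFFFFF)
        m = ElasticNetCV(l1_ratio=L1_RATIO, alphas=n_alphas, cv=cv,
                         max_iter=5000, tol=1e-5)
        m.fit(Xtr, ytr)
        return m

    full = fit_cv(Xs, y)
    full_alpha = alpha_override if alpha_override is not None else full.alpha_
    preds = np.empty(n)
    for f in range(folds):
        te = fold == f
        tr = ~te
        if nested:
            m = fit_cv(Xs[tr], y[tr])
        else:
            m = fit_fixed(Xs[tr], y[tr], full_alpha)
        preds[te] = m.predict(Xs[te])
    # weights back on the dosage scale; predictions back in input order
    w = full.coef_ / sd
    return preds[inv], w, float(full_alpha)


def cis_candidates(panel: GenotypePanel, span: tuple,
                   prioritized_ids, window_bp: int = 1_000_000) -> np.ndarray:
    """Boolean mask over panel variants: prioritized AND inside the cis
    window ``[start - window_bp, end + window_bp]`` on the trait's chrom."""
    chrom, start, end = span
    v = panel.variants
    in_window = ((v["chrom"].astype(str) == str(chrom))
                 & (v["pos"] >= int(start) - window_bp)
                 & (v["pos"] <= int(end) + window_bp)).to_numpy()
    in_set = v["id"].isin(set(prioritized_ids)).to_numpy()
    return in_window & in_set


def train_gene_model(genotypes: GenotypePanel, trait: pd.Series, span: tuple,
                     prioritized_ids, window_bp: int = 1_000_000,
                     folds: int = 10, seed: int = 0, nested: bool = True,
                     r2_mode: str = "pearson", universe_label: str = "",
                     alpha_override: float | None = None) -> GeneModel:
    """Train one gene's elastic-net model from prioritized cis-variants.

    Raises :class:`GeneSkipped` when no prioritized cis-variant exists or
    the trait has zero variance.  ``r2_mode`` selects the CV R^2 flavor:
    squared Pearson correlation of pooled out-of-fold predictions (default)
    or ``"sse"`` for 1 - SSE/SST.
    """
    mask = cis_candidates(genotypes, span, prioritized_ids, window_bp)
    if not mask.any():
        raise GeneSkipped(f"{trait.name}: no prioritized cis-variants")
    y = trait.reindex(genotypes.samples).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise GeneSkipped(f"{trait.name}: trait missing for some samples")
    if np.std(y) < 1e-12:
        raise GeneSkipped(f"{trait.name}: trait variance is zero")
    X = genotypes.dosages[:, mask]
    if np.isnan(X).any():
        raise GeneSkipped(f"{trait.name}: unimputed missing dosages; "
                          "run mean_impute first")
    preds, w, alpha = _enet_cv_weights(X, y, folds, seed, nested,
                                       sample_ids=genotypes.samples,
                                       alpha_override=alpha_override)
    r2 = _pearson_r2(preds, y) if r2_mode == "pearson" else _sse_r2(preds, y)
    ids = genotypes.variants.loc[mask, "id"].to_numpy()
    nz = w != 0
    return GeneModel(
        trait_id=str(trait.name), cis_window=tuple(span),
        variant_ids=list(ids[nz]), weights=w[nz], cv_r2=r2,
        n_train=len(y), alpha=alpha,
        training_variant_universe=universe_label,
        n_candidates=int(mask.sum()),
    )


def train_models(genotypes: GenotypePanel, traits: pd.DataFrame,
                 spans: pd.DataFrame, prioritized_ids, **kwargs):
    """Train all traits; returns (models, skipped: {trait: reason}).

    ``spans`` is indexed by trait with columns chrom/start/end.
    """
    models, skipped = [], {}
    for trait_id in traits.columns:
        if trait_id not in spans.index:
            skipped[trait_id] = "no genomic span"
            continue
        row = spans.loc[trait_id]
        try:
            models.append(train_gene_model(
                genotypes, traits[trait_id],
                (row["chrom"], row["start"], row["end"]),
                prioritized_ids, **kwargs))
        except GeneSkipped as exc:
            skipped[trait_id] = str(exc)
    return models, skipped


def select_models(models: list[GeneModel],
                  r2_min: float = 0.01) -> list[GeneModel]:
    """Keep models with CV R^2 strictly greater than ``r2_min``."""
    return [m for m in models if m.cv_r2 > r2_min]


# ---------------------------------------------------------------------------
# PredictDB-convention model store
# ---------------------------------------------------------------------------

def write_model_store(models: list[GeneModel], panel: GenotypePanel,
                      out_dir) -> None:
    """Write weights.tsv / extra.tsv / covariance.tsv for a model set.

    The variant covariance is computed on the training panel, the same
    samples the weights came from.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vinfo = panel.variants.set_index("id")
    wrows, erows, crows = [], [], []
    for m in models:
        for vid, w in zip(m.variant_ids, m.weights):
            wrows.append((m.trait_id, vid, vinfo.loc[vid, "ref"],
                          vinfo.loc[vid, "alt"], w))
        erows.append((m.trait_id, m.cv_r2, len(m.variant_ids)))
        if m.variant_ids:
            idx = [vinfo.index.get_loc(v) for v in m.variant_ids]
            sub = panel.dosages[:, idx]
            cov = np.cov(sub, rowvar=False, ddof=1).reshape(len(idx), len(idx))
            for a in range(len(idx)):
                for b in range(a, len(idx)):
                    crows.append((m.trait_id, m.variant_ids[a],
                                  m.variant_ids[b], cov[a, b]))
    pd.DataFrame(wrows, columns=["gene", "variant_id", "ref", "alt",
                                 "weight"]).to_csv(
        out / "weights.tsv", sep="\t", index=False)
    pd.DataFrame(erows, columns=["gene", "cv_r2", "n_snps"]).to_csv(
        out / "extra.tsv", sep="\t", index=False)
    pd.DataFrame(crows, columns=["gene", "variant_i", "variant_j",
                                 "cov"]).to_csv(
        out / "covariance.tsv", sep="\t", index=False)
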