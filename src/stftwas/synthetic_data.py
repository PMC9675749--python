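"""Synthetic input generator: LD-structured genotypes, TF peak annotations
with controllable causal-variant enrichment, expression panels, GWAS cohorts
and summary statistics.

Genotypes are drawn per LD block from a latent Gaussian copula with
exchangeable within-block correlation ``rho``: each haplotype's latent value
is ``sqrt(rho) * f + sqrt(1 - rho) * e`` with a shared block factor *f*, and
an allele is carried when the latent exceeds the normal quantile of its
target allele frequency.  Dosage = sum of two independent haplotypes.  This
gives analytically tractable LD expectations; no attempt is made at
realistic haplotype structure (no recombination maps, no coalescent).

Every file the bundle writes round-trips through :mod:`stftwas.data_io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypePanel, TFPeakSet, _variant_stats

#: base-pair spacing between adjacent synthetic variants; wide enough that
#: one cis window (+/- 1 Mb) holds ~80 variants rather than the whole panel
VARIANT_SPACING = 25_000
#: half-width of a synthetic TF peak around a covered variant (< spacing/2,
#: so a peak never spills onto a neighboring variant)
PEAK_HALFWIDTH = 25


@dataclass
class FixtureSpec:
    """Configuration of one synthetic study bundle.

    Defaults emulate a desk-scale version of the study conditions: a few
    hundred reference samples, a few thousand GWAS cohort samples,
    LD blocks of correlated common variants, a minority of TFs whose peaks
    are enriched for causal variants, and moderately heritable expression.
    """

    n_ref_samples: int = 300
    n_cohort_samples: int = 2000
    n_variants: int = 4000
    n_blocks: int = 50
    within_block_correlation: float = 0.3
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 20
    n_tfs: int = 8
    n_susceptible_tfs: int = 2
    tf_peak_fraction: float = 0.10
    causal_in_peak_enrichment: float = 5.0
    n_causal_per_gene: int = 5
    h2_expr: float = 0.3
    h2_trait: float = 0.1
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self):
        if min(self.n_ref_samples, self.n_cohort_samples, self.n_variants,
               self.n_blocks, self.n_genes, self.n_tfs) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.within_block_correlation < 1):
            raise ValueError("within-block correlation must be in [0, 1)")
        if self.causal_in_peak_enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"infeasible maf_range {self.maf_range}")
        if self.causal_in_peak_enrichment * self.tf_peak_fraction > 1:
            raise ValueError("enrichment x tf_peak_fraction exceeds 1; "
                             "causal coverage probability is not a rate")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _block_sizes(n_variants: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, n_variants // n_blocks)
    sizes[: n_variants % n_blocks] += 1
    return sizes


def sample_dosages(n_samples: int, mafs: np.ndarray, block_sizes: np.ndarray,
                   rho: float, rng: np.random.Generator) -> np.ndarray:
    """Draw {0,1,2} dosages from the exchangeable-block Gaussian copula."""
    n_variants = len(mafs)
    thresholds = stats.norm.isf(mafs)  # latent > threshold => allele carried
    dosage = np.zeros((n_samples, n_variants), dtype=float)
    start = 0
    for size in block_sizes:
        sl = slice(start, start + size)
        for _copy in range(2):
            f = rng.standard_normal((n_samples, 1))
            e = rng.standard_normal((n_samples, size))
            latent = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * e
            dosage[:, sl] += latent > thresholds[sl]
        start += size
    return dosage


def generate_genotypes(spec: FixtureSpec, n_samples: int | None = None,
                       rng: np.random.Generator | None = None,
                       id_prefix: str = "v"):
    """LD-structured :class:`GenotypePanel` plus its block assignment.

    Returns ``(panel, blocks)`` where ``blocks`` maps variant id to block id;
    block boundaries are also what :func:`write_ld_block_bed` emits.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = n_samples if n_samples is not None else spec.n_ref_samples
    mafs = rng.uniform(*spec.maf_range, size=spec.n_variants)
    sizes = _block_sizes(spec.n_variants, spec.n_blocks)
    dosages = sample_dosages(n, mafs, sizes, spec.within_block_correlation,
                             rng)
    pos = 1 + np.arange(spec.n_variants) * VARIANT_SPACING
    ref, alt = _draw_alleles(spec.n_variants, rng)
    variants = pd.DataFrame({
        "id": [f"{id_prefix}{i:06d}" for i in range(spec.n_variants)],
        "chrom": spec.chrom, "pos": pos, "ref": ref, "alt": alt,
    })
    maf, miss, hwe = _variant_stats(dosages)
    variants["maf"] = maf
    variants["missing_rate"] = miss
    variants["hwe_p"] = hwe
    panel = GenotypePanel([f"S{i:05d}" for i in range(n)], variants, dosages)
    block_ids = np.repeat([f"block{b:03d}" for b in range(spec.n_blocks)],
                          sizes)
    blocks = pd.Series(block_ids,
                       index=pd.Index(variants["id"], name="variant_id"))
    return panel, blocks


def _draw_alleles(n: int, rng: np.random.Generator):
    """Non-palindromic ref/alt pairs, so default GWAS harmonization keeps
    every variant."""
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    idx = rng.integers(0, len(pairs), size=n)
    swap = rng.random(n) < 0.5
    ref = np.array([pairs[i][1 if s else 0] for i, s in zip(idx, swap)])
    alt = np.array([pairs[i][0 if s else 1] for i, s in zip(idx, swap)])
    return ref, alt


# ---------------------------------------------------------------------------
# TF annotations
# ---------------------------------------------------------------------------

def generate_tf_annotations(spec: FixtureSpec, variants: pd.DataFrame,
                            causal_variant_ids,
                            rng: np.random.Generator | None = None):
    """Peak sets plus the coverage truth table.

    Susceptible TFs cover causal variants at ``enrichment x baseline`` and
    other variants at the baseline ``tf_peak_fraction``; decoy TFs cover all
    variants uniformly at the baseline.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    causal = variants["id"].isin(set(causal_variant_ids)).to_numpy()
    base = spec.tf_peak_fraction
    peak_sets, cols = [], {}
    for t in range(spec.n_tfs):
        susceptible = t < spec.n_susceptible_tfs
        name = f"TF{'S' if susceptible else 'D'}{t:02d}"
        p = np.where(causal & susceptible,
                     base * spec.causal_in_peak_enrichment, base)
        covered = rng.random(len(variants)) < p
        triples = [
            (chrom, max(0, pos - 1 - PEAK_HALFWIDTH), pos - 1 + PEAK_HALFWIDTH + 1)
            for chrom, pos in zip(variants.loc[covered, "chrom"],
                                  variants.loc[covered, "pos"])
        ]
        if not triples:  # degenerate tiny spec; keep the TF with no peaks
            peak_sets.append(TFPeakSet(tf_name=name))
        else:
            peak_sets.append(TFPeakSet.from_intervals(name, triples))
        cols[name] = covered.astype(np.int8)
    truth = pd.DataFrame(cols, index=pd.Index(variants["id"],
                                              name="variant_id"))
    return peak_sets, truth


# ---------------------------------------------------------------------------
# Writers (plain-text formats only)
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path, chrom_lengths=None) -> None:
    """Write the panel as an uncompressed VCF v4.2 with GT fields."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in panel.variants["chrom"].astype(str).unique():
        length = (chrom_lengths or {}).get(
            chrom, int(panel.variants["pos"].max()) + VARIANT_SPACING)
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, row in enumerate(panel.variants.itertuples(index=False)):
        gts = [gt_map.get(d, "./.") if not np.isnan(d) else "./."
               for d in panel.dosages[:, j]]
        lines.append(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")


def write_peak_beds(peak_sets: list[TFPeakSet], out_dir) -> Path:
    """One BED per TF plus a ``tf_name<TAB>path`` manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ps in peak_sets:
        bed = out / f"{ps.tf_name}.bed"
        rows = []
        for chrom, ivals in sorted(ps.intervals.items()):
            for s, e in ivals:
                rows.append(f"{chrom}\t{s}\t{e}")
        bed.write_text("\n".join(rows) + ("\n" if rows else ""))
        manifest.append(f"{ps.tf_name}\t{bed.name}")
    mpath = out / "peaks_manifest.tsv"
    mpath.write_text("\n".join(manifest) + "\n")
    return mpath


def write_ld_block_bed(variants: pd.DataFrame, blocks: pd.Series,
                       path) -> None:
    rows = []
    for block_id, ids in blocks.groupby(blocks).groups.items():
        sub = variants.set_index("id").loc[list(ids)]
        chrom = sub["chrom"].iloc[0]
        start = int(sub["pos"].min()) - 1
        end = int(sub["pos"].max())
        rows.append((chrom, start, end, block_id))
    rows.sort(key=lambda r: (str(r[0]), r[1]))
    Path(path).write_text(
        "\n".join(f"{c}\t{s}\t{e}\t{n}" for c, s, e, n in rows) + "\n")


def linear_gwas(X: np.ndarray, y: np.ndarray):
    """Vectorized per-variant simple linear regression.

    Returns (beta, se, pvalue) arrays; degenerate columns give beta 0 with
    infinite se.
    """
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), 0.0)
        rss = (yc ** 2).sum() - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / max(n - 2, 1)
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.maximum(sxx, 1e-300),
                              np.inf))
    z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=max(n - 2, 1))
    return beta, se, p


def logistic_score_gwas(X: np.ndarray, y: np.ndarray):
    """Vectorized per-variant logistic-regression score test for a binary
    phenotype; returns (z, chi2, pvalue)."""
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("binary phenotype is constant")
    xc = X - X.mean(axis=0)
    u = xc.T @ (y - ybar)
    v = ybar * (1.0 - ybar) * (xc ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, u / np.sqrt(np.maximum(v, 1e-300)), 0.0)
    chi2 = z ** 2
    p = stats.chi2.sf(chi2, df=1)
    return z, chi2, p


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

def generate_study_bundle(spec: FixtureSpec, out_dir) -> dict:
    """Write a complete synthetic workspace; returns the truth record.

    Files: ``ref.vcf``, ``cohort.vcf``, ``peaks/`` + manifest,
    ``ld_blocks.bed``, ``expression.tsv``, ``covariates.tsv``,
    ``genes.tsv``, ``gwas.tsv``, ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    ref_panel, blocks = generate_genotypes(spec, spec.n_ref_samples, rng)
    cohort_mafs_rng = rng  # cohort shares variant metadata, new samples
    cohort_dos = sample_dosages(
        spec.n_cohort_samples,
        # re-derive per-variant carrier thresholds from the realized panel
        np.clip(ref_panel.variants["maf"].to_numpy(), 1e-3, 0.5),
        _block_sizes(spec.n_variants, spec.n_blocks),
        spec.within_block_correlation, cohort_mafs_rng)
    cohort_variants = ref_panel.variants[["id", "chrom", "pos", "ref",
                                          "alt"]].copy()
    maf, miss, hwe = _variant_stats(cohort_dos)
    cohort_variants["maf"] = maf
    cohort_variants["missing_rate"] = miss
    cohort_variants["hwe_p"] = hwe
    cohort_panel = GenotypePanel(
        [f"C{i:05d}" for i in range(spec.n_cohort_samples)],
        cohort_variants, cohort_dos)

    # gene spans and causal variants (drawn inside each gene's cis window)
    variants = ref_panel.variants
    stride = spec.n_variants // spec.n_genes
    half_window = 1_000_000 // VARIANT_SPACING
    genes, causal_map = [], {}
    for g in range(spec.n_genes):
        center = min(g * stride + stride // 2, spec.n_variants - 1)
        start_pos = int(variants["pos"].iloc[center])
        genes.append((f"gene{g:03d}", spec.chrom, start_pos,
                      start_pos + 10_000))
        lo = max(0, center - half_window)
        hi = min(spec.n_variants, center + half_window + 1)
        window_ids = variants["id"].iloc[lo:hi]
        eligible = window_ids[variants["maf"].iloc[lo:hi].to_numpy() >= 0.01]
        n_causal = min(spec.n_causal_per_gene, len(eligible))
        causal_map[genes[-1][0]] = list(
            rng.choice(eligible.to_numpy(), size=n_causal, replace=False))
    gene_df = pd.DataFrame(genes, columns=["gene", "chrom", "start", "end"])
    all_causal = sorted({v for ids in causal_map.values() for v in ids})

    peak_sets, truth_cov = generate_tf_annotations(spec, variants,
                                                   all_causal, rng)

    # expression in the reference panel + phenotype in the cohort
    vindex = pd.Index(variants["id"])
    expr = {}
    effects = {}
    cohort_genetic = np.zeros(spec.n_cohort_samples)
    for gene, _, _, _ in genes:
        cidx = [vindex.get_loc(v) for v in causal_map[gene]]
        beta = rng.standard_normal(len(cidx))
        effects[gene] = dict(zip(causal_map[gene], beta.tolist()))
        f1 = ref_panel.dosages[:, cidx] @ beta
        expr[gene] = _add_scaled_noise(f1, spec.h2_expr, rng)
        cohort_genetic += cohort_dos[:, cidx] @ beta
    phenotype = _add_scaled_noise(cohort_genetic, spec.h2_trait, rng)

    # covariates that genuinely enter expression, so residualization matters
    cov = pd.DataFrame({
        "PC1": rng.standard_normal(spec.n_ref_samples),
        "PC2": rng.standard_normal(spec.n_ref_samples),
        "age": rng.integers(25, 75, spec.n_ref_samples).astype(float),
    }, index=ref_panel.samples)
    cov_effect = 0.5 * cov["PC1"].to_numpy() - 0.3 * (
        (cov["age"].to_numpy() - 50.0) / 25.0)
    expr_df = pd.DataFrame(expr, index=ref_panel.samples)
    expr_df = expr_df.add(cov_effect, axis=0)

    beta_g, se_g, p_g = linear_gwas(cohort_dos, phenotype)
    gwas = pd.DataFrame({
        "variant_id": variants["id"], "chrom": variants["chrom"],
        "pos": variants["pos"], "effect_allele": variants["alt"],
        "other_allele": variants["ref"], "beta": beta_g, "se": se_g,
        "pvalue": p_g, "n": spec.n_cohort_samples,
    })

    write_vcf(ref_panel, out / "ref.vcf")
    write_vcf(cohort_panel, out / "cohort.vcf")
    write_peak_beds(peak_sets, out / "peaks")
    write_ld_block_bed(variants, blocks, out / "ld_blocks.bed")
    expr_df.rename_axis("sample").reset_index().to_csv(
        out / "expression.tsv", sep="\t", index=False)
    cov.rename_axis("sample").reset_index().to_csv(
        out / "covariates.tsv", sep="\t", index=False)
    gene_df.to_csv(out / "genes.tsv", sep="\t", index=False)
    gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)

    truth = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
        "causal_variants": causal_map,
        "effects": effects,
        "h2_expr": spec.h2_expr,
        "h2_trait": spec.h2_trait,
        "susceptible_tfs": [ps.tf_name for ps in peak_sets
                            if ps.tf_name.startswith("TFS")],
        "tf_coverage_counts": {c: int(truth_cov[c].sum())
                               for c in truth_cov.columns},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    # in-memory extras for tests / direct pipeline use
    truth["_panels"] = {"ref": ref_panel, "cohort": cohort_panel,
                        "blocks": blocks, "binding_truth": truth_cov,
                        "expression": expr_df, "covariates": cov,
                        "gwas": gwas, "genes": gene_df}
    return truth


def _add_scaled_noise(genetic: np.ndarray, h2: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Add N(0, s2_e) noise with s2_e = s2_g (1 - h2) / h2, so the genetic
    fraction of variance equals h2 in expectation; h2=0 drops the genetic
    component, h2=1 adds no noise."""
    if h2 <= 0:
        return rng.standard_normal(len(genetic))
    s2_g = float(np.var(genetic))
    if h2 >= 1 or s2_g == 0:
        return genetic.copy()
    s2_e = s2_g * (1.0 - h2) / h2
    return genetic + rng.normal(0.0, np.sqrt(s2_e), len(genetic))
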