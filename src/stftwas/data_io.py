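"""Input readers, QC filters and harmonization for the sTF-TWAS pipeline.

Conventions
-----------
* Variant positions are 1-based (VCF); peak and LD-block intervals are
  0-based half-open (BED).  A BED interval ``[start, end)`` therefore covers
  the 1-based positions ``start+1 .. end``.
* Variant identity for cross-file matching is ``(chrom, pos, sorted allele
  pair)`` — rsID-style names are carried along but never used as keys.
* Genotypes are effect-allele (ALT) dosages in {0, 1, 2}; missing calls are
  ``NaN`` until :func:`mean_impute` is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf", "missing_rate", "hwe_p"]

GWAS_REQUIRED = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "pvalue", "n"]

#: strand-ambiguous allele pairs (indistinguishable after complementing)
PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


def variant_key(chrom, pos, ref, alt) -> str:
    """Order-insensitive allele key used to match variants across files."""
    a, b = sorted((str(ref).upper(), str(alt).upper()))
    return f"{chrom}:{int(pos)}:{a}:{b}"


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with per-variant QC statistics.

    ``variants`` rows are sorted by (chrom, pos) and align with the columns
    of ``dosages``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask_or_ids) -> "GenotypePanel":
        """Return a panel restricted to a boolean mask or an ID list."""
        if isinstance(mask_or_ids, (list, tuple, set, pd.Index)):
            mask = self.variants["id"].isin(list(mask_or_ids)).to_numpy()
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        return GenotypePanel(
            samples=list(self.samples),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )


@dataclass
class TFPeakSet:
    """Merged binding intervals for one TF in one cell context."""

    tf_name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    cell_context: str = ""

    @classmethod
    def from_intervals(cls, tf_name, triples, cell_context=""):
        """Build from an iterable of (chrom, start, end), merging overlaps."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        merged = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            out = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64).reshape(-1, 2)
        return cls(tf_name=tf_name, intervals=merged, cell_context=cell_context)

    def covers(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized: does any interval cover each 1-based position?"""
        pos0 = np.asarray(pos, dtype=np.int64) - 1
        ivals = self.intervals.get(str(chrom))
        if ivals is None or len(ivals) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(ivals[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos0), dtype=bool)
        hit[ok] = pos0[ok] < ivals[idx[ok], 1]
        return hit


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact (SNP-HWE) two-sided p-value for Hardy-Weinberg equilibrium.

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more likely than the observed one.
    """
    n_het, n_hom_minor, n_hom_major = int(n_het), int(n_hom_minor), int(n_hom_major)
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het
    if rare > n:  # ensure 'rare' really is the minor allele
        rare = 2 * n - rare
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(len(het_values))
    # unnormalized log-probabilities via the recurrence
    #   P(het+2)/P(het) = 4*hr*hc / ((het+2)*(het+1))
    for k in range(1, len(het_values)):
        het = het_values[k - 1]
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        logp[k] = logp[k - 1] + np.log(4.0 * hom_r * hom_c) - np.log(
            (het + 2.0) * (het + 1.0)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = min(n_het, rare)
    obs_idx = np.searchsorted(het_values, obs)
    # tolerance guards against float ties in the 'no more likely' rule
    p = probs[probs <= probs[obs_idx] * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def _variant_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (maf, missing_rate, hwe_p) from a dosage matrix with NaNs."""
    n_samples, n_variants = dosages.shape
    miss = np.isnan(dosages)
    n_called = n_samples - miss.sum(axis=0)
    missing_rate = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(dosages, axis=0) / np.maximum(2 * n_called, 1)
    alt_freq = np.where(n_called == 0, 0.0, alt_freq)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    hwe = np.ones(n_variants)
    for j in range(n_variants):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        n_hom_ref = int((col == 0).sum())
        if (2 * n_hom_alt + n_het) <= (2 * n_hom_ref + n_het):
            hwe[j] = hwe_exact_p(n_het, n_hom_alt, n_hom_ref)
        else:
            hwe[j] = hwe_exact_p(n_het, n_hom_ref, n_hom_alt)
    return maf, missing_rate, hwe


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def load_genotype_panel(path) -> GenotypePanel:
    """Read a VCF (GT field) into a :class:`GenotypePanel`.

    Multiallelic records are skipped with a warning; per-variant MAF,
    missingness and HWE exact-test p-values are computed from the data.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ValueError(f"malformed or unreadable VCF: {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF has zero samples: {path}")

    rows, cols = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        vid = rec.ID if rec.ID not in (None, ".") else variant_key(
            rec.CHROM, rec.POS, rec.REF, rec.ALT[0]
        )
        rows.append((vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
        cols.append(gt)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records in {path}")

    if not rows:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
        return GenotypePanel(samples, variants,
                             np.zeros((len(samples), 0)))

    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(cols)
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    maf, missing_rate, hwe = _variant_stats(dosages)
    variants["maf"] = maf
    variants["missing_rate"] = missing_rate
    variants["hwe_p"] = hwe
    return GenotypePanel(samples, variants, dosages)


def qc_filter_variants(panel: GenotypePanel, maf_min: float = 0.01,
                       miss_max: float = 0.10,
                       hwe_alpha: float = 1e-6) -> GenotypePanel:
    """Drop variants with MAF < ``maf_min``, missingness > ``miss_max`` or
    HWE exact-test p < ``hwe_alpha``; sample order is unchanged."""
    v = panel.variants
    keep = ((v["maf"].to_numpy() >= maf_min)
            & (v["missing_rate"].to_numpy() <= miss_max)
            & (v["hwe_p"].to_numpy() >= hwe_alpha))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("QC removed %d/%d variants", dropped, len(v))
    return panel.subset_variants(keep)


def mean_impute(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the per-variant mean (post-QC convention)."""
    dos = panel.dosages.copy()
    if dos.size:
        col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]
    return GenotypePanel(list(panel.samples), panel.variants.copy(), dos)


# ---------------------------------------------------------------------------
# TF peaks / binding status
# ---------------------------------------------------------------------------

def load_peaks_manifest(manifest_path) -> list[TFPeakSet]:
    """Read a two-column manifest ``tf_name<TAB>bed_path`` into peak sets."""
    manifest_path = Path(manifest_path)
    peak_sets = []
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tf_name, bed_path = line.split("\t")[:2]
        bed_path = Path(bed_path)
        if not bed_path.is_absolute():
            bed_path = manifest_path.parent / bed_path
        peak_sets.append(load_peak_bed(bed_path, tf_name=tf_name))
    return peak_sets


def load_peak_bed(path, tf_name: str | None = None) -> TFPeakSet:
    """Read one BED3+ file (columns beyond 3 ignored) for one TF."""
    path = Path(path)
    name = tf_name if tf_name is not None else path.stem
    triples = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: BED line has <3 columns")
        triples.append((parts[0], int(parts[1]), int(parts[2])))
    return TFPeakSet.from_intervals(name, triples)


def annotate_binding_status(variants: pd.DataFrame,
                            peaks: list[TFPeakSet]) -> pd.DataFrame:
    """Binary variants x TFs occupancy matrix.

    ``status[v, t] = 1`` iff the variant's 1-based position falls in a merged
    BED interval of TF *t* under the half-open convention.  Chromosomes
    absent from a peak file give zero entries (with a warning), not errors.
    """
    status = pd.DataFrame(
        0, index=pd.Index(variants["id"], name="variant_id"),
        columns=[p.tf_name for p in peaks], dtype=np.int8,
    )
    chroms = variants["chrom"].astype(str)
    for peak in peaks:
        col = np.zeros(len(variants), dtype=bool)
        for chrom in chroms.unique():
            sel = (chroms == chrom).to_numpy()
            if chrom not in peak.intervals:
                continue
            col[sel] = peak.covers(chrom, variants.loc[sel, "pos"].to_numpy())
        missing = set(peak.intervals) - set(chroms.unique())
        if missing and len(variants):
            logger.warning("TF %s: peak chromosomes %s absent from variants",
                           peak.tf_name, sorted(missing))
        status[peak.tf_name] = col.astype(np.int8)
    return status


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

def load_ld_blocks(path, variants: pd.DataFrame) -> pd.Series:
    """Assign every variant to one LD block from a BED3+ file.

    Variants covered by no block get singleton blocks (logged); the first
    covering block wins if intervals overlap.
    """
    blocks = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: BED line has <3 columns")
        name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
        blocks.append((parts[0], int(parts[1]), int(parts[2]), name))

    assignment = pd.Series(index=pd.Index(variants["id"], name="variant_id"),
                           dtype=object)
    chroms = variants["chrom"].astype(str).to_numpy()
    pos0 = variants["pos"].to_numpy() - 1
    for chrom, start, end, name in blocks:
        hit = (chroms == chrom) & (pos0 >= start) & (pos0 < end)
        unset = assignment.isna().to_numpy()
        assignment.iloc[np.where(hit & unset)[0]] = name
    n_orphan = int(assignment.isna().sum())
    if n_orphan:
        logger.info("%d variants outside all LD blocks get singleton blocks",
                    n_orphan)
        orphan_idx = np.where(assignment.isna().to_numpy())[0]
        for i in orphan_idx:
            assignment.iloc[i] = f"singleton:{assignment.index[i]}"
    return assignment


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def load_gwas(path) -> pd.DataFrame:
    """Read a GWAS summary TSV; required columns per the interface contract,
    extra columns ignored."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GWAS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table missing columns: {missing}")
    df = df[GWAS_REQUIRED].copy()
    df["chrom"] = df["chrom"].astype(str)
    return df


def harmonize_gwas(gwas: pd.DataFrame, panel: GenotypePanel,
                   drop_ambiguous: bool = True) -> pd.DataFrame:
    """Align GWAS effect alleles to the panel's ALT allele.

    * effect allele == panel ALT: kept as-is;
    * effect allele == panel REF (swap): beta sign flipped;
    * palindromic (A/T, C/G) variants dropped when ``drop_ambiguous``;
    * variants absent from the panel (by chrom/pos/allele-pair key) dropped.

    ``chi2`` is (beta/se)^2, or recovered from the p-value via the 1-df
    chi-squared upper tail when beta or se is unavailable.  Idempotent.
    """
    gwas = gwas.copy()
    gwas["key"] = [variant_key(c, p, ea, oa) for c, p, ea, oa in
                   zip(gwas["chrom"], gwas["pos"], gwas["effect_allele"],
                       gwas["other_allele"])]
    pv = panel.variants
    panel_keys = pd.DataFrame({
        "key": [variant_key(c, p, r, a) for c, p, r, a in
                zip(pv["chrom"], pv["pos"], pv["ref"], pv["alt"])],
        "panel_id": pv["id"].to_numpy(),
        "panel_ref": pv["ref"].to_numpy(),
        "panel_alt": pv["alt"].to_numpy(),
    })
    merged = gwas.merge(panel_keys, on="key", how="inner")
    n_unmatched = len(gwas) - len(merged)
    if n_unmatched:
        logger.info("harmonize: %d GWAS variants not in panel", n_unmatched)
    if merged.empty:
        raise ValueError("no GWAS variants overlap the genotype panel")

    if drop_ambiguous:
        pal = np.array([
            frozenset((str(ea).upper(), str(oa).upper())) in PALINDROMIC
            for ea, oa in zip(merged["effect_allele"], merged["other_allele"])
        ])
        if pal.any():
            logger.info("harmonize: dropped %d palindromic variants",
                        int(pal.sum()))
        merged = merged.loc[~pal]
        if merged.empty:
            raise ValueError("all overlapping variants were palindromic")

    ea = merged["effect_allele"].astype(str).str.upper()
    oa = merged["other_allele"].astype(str).str.upper()
    ref = merged["panel_ref"].astype(str).str.upper()
    alt = merged["panel_alt"].astype(str).str.upper()
    aligned = (ea == alt) & (oa == ref)
    swapped = (ea == ref) & (oa == alt)
    merged = merged.loc[aligned | swapped].copy()
    if merged.empty:
        raise ValueError("no allele-consistent GWAS/panel overlap")
    flip = swapped.loc[merged.index]
    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, ["effect_allele", "other_allele"]] = (
        merged.loc[flip, ["other_allele", "effect_allele"]].to_numpy())

    beta = merged["beta"].to_numpy(dtype=float)
    se = merged["se"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (beta / se) ** 2
    need_p = ~np.isfinite(chi2)
    if need_p.any():
        chi2[need_p] = stats.chi2.isf(
            merged["pvalue"].to_numpy(dtype=float)[need_p], df=1)
    merged["chi2"] = chi2
    merged["variant_id"] = merged["panel_id"]
    merged["harmonized"] = True
    out = merged[["variant_id", "chrom", "pos", "effect_allele",
                  "other_allele", "beta", "se", "pvalue", "n",
                  "chi2", "harmonized"]].reset_index(drop=True)
    return out
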