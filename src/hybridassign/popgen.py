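"""Summary statistics on biallelic genotype matrices.

All functions take alt-allele dosage matrices of shape (n_sites, n_samples)
with entries in {0, 1, 2} and -1 for missing calls.  Differentiation uses the
Hudson FST estimator with finite-sample correction (Bhatia-style ratio of
averages for the composite); diversity statistics are the standard
frequency-spectrum estimators computed from allele counts, with Tajima's D
using the published variance constants.

Note these are SNP-genotype statistics (labelled FST), not the
haplotype-sequence PhiST of sequence-based packages; on biallelic data with
uniform weighting the two target the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "allele_counts",
    "hudson_fst",
    "fst_per_locus",
    "diversity",
    "tajimas_d_constants",
    "dxy",
    "locus_stats_table",
]


def allele_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt count, total called alleles) per site from a dosage matrix."""
    geno = np.asarray(geno)
    called = geno >= 0
    alt = np.where(called, geno, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    return alt.astype(float), tot.astype(float)


def _hudson_components(geno_a, geno_b):
    alt_a, n_a = allele_counts(geno_a)
    alt_b, n_b = allele_counts(geno_b)
    ok = (n_a >= 4) & (n_b >= 4)  # need >=2 diploids with calls per pop
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = alt_a / n_a
        p_b = alt_b / n_b
        num = (p_a - p_b) ** 2 \
            - p_a * (1 - p_a) / (n_a - 1) \
            - p_b * (1 - p_b) / (n_b - 1)
        den = p_a * (1 - p_b) + p_b * (1 - p_a)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


@dataclass(frozen=True)
class FstResult:
    per_locus: np.ndarray       # NaN where undefined (monomorphic / too few calls)
    composite: float            # ratio of averages over defined loci
    n_excluded: int             # loci with undefined FST
    clamped: bool               # True if the composite was negative (reported unclamped)


def hudson_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> FstResult:
    """Per-locus and composite Hudson FST between two genotype matrices.

    Monomorphic loci (zero between-population heterozygosity) are undefined
    per locus and excluded from the composite numerator/denominator sums; the
    composite is sum(numerators) / sum(denominators) across the rest.
    """
    num, den = _hudson_components(geno_a, geno_b)
    defined = np.isfinite(den) & (den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = np.where(defined, num / den, np.nan)
    if defined.sum() == 0:
        composite = np.nan
    else:
        composite = float(np.nansum(num[defined]) / np.nansum(den[defined]))
    return FstResult(
        per_locus=per_locus,
        composite=composite,
        n_excluded=int((~defined).sum()),
        clamped=bool(np.isfinite(composite) and composite < 0),
    )


def fst_per_locus(geno: np.ndarray, pop_labels) -> FstResult:
    """Hudson FST from one matrix plus a two-level population label vector."""
    labels = np.asarray(pop_labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError("exactly two population labels required")
    a = np.asarray(geno)[:, labels == levels[0]]
    b = np.asarray(geno)[:, labels == levels[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per population")
    return hudson_fst(a, b)


def tajimas_d_constants(n: int) -> dict:
    """Variance constants a1, a2, b1, b2, c1, c2, e1, e2 for n chromosomes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def diversity(geno: np.ndarray, n_sites: int | None = None) -> dict:
    """Nucleotide diversity, Watterson's theta, and Tajima's D.

    Sites with missing calls are evaluated at their called sample size for
    pairwise diversity; S and the D constants use the minimum fully-usable
    chromosome count.  ``n_sites`` (default: number of matrix rows) scales pi
    and theta to per-site values when the matrix includes only variable sites
    of a longer locus.

    Returns dict with keys ``pi``, ``theta_w``, ``tajimas_d``, ``S``, ``n``;
    ``tajimas_d`` is None when there are no segregating sites or fewer than
    4 chromosomes.
    """
    geno = np.asarray(geno)
    if n_sites is None:
        n_sites = geno.shape[0]
    alt, tot = allele_counts(geno)
    usable = tot >= 2
    alt, tot = alt[usable], tot[usable]
    seg = (alt > 0) & (alt < tot)
    S = int(seg.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site_pi = 2.0 * alt * (tot - alt) / (tot * (tot - 1))
    pi_sum = float(np.nansum(per_site_pi))
    n_chrom = int(tot.min()) if tot.size else 0
    if n_chrom >= 2 and S > 0:
        a1 = tajimas_d_constants(n_chrom)["a1"]
        theta_w_sum = S / a1
    else:
        theta_w_sum = 0.0
    d = None
    if n_chrom >= 4 and S > 0:
        k = tajimas_d_constants(n_chrom)
        var = k["e1"] * S + k["e2"] * S * (S - 1)
        if var > 0:
            d = float((pi_sum - S / k["a1"]) / np.sqrt(var))
    return {
        "pi": pi_sum / n_sites,
        "theta_w": theta_w_sum / n_sites,
        "tajimas_d": d,
        "S": S,
        "n": n_chrom,
    }


def dxy(geno_a: np.ndarray, geno_b: np.ndarray, n_sites: int | None = None) -> float:
    """Average between-population pairwise difference per site.

    Per site this is p_a(1-p_b) + p_b(1-p_a) with population allele
    frequencies; summed over sites and divided by ``n_sites`` (default: the
    number of matrix rows, which must then include invariant sites for a
    per-bp rate).
    """
    geno_a, geno_b = np.asarray(geno_a), np.asarray(geno_b)
    if geno_a.shape[1] == 0 or geno_b.shape[1] == 0:
        raise ValueError("both populations must be non-empty")
    if n_sites is None:
        n_sites = geno_a.shape[0]
    alt_a, n_a = allele_counts(geno_a)
    alt_b, n_b = allele_counts(geno_b)
    ok = (n_a > 0) & (n_b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = alt_a / n_a
        p_b = alt_b / n_b
        per_site = p_a * (1 - p_b) + p_b * (1 - p_a)
    return float(np.nansum(np.where(ok, per_site, 0.0))) / n_sites


def locus_stats_table(geno: np.ndarray, pop_labels, chrom=None, pos=None) -> pd.DataFrame:
    """Per-SNP statistics table (Manhattan-ready chromosome/bp ordering)."""
    labels = np.asarray(pop_labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError("exactly two population labels required")
    a = np.asarray(geno)[:, labels == levels[0]]
    b = np.asarray(geno)[:, labels == levels[1]]
    fst = hudson_fst(a, b)
    n = geno.shape[0]
    rows = {
        "chrom": chrom if chrom is not None else np.repeat("locus", n),
        "pos": pos if pos is not None else np.arange(1, n + 1),
        "fst": fst.per_locus,
    }
    for tag, g in ((str(levels[0]), a), (str(levels[1]), b)):
        alt, tot = allele_counts(g)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(tot >= 2, 2.0 * alt * (tot - alt) / (tot * (tot - 1)), np.nan)
        rows[f"pi_{tag}"] = pi
    alt_a, n_a = allele_counts(a)
    alt_b, n_b = allele_counts(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        rows["dxy"] = (alt_a / n_a) * (1 - alt_b / n_b) + (alt_b / n_b) * (1 - alt_a / n_a)
    return pd.DataFrame(rows)
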