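"""Assignment-probability pipeline: simulated hybrid indices and q-based bins.

Hybrid genotypes are simulated by allele sampling at unlinked biallelic SNPs:
an F1 draws one allele per SNP from each parental gene pool (probability
proportional to the pool's allele frequency), and each backcross generation
draws one allele from the previous hybrid's genotype (either of its two
alleles with probability 1/2) and one from the recurrent population's
frequencies.  Under fixed differences the expected interspecific fraction
therefore halves each generation: E[1 - q at F_t] = 2**-t.

Admixture proportions q are estimated by supervised maximum likelihood
against the two parental allele-frequency panels (the likelihood is concave
in q), with an optional unsupervised K=2 EM refinement of both q and the
population frequencies for cross-checks.  Simulated per-generation q
envelopes (mean/min/max) provide the expected-assignment bins that classify
empirical samples into pure / F1 / backcross categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .synthetic import AllelePanel

__all__ = [
    "HybridClass",
    "TABLE1_BINS",
    "SupervisedAdmixture",
    "AdmixtureK2",
    "HybridBinClassifier",
    "simulate_hybrid_genotypes",
    "estimate_admixture",
    "derive_envelopes",
    "classify",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# hybrid genotype simulation (unlinked SNPs; no recombination map by design)

def simulate_hybrid_genotypes(
    panel: AllelePanel,
    n_f1: int = 10,
    lineages_per_direction: int = 5,
    generations: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate F1 hybrids and recurrent-backcross lineages by allele sampling.

    ``generations`` counts backcross meioses after the F1, so the labels run
    F1 then F2..F(1+generations).  Returns a long-format table with one row
    per simulated individual: columns ``generation`` (int, 1 = F1),
    ``direction`` ('A', 'B', or 'none' for F1), ``lineage``, and ``genotype``
    (0/1/2 alt-dosage ndarray over the panel SNPs).
    """
    rng = np.random.default_rng(seed)
    qa, qb = panel.freqs(smoothing=0.0)
    n = panel.n_snps
    rows = []

    def draw(freq):
        return (rng.random(n) < freq).astype(np.int8)

    f1_alleles = []
    for i in range(n_f1):
        pair = np.stack([draw(qa), draw(qb)])  # allele 0 from pool A, 1 from pool B
        f1_alleles.append(pair)
        rows.append((1, "none", i, pair.sum(axis=0).astype(np.int16)))

    for d_idx, (direction, q_rec) in enumerate((("A", qa), ("B", qb))):
        for lineage in range(lineages_per_direction):
            # the first half of the F1s seeds direction A, the second half B
            pair = f1_alleles[(lineage + d_idx * lineages_per_direction) % n_f1]
            for g in range(2, generations + 2):
                pick = rng.integers(2, size=n)
                inherited = pair[pick, np.arange(n)]
                pair = np.stack([inherited, draw(q_rec)])
                rows.append((g, direction, lineage, pair.sum(axis=0).astype(np.int16)))

    return pd.DataFrame(rows, columns=["generation", "direction", "lineage", "genotype"])


# ---------------------------------------------------------------------------
# supervised maximum-likelihood q

def _q_loglik(q, g, pa, pb):
    p = q * pa + (1 - q) * pb
    return float(
        np.sum(g * np.log(np.clip(p, _EPS, None))
               + (2 - g) * np.log(np.clip(1 - p, _EPS, None)))
    )


def _fit_q(g, pa, pb, tol=1e-9):
    """Maximize the binomial mixture likelihood over q in [0, 1] (concave)."""
    res = minimize_scalar(
        lambda q: -_q_loglik(q, g, pa, pb),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": tol},
    )
    q = float(res.x)
    # bounded Brent keeps a small offset from the boundary; snap when the
    # boundary is at least as good
    for edge in (0.0, 1.0):
        if _q_loglik(edge, g, pa, pb) >= -res.fun:
            q = edge
    return q


class SupervisedAdmixture(BaseEstimator):
    """Supervised two-population admixture-proportion estimator.

    Fit on parental reference data (either an :class:`AllelePanel` or a
    genotype matrix plus two-level population labels); ``predict`` returns
    the maximum-likelihood proportion q of population-A ancestry per sample,
    treating SNPs as unlinked binomial draws from the mixed frequency
    q*p_A + (1-q)*p_B.  The log-likelihood is concave in q so the maximizer
    is unique whenever any SNP differentiates the panels.

    Parameters
    ----------
    tol : float
        Bracket tolerance of the bounded scalar maximization.

    Attributes
    ----------
    p_a_, p_b_ : ndarray
        Panel alt-allele frequencies per SNP.
    """

    def __init__(self, tol: float = 1e-9):
        self.tol = tol

    def fit(self, X, y=None):
        if isinstance(X, AllelePanel):
            self.p_a_, self.p_b_ = X.freqs(smoothing=0.0)
        else:
            geno = np.asarray(X)
            labels = np.asarray(y)
            levels = pd.unique(labels)
            if len(levels) != 2:
                raise ValueError("need exactly two population labels")
            out = []
            for lv in levels:
                g = geno[:, labels == lv]
                called = g >= 0
                out.append(np.where(called, g, 0).sum(axis=1) / np.maximum(2 * called.sum(axis=1), 1))
            self.p_a_, self.p_b_ = out
        if np.allclose(self.p_a_, self.p_b_):
            raise ValueError("panel is monomorphic everywhere; q is unidentifiable")
        return self

    def predict(self, X) -> np.ndarray:
        """q (population-A ancestry proportion) per sample; X is (n_snps, n_samples)."""
        geno = np.atleast_2d(np.asarray(X, dtype=float))
        if geno.shape[0] != self.p_a_.size and geno.shape[1] == self.p_a_.size:
            geno = geno.T
        if geno.shape[0] == 0:
            raise ValueError("need >= 1 SNP")
        qs = np.empty(geno.shape[1])
        for j in range(geno.shape[1]):
            g = geno[:, j]
            ok = g >= 0
            qs[j] = _fit_q(g[ok], self.p_a_[ok], self.p_b_[ok], tol=self.tol)
        return qs


class AdmixtureK2(BaseEstimator):
    """Unsupervised K=2 admixture by alternating EM over q and frequencies.

    Initialized from the supervised estimates against the provided panel;
    iterates ADMIXTURE-style EM updates of per-sample ancestry fractions and
    per-SNP population frequencies on the combined data until the
    log-likelihood improves by less than ``tol`` (default 1e-4) or
    ``max_iter`` is reached.  The EM log-likelihood is non-decreasing.

    Attributes
    ----------
    q_ : ndarray            fitted ancestry proportions per sample
    freqs_ : (2, n_snps)    fitted population alt frequencies
    loglik_path_ : list     log-likelihood per iteration
    """

    def __init__(self, panel: AllelePanel = None, max_iter: int = 500, tol: float = 1e-4):
        self.panel = panel
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _loglik(g, q, p1, p2):
        p = q[None, :] * p1[:, None] + (1 - q[None, :]) * p2[:, None]
        return float(np.sum(g * np.log(np.clip(p, _EPS, None))
                            + (2 - g) * np.log(np.clip(1 - p, _EPS, None))))

    def fit(self, X, y=None):
        g = np.asarray(X, dtype=float)  # (n_snps, n_samples), no missing
        if self.panel is None:
            raise ValueError("panel required for initialization")
        sup = SupervisedAdmixture().fit(self.panel)
        q = np.clip(sup.predict(g), 1e-3, 1 - 1e-3)
        p1 = np.clip(sup.p_a_.astype(float), 1e-3, 1 - 1e-3)
        p2 = np.clip(sup.p_b_.astype(float), 1e-3, 1 - 1e-3)
        ll = self._loglik(g, q, p1, p2)
        path = [ll]
        for _ in range(self.max_iter):
            mix_alt = q[None, :] * p1[:, None] + (1 - q[None, :]) * p2[:, None]
            mix_ref = q[None, :] * (1 - p1[:, None]) + (1 - q[None, :]) * (1 - p2[:, None])
            # responsibility of population 1 for alt / ref alleles
            a = q[None, :] * p1[:, None] / np.clip(mix_alt, _EPS, None)
            b = q[None, :] * (1 - p1[:, None]) / np.clip(mix_ref, _EPS, None)
            exp_alt1 = g * a            # expected pop-1 alt alleles per snp/sample
            exp_ref1 = (2 - g) * b
            exp_alt2 = g * (1 - a)
            exp_ref2 = (2 - g) * (1 - b)
            q = (exp_alt1.sum(axis=0) + exp_ref1.sum(axis=0)) / (2 * g.shape[0])
            p1 = exp_alt1.sum(axis=1) / np.clip((exp_alt1 + exp_ref1).sum(axis=1), _EPS, None)
            p2 = exp_alt2.sum(axis=1) / np.clip((exp_alt2 + exp_ref2).sum(axis=1), _EPS, None)
            q = np.clip(q, _EPS, 1 - _EPS)
            p1 = np.clip(p1, _EPS, 1 - _EPS)
            p2 = np.clip(p2, _EPS, 1 - _EPS)
            ll_new = self._loglik(g, q, p1, p2)
            path.append(ll_new)
            if ll_new - ll < self.tol:
                break
            ll = ll_new
        self.q_ = q
        self.freqs_ = np.stack([p1, p2])
        self.loglik_path_ = path
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).q_


def estimate_admixture(geno, panel: AllelePanel, mode: str = "supervised"):
    """q per sample for a (n_snps, n_samples) dosage matrix.

    ``mode`` is ``supervised`` (maximum likelihood against the panel
    frequencies) or ``unsupervised_K2`` (EM refinement of frequencies and q
    on the combined data, initialized from the supervised fit).
    """
    if mode == "supervised":
        return SupervisedAdmixture().fit(panel).predict(geno)
    if mode == "unsupervised_K2":
        return AdmixtureK2(panel=panel).fit_predict(np.asarray(geno, dtype=float))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# per-generation envelopes

def derive_envelopes(q_table: pd.DataFrame, pure_threshold: float = 0.95) -> pd.DataFrame:
    """Per-generation/direction assignment envelopes from simulated q values.

    ``q_table`` must have columns ``generation``, ``direction``, ``q`` where q
    is the proportion assigned to population A.  The envelope summarizes the
    *intraspecific* assignment toward the backcross parent (for direction B
    that is 1-q).  Returns mean/min/max per (generation, direction) plus a
    ``plateau`` flag marking the first generation whose whole envelope lies
    inside the pure bin (own-assignment >= ``pure_threshold``).
    """
    df = q_table.copy()
    df["own"] = np.where(df["direction"] == "B", 1.0 - df["q"], df["q"])
    env = (
        df.groupby(["direction", "generation"])["own"]
        .agg(["mean", "min", "max"])
        .reset_index()
        .sort_values(["direction", "generation"])
    )
    env["plateau"] = False
    for d, sub in env.groupby("direction"):
        hit = sub.index[sub["min"] >= pure_threshold]
        if len(hit):
            env.loc[hit[0], "plateau"] = True
    return env


# ---------------------------------------------------------------------------
# Table-1 style bins

@dataclass(frozen=True)
class HybridClass:
    """One assignment bin on the population-A proportion scale.

    The interval is (lo, hi) with inclusivity flags; bins for the two
    backcross directions are asymmetric, as derived from simulation.
    """

    label: str
    lo: float
    hi: float
    lo_inclusive: bool = False
    hi_inclusive: bool = True

    def contains(self, q: float) -> bool:
        above = q > self.lo or (self.lo_inclusive and q == self.lo)
        below = q < self.hi or (self.hi_inclusive and q == self.hi)
        return above and below


#: Default bins on q = proportion assigned to population A (black duck side).
#: Pure-A requires >= 95% own assignment while pure-B requires >= 98%
#: (interspecific <= 2%); the (0.27, 0.28] stretch is an explicit gap.
TABLE1_BINS = (
    HybridClass("PURE_A", 0.95, 1.00, lo_inclusive=True, hi_inclusive=True),
    HybridClass("F3_toward_A", 0.90, 0.95, lo_inclusive=True, hi_inclusive=False),
    HybridClass("F2_toward_A", 0.73, 0.90, lo_inclusive=True, hi_inclusive=False),
    HybridClass("F1", 0.28, 0.73, lo_inclusive=False, hi_inclusive=False),
    HybridClass("F2_toward_B", 0.02, 0.27, lo_inclusive=False, hi_inclusive=True),
    HybridClass("PURE_B", 0.00, 0.02, lo_inclusive=True, hi_inclusive=True),
)


def classify(q: float, bins=TABLE1_BINS) -> str:
    """Bin label for an ancestry proportion q in [0, 1].

    Values falling in none of the bins (the envelopes leave explicit gaps)
    are labelled ``UNASSIGNED``; the function is total on [0, 1].
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    for b in bins:
        if b.contains(q):
            return b.label
    return "UNASSIGNED"


class HybridBinClassifier(BaseEstimator):
    """sklearn-style wrapper assigning bin labels to q estimates."""

    def __init__(self, bins=TABLE1_BINS):
        self.bins = bins

    def fit(self, X=None, y=None):
        self.bins_ = tuple(self.bins)
        return self

    def predict(self, X):
        if not hasattr(self, "bins_"):
            self.fit()
        q = np.atleast_1d(np.asarray(X, dtype=float))
        return np.array([classify(v, self.bins_) for v in q])
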