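"""Two-way local-ancestry HMM with a prior-regularized hybrid age.

For one putative hybrid, the diploid ancestry state at each SNP is one of
{AA, AB, BB} (2, 1 or 0 chromosome copies of population-A ancestry).  The two
haplotypes are modelled as independent two-state Markov chains along the
chromosome, the standard well-mixed (pulse-admixture) approximation of
two-way local-ancestry HMMs: between SNPs separated by genetic distance d
Morgan a haplotype relaxes toward its stationary ancestry mix with factor
exp(-t d), where t is the hybrid age in generations (admixture t generations
back leaves ancestry blocks of scale ~1/t Morgan).  The stationary
minor-ancestry proportion is tied to t as 2**-t, the genome-wide expectation
under recurrent backcrossing; the backcross direction (which ancestry is the
minor one) is profiled alongside t.

The independence approximation cannot represent a literal F1, whose two
haplotypes are perfectly anti-correlated (all-heterozygous, zero junctions):
with strongly diagnostic markers the emissions still recover the F1 pattern,
but with weakly differentiated panels heterozygosity is under-detected and
spurious ancestry switches are called — a documented failure mode of this
model class on low-divergence data that downstream junction counting
inherits deliberately.

Emissions come from parental reference-panel allele counts with add-one
smoothing; the heterozygous state mixes one binomial draw from each
population.  The hybrid age maximizes the profile log-likelihood plus a
log Exponential prior (default mean 10 generations) over a fixed grid
t in {1, 1.1, ..., 50}, ties toward smaller t; per-SNP posteriors come from
forward-backward at the selected age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .synthetic import AllelePanel, MarkerMap

__all__ = [
    "PosteriorAncestry",
    "ReferencePanelSet",
    "LocalAncestryHMM",
    "infer_local_ancestry",
    "build_reference_panels",
]

STATES = ("AA", "AB", "BB")


@dataclass
class PosteriorAncestry:
    """Per-SNP diploid ancestry posteriors for one individual.

    ``table`` columns: chrom, pos_bp, pos_morgan, p_AA, p_AB, p_BB (rows sum
    to 1); ``t_hat`` is the prior-regularized hybrid age, ``direction`` the
    profiled recurrent parent ('A' or 'B'), ``loglik_by_chrom`` the
    per-chromosome log-likelihood at t_hat.
    """

    table: pd.DataFrame
    t_hat: float
    direction: str
    loglik_by_chrom: dict
    prior_mean: float
    n_skipped: int = 0

    @property
    def loglik(self) -> float:
        return float(sum(self.loglik_by_chrom.values()))

    def state_calls(self) -> pd.DataFrame:
        """Argmax ancestry state per SNP."""
        probs = self.table[["p_AA", "p_AB", "p_BB"]].to_numpy()
        out = self.table[["chrom", "pos_bp", "pos_morgan"]].copy()
        out["state"] = np.array(STATES)[np.argmax(probs, axis=1)]
        return out


@dataclass
class ReferencePanelSet:
    """Vetted parental allele-count panel with provenance.

    ``variant`` is 'default' (assignment-vetted individuals), 'pure'
    (individuals whose leave-one-out self-inference shows zero junctions on
    every chromosome) or 'one_recombination' (at most one recombined
    chromosome).  Counts are equalized: per SNP both populations contribute
    the same number of alleles (the larger population is subsampled without
    replacement).
    """

    variant: str
    panel: AllelePanel
    members_a: np.ndarray
    members_b: np.ndarray

    def __post_init__(self) -> None:
        ta, tb = self.panel.totals()
        if not np.array_equal(ta, tb):
            raise ValueError("panel counts are not equalized")


def _emission_matrix(geno: np.ndarray, qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """(n, 3) emission probabilities for one individual; missing -> 1s."""
    g = np.asarray(geno)
    e = np.empty((g.size, 3))
    paa = np.stack([(1 - qa) ** 2, 2 * qa * (1 - qa), qa**2], axis=1)
    pbb = np.stack([(1 - qb) ** 2, 2 * qb * (1 - qb), qb**2], axis=1)
    pab = np.stack(
        [(1 - qa) * (1 - qb), qa * (1 - qb) + qb * (1 - qa), qa * qb], axis=1
    )
    miss = g < 0
    gi = np.where(miss, 0, g)
    rows = np.arange(g.size)
    e[:, 0] = paa[rows, gi]
    e[:, 1] = pab[rows, gi]
    e[:, 2] = pbb[rows, gi]
    e[miss] = 1.0
    return e


def _diploid_transition(pi_b: float, r) -> np.ndarray:
    """Lumped 3-state transition matrix for scalar stationary and relaxation r.

    Per haplotype M = [[pi_a + pi_b r, pi_b (1-r)], [pi_a (1-r), pi_b + pi_a r]];
    the two independent haplotypes are lumped to dosage states (AA, AB, BB).
    """
    pi_a = 1.0 - pi_b
    m00 = pi_a + pi_b * r
    m01 = pi_b * (1 - r)
    m10 = pi_a * (1 - r)
    m11 = pi_b + pi_a * r
    return np.array(
        [
            [m00 * m00, 2 * m00 * m01, m01 * m01],
            [m00 * m10, m00 * m11 + m01 * m10, m01 * m11],
            [m10 * m10, 2 * m10 * m11, m11 * m11],
        ]
    )


def _transition_coeffs(pi_b: np.ndarray):
    """Quadratic-in-r coefficients (C0, C1, C2) of the lumped transition.

    Every entry of the lumped matrix is a quadratic polynomial in the
    relaxation factor r = exp(-(t-1) d); fitting at r in {0, 1/2, 1} recovers
    the coefficients exactly, per model in the batch.
    """
    G = pi_b.size
    t0 = np.empty((G, 3, 3))
    t1 = np.empty((G, 3, 3))
    th = np.empty((G, 3, 3))
    for g in range(G):
        t0[g] = _diploid_transition(pi_b[g], 0.0)
        t1[g] = _diploid_transition(pi_b[g], 1.0)
        th[g] = _diploid_transition(pi_b[g], 0.5)
    c1 = 4 * th - t1 - 3 * t0
    c2 = t1 - t0 - c1
    return t0, c1, c2


def _batched_forward_loglik(emissions, gaps, pi_b, lam):
    """Log-likelihood of one chromosome under a batch of models.

    emissions: (n, K, 3) for K individuals; gaps: (n-1,) Morgan distances;
    pi_b: (G,) stationary B proportions; lam: (G,) relaxation rates.
    Returns (G, K) log-likelihoods.
    """
    n, K, _ = emissions.shape
    G = pi_b.size
    pi_a = 1.0 - pi_b
    init = np.stack([pi_a**2, 2 * pi_a * pi_b, pi_b**2], axis=1)  # (G, 3)
    c0, c1, c2 = _transition_coeffs(pi_b)
    r_all = np.exp(-np.outer(lam, gaps))  # (G, n-1)

    alpha = init[:, None, :] * emissions[0][None, :, :]  # (G, K, 3)
    s = alpha.sum(axis=2)
    alpha /= s[:, :, None]
    ll = np.log(s)
    for i in range(1, n):
        r = r_all[:, i - 1][:, None, None]
        T = c0 + c1 * r + c2 * (r * r)
        alpha = np.einsum("gki,gij->gkj", alpha, T) * emissions[i][None, :, :]
        s = alpha.sum(axis=2)
        alpha /= s[:, :, None]
        ll += np.log(s)
    return ll


def _forward_backward(emissions, gaps, pi_b: float, lam: float):
    """Scaled forward-backward for a single model; returns (gamma, loglik)."""
    n = emissions.shape[0]
    pi_a = 1.0 - pi_b
    init = np.array([pi_a**2, 2 * pi_a * pi_b, pi_b**2])
    Ts = [_diploid_transition(pi_b, float(np.exp(-lam * d))) for d in gaps]

    alpha = np.empty((n, 3))
    scale = np.empty(n)
    a = init * emissions[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for i in range(1, n):
        a = (alpha[i - 1] @ Ts[i - 1]) * emissions[i]
        scale[i] = a.sum()
        alpha[i] = a / scale[i]

    beta = np.empty((n, 3))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta[i] = (Ts[i] @ (emissions[i + 1] * beta[i + 1])) / scale[i + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, float(np.sum(np.log(scale)))


class LocalAncestryHMM(BaseEstimator):
    """Local-ancestry inference with a prior-regularized hybrid age.

    Parameters
    ----------
    prior_mean : float
        Mean of the exponential prior on the hybrid age t (generations).
    t_max, t_step : float
        Age grid {1, 1+t_step, ..., t_max}; ties break toward smaller t.
    smoothing : float
        Add-x pseudocount on panel allele counts for the emissions.

    Attributes (after ``fit``)
    --------------------------
    q_a_, q_b_ : ndarray   smoothed panel alt frequencies over usable SNPs
    usable_ : ndarray      boolean mask of SNPs with nonzero panel counts
    marker_map_ : MarkerMap
    """

    def __init__(self, prior_mean: float = 10.0, t_max: float = 50.0,
                 t_step: float = 0.1, smoothing: float = 1.0):
        self.prior_mean = prior_mean
        self.t_max = t_max
        self.t_step = t_step
        self.smoothing = smoothing

    # -- fitting ----------------------------------------------------------
    def fit(self, panel, y=None, marker_map: MarkerMap | None = None):
        """Fit to a reference panel (AllelePanel or ReferencePanelSet)."""
        if isinstance(panel, ReferencePanelSet):
            panel = panel.panel
        if not isinstance(panel, AllelePanel):
            raise TypeError("panel must be an AllelePanel or ReferencePanelSet")
        self.marker_map_ = marker_map or panel.marker_map
        ta, tb = panel.totals()
        usable = (ta > 0) & (tb > 0)
        n_bad = int((~usable).sum())
        if n_bad:
            warnings.warn(f"skipping {n_bad} SNP(s) with zero panel counts")
        qa, qb = panel.freqs(smoothing=self.smoothing)
        self.usable_ = usable
        self.q_a_ = qa[usable]
        self.q_b_ = qb[usable]
        self._chrom_slices_ = self._slices()
        grid = np.arange(1.0, self.t_max + 1e-9, self.t_step)
        # direction A-recurrent (minor ancestry B), then B-recurrent
        self.t_grid_ = np.concatenate([grid, grid])
        self.dir_grid_ = np.array(["A"] * grid.size + ["B"] * grid.size)
        minor = 2.0 ** (-self.t_grid_)
        self.pi_b_grid_ = np.where(self.dir_grid_ == "A", minor, 1.0 - minor)
        self.lam_grid_ = self.t_grid_.copy()  # ancestry-switch intensity t*d
        return self

    def _slices(self):
        """Per-chromosome (slice into usable-SNP arrays, morgan positions)."""
        out = {}
        offset = 0
        u_offset = 0
        for chrom in self.marker_map_.chromosomes:
            n = self.marker_map_.positions_bp[chrom.name].size
            if n == 0:
                offset += n
                continue
            mask = self.usable_[offset:offset + n]
            n_use = int(mask.sum())
            pos_m = self.marker_map_.positions_morgan(chrom.name)[mask]
            pos_bp = self.marker_map_.positions_bp[chrom.name][mask]
            if n_use < 2:
                raise ValueError(
                    f"chromosome {chrom.name}: need >= 2 usable SNPs, have {n_use}"
                )
            out[chrom.name] = (slice(offset, offset + n), mask,
                               slice(u_offset, u_offset + n_use), pos_m, pos_bp)
            offset += n
            u_offset += n_use
        return out

    # -- inference --------------------------------------------------------
    def _log_prior(self):
        return -self.t_grid_ / self.prior_mean - np.log(self.prior_mean)

    def _emissions_for(self, geno_matrix):
        """Per-chromosome emission stacks for K individuals."""
        K = geno_matrix.shape[1]
        out = {}
        for chrom, (full_sl, mask, use_sl, pos_m, _) in self._chrom_slices_.items():
            g = geno_matrix[full_sl][mask]  # (n_use, K)
            qa = self.q_a_[use_sl]
            qb = self.q_b_[use_sl]
            e = np.empty((g.shape[0], K, 3))
            for k in range(K):
                e[:, k, :] = _emission_matrix(g[:, k], qa, qb)
            out[chrom] = (e, np.diff(pos_m))
        return out

    def profile(self, geno_matrix) -> dict:
        """Profile objective over the (t, direction) grid for K individuals.

        Returns dict with 'objective' (G, K), 'best' indices (K,), and the
        grid arrays.
        """
        geno_matrix = np.atleast_2d(np.asarray(geno_matrix))
        if geno_matrix.shape[0] != self.usable_.size:
            if geno_matrix.shape[1] == self.usable_.size:
                geno_matrix = geno_matrix.T
            else:
                raise ValueError("genotype matrix does not match the marker map")
        ems = self._emissions_for(geno_matrix)
        G = self.t_grid_.size
        ll = np.zeros((G, geno_matrix.shape[1]))
        for chrom, (e, gaps) in ems.items():
            ll += _batched_forward_loglik(e, gaps, self.pi_b_grid_, self.lam_grid_)
        objective = ll + self._log_prior()[:, None]
        # ties toward smaller t, direction A first: grid order is (A block
        # ascending t, B block ascending t); stable argmax after keying
        best = np.empty(geno_matrix.shape[1], dtype=int)
        order = np.lexsort((self.dir_grid_, self.t_grid_))
        for k in range(geno_matrix.shape[1]):
            obj = objective[:, k]
            top = obj[order].max()
            best[k] = order[np.nonzero(obj[order] >= top - 1e-12)[0][0]]
        return {"objective": objective, "loglik": ll, "best": best,
                "emissions": ems, "geno": geno_matrix}

    def infer(self, genotypes) -> "PosteriorAncestry | list[PosteriorAncestry]":
        """Posterior ancestry for one genotype vector or a (snp, sample) matrix."""
        single = np.asarray(genotypes).ndim == 1
        prof = self.profile(genotypes)
        out = []
        for k in range(prof["geno"].shape[1]):
            g_idx = prof["best"][k]
            t_hat = float(self.t_grid_[g_idx])
            direction = str(self.dir_grid_[g_idx])
            pi_b = float(self.pi_b_grid_[g_idx])
            lam = float(self.lam_grid_[g_idx])
            frames = []
            ll_by_chrom = {}
            for chrom, (e, gaps) in prof["emissions"].items():
                gamma, ll = _forward_backward(e[:, k, :], gaps, pi_b, lam)
                _, _, use_sl, pos_m, pos_bp = self._chrom_slices_[chrom]
                frames.append(pd.DataFrame({
                    "chrom": chrom, "pos_bp": pos_bp, "pos_morgan": pos_m,
                    "p_AA": gamma[:, 0], "p_AB": gamma[:, 1], "p_BB": gamma[:, 2],
                }))
                ll_by_chrom[chrom] = ll
            out.append(PosteriorAncestry(
                table=pd.concat(frames, ignore_index=True),
                t_hat=t_hat,
                direction=direction,
                loglik_by_chrom=ll_by_chrom,
                prior_mean=self.prior_mean,
                n_skipped=int((~self.usable_).sum()),
            ))
        return out[0] if single else out

    def predict(self, genotypes):
        """Argmax ancestry state per SNP ('AA'/'AB'/'BB'); single vector or matrix."""
        res = self.infer(genotypes)
        if isinstance(res, PosteriorAncestry):
            return res.state_calls()["state"].to_numpy()
        return np.stack([r.state_calls()["state"].to_numpy() for r in res], axis=1)


def infer_local_ancestry(genotypes, marker_map: MarkerMap, panels,
                         prior_mean_generations: float = 10.0,
                         **kwargs) -> PosteriorAncestry:
    """Functional surface over :class:`LocalAncestryHMM` for one individual."""
    model = LocalAncestryHMM(prior_mean=prior_mean_generations, **kwargs)
    model.fit(panels, marker_map=marker_map)
    return model.infer(genotypes)


# ---------------------------------------------------------------------------
# reference panel vetting

def _counts_from_members(geno, members):
    g = geno[:, members]
    called = g >= 0
    alt = np.where(called, g, 0).sum(axis=1).astype(np.int64)
    tot = (2 * called.sum(axis=1)).astype(np.int64)
    return tot - alt, alt


def build_reference_panels(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    marker_map: MarkerMap,
    q_a=None,
    q_b=None,
    variant: str = "default",
    assign_threshold: float = 0.99,
    windows_per_chrom: int = 20,
    prior_mean: float = 10.0,
    seed: int = 0,
) -> ReferencePanelSet:
    """Vet parental individuals into a reference panel of the given variant.

    ``q_a``/``q_b`` are per-individual population-A assignment proportions
    (from the admixture estimator); when omitted they are computed internally
    against the raw all-individual panel.  'default' keeps individuals with
    >= ``assign_threshold`` assignment to their own population; 'pure'
    additionally requires a leave-one-out self-inference (HMM + windowed
    junction calling) with zero junctions on all chromosomes;
    'one_recombination' allows at most one chromosome with junctions.
    Final counts are equalized per SNP across populations.
    """
    from .junctions import call_junctions  # local import; junctions sits above this module

    if variant not in ("default", "pure", "one_recombination"):
        raise ValueError(f"unknown panel variant {variant!r}")
    geno_a = np.asarray(geno_a)
    geno_b = np.asarray(geno_b)
    rng = np.random.default_rng(seed)

    if q_a is None or q_b is None:
        from .admixture import SupervisedAdmixture

        all_panel = AllelePanel(
            marker_map,
            *_counts_from_members(geno_a, np.arange(geno_a.shape[1])),
            *_counts_from_members(geno_b, np.arange(geno_b.shape[1])),
        )
        est = SupervisedAdmixture().fit(all_panel)
        q_a = est.predict(geno_a)
        q_b = est.predict(geno_b)

    members_a = np.nonzero(np.asarray(q_a) >= assign_threshold)[0]
    members_b = np.nonzero(np.asarray(q_b) <= 1.0 - assign_threshold)[0]
    if members_a.size == 0 or members_b.size == 0:
        raise ValueError(
            f"default-panel filter (assignment >= {assign_threshold}) left an empty panel"
        )

    if variant != "default":
        keep_a, keep_b = [], []
        for side, geno, members, out in (
            ("a", geno_a, members_a, keep_a),
            ("b", geno_b, members_b, keep_b),
        ):
            for idx in members:
                ref_a, alt_a = _counts_from_members(geno_a, members_a)
                ref_b, alt_b = _counts_from_members(geno_b, members_b)
                g = geno[:, idx]
                called = g >= 0
                if side == "a":
                    alt_a = alt_a - np.where(called, g, 0)
                    ref_a = ref_a - np.where(called, 2 - g, 0)
                else:
                    alt_b = alt_b - np.where(called, g, 0)
                    ref_b = ref_b - np.where(called, 2 - g, 0)
                loo = AllelePanel(marker_map, ref_a, alt_a, ref_b, alt_b)
                model = LocalAncestryHMM(prior_mean=prior_mean).fit(loo)
                post = model.infer(g)
                counts = call_junctions(post, windows_per_chrom=windows_per_chrom,
                                        marker_map=marker_map)
                n_recombined = sum(1 for v in counts.values() if v > 0)
                limit = 0 if variant == "pure" else 1
                if n_recombined <= limit:
                    out.append(idx)
        members_a = np.array(keep_a, dtype=int)
        members_b = np.array(keep_b, dtype=int)
        if members_a.size == 0 or members_b.size == 0:
            raise ValueError(f"panel variant {variant!r} left an empty panel")

    panel = AllelePanel(
        marker_map,
        *_counts_from_members(geno_a, members_a),
        *_counts_from_members(geno_b, members_b),
    ).equalized(rng)
    return ReferencePanelSet(variant=variant, panel=panel,
                             members_a=members_a, members_b=members_b)
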