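"""Junction counting and generation assignment by AIC weights.

Junctions are called from posterior local ancestry by windowing: each
chromosome is split into equal-Morgan non-overlapping windows (20 per
chromosome by default), the window state is the argmax of the mean posterior
over its SNPs, empty windows inherit the previous non-empty window's state,
and adjacent state changes are counted as junctions.

There is no analytic distribution for the number of windowed junctions after
t generations, so P(j | t, L) is tabulated from pedigree simulations (1,000
replicates per generation by default), using exactly the same windowed
counting on the true ancestry dosage.  The full likelihood of an individual
is the product over chromosomes of P(j_chrom | t, L_chrom); each candidate
generation gets AIC = 2*1 - 2 log P(t) (one degree of freedom) and the
relative support is its AIC weight exp(-delta_t/2) / sum exp(-delta/2).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import pedigree
from .ancestry import PosteriorAncestry
from .pedigree import SchemeSpec, windowed_true_junctions
from .synthetic import MarkerMap

__all__ = [
    "JunctionLikelihoodTable",
    "GenerationAssignment",
    "call_junctions",
    "build_table",
    "assign_generation",
    "GenerationClassifier",
]


# ---------------------------------------------------------------------------
# junction calling from posteriors

def call_junctions(posterior: PosteriorAncestry, windows_per_chrom: int = 20,
                   marker_map=None) -> dict:
    """Windowed junction counts per chromosome from posterior ancestry.

    ``marker_map`` (a MarkerMap or {chrom: Morgan length} dict) provides the
    chromosome lengths defining the equal-Morgan windows.  Chromosomes with
    no SNPs in the posterior are omitted with a warning.
    """
    lengths = pedigree.chrom_lengths(marker_map)
    counts = {}
    tbl = posterior.table
    for chrom, L in lengths.items():
        sub = tbl[tbl["chrom"] == chrom]
        if len(sub) == 0:
            warnings.warn(f"chromosome {chrom}: no SNPs with posteriors; omitted")
            continue
        w = np.clip(
            (sub["pos_morgan"].to_numpy() / L * windows_per_chrom).astype(int),
            0, windows_per_chrom - 1,
        )
        probs = sub[["p_AA", "p_AB", "p_BB"]].to_numpy()
        states = np.full(windows_per_chrom, -1)
        for win in range(windows_per_chrom):
            sel = w == win
            if sel.any():
                states[win] = int(np.argmax(probs[sel].mean(axis=0)))
        # empty windows inherit the previous non-empty state; leading empties
        # take the first non-empty state
        first = states[states >= 0][0]
        prev = first
        for win in range(windows_per_chrom):
            if states[win] < 0:
                states[win] = prev
            prev = states[win]
        counts[chrom] = int(np.sum(states[1:] != states[:-1]))
    return counts


# ---------------------------------------------------------------------------
# simulation-approximated likelihood tables

@dataclass
class JunctionLikelihoodTable:
    """Monte-Carlo estimate of P(j junctions | generation t) for one chromosome.

    ``counts[t-1, j]`` is the number of simulated replicates of generation t
    showing j windowed junctions; ``probs`` are the observed frequencies
    (each row sums to 1) and ``se`` their binomial standard errors.  Zero
    cells are NOT floored here; flooring happens at likelihood evaluation.
    """

    scheme: str
    length_morgan: float
    windows: int
    replicates: int
    seed: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def t_max(self) -> int:
        return self.counts.shape[0]

    @property
    def j_max(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def probs(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / totals

    @property
    def se(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        p = self.probs
        return np.sqrt(p * (1 - p) / totals)

    @property
    def floor(self) -> float:
        return 1.0 / (10.0 * self.replicates)

    def prob(self, j: int, t: int, floored: bool = True) -> float:
        """P(j | t); unobserved counts within support get the floor value,
        counts beyond the simulated support get 0."""
        if not 1 <= t <= self.t_max:
            raise ValueError(f"t={t} outside table range 1..{self.t_max}")
        if j < 0:
            raise ValueError("j must be >= 0")
        if j > self.j_max:
            return 0.0
        p = self.probs[t - 1, j]
        if p == 0.0 and floored:
            return self.floor
        return float(p)

    def to_frame(self) -> pd.DataFrame:
        p, se = self.probs, self.se
        rows = [
            (t + 1, j, p[t, j], se[t, j])
            for t in range(self.t_max)
            for j in range(self.j_max + 1)
        ]
        return pd.DataFrame(rows, columns=["t", "j", "probability", "se"])


def _cache_path(cache_dir, scheme, L, windows, replicates, t_max, seed, swarm_size):
    key = json.dumps(
        dict(scheme=scheme, L=L, windows=windows, replicates=replicates,
             t_max=t_max, seed=seed, swarm_size=swarm_size),
        sort_keys=True,
    )
    digest = hashlib.sha256(key.encode()).hexdigest()[:16]
    return Path(cache_dir) / f"junction_table_{digest}.npz"


def build_table(
    scheme: str,
    L: float,
    replicates: int = 1000,
    t_max: int = 10,
    windows: int = 20,
    seed: int = 0,
    swarm_size: int = 100,
    cache_dir=None,
) -> JunctionLikelihoodTable:
    """Tabulate P(j | t, L) by simulating pedigrees on one chromosome.

    Backcross: ``replicates`` independent lineages followed from F1 to
    generation ``t_max``.  Hybrid swarm: populations of ``swarm_size``
    diploids run for ``t_max - 1`` mating rounds, enough populations to give
    at least ``replicates`` sampled individuals per generation (the founder
    cohort is hybrid age t=1).  Windowed diploid junction counts use the
    same definition as :func:`call_junctions`.  When ``cache_dir`` is given,
    the count matrix is cached keyed by all parameters.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    path = None
    if cache_dir is not None:
        path = _cache_path(cache_dir, scheme, L, windows, replicates, t_max, seed, swarm_size)
        if path.exists():
            counts = np.load(path)["counts"]
            return JunctionLikelihoodTable(scheme, L, windows, replicates, seed, counts)

    lengths = {"chrom": float(L)}
    per_t: list[list[int]] = [[] for _ in range(t_max)]
    if scheme == "backcross":
        spec = SchemeSpec(scheme="backcross", generations=t_max,
                          replicates=replicates, seed=seed)
        for lineage in pedigree.simulate_backcross(spec, lengths):
            for t, genome in enumerate(lineage, start=1):
                per_t[t - 1].append(windowed_true_junctions(genome, windows)["chrom"])
    elif scheme == "hybrid_swarm":
        n_pops = int(np.ceil(replicates / swarm_size))
        spec = SchemeSpec(scheme="hybrid_swarm", swarm_size=swarm_size,
                          generations=t_max - 1, replicates=n_pops, seed=seed)
        for pops in pedigree.simulate_swarm(spec, lengths):
            for g, cohort in enumerate(pops):  # t = g + 1
                if g + 1 > t_max:
                    break
                for genome in cohort:
                    per_t[g].append(windowed_true_junctions(genome, windows)["chrom"])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    j_max = max(max(v) for v in per_t)
    counts = np.zeros((t_max, j_max + 1), dtype=np.int64)
    for t_idx, vals in enumerate(per_t):
        for j in vals:
            counts[t_idx, j] += 1
    table = JunctionLikelihoodTable(scheme, L, windows, replicates, seed, counts)
    if path is not None:
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, counts=counts)
    return table


# ---------------------------------------------------------------------------
# AIC-weight generation assignment

@dataclass
class GenerationAssignment:
    """Per-candidate-generation support for one individual.

    ``table`` columns: t, loglik, aic, weight.  ``best_t`` is the candidate
    with the highest AIC weight (ties toward smaller t); ``ambiguous`` is set
    when the top two weights differ by less than 0.1; ``used_floor`` when any
    evaluated likelihood fell back to the unobserved-count floor.
    """

    table: pd.DataFrame
    best_t: int
    ambiguous: bool
    used_floor: bool

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


def assign_generation(counts: dict, tables: dict) -> GenerationAssignment:
    """Combine per-chromosome junction counts into a generation assignment.

    ``counts`` maps chromosome name -> observed junction count; ``tables``
    maps the same chromosomes to :class:`JunctionLikelihoodTable` objects.
    The log-likelihood of candidate t is the sum of log P(j_chrom | t) over
    chromosomes.  Raises if every candidate has zero likelihood (some count
    lies beyond the simulated support for all t).
    """
    if set(counts) != set(tables):
        raise ValueError("counts and tables must cover the same chromosomes")
    t_max = min(tb.t_max for tb in tables.values())
    loglik = np.zeros(t_max)
    used_floor = False
    for t in range(1, t_max + 1):
        ll = 0.0
        for chrom, j in counts.items():
            tb = tables[chrom]
            p = tb.prob(j, t, floored=True)
            if p == 0.0:
                ll = -np.inf
                break
            if tb.probs[t - 1, j] == 0.0:
                used_floor = True
            ll += np.log(p)
        loglik[t - 1] = ll
    if not np.any(np.isfinite(loglik)):
        raise ValueError("counts outside simulated support")
    aic = 2.0 * 1 - 2.0 * loglik
    delta = aic - np.nanmin(aic[np.isfinite(aic)])
    w = np.where(np.isfinite(delta), np.exp(-delta / 2.0), 0.0)
    w = w / w.sum()
    best = int(np.argmax(w)) + 1  # argmax takes the first (smallest t) on ties
    top2 = np.sort(w)[-2:] if w.size > 1 else np.array([0.0, w[0]])
    return GenerationAssignment(
        table=pd.DataFrame({"t": np.arange(1, t_max + 1), "loglik": loglik,
                            "aic": aic, "weight": w}),
        best_t=best,
        ambiguous=bool(top2[1] - top2[0] < 0.1),
        used_floor=used_floor,
    )


class GenerationClassifier(BaseEstimator):
    """Junction-count-based hybrid generation classifier.

    ``fit`` builds (or loads from cache) the Monte-Carlo junction likelihood
    tables for every chromosome; ``predict`` maps per-chromosome junction
    counts to the max-AIC-weight generation and ``predict_proba`` to the full
    AIC weight vectors.

    Parameters
    ----------
    chrom_lengths : dict
        Chromosome name -> genetic length in Morgan.
    scheme : 'backcross' or 'hybrid_swarm'
    replicates, t_max, windows, seed, swarm_size, cache_dir :
        Passed to :func:`build_table`.

    Attributes
    ----------
    tables_ : dict of chromosome -> JunctionLikelihoodTable
    classes_ : ndarray of candidate generations 1..t_max
    """

    def __init__(self, chrom_lengths=None, scheme: str = "backcross",
                 replicates: int = 1000, t_max: int = 10, windows: int = 20,
                 seed: int = 0, swarm_size: int = 100, cache_dir=None):
        self.chrom_lengths = chrom_lengths
        self.scheme = scheme
        self.replicates = replicates
        self.t_max = t_max
        self.windows = windows
        self.seed = seed
        self.swarm_size = swarm_size
        self.cache_dir = cache_dir

    def fit(self, X=None, y=None):
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths is required")
        lengths = pedigree.chrom_lengths(self.chrom_lengths)
        ss = np.random.SeedSequence(self.seed).spawn(len(lengths))
        self.tables_ = {}
        for (chrom, L), sub in zip(lengths.items(), ss):
            self.tables_[chrom] = build_table(
                self.scheme, L, replicates=self.replicates, t_max=self.t_max,
                windows=self.windows, seed=int(sub.generate_state(1)[0] % (2**31)),
                swarm_size=self.swarm_size, cache_dir=self.cache_dir,
            )
        self.classes_ = np.arange(1, self.t_max + 1)
        return self

    def _as_count_dicts(self, X):
        if isinstance(X, dict):
            return [X]
        if isinstance(X, pd.DataFrame):
            return [row.to_dict() for _, row in X.iterrows()]
        raise TypeError("X must be a counts dict or a DataFrame of counts")

    def assign(self, counts: dict) -> GenerationAssignment:
        return assign_generation(counts, self.tables_)

    def predict(self, X) -> np.ndarray:
        return np.array([self.assign(c).best_t for c in self._as_count_dicts(X)])

    def predict_proba(self, X) -> np.ndarray:
        return np.stack([self.assign(c).weights for c in self._as_count_dicts(X)])
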