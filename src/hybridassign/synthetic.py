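"""Synthetic marker maps, parental allele panels, and parental genotypes.

Emulates a sparse ddRAD-like SNP panel for a pair of weakly differentiated
populations (composite Hudson FST of order 0.01), optionally spiked with a
fraction of strongly diagnostic SNPs, so the whole inference pipeline can be
exercised without any external data.

Frequencies follow a symmetric divergence model: a common ancestral allele
frequency is drawn from a U-shaped Beta(0.5, 0.5) distribution and each
population's frequency is a Balding-Nichols perturbation around it with
differentiation parameter equal to the target FST.  Genotypes are binomial
draws per diploid individual; panel allele counts are tallied from genotypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Chromosome",
    "MarkerMap",
    "PanelSpec",
    "AllelePanel",
    "DUCK_CHROM_MORGAN",
    "make_marker_map",
    "simulate_panels",
]

#: Genetic lengths (Morgan) of the seven largest chromosomes used throughout,
#: in chromosome order 1-7.
DUCK_CHROM_MORGAN = (3.17, 2.26, 1.12, 0.93, 0.79, 1.20, 0.98)

#: Physical lengths (bp) paired with the defaults above; chosen so marker
#: density at ~450 SNPs per chromosome is one per a few hundred kbp.
DUCK_CHROM_BP = (
    200_000_000,
    150_000_000,
    110_000_000,
    70_000_000,
    60_000_000,
    80_000_000,
    75_000_000,
)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_morgan: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be positive")
        if self.length_morgan <= 0:
            raise ValueError(f"chromosome {self.name}: length_morgan must be positive")


@dataclass
class MarkerMap:
    """SNP positions on a set of chromosomes, in bp and Morgan coordinates.

    bp positions are 1-based and strictly increasing within a chromosome;
    the Morgan coordinate of a SNP is ``bp / length_bp * length_morgan``
    (uniform recombination rate along each chromosome).
    """

    chromosomes: list[Chromosome]
    positions_bp: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if set(self.positions_bp) - set(names):
            raise ValueError("positions for unknown chromosome")
        for chrom in self.chromosomes:
            pos = np.asarray(self.positions_bp.get(chrom.name, ()), dtype=np.int64)
            self.positions_bp[chrom.name] = pos
            if pos.size == 0:
                continue
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom.name}: bp positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > chrom.length_bp:
                raise ValueError(f"{chrom.name}: bp positions outside [1, length_bp]")

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_snps(self) -> int:
        return sum(p.size for p in self.positions_bp.values())

    @property
    def total_morgan(self) -> float:
        return float(sum(c.length_morgan for c in self.chromosomes))

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def positions_morgan(self, name: str) -> np.ndarray:
        c = self.chromosome(name)
        return self.positions_bp[name] / c.length_bp * c.length_morgan

    def snp_table(self):
        """Flat (chrom, pos_bp, pos_morgan) table in map order."""
        import pandas as pd

        rows = []
        for c in self.chromosomes:
            bp = self.positions_bp[c.name]
            cm = self.positions_morgan(c.name)
            for b, m in zip(bp, cm):
                rows.append((c.name, int(b), float(m)))
        return pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_morgan"])


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of the two-population panel simulation."""

    n_pop_a: int = 82
    n_pop_b: int = 65
    target_fst: float = 0.01
    diag_fraction: float = 0.0
    diag_delta: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop_a < 2 or self.n_pop_b < 2:
            raise ValueError("panel sizes must be >= 2 diploids")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must lie in [0, 1)")
        for name in ("diag_fraction", "diag_delta", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class AllelePanel:
    """Per-SNP (ref, alt) allele counts for each parental population.

    Arrays are aligned with the flattened SNP order of the marker map
    (chromosome order, then position order).
    """

    marker_map: MarkerMap
    ref_a: np.ndarray
    alt_a: np.ndarray
    ref_b: np.ndarray
    alt_b: np.ndarray

    def __post_init__(self) -> None:
        n = self.marker_map.n_snps
        for name in ("ref_a", "alt_a", "ref_b", "alt_b"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name}: expected shape ({n},), got {arr.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name}: counts must be non-negative")

    @property
    def n_snps(self) -> int:
        return self.marker_map.n_snps

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        return self.ref_a + self.alt_a, self.ref_b + self.alt_b

    def freqs(self, smoothing: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele frequencies per population, optionally smoothed.

        ``smoothing`` is an add-x pseudocount on both alleles (x=1 gives the
        add-one posterior mean used by the ancestry HMM emissions).
        """
        ta, tb = self.totals()
        qa = (self.alt_a + smoothing) / np.maximum(ta + 2 * smoothing, 1e-300)
        qb = (self.alt_b + smoothing) / np.maximum(tb + 2 * smoothing, 1e-300)
        return qa, qb

    def equalized(self, rng: np.random.Generator) -> "AllelePanel":
        """Per-SNP subsample of the larger population down to equal totals.

        Alleles are drawn without replacement (hypergeometric) from the more
        frequent population so both populations contribute the same number of
        alleles at every SNP.
        """
        ta, tb = self.totals()
        target = np.minimum(ta, tb)
        out = {}
        for tag, ref, alt, tot in (("a", self.ref_a, self.alt_a, ta),
                                   ("b", self.ref_b, self.alt_b, tb)):
            new_alt = alt.copy()
            shrink = tot > target
            if np.any(shrink):
                new_alt[shrink] = rng.hypergeometric(
                    alt[shrink], ref[shrink], target[shrink]
                )
            out["alt_" + tag] = new_alt
            out["ref_" + tag] = target - new_alt
        return dataclasses.replace(self, **out)


def make_marker_map(
    n_snps_per_chrom,
    chrom_lengths_bp=DUCK_CHROM_BP,
    chrom_lengths_morgan=DUCK_CHROM_MORGAN,
    seed: int = 0,
    names=None,
) -> MarkerMap:
    """Draw SNP positions uniformly without replacement on each chromosome.

    ``n_snps_per_chrom`` is either one integer applied to every chromosome or
    a sequence with one entry per chromosome.
    """
    chrom_lengths_bp = list(chrom_lengths_bp)
    chrom_lengths_morgan = list(chrom_lengths_morgan)
    if len(chrom_lengths_bp) != len(chrom_lengths_morgan):
        raise ValueError("bp and Morgan length lists differ in length")
    k = len(chrom_lengths_bp)
    if names is None:
        names = [f"chr{i + 1}" for i in range(k)]
    if np.isscalar(n_snps_per_chrom):
        n_snps_per_chrom = [int(n_snps_per_chrom)] * k
    n_snps_per_chrom = [int(n) for n in n_snps_per_chrom]
    if len(n_snps_per_chrom) != k:
        raise ValueError("n_snps_per_chrom length does not match chromosomes")

    rng = np.random.default_rng(seed)
    chroms, positions = [], {}
    for name, bp, morgan, n in zip(names, chrom_lengths_bp, chrom_lengths_morgan, n_snps_per_chrom):
        if n < 1:
            raise ValueError(f"{name}: need at least one SNP")
        if n > bp:
            raise ValueError(f"{name}: requested {n} SNPs but only {bp} bp positions")
        chroms.append(Chromosome(name, int(bp), float(morgan)))
        pos = rng.choice(int(bp), size=n, replace=False) + 1  # 1-based
        positions[name] = np.sort(pos).astype(np.int64)
    return MarkerMap(chroms, positions)


def _population_freqs(n_snps: int, spec: PanelSpec, rng: np.random.Generator):
    """Alt-allele frequencies (q_a, q_b) under the divergence model."""
    # ancestral frequency: U-shaped, mimicking a site-frequency-spectrum-rich
    # SNP ascertainment; clipped away from 0/1 so Balding-Nichols shapes exist
    anc = rng.beta(0.5, 0.5, size=n_snps)
    anc = np.clip(anc, 0.02, 0.98)
    f = spec.target_fst
    if f <= 0.0:
        qa = anc.copy()
        qb = anc.copy()
    else:
        shape = (1.0 - f) / f
        qa = rng.beta(anc * shape, (1.0 - anc) * shape)
        qb = rng.beta(anc * shape, (1.0 - anc) * shape)

    n_diag = int(round(spec.diag_fraction * n_snps))
    if n_diag > 0:
        idx = rng.choice(n_snps, size=n_diag, replace=False)
        # which population carries the alt allele alternates at random
        flip = rng.random(n_diag) < 0.5
        hi = (1.0 + spec.diag_delta) / 2.0
        lo = (1.0 - spec.diag_delta) / 2.0
        qa[idx] = np.where(flip, hi, lo)
        qb[idx] = np.where(flip, lo, hi)
    return qa, qb


def simulate_panels(marker_map: MarkerMap, spec: PanelSpec):
    """Simulate parental genotypes and tally them into an allele panel.

    Returns ``(panel, genotypes_a, genotypes_b, true_freqs)`` where genotype
    matrices have shape (n_snps, n_individuals) holding 0/1/2 alt-allele
    dosages (-1 for missing calls) and ``true_freqs`` is the (q_a, q_b) pair
    of generating frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    n = marker_map.n_snps
    qa, qb = _population_freqs(n, spec, rng)

    geno = {}
    for tag, q, size in (("a", qa, spec.n_pop_a), ("b", qb, spec.n_pop_b)):
        g = rng.binomial(2, q[:, None], size=(n, size)).astype(np.int16)
        if spec.missing_rate > 0.0:
            miss = rng.random(g.shape) < spec.missing_rate
            g[miss] = -1
        geno[tag] = g

    counts = {}
    for tag in ("a", "b"):
        g = geno[tag]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        tot = 2 * called.sum(axis=1)
        counts["alt_" + tag] = alt.astype(np.int64)
        counts["ref_" + tag] = (tot - alt).astype(np.int64)

    panel = AllelePanel(marker_map, counts["ref_a"], counts["alt_a"],
                        counts["ref_b"], counts["alt_b"])
    return panel, geno["a"], geno["b"], (qa, qb)
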