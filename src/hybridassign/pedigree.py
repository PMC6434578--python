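"""Recombining-pedigree simulation with explicit ancestry tracts.

Individuals are diploid; each haplotype of each chromosome is a list of
maximal ancestry tracts labelled by parental origin (A or B).  Crossovers are
Poisson with no interference (one draw per chromosome per meiosis, expected
number equal to the genetic length in Morgan), so a junction — a boundary
between tracts of different origin — is formed whenever a crossover falls at
a site heterogenic for ancestry.

Two mating schemes are provided:

* ``backcross``: F1 = one pure-A plus one pure-B haplotype; each following
  generation is a gamete of the previous hybrid mated to the pure recurrent
  parent.  Expected ancestry heterozygosity at generation t is 2**-(t-1) and
  the expected recurrent-parent genome fraction is 1 - 2**-t, independent of
  any population size.
* ``hybrid_swarm``: a closed, randomly mating population of N diploids whose
  founder haplotypes are pure A or pure B with probability 1/2 each
  (Hardy-Weinberg start); expected heterozygosity of first-generation
  offspring is 0.5 and decays by the factor (1 - 1/(2N)) per generation.

Generation labels follow t=1 for the F1; F(k) has k-1 further meioses
behind it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import AllelePanel, MarkerMap

__all__ = [
    "Haplotype",
    "AncestryGenome",
    "SchemeSpec",
    "JunctionCounts",
    "make_gamete",
    "meiosis",
    "simulate_backcross",
    "simulate_swarm",
    "true_junctions",
    "windowed_true_junctions",
    "ancestry_heterozygosity",
    "origin_fraction",
    "expected_stats",
    "artificial_genotype",
    "dosage_profile",
]

ORIGIN_A = 0
ORIGIN_B = 1
_ORIGIN_CODE = {"A": ORIGIN_A, "B": ORIGIN_B}


@dataclass
class Haplotype:
    """Ancestry tracts of one chromosome copy.

    ``breaks[i]`` is the start (Morgan) of tract i; tract i ends at
    ``breaks[i+1]`` (or at ``length`` for the last tract).  ``origins[i]`` is
    0 for ancestry A, 1 for ancestry B.  Tracts are maximal: adjacent origins
    differ.  The tract list tiles [0, length] exactly.
    """

    breaks: np.ndarray
    origins: np.ndarray
    length: float

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.origins = np.asarray(self.origins, dtype=np.int8)
        if self.breaks.size != self.origins.size or self.breaks.size == 0:
            raise ValueError("breaks and origins must be equal-length, non-empty")
        if self.breaks[0] != 0.0:
            raise ValueError("first tract must start at 0")
        if np.any(np.diff(self.breaks) <= 0) or (self.breaks.size > 1 and self.breaks[-1] >= self.length):
            raise ValueError("tract starts must be strictly increasing inside [0, L)")
        if np.any(self.origins[1:] == self.origins[:-1]):
            raise ValueError("tracts must be maximal (adjacent origins differ)")

    @classmethod
    def pure(cls, origin, length: float) -> "Haplotype":
        code = _ORIGIN_CODE.get(origin, origin)
        return cls(np.zeros(1), np.array([code], dtype=np.int8), float(length))

    @property
    def n_junctions(self) -> int:
        return self.breaks.size - 1

    def origin_at(self, pos_morgan) -> np.ndarray:
        """Ancestry origin at the given Morgan position(s)."""
        pos = np.asarray(pos_morgan, dtype=float)
        if np.any(pos < 0) or np.any(pos > self.length):
            raise ValueError("position outside [0, L]")
        idx = np.searchsorted(self.breaks, pos, side="right") - 1
        return self.origins[idx]

    def origin_length(self, code: int) -> float:
        ends = np.append(self.breaks[1:], self.length)
        return float(np.sum((ends - self.breaks)[self.origins == code]))


def _merge(breaks: np.ndarray, origins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero-length tracts and merge adjacent same-origin tracts."""
    keep = np.ones(len(breaks), dtype=bool)
    keep[1:] = origins[1:] != origins[:-1]
    return breaks[keep], origins[keep]


@dataclass
class AncestryGenome:
    """Diploid individual: two tract haplotypes per chromosome."""

    haplotypes: dict  # chrom name -> (Haplotype, Haplotype)
    generation: int = 1

    @classmethod
    def f1(cls, lengths: dict) -> "AncestryGenome":
        return cls(
            {c: (Haplotype.pure("A", L), Haplotype.pure("B", L)) for c, L in lengths.items()},
            generation=1,
        )

    @classmethod
    def pure(cls, origin, lengths: dict, generation: int = 1) -> "AncestryGenome":
        return cls(
            {c: (Haplotype.pure(origin, L), Haplotype.pure(origin, L)) for c, L in lengths.items()},
            generation=generation,
        )

    @property
    def chrom_names(self) -> list:
        return list(self.haplotypes)

    def length(self, chrom) -> float:
        return self.haplotypes[chrom][0].length


def chrom_lengths(source) -> dict:
    """Normalize a MarkerMap or {name: Morgan length} mapping to a dict."""
    if isinstance(source, MarkerMap):
        return {c.name: c.length_morgan for c in source.chromosomes}
    return dict(source)


def meiosis(hap0: Haplotype, hap1: Haplotype, rng: np.random.Generator) -> Haplotype:
    """One gamete for one chromosome: Poisson(L) crossovers, uniform positions.

    The gamete starts on a uniformly chosen haplotype and switches source at
    every crossover; the returned tract list is normalized (zero-length tracts
    dropped, adjacent same-origin tracts merged).  A degenerate chromosome of
    length 0 is not supported by Haplotype; L=0 is treated upstream.
    """
    L = hap0.length
    n_x = rng.poisson(L)
    source = (hap0, hap1)
    phase = int(rng.integers(2))
    if n_x == 0:
        h = source[phase]
        return Haplotype(h.breaks.copy(), h.origins.copy(), L)
    xpos = np.sort(rng.uniform(0.0, L, size=n_x))
    bounds = np.concatenate(([0.0], xpos, [L]))
    parts_b, parts_o = [], []
    for i in range(n_x + 1):
        a, b = bounds[i], bounds[i + 1]
        if a == b:
            continue
        h = source[(phase + i) % 2]
        i0 = np.searchsorted(h.breaks, a, side="right") - 1
        i1 = np.searchsorted(h.breaks, b, side="left")
        parts_b.append(np.concatenate(([a], h.breaks[i0 + 1:i1])))
        parts_o.append(h.origins[i0:i1])
    breaks, origins = _merge(np.concatenate(parts_b), np.concatenate(parts_o))
    return Haplotype(breaks, origins, L)


def make_gamete(parent: AncestryGenome, chrom, rng: np.random.Generator) -> Haplotype:
    """Gamete haplotype for one chromosome of a diploid parent."""
    h0, h1 = parent.haplotypes[chrom]
    return meiosis(h0, h1, rng)


def _offspring(p1: AncestryGenome, p2: AncestryGenome, rng, generation: int) -> AncestryGenome:
    haps = {}
    for chrom in p1.haplotypes:
        haps[chrom] = (make_gamete(p1, chrom, rng), make_gamete(p2, chrom, rng))
    return AncestryGenome(haps, generation=generation)


@dataclass(frozen=True)
class SchemeSpec:
    """Mating-scheme parameters for pedigree simulation."""

    scheme: str = "backcross"
    recurrent_parent: str = "A"
    swarm_size: int = 100
    generations: int = 10
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("backcross", "hybrid_swarm"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.scheme == "hybrid_swarm" and self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.recurrent_parent not in ("A", "B"):
            raise ValueError("recurrent_parent must be 'A' or 'B'")


def simulate_backcross(spec: SchemeSpec, marker_map) -> list:
    """Recurrent backcross lineages.

    Returns ``lineages[replicate][k]`` = the generation-(k+1) hybrid
    (index 0 is the F1; generation t has had t-1 backcross meioses).
    """
    if spec.scheme != "backcross":
        raise ValueError("spec.scheme must be 'backcross'")
    lengths = chrom_lengths(marker_map)
    parent_pure = AncestryGenome.pure(spec.recurrent_parent, lengths)
    rec_code = _ORIGIN_CODE[spec.recurrent_parent]
    out = []
    for ss in np.random.SeedSequence(spec.seed).spawn(spec.replicates):
        rng = np.random.default_rng(ss)
        lineage = [AncestryGenome.f1(lengths)]
        for t in range(2, spec.generations + 1):
            haps = {}
            for chrom, L in lengths.items():
                haps[chrom] = (
                    make_gamete(lineage[-1], chrom, rng),
                    Haplotype.pure(rec_code, L),
                )
            lineage.append(AncestryGenome(haps, generation=t))
        out.append(lineage)
    return out


def simulate_swarm(spec: SchemeSpec, marker_map) -> list:
    """Closed randomly mating hybrid swarm.

    Returns ``reps[replicate][g]`` = list of N genomes after g rounds of
    random mating (selfing excluded).  The g=0 cohort holds the founders:
    each haplotype independently pure A or pure B with probability 1/2, the
    Hardy-Weinberg cohort of offspring of randomly mating pure ancestors, so
    it carries hybrid-age label t=1 (expected ancestry heterozygosity 0.5,
    no junctions).  The cohort after g mating rounds carries ``generation =
    g + 1``; its expected heterozygosity is 0.5 * (1 - 1/(2N))**g.
    """
    if spec.scheme != "hybrid_swarm":
        raise ValueError("spec.scheme must be 'hybrid_swarm'")
    lengths = chrom_lengths(marker_map)
    N = spec.swarm_size
    out = []
    for ss in np.random.SeedSequence(spec.seed).spawn(spec.replicates):
        rng = np.random.default_rng(ss)
        founders = []
        for _ in range(N):
            haps = {
                c: (
                    Haplotype.pure(int(rng.integers(2)), L),
                    Haplotype.pure(int(rng.integers(2)), L),
                )
                for c, L in lengths.items()
            }
            founders.append(AncestryGenome(haps, generation=1))
        gens = [founders]
        for g in range(1, spec.generations + 1):
            prev = gens[-1]
            kids = []
            for _ in range(N):
                i = int(rng.integers(N))
                j = int(rng.integers(N - 1))
                if j >= i:
                    j += 1
                kids.append(_offspring(prev[i], prev[j], rng, generation=g + 1))
            gens.append(kids)
        out.append(gens)
    return out


def dosage_profile(genome: AncestryGenome, chrom) -> tuple[np.ndarray, np.ndarray]:
    """Step function of A-ancestry dosage (2, 1, 0) along one chromosome.

    Returns (breaks, dosage) with maximal constant segments; segment i spans
    [breaks[i], breaks[i+1]) and the last ends at L.
    """
    h0, h1 = genome.haplotypes[chrom]
    breaks = np.union1d(h0.breaks, h1.breaks)
    o0 = h0.origins[np.searchsorted(h0.breaks, breaks, side="right") - 1]
    o1 = h1.origins[np.searchsorted(h1.breaks, breaks, side="right") - 1]
    dosage = ((o0 == ORIGIN_A).astype(np.int8) + (o1 == ORIGIN_A).astype(np.int8))
    keep = np.ones(len(breaks), dtype=bool)
    keep[1:] = dosage[1:] != dosage[:-1]
    return breaks[keep], dosage[keep]


@dataclass(frozen=True)
class JunctionCounts:
    diploid: int
    hap0: int
    hap1: int


def true_junctions(genome: AncestryGenome) -> dict:
    """Per-chromosome junction counts from the true tracts.

    The diploid count is the number of change points of the A-ancestry dosage
    signal (the same signal the HMM posterior argmax estimates); per-haplotype
    counts are the tract-boundary counts.
    """
    out = {}
    for chrom, (h0, h1) in genome.haplotypes.items():
        _, dosage = dosage_profile(genome, chrom)
        out[chrom] = JunctionCounts(len(dosage) - 1, h0.n_junctions, h1.n_junctions)
    return out


def _window_occupancy(breaks, values, L, n_windows, n_states) -> np.ndarray:
    """Occupancy (total length) of each state within equal-Morgan windows."""
    occ = np.zeros((n_windows, n_states))
    edges = np.linspace(0.0, L, n_windows + 1)
    ends = np.append(breaks[1:], L)
    for a, b, v in zip(breaks, ends, values):
        w0 = max(0, np.searchsorted(edges, a, side="right") - 1)
        w1 = max(0, np.searchsorted(edges, b, side="left") - 1)
        for w in range(w0, w1 + 1):
            occ[w, v] += min(b, edges[w + 1]) - max(a, edges[w])
    return occ


def windowed_true_junctions(genome: AncestryGenome, n_windows: int = 20) -> dict:
    """Diploid junction counts after windowing the true dosage signal.

    Each chromosome is split into ``n_windows`` equal-Morgan windows; the
    window state is the dosage value occupying most of the window (ties break
    toward higher A dosage) and adjacent state changes are counted.  This is
    the truth-side analogue of posterior-based junction calling, so simulated
    likelihood tables and HMM-called counts share one definition.
    """
    out = {}
    for chrom in genome.haplotypes:
        L = genome.length(chrom)
        breaks, dosage = dosage_profile(genome, chrom)
        occ = _window_occupancy(breaks, 2 - dosage, L, n_windows, 3)
        states = np.argmax(occ, axis=1)  # 0=AA, 1=AB, 2=BB
        out[chrom] = int(np.sum(states[1:] != states[:-1]))
    return out


def ancestry_heterozygosity(genome: AncestryGenome):
    """Fraction of the genome where the two homologs differ in origin.

    Returns (per-chromosome dict, genome-wide Morgan-weighted mean).
    """
    per = {}
    tot_len = 0.0
    tot_het = 0.0
    for chrom, (h0, h1) in genome.haplotypes.items():
        L = h0.length
        breaks = np.union1d(h0.breaks, h1.breaks)
        o0 = h0.origins[np.searchsorted(h0.breaks, breaks, side="right") - 1]
        o1 = h1.origins[np.searchsorted(h1.breaks, breaks, side="right") - 1]
        seg = np.diff(np.append(breaks, L))
        het = float(np.sum(seg[o0 != o1]))
        per[chrom] = het / L
        tot_len += L
        tot_het += het
    return per, tot_het / tot_len


def origin_fraction(genome: AncestryGenome, origin="A") -> float:
    """Fraction of the diploid genome descending from the given parent."""
    code = _ORIGIN_CODE.get(origin, origin)
    tot = 0.0
    own = 0.0
    for h0, h1 in genome.haplotypes.values():
        tot += 2 * h0.length
        own += h0.origin_length(code) + h1.origin_length(code)
    return own / tot


def expected_stats(scheme: str, t: int, N: int | None = None, L: float | None = None):
    """Analytic (heterozygosity, recurrent-parent genome fraction).

    Backcross: H = 2**-(t-1) and fraction = 1 - 2**-t, independent of any
    population size (the recurrent parent is an effectively infinite pool).
    Hybrid swarm of size N: H = 0.5 * (1 - 1/(2N))**(t-1); the expected share
    of either founder ancestry stays 0.5.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if scheme == "backcross":
        return 2.0 ** (-(t - 1)), 1.0 - 2.0 ** (-t)
    if scheme == "hybrid_swarm":
        if N is None or N < 2:
            raise ValueError("swarm expectation needs N >= 2")
        return 0.5 * (1.0 - 1.0 / (2.0 * N)) ** (t - 1), 0.5
    raise ValueError(f"unknown scheme {scheme!r}")


def artificial_genotype(
    genome: AncestryGenome,
    marker_map: MarkerMap,
    panel: AllelePanel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype a simulated individual at the panel SNPs.

    For each SNP and each haplotype the true origin at the SNP's Morgan
    position selects the parental population, and an allele is drawn from
    that population's observed allele-count distribution (P(alt) = alt
    count / total count).  Returns the 0/1/2 alt-dosage vector in map order.
    """
    qa, qb = panel.freqs(smoothing=0.0)
    out = np.empty(marker_map.n_snps, dtype=np.int16)
    offset = 0
    for chrom in marker_map.chromosomes:
        pos = marker_map.positions_morgan(chrom.name)
        n = pos.size
        if n == 0:
            continue
        if chrom.name not in genome.haplotypes:
            raise ValueError(f"genome lacks chromosome {chrom.name}")
        q = np.empty(n)
        g = np.zeros(n, dtype=np.int16)
        for hap in genome.haplotypes[chrom.name]:
            origin = hap.origin_at(pos)
            q = np.where(origin == ORIGIN_A, qa[offset:offset + n], qb[offset:offset + n])
            g += (rng.random(n) < q).astype(np.int16)
        out[offset:offset + n] = g
        offset += n
    return out
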