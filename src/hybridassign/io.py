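"""File formats and run configuration.

Genotypes travel either as a minimal GT-only VCF or as a tab-delimited
dosage matrix (rows = SNPs: chrom, pos, then one 0/1/2 alt-dosage column per
sample; -1 or '.' for missing).  Allele panels are TSV with per-population
ref/alt counts (chrom, pos, ref_a, alt_a, ref_b, alt_b), a layout that maps
directly onto ancestry-HMM-style reference inputs.  Ancestry tracts are
written as BED-like TSV in Morgan coordinates.  Run configuration
round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import AncestryGenome
from .synthetic import AllelePanel, Chromosome, MarkerMap

logger = logging.getLogger("hybridassign")

__all__ = [
    "GenotypeData",
    "RunConfig",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_panel_tsv",
    "write_panel_tsv",
    "write_tracts",
    "write_posterior",
    "marker_map_from_sites",
]


@dataclass
class GenotypeData:
    """Dosage matrix plus site and sample metadata.

    ``dosages`` has shape (n_snps, n_samples); ``sites`` has columns chrom
    and pos (1-based bp) in matrix order.
    """

    dosages: np.ndarray
    samples: list
    sites: pd.DataFrame
    n_multiallelic_dropped: int = 0


def marker_map_from_sites(sites: pd.DataFrame, chrom_table) -> MarkerMap:
    """MarkerMap from a site table plus chromosome lengths.

    ``chrom_table`` is an iterable of (name, length_bp, length_morgan); every
    chromosome present in ``sites`` must appear in it.
    """
    chroms = [Chromosome(str(n), int(bp), float(m)) for n, bp, m in chrom_table]
    known = {c.name for c in chroms}
    missing = set(map(str, sites["chrom"].unique())) - known
    if missing:
        raise ValueError(f"chromosome(s) {sorted(missing)} absent from the chromosome table")
    positions = {
        c.name: sites.loc[sites["chrom"].astype(str) == c.name, "pos"].to_numpy(dtype=np.int64)
        for c in chroms
    }
    positions = {k: v for k, v in positions.items() if v.size}
    return MarkerMap([c for c in chroms if c.name in positions], positions)


# ---------------------------------------------------------------------------
# genotype matrices

def read_genotypes(path, fmt: str | None = None) -> GenotypeData:
    """Read genotypes from VCF or dosage TSV (format inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    dropped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            dropped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        rows.append((var.CHROM, var.POS))
        dosages.append(dose.astype(np.int16))
    if dropped:
        logger.info("dropped %d multi-allelic site(s) from %s", dropped, path)
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    mat = np.stack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int16)
    return GenotypeData(mat, samples, sites, n_multiallelic_dropped=dropped)


def _read_genotypes_tsv(path) -> GenotypeData:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["."])
    except Exception as exc:  # pragma: no cover - pandas reports the line itself
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError(f"{path}: first columns must be 'chrom' and 'pos'")
    samples = list(df.columns[2:])
    mat = df[samples].to_numpy(dtype=float)
    mat = np.where(np.isnan(mat), -1, mat).astype(np.int16)
    return GenotypeData(mat, samples, df[["chrom", "pos"]].copy())


def write_genotypes_tsv(path, data: GenotypeData) -> None:
    df = data.sites.copy()
    for i, s in enumerate(data.samples):
        col = data.dosages[:, i].astype(object)
        df[s] = np.where(data.dosages[:, i] < 0, ".", col)
    df.to_csv(path, sep="\t", index=False)


def write_vcf(path, data: GenotypeData, chrom_table=None) -> None:
    """Minimal GT-only VCF (alleles coded A=ref, T=alt)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridassign\n")
        if chrom_table is not None:
            for name, bp, _ in chrom_table:
                fh.write(f"##contig=<ID={name},length={bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, data.samples)) + "\n")
        for i, (_, site) in enumerate(data.sites.iterrows()):
            gts = "\t".join(code[int(d)] for d in data.dosages[i])
            fh.write(f"{site['chrom']}\t{site['pos']}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# allele panels

def write_panel_tsv(path, panel: AllelePanel) -> None:
    df = panel.marker_map.snp_table()[["chrom", "pos_bp"]].rename(columns={"pos_bp": "pos"})
    df["ref_a"] = panel.ref_a
    df["alt_a"] = panel.alt_a
    df["ref_b"] = panel.ref_b
    df["alt_b"] = panel.alt_b
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path, chrom_table) -> AllelePanel:
    df = pd.read_csv(path, sep="\t")
    mmap = marker_map_from_sites(df[["chrom", "pos"]], chrom_table)
    return AllelePanel(
        mmap,
        df["ref_a"].to_numpy(), df["alt_a"].to_numpy(),
        df["ref_b"].to_numpy(), df["alt_b"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# tracts and posteriors

def write_tracts(path, genome: AncestryGenome, label: str = "") -> None:
    """BED-like TSV of ancestry tracts: chrom, start/end (Morgan), hap, origin."""
    rows = []
    for chrom, haps in genome.haplotypes.items():
        for h_idx, hap in enumerate(haps):
            ends = np.append(hap.breaks[1:], hap.length)
            for a, b, o in zip(hap.breaks, ends, hap.origins):
                rows.append((chrom, a, b, h_idx, "AB"[int(o)], label))
    pd.DataFrame(rows, columns=["chrom", "start_morgan", "end_morgan",
                                "haplotype", "origin", "sample"]).to_csv(
        path, sep="\t", index=False)


def write_posterior(prefix, posterior, sample: str = "sample") -> None:
    """Posterior TSV plus JSON sidecar with the inferred age and likelihoods."""
    import json

    prefix = Path(prefix)
    tbl = posterior.table.rename(columns={"pos_bp": "pos"})
    tbl.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    meta = {
        "sample": sample,
        "t_hat": posterior.t_hat,
        "direction": posterior.direction,
        "loglik_by_chrom": posterior.loglik_by_chrom,
        "prior_mean": posterior.prior_mean,
        "n_skipped_snps": posterior.n_skipped,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; YAML round-trips losslessly."""

    seed: int = 0
    scheme: str = "backcross"
    chromosomes: list = field(default_factory=lambda: [
        ["chr1", 200_000_000, 3.17],
        ["chr2", 150_000_000, 2.26],
        ["chr3", 110_000_000, 1.12],
        ["chr4", 70_000_000, 0.93],
        ["chr5", 60_000_000, 0.79],
        ["chr6", 80_000_000, 1.20],
        ["chr7", 75_000_000, 0.98],
    ])
    panel_variant: str = "default"
    windows_per_chrom: int = 20
    replicates: int = 1000
    t_max: int = 10
    prior_mean: float = 10.0
    bins: list | None = None
    outdir: str = "."

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**data)

    @property
    def chrom_lengths(self) -> dict:
        return {str(n): float(m) for n, _, m in self.chromosomes}
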