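"""Synthetic genome pairs and WGBS count data with known truth.

The generator emulates the structure of a two-genotype WGBS comparison:

* a CpG-enriched reference sequence for genotype A;
* a variant set for genotype B — C>T / G>A substitutions at CpGs (producing
  TG and CA dinucleotides, i.e. A-unique CpGs), background SNVs, small
  indels, and optionally CpG-creating T>C substitutions inside planted
  regions (producing B-unique CpGs);
* a spatially autocorrelated latent methylation field shared by both
  genotypes, with planted mean shifts (DMRs) applied to genotype B samples,
  optionally restricted to shared-only or unique-only CpGs;
* per-sample binomial counts at Poisson coverage, emitted as Bismark
  coverage records in each sample's own genome coordinates.

Everything is deterministic given the seed, so tests and the end-to-end
pipeline can assert against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .cpg_catalog import COMMON_CG, classify_cross_genome, find_cpgs
from .differential import GroupDesign
from .genomes import (
    CoordinateMap,
    PersonalGenome,
    Variant,
    VariantSet,
    build_pseudogenome,
    write_fasta,
    write_vcf,
)
from .meth_io import SampleMeth, write_bismark_coverage

__all__ = [
    "PlantedRegion",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_reference",
    "simulate_variants",
    "simulate_counts",
    "simulate_dataset",
    "write_dataset",
]

TargetClass = Literal["all", "shared", "unique"]


@dataclass(frozen=True)
class PlantedRegion:
    """A region (reference coordinates, 1-based inclusive) where genotype-B
    samples get a latent methylation shift of ``delta``, applied to the
    configured target class of CpGs."""

    chrom: str
    start: int
    end: int
    delta: float
    target: TargetClass = "all"

    def __post_init__(self):
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [-1, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic two-genotype comparison.

    Defaults describe a desk-scale version of a divergent-strain experiment:
    a 2 Mb chromosome at ~1 CpG per 100 bp, a 10% per-CpG loss rate in the
    other genotype, four samples per genotype at 15x mean coverage, and a
    smoothly varying baseline methylation around 0.75.
    """

    chrom: str = "chr1"
    length: int = 2_000_000
    cpg_rate: float = 0.01  # probability of starting a CG at each position
    island_cpg_rate: float = 0.08  # CpG density inside planted shared/all regions
    cpg_ct_rate: float = 0.10  # per-CpG probability of C>T / G>A loss in B
    snv_rate: float = 0.002  # background SNV probability per base
    indel_rate: float = 0.0002  # indel events per base
    indel_max_len: int = 6
    cpg_gain_rate: float = 0.5  # TG->CG conversion rate inside unique-target regions
    tg_to_cg_rate: float = 0.01  # background TG->CG rate, so B has unique CpGs too
    het_fraction: float = 0.0
    n_per_genotype: int = 4
    mean_coverage: float = 15.0
    baseline_meth: float = 0.75
    meth_sigma: float = 1.0  # sd of the latent logit field
    autocorr_bp: int = 2000
    planted: tuple[PlantedRegion, ...] = ()
    genotype_a: str = "A"
    genotype_b: str = "B"
    seed: int = 0


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the generative truth."""

    config: SimulationConfig
    reference: dict[str, str]
    variants: VariantSet
    personal: PersonalGenome
    cmap: CoordinateMap  # reference (A) -> personal (B)
    samples: list[SampleMeth]
    design: GroupDesign
    truth: pd.DataFrame  # planted regions with per-region target class


def simulate_reference(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """A random sequence whose CpG dinucleotides occur at ~``cpg_rate`` per
    position, elevated to ``island_cpg_rate`` inside planted shared/all
    regions.

    The background is CpG-depleted (a G is never drawn right after a C, as
    in mammalian genomes), so essentially all CG dinucleotides are the
    explicitly planted ones and the realized density tracks the configured
    rate.  Planted regions targeting shared (or all) CpGs are embedded in
    CpG-island-like density, mirroring where focal DMRs occur in real
    genomes; unique-target regions keep background density so their signal
    is carried by the CpGs the variant step creates.
    """
    L = config.length
    rate = np.full(L, config.cpg_rate)
    for region in config.planted:
        if region.target != "unique":
            rate[region.start - 1 : region.end] = config.island_cpg_rate
    bases = np.array(list("ACGT"))
    no_g = np.array(list("ACT"))
    starts_cg = rng.random(L) < rate
    rand_bases = bases[rng.integers(0, 4, size=L)]
    depleted = no_g[rng.integers(0, 3, size=L)]
    buf: list[str] = []
    i = 0
    prev_c = False
    while i < L:
        if starts_cg[i] and i + 1 < L:
            buf.append("CG")
            prev_c = False
            i += 2
        else:
            b = depleted[i] if prev_c else rand_bases[i]
            buf.append(b)
            prev_c = b == "C"
            i += 1
    seq = "".join(buf)[:L]
    return {config.chrom: seq}


def simulate_variants(
    reference: dict[str, str], config: SimulationConfig, rng: np.random.Generator
) -> VariantSet:
    """Genotype B's variants relative to the reference (genotype A).

    CpG-loss substitutions are split evenly between the two strands (C>T
    giving TG, G>A giving CA); indels avoid other variants; inside planted
    regions with ``target='unique'`` eligible TG dinucleotides become CG in B
    at ``cpg_gain_rate``, creating B-unique CpGs that carry the planted
    signal.
    """
    chrom = config.chrom
    seq = reference[chrom]
    L = len(seq)
    occupied = np.zeros(L + 2, dtype=bool)  # 0-based, slack for dinucleotides
    variants: list[Variant] = []

    def claim(start0: int, length: int) -> bool:
        if start0 < 0 or start0 + length > L:
            return False
        if occupied[start0 : start0 + length].any():
            return False
        occupied[start0 : start0 + length] = True
        return True

    # 1. B-unique CpG creation inside unique-target planted regions
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for region in config.planted:
        if region.target != "unique":
            continue
        a, b = region.start - 1, min(region.end, L - 1)
        tg = np.flatnonzero((arr[a:b] == ord("T")) & (arr[a + 1 : b + 1] == ord("G"))) + a
        # skip TGs whose T is preceded by C (already the G of a CpG upstream)
        tg = tg[(tg == 0) | (arr[np.maximum(tg - 1, 0)] != ord("C"))]
        chosen = tg[rng.random(tg.size) < config.cpg_gain_rate]
        for p0 in chosen:
            if claim(int(p0), 2):
                variants.append(Variant(chrom, int(p0) + 1, "T", "C"))

    # 1b. background CpG gains genome-wide, so genotype B carries unique
    # CpGs at a rate comparable to genotype A's losses (the symmetric
    # structure seen between real divergent strains)
    if config.tg_to_cg_rate > 0:
        tg_all = np.flatnonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("G")))
        tg_all = tg_all[(tg_all == 0) | (arr[np.maximum(tg_all - 1, 0)] != ord("C"))]
        chosen = tg_all[rng.random(tg_all.size) < config.tg_to_cg_rate]
        for p0 in chosen:
            if claim(int(p0), 2):
                variants.append(Variant(chrom, int(p0) + 1, "T", "C"))

    # 2. CpG-loss substitutions at reference CpGs
    cpgs = find_cpgs(seq)
    lose = cpgs[rng.random(cpgs.size) < config.cpg_ct_rate]
    strand_is_fwd = rng.random(lose.size) < 0.5
    for pos, fwd in zip(lose, strand_is_fwd):
        p0 = int(pos) - 1
        if not claim(p0, 2):
            continue
        if fwd:
            variants.append(Variant(chrom, int(pos), "C", "T"))  # CG -> TG
        else:
            variants.append(Variant(chrom, int(pos) + 1, "G", "A"))  # CG -> CA

    # 3. background SNVs away from CpGs
    n_snv = rng.binomial(L, config.snv_rate)
    snv_pos = np.sort(rng.choice(L, size=min(n_snv, L), replace=False))
    bases = "ACGT"
    for p0 in snv_pos:
        p0 = int(p0)
        ref_base = seq[p0]
        # avoid touching CpG dinucleotides so loss events stay controlled
        if (ref_base == "C" and p0 + 1 < L and seq[p0 + 1] == "G") or (
            ref_base == "G" and p0 > 0 and seq[p0 - 1] == "C"
        ):
            continue
        if not claim(p0, 1):
            continue
        alts = [b for b in bases if b != ref_base]
        variants.append(Variant(chrom, p0 + 1, ref_base, alts[rng.integers(0, 3)]))

    # 4. small indels
    n_indel = rng.binomial(L, config.indel_rate)
    indel_pos = np.sort(rng.choice(L - config.indel_max_len - 2, size=n_indel, replace=False))
    for p0 in indel_pos:
        p0 = int(p0)
        length = int(rng.integers(1, config.indel_max_len + 1))
        if rng.random() < 0.5:  # deletion: anchor base + deleted span
            if not claim(p0, length + 1):
                continue
            variants.append(Variant(chrom, p0 + 1, seq[p0 : p0 + length + 1], seq[p0]))
        else:  # insertion after the anchor base
            if not claim(p0, 1):
                continue
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            variants.append(Variant(chrom, p0 + 1, seq[p0], seq[p0] + ins))

    # 5. zygosity
    if config.het_fraction > 0:
        variants = [
            replace(v, zygosity="heterozygous")
            if rng.random() < config.het_fraction
            else v
            for v in variants
        ]
    return VariantSet(variants)


class _LatentField:
    """Smooth latent methylation logit over reference coordinates: Gaussian
    noise on a coarse grid, box-filtered to the configured autocorrelation
    length, evaluable at any position."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        from scipy.ndimage import uniform_filter1d

        self.grid = max(1, config.autocorr_bp // 5)
        n_cells = config.length // self.grid + 2
        z = rng.normal(size=n_cells)
        window = max(1, config.autocorr_bp // self.grid)
        smooth = uniform_filter1d(z, size=window, mode="nearest")
        sd = smooth.std() or 1.0
        mu0 = np.log(config.baseline_meth / (1 - config.baseline_meth))
        self.logit = mu0 + config.meth_sigma * smooth / sd

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(positions, dtype=np.int64) // self.grid, 0, len(self.logit) - 1)
        return 1.0 / (1.0 + np.exp(-self.logit[idx]))


def simulate_counts(
    reference: dict[str, str],
    personal: PersonalGenome,
    cmap: CoordinateMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[SampleMeth], pd.DataFrame]:
    """Binomial counts at Poisson coverage for every sample of both
    genotypes, each in its own genome's coordinates, plus the truth table of
    planted regions."""
    chrom = config.chrom
    field_fn = _LatentField(config, rng)

    cpgs_a = find_cpgs(reference[chrom])
    cpgs_b = find_cpgs(personal[chrom])
    # genotype B sites evaluated at their reference-coordinate image where
    # mappable (indels are short, so unmappable B sites fall back to their
    # own coordinate, which is offset by at most a few bases)
    mapped_b = cmap.map_positions(chrom, cpgs_b, direction="to_reference")
    b_eval = np.where(mapped_b >= 0, mapped_b, cpgs_b)

    # shared CpGs of A (COMMON_CG against B) for target-class restrictions
    cls = classify_cross_genome({chrom: cpgs_a}, cmap, personal.sequences)
    shared_a = set(cls.loc[cls["category"] == COMMON_CG, "pos"].tolist())

    latent_a = field_fn(cpgs_a)
    latent_b_base = field_fn(b_eval)

    # planted shifts apply to genotype B's latent profile
    delta_b = np.zeros(cpgs_b.size)
    truth_rows = []
    for region in config.planted:
        in_region = (b_eval >= region.start) & (b_eval <= region.end)
        is_shared = np.isin(b_eval, list(shared_a)) & (mapped_b >= 0)
        if region.target == "shared":
            sel = in_region & is_shared
        elif region.target == "unique":
            sel = in_region & ~is_shared
        else:
            sel = in_region
        delta_b[sel] += region.delta
        truth_rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "delta": region.delta,
                "target": region.target,
                "n_target_sites": int(sel.sum()),
            }
        )
    latent_b = np.clip(latent_b_base + delta_b, 1e-3, 1 - 1e-3)
    latent_a = np.clip(latent_a, 1e-3, 1 - 1e-3)

    samples: list[SampleMeth] = []
    for g, positions, latent in (
        (config.genotype_a, cpgs_a, latent_a),
        (config.genotype_b, cpgs_b, latent_b),
    ):
        for k in range(config.n_per_genotype):
            cov = rng.poisson(config.mean_coverage, size=positions.size)
            m = rng.binomial(cov, latent)
            samples.append(
                SampleMeth(
                    sample_id=f"{g}{k + 1}",
                    genotype=g,
                    records=pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": positions,
                            "n_meth": m,
                            "n_unmeth": cov - m,
                        }
                    ),
                )
            )
    return samples, pd.DataFrame(truth_rows)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: reference, variants, pseudogenome + map,
    counts and design, all from one seed."""
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    variants = simulate_variants(reference, config, rng)
    personal, cmap = build_pseudogenome(
        reference,
        variants,
        het_policy="reference",
        reference_id=config.genotype_a,
        variant_set_id=config.genotype_b,
    )
    samples, truth = simulate_counts(reference, personal, cmap, config, rng)
    design = GroupDesign.from_lists(
        [s.sample_id for s in samples],
        [1 if s.genotype == config.genotype_a else 2 for s in samples],
        [s.genotype for s in samples],
    )
    return SimulatedDataset(config, reference, variants, personal, cmap, samples, design, truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the standard files the rest of the pipeline consumes: FASTA for
    both genomes, a VCF, Bismark coverage files, a design TSV and a truth
    BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.reference, outdir / f"{ds.config.genotype_a}.fa")
    write_fasta(ds.personal.sequences, outdir / f"{ds.config.genotype_b}.fa")
    write_vcf(ds.variants, outdir / f"{ds.config.genotype_b}.vcf", sample=ds.config.genotype_b)
    ds.cmap.to_tsv(outdir / "a2b.map.tsv")
    rows = []
    for s in ds.samples:
        fname = f"{s.sample_id}.cov.txt"
        write_bismark_coverage(s.records, outdir / fname)
        rows.append({"sample_id": s.sample_id, "genotype": s.genotype, "counts_file": fname})
    pd.DataFrame(rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "truth.bed", "w") as fh:
        for _, r in ds.truth.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                f"{r['target']}\t{r['delta']}\n"
            )
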