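"""Per-sample methylation counts, common-coordinate matrices and site filters.

Counts come in as Bismark-style per-CpG records in each sample's own genome
coordinates.  Each sample is lifted into a user-chosen target coordinate
system through its genotype's coordinate map; the union of lifted CpG sets
forms one matrix of methylated / total counts.  A CpG absent from a sample's
genome (or unmappable to the target for that sample) simply has zero coverage
for that sample — the representation that later lets the smoother treat
genotype-unique CpGs as missing data to impute across rather than as zeros.

Filters implement the two analysis modes (unique-removed keeps only CpGs
shared by all genotypes, unique-included keeps everything), per-sample
removal of heterozygous CpGs, the variation-filtering fallback for studies
without personal genomes, and the coverage mask used for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomes import CoordinateMap, map_sites

__all__ = [
    "SampleMeth",
    "MethMatrix",
    "read_bismark",
    "write_bismark_coverage",
    "to_common_coordinates",
    "restrict_to_shared",
    "filter_heterozygous",
    "filter_variant_cpgs",
    "coverage_mask",
]


@dataclass
class SampleMeth:
    """One sample's per-CpG counts in its own genome coordinates.

    ``records`` has columns ``chrom, pos, n_meth, n_unmeth`` with unique,
    sorted positions per chromosome.
    """

    sample_id: str
    genotype: str
    records: pd.DataFrame

    def __post_init__(self):
        r = self.records
        if (r["n_meth"] < 0).any() or (r["n_unmeth"] < 0).any():
            raise ValueError(f"negative counts in sample {self.sample_id}")
        self.records = r.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if self.records.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"duplicate positions in sample {self.sample_id}")


@dataclass
class MethMatrix:
    """Union-of-CpGs x samples count matrices in one coordinate system.

    ``sites`` (chrom, pos) is sorted; ``M`` and ``Cov`` are
    (n_samples, n_sites) integer arrays with ``0 <= M <= Cov``.  ``present``
    is (n_genotypes, n_sites) boolean: which genotypes' data contributed a
    record at each site (a genome's CpG census, when complete count files are
    used).
    """

    sites: pd.DataFrame
    M: np.ndarray
    Cov: np.ndarray
    samples: list[str]
    genotypes: list[str]
    genotype_labels: list[str] = field(default_factory=list)
    present: np.ndarray | None = None

    def __post_init__(self):
        if not self.genotype_labels:
            self.genotype_labels = sorted(set(self.genotypes))
        if (self.M > self.Cov).any() or (self.M < 0).any():
            raise ValueError("require 0 <= M <= Cov elementwise")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def genotype_of(self, sample_id: str) -> str:
        return self.genotypes[self.sample_index(sample_id)]

    def shared_sites(self) -> np.ndarray:
        """Boolean mask of sites present in every genotype's data."""
        if self.present is None:
            raise ValueError("present-in annotation not populated")
        return self.present.all(axis=0)

    def take_sites(self, mask_or_idx) -> "MethMatrix":
        idx = np.flatnonzero(mask_or_idx) if np.asarray(mask_or_idx).dtype == bool else mask_or_idx
        return MethMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            self.M[:, idx].copy(),
            self.Cov[:, idx].copy(),
            list(self.samples),
            list(self.genotypes),
            list(self.genotype_labels),
            None if self.present is None else self.present[:, idx].copy(),
        )

    def copy(self) -> "MethMatrix":
        return MethMatrix(
            self.sites.copy(),
            self.M.copy(),
            self.Cov.copy(),
            list(self.samples),
            list(self.genotypes),
            list(self.genotype_labels),
            None if self.present is None else self.present.copy(),
        )

    # --- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Long-form TSV `chrom pos sample M Cov` (zero-coverage cells skipped
        unless the site would otherwise vanish)."""
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tsample\tM\tCov\n")
            chroms = self.sites["chrom"].to_numpy()
            pos = self.sites["pos"].to_numpy()
            for i, sample in enumerate(self.samples):
                for j in range(self.n_sites):
                    if self.Cov[i, j] > 0 or i == 0:
                        fh.write(
                            f"{chroms[j]}\t{pos[j]}\t{sample}\t{self.M[i, j]}\t{self.Cov[i, j]}\n"
                        )


def read_bismark(path: str | Path, dialect: str = "coverage") -> pd.DataFrame:
    """Read a Bismark counts file into ``chrom, pos, n_meth, n_unmeth``.

    ``coverage`` dialect: `chrom start end %meth count_M count_U`, 1-based,
    one row per CpG (already strand-combined).  ``cpg_report`` dialect:
    cytosine report `chrom pos strand count_M count_U context [tri]`; rows on
    the reverse strand at ``p`` are folded into the forward-strand CpG at
    ``p - 1`` by summing counts, and non-CpG contexts are skipped.
    """
    if dialect == "coverage":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
                dtype={"chrom": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed Bismark coverage file {path}: {exc}") from exc
        out = df[["chrom", "start", "n_meth", "n_unmeth"]].rename(columns={"start": "pos"})
    elif dialect == "cpg_report":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                usecols=[0, 1, 2, 3, 4, 5],
                names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"],
                dtype={"chrom": str, "strand": str, "context": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed Bismark cytosine report {path}: {exc}") from exc
        df = df[df["context"].str.upper().isin(["CG", "CPG"])]
        rev = df["strand"] == "-"
        df = df.assign(pos=np.where(rev, df["pos"] - 1, df["pos"]))
        out = (
            df.groupby(["chrom", "pos"], as_index=False)[["n_meth", "n_unmeth"]]
            .sum()
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in ("pos", "n_meth", "n_unmeth"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"malformed {col!r} field at data line {line} of {path}")
        out[col] = coerced.astype(np.int64)
    bad = out["pos"] < 1
    if bad.any():
        raise ValueError(f"non-positive position at data line {int(np.flatnonzero(bad)[0]) + 1}")
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_bismark_coverage(records: pd.DataFrame, path: str | Path) -> None:
    """Write `chrom, pos, n_meth, n_unmeth` records as a Bismark coverage file."""
    cov = records["n_meth"] + records["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * records["n_meth"] / np.maximum(cov, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"],
            "end": records["pos"],
            "pct": pct,
            "n_meth": records["n_meth"],
            "n_unmeth": records["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def to_common_coordinates(
    samples: Sequence[SampleMeth],
    maps: Mapping[str, CoordinateMap | None],
    target_genotype: str,
) -> MethMatrix:
    """Lift every sample into the target genotype's coordinates and join.

    ``maps[g]`` is the CoordinateMap built from the target reference for
    genotype ``g`` (reference side = target, personal side = g); the target
    genotype itself may map to ``None`` (identity).  Sites a sample cannot
    lift (C or G inside an indel) are dropped for that sample, per the
    discard rule.  The output site list is the union over samples; cells
    with no data have Cov = 0.
    """
    lifted: list[pd.DataFrame] = []
    for s in samples:
        if s.genotype == target_genotype or maps.get(s.genotype) is None:
            if s.genotype != target_genotype and s.genotype not in maps:
                raise KeyError(f"no coordinate map for genotype {s.genotype!r}")
            lifted.append(s.records.copy())
            continue
        if s.genotype not in maps:
            raise KeyError(f"no coordinate map for genotype {s.genotype!r}")
        cmap = maps[s.genotype]
        parts = []
        for chrom, grp in s.records.groupby("chrom", sort=False):
            kept, mapped, _ = map_sites(
                cmap, chrom, grp["pos"].to_numpy(), direction="to_reference"
            )
            keep_mask = np.isin(grp["pos"].to_numpy(), kept)
            sub = grp.loc[keep_mask].copy()
            sub["pos"] = mapped
            parts.append(sub)
        lifted.append(
            pd.concat(parts, ignore_index=True)
            if parts
            else s.records.iloc[0:0].copy()
        )

    # union site list
    all_sites = (
        pd.concat([df[["chrom", "pos"]] for df in lifted], ignore_index=True)
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(all_sites)
    site_index = pd.Series(np.arange(len(all_sites)), index=key)

    n_samples, n_sites = len(samples), len(all_sites)
    M = np.zeros((n_samples, n_sites), dtype=np.int64)
    Cov = np.zeros((n_samples, n_sites), dtype=np.int64)
    genotype_labels = sorted({s.genotype for s in samples})
    present = np.zeros((len(genotype_labels), n_sites), dtype=bool)
    g_index = {g: i for i, g in enumerate(genotype_labels)}

    for i, (s, df) in enumerate(zip(samples, lifted)):
        idx = site_index.loc[pd.MultiIndex.from_frame(df[["chrom", "pos"]])].to_numpy()
        M[i, idx] = df["n_meth"].to_numpy()
        Cov[i, idx] = (df["n_meth"] + df["n_unmeth"]).to_numpy()
        present[g_index[s.genotype], idx] = True

    return MethMatrix(
        all_sites,
        M,
        Cov,
        [s.sample_id for s in samples],
        [s.genotype for s in samples],
        genotype_labels,
        present,
    )


def restrict_to_shared(matrix: MethMatrix, mode: str = "unique-removed") -> MethMatrix:
    """Apply the unique-removed filter (keep only CpGs present in every
    genotype); ``mode='unique-included'`` is the identity."""
    if mode == "unique-included":
        return matrix.copy()
    if mode != "unique-removed":
        raise ValueError(f"unknown mode {mode!r}")
    return matrix.take_sites(matrix.shared_sites())


def filter_heterozygous(
    matrix: MethMatrix,
    het_sites: Mapping[str, Iterable[tuple[str, int]]],
) -> MethMatrix:
    """Zero out (sample, site) cells at each sample's heterozygous CpGs.

    ``het_sites[sample_id]`` is an iterable of ``(chrom, pos)`` in the common
    coordinate system.  Sites stay in the matrix for other samples.
    """
    out = matrix.copy()
    key = pd.MultiIndex.from_frame(matrix.sites)
    site_index = pd.Series(np.arange(matrix.n_sites), index=key)
    for sample_id, sites in het_sites.items():
        sites = list(sites)
        if not sites:
            continue
        i = matrix.sample_index(sample_id)
        mi = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"])
        hits = site_index.reindex(mi).dropna().astype(int).to_numpy()
        out.M[i, hits] = 0
        out.Cov[i, hits] = 0
    return out


def filter_variant_cpgs(
    matrix: MethMatrix, variant_cpg_positions: Iterable[tuple[str, int]]
) -> MethMatrix:
    """Remove listed sites from the matrix entirely (all samples) — the
    variation-filtering strategy for analyses without personal genomes."""
    positions = set(variant_cpg_positions)
    if not positions:
        return matrix.copy()
    keys = list(zip(matrix.sites["chrom"], matrix.sites["pos"]))
    keep = np.array([k not in positions for k in keys], dtype=bool)
    return matrix.take_sites(keep)


def coverage_mask(
    matrix: MethMatrix,
    groups: Mapping[str, Sequence[str]],
    min_cov: int = 2,
    min_samples_per_group: int = 3,
) -> np.ndarray:
    """Boolean site mask: both groups have >= ``min_samples_per_group``
    samples with coverage >= ``min_cov``.

    In a genotype-vs-genotype design genotype-unique sites automatically
    fail (one group's coverage is all zero there).
    """
    mask = np.ones(matrix.n_sites, dtype=bool)
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {name!r} is empty")
        if min_samples_per_group > len(members):
            raise ValueError(
                f"min_samples_per_group={min_samples_per_group} exceeds size of group {name!r}"
            )
        idx = [matrix.sample_index(m) for m in members]
        ok = (matrix.Cov[idx, :] >= min_cov).sum(axis=0) >= min_samples_per_group
        mask &= ok
    return mask
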