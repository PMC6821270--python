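"""Quantification-bias diagnostics and descriptive methylation statistics.

Aligning a sample to a distant reference genome silently scores
reference-unique CpGs — positions where the sample's genome carries TG or CA
instead of CG — as covered but 0% methylated, because bisulfite-converted
reads match the reference there without mismatches.  The result is a
systematic depression of the sample's apparent methylation ("quantification
bias").  This module computes the summary statistics that expose the bias
(global and per-category methylation), simulates the wrong-reference pipeline
on a correctly-quantified matrix so the bias can be measured on synthetic
data, and quantifies the contribution of genotype-unique CpGs to candidate
regions via the unique-shared disparity.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .cpg_catalog import TG_CA
from .differential import CandidateRegion, GroupDesign
from .meth_io import MethMatrix

__all__ = [
    "global_methylation",
    "category_methylation",
    "simulate_wrong_reference",
    "raw_region_diff",
    "unique_shared_disparity",
]


def global_methylation(
    matrix: MethMatrix, chrom_filter: Iterable[str] | None = None
) -> pd.Series:
    """Per-sample unweighted mean of M/Cov over read-covered CpGs.

    ``chrom_filter`` restricts to the given chromosomes (e.g. the autosome
    list); by default all chromosomes count.  A sample with no covered site
    gets NaN.  The mean counts CpGs, not reads, so it is insensitive to local
    coverage differences.
    """
    if chrom_filter is not None:
        keep = matrix.sites["chrom"].isin(set(chrom_filter)).to_numpy()
    else:
        keep = np.ones(matrix.n_sites, dtype=bool)
    out = {}
    for i, sample in enumerate(matrix.samples):
        cov = matrix.Cov[i, keep]
        m = matrix.M[i, keep]
        covered = cov >= 1
        out[sample] = float((m[covered] / cov[covered]).mean()) if covered.any() else np.nan
    return pd.Series(out, name="global_methylation")


def category_methylation(
    matrix: MethMatrix,
    classifications: pd.DataFrame,
    chrom_filter: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-sample mean methylation within each CpG classification category.

    ``classifications`` (chrom, pos, category) is joined to the matrix sites
    by position; matrix sites without a classification are ignored.  Returns
    samples x categories; a category with no covered site for a sample is
    NaN.
    """
    merged = matrix.sites.merge(
        classifications[["chrom", "pos", "category"]], on=["chrom", "pos"], how="left"
    )
    cats = merged["category"].to_numpy()
    rows = {}
    for cat in pd.unique(cats[pd.notna(cats)]):
        sub = matrix.take_sites(np.flatnonzero(cats == cat))
        rows[cat] = global_methylation(sub, chrom_filter)
    return pd.DataFrame(rows)


def simulate_wrong_reference(
    matrix: MethMatrix,
    classifications: pd.DataFrame,
    ref_genotype: str,
) -> MethMatrix:
    """Transform a correctly-quantified matrix into what naive alignment of
    every sample to ``ref_genotype``'s genome would yield.

    For each sample of a genotype other than the reference:

    * at reference-unique TG/CA sites, reads align without mismatch and are
      called unmethylated — coverage is kept (or filled with the sample's
      mean coverage where absent) and M is set to 0;
    * at sites unique to the sample's own genotype, the data is removed
      (those positions do not exist in the reference coordinate system).

    Reference-genotype samples are unchanged.  ``classifications`` must be in
    the reference genotype's coordinates (reference CpGs classified against
    the other genome).
    """
    out = matrix.copy()
    if matrix.present is None:
        raise ValueError("matrix needs present-in annotations")
    g_idx = {g: i for i, g in enumerate(matrix.genotype_labels)}
    ref_present = matrix.present[g_idx[ref_genotype]]

    merged = matrix.sites.merge(
        classifications[["chrom", "pos", "category"]], on=["chrom", "pos"], how="left"
    )
    is_tgca = (merged["category"] == TG_CA).to_numpy()

    for i, sample in enumerate(matrix.samples):
        g = matrix.genotypes[i]
        if g == ref_genotype:
            continue
        own_present = matrix.present[g_idx[g]]
        # ref-unique TG/CA sites read as unmethylated with full coverage
        fake = is_tgca & ref_present & ~own_present
        covered = matrix.Cov[i] > 0
        mean_cov = max(1, int(round(matrix.Cov[i][covered].mean()))) if covered.any() else 1
        cov_fill = np.where(out.Cov[i, fake] > 0, out.Cov[i, fake], mean_cov)
        out.Cov[i, fake] = cov_fill
        out.M[i, fake] = 0
        # sites absent from the reference genome vanish from the alignment
        own_unique = own_present & ~ref_present
        out.M[i, own_unique] = 0
        out.Cov[i, own_unique] = 0
    return out


def _pooled_group_props(
    matrix: MethMatrix, design: GroupDesign, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site pooled proportions sum(M)/sum(Cov) for each group over the
    given site indices, plus per-site group coverage."""
    s1 = [matrix.sample_index(s) for s in np.array(design.samples)[design.group_indices(1)]]
    s2 = [matrix.sample_index(s) for s in np.array(design.samples)[design.group_indices(2)]]
    cov1 = matrix.Cov[np.ix_(s1, idx)].sum(axis=0)
    cov2 = matrix.Cov[np.ix_(s2, idx)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(cov1 > 0, matrix.M[np.ix_(s1, idx)].sum(axis=0) / np.maximum(cov1, 1), np.nan)
        p2 = np.where(cov2 > 0, matrix.M[np.ix_(s2, idx)].sum(axis=0) / np.maximum(cov2, 1), np.nan)
    return p1, p2, cov1, cov2


def _region_site_subsets(
    matrix: MethMatrix, region: CandidateRegion
) -> tuple[np.ndarray, np.ndarray]:
    """(indices of region sites, shared-site mask among them)."""
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    in_region = (chroms == region.chrom) & (pos >= region.start) & (pos <= region.end)
    idx = np.flatnonzero(in_region)
    shared = matrix.shared_sites()[idx]
    return idx, shared


def raw_region_diff(
    matrix: MethMatrix,
    region: CandidateRegion,
    site_subset: Literal["shared", "unique", "all"],
    design: GroupDesign,
) -> float:
    """Mean unsmoothed methylation difference (group2 - group1) over a
    region's sites of the requested subset.

    Per site, each group's raw methylation is the pooled proportion
    sum(M)/sum(Cov) across the group's samples; only sites with coverage in
    both groups contribute.  NaN when no site is eligible.
    """
    idx, shared = _region_site_subsets(matrix, region)
    if site_subset == "shared":
        idx = idx[shared]
    elif site_subset == "unique":
        idx = idx[~shared]
    elif site_subset != "all":
        raise ValueError(f"unknown site_subset {site_subset!r}")
    if idx.size == 0:
        return np.nan
    p1, p2, cov1, cov2 = _pooled_group_props(matrix, design, idx)
    eligible = (cov1 > 0) & (cov2 > 0)
    if not eligible.any():
        return np.nan
    return float((p2[eligible] - p1[eligible]).mean())


def unique_shared_disparity(
    matrix: MethMatrix,
    region: CandidateRegion,
    design: GroupDesign,
) -> float:
    """(mean difference over the region's unique CpGs) minus (mean difference
    over its shared CpGs).

    A unique CpG has data in only one group of a genotype-vs-genotype
    design, so its "difference" is formed across unique-site classes: mean
    raw methylation at group-2-genotype-unique sites in group 2, minus the
    mean at group-1-genotype-unique sites in group 1.  When only one class is
    present in the region, the available side is compared against the other
    group's mean over the region's shared CpGs.  Positive values indicate
    differential methylation carried by the unique sites.  NaN when the
    region lacks eligible unique or shared sites.
    """
    idx, shared = _region_site_subsets(matrix, region)
    shared_idx = idx[shared]
    unique_idx = idx[~shared]
    if shared_idx.size == 0 or unique_idx.size == 0:
        return np.nan

    p1s, p2s, cov1s, cov2s = _pooled_group_props(matrix, design, shared_idx)
    elig = (cov1s > 0) & (cov2s > 0)
    if not elig.any():
        return np.nan
    shared_diff = float((p2s[elig] - p1s[elig]).mean())
    shared_mean1 = float(p1s[elig].mean())
    shared_mean2 = float(p2s[elig].mean())

    if matrix.present is None:
        raise ValueError("matrix needs present-in annotations")
    g_idx = {g: i for i, g in enumerate(matrix.genotype_labels)}
    g1 = design.genotype_of_group(1)
    g2 = design.genotype_of_group(2)
    u1_mask = matrix.present[g_idx[g1], unique_idx] & ~matrix.present[g_idx[g2], unique_idx]
    u2_mask = matrix.present[g_idx[g2], unique_idx] & ~matrix.present[g_idx[g1], unique_idx]

    p1u, p2u, cov1u, cov2u = _pooled_group_props(matrix, design, unique_idx)
    side1 = p1u[u1_mask & (cov1u > 0)]
    side2 = p2u[u2_mask & (cov2u > 0)]

    if side1.size and side2.size:
        unique_diff = float(side2.mean()) - float(side1.mean())
    elif side2.size:
        unique_diff = float(side2.mean()) - shared_mean1
    elif side1.size:
        unique_diff = shared_mean2 - float(side1.mean())
    else:
        return np.nan
    return unique_diff - shared_diff
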