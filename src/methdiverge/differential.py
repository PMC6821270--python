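"""Group-difference t statistics, region segmentation and permutation FWER.

After smoothing, differential methylation between two groups is scored per
site with a t-like statistic: the difference of group means of the smoothed
values, divided by a pooled within-group standard deviation that is floored
at its 75th percentile (so near-constant stretches cannot produce huge t) and
then smoothed with a running mean.  Candidate regions are maximal runs of
same-sign sites exceeding a |t| cutoff with small inter-site gaps, summarised
by their CpG count and area statistic (sum of member t values).

Significance uses genotype-balanced label permutations: reassigning samples
to pseudo-groups that each contain half of every genotype destroys the
group-genotype confound while preserving within-group structure.  A region's
gFWER is the fraction of permutations in which some null region anywhere is
at least as good on both criteria (CpG count and |areaStat|) — a genome-wide
family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .smoothing import SmoothedTrack

__all__ = [
    "GroupDesign",
    "TStatTrack",
    "DmrParams",
    "CandidateRegion",
    "compute_tstat",
    "find_regions",
    "balanced_permutations",
    "null_regions",
    "assign_gfwer",
    "regions_to_dataframe",
    "write_regions",
]


@dataclass(frozen=True)
class GroupDesign:
    """Two-group design: sample ids, group assignment (values ``1`` or ``2``)
    and genotype labels, index-aligned.  meanDiff is oriented group2 - group1."""

    samples: tuple[str, ...]
    groups: tuple[int, ...]
    genotypes: tuple[str, ...]

    def __post_init__(self):
        if not (len(self.samples) == len(self.groups) == len(self.genotypes)):
            raise ValueError("samples, groups and genotypes must be index-aligned")
        if set(self.groups) != {1, 2}:
            raise ValueError("both groups must be non-empty and labeled 1/2")

    @classmethod
    def from_lists(cls, samples, groups, genotypes) -> "GroupDesign":
        return cls(tuple(samples), tuple(int(g) for g in groups), tuple(genotypes))

    def group_indices(self, group: int) -> np.ndarray:
        return np.flatnonzero(np.array(self.groups) == group)

    def with_groups(self, groups: Sequence[int]) -> "GroupDesign":
        return GroupDesign(self.samples, tuple(int(g) for g in groups), self.genotypes)

    def genotype_of_group(self, group: int) -> str:
        """The single genotype of a group in a genotype-vs-genotype design."""
        gs = {self.genotypes[i] for i in self.group_indices(group)}
        if len(gs) != 1:
            raise ValueError(f"group {group} mixes genotypes {sorted(gs)}")
        return gs.pop()


@dataclass
class TStatTrack:
    mean1: np.ndarray
    mean2: np.ndarray
    mean_diff: np.ndarray  # mean2 - mean1
    sd: np.ndarray  # floored and running-mean smoothed
    t: np.ndarray
    mask: np.ndarray
    sites: pd.DataFrame


@dataclass(frozen=True)
class DmrParams:
    """|t| cutoff, maximum bp gap between member CpGs, and the minimum CpG
    count / mean methylation difference a region must reach to be reported.

    The standard presets are (cutoff=4.6, max_gap=300) for small DMRs and
    (cutoff=2, max_gap=10000) for large blocks.
    """

    cutoff: float = 4.6
    max_gap: int = 300
    min_cpgs: int = 3
    min_meandiff: float = 0.10

    def __post_init__(self):
        if self.cutoff <= 0 or not 0 <= self.min_meandiff <= 1:
            raise ValueError("require cutoff > 0 and min_meandiff in [0, 1]")


BLOCK_DMR_PRESET = DmrParams(cutoff=2.0, max_gap=10_000)


@dataclass
class CandidateRegion:
    chrom: str
    start: int  # position of first member CpG, 1-based inclusive
    end: int  # position of last member CpG
    n_cpgs: int
    mean_diff: float
    area_stat: float
    direction: int
    gfwer: float | None = None
    member_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64), repr=False)


def compute_tstat(
    smoothed: SmoothedTrack,
    design: GroupDesign,
    mask: np.ndarray,
    sd_floor_quantile: float = 0.75,
    sd_smooth_window: int = 101,
) -> TStatTrack:
    """Per-site t statistics of smoothed methylation between the two groups.

    Pooled within-group sd is floored at its ``sd_floor_quantile`` quantile
    over masked sites, then smoothed with a centered running mean over
    ``sd_smooth_window`` masked sites (per chromosome, truncated at ends).
    t = meanDiff / (sd * sqrt(1/n1 + 1/n2)).
    """
    idx1 = [smoothed.samples.index(s) for s in np.array(design.samples)[design.group_indices(1)]]
    idx2 = [smoothed.samples.index(s) for s in np.array(design.samples)[design.group_indices(2)]]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples for a within-group sd")

    vals = smoothed.values
    mask = np.asarray(mask, dtype=bool) & np.isfinite(vals).all(axis=0)

    mean1 = vals[idx1].mean(axis=0)
    mean2 = vals[idx2].mean(axis=0)
    mean_diff = mean2 - mean1
    var1 = vals[idx1].var(axis=0, ddof=1)
    var2 = vals[idx2].var(axis=0, ddof=1)
    raw_sd = np.sqrt(((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2))

    sd = np.full_like(raw_sd, np.nan)
    if mask.any():
        floor = np.quantile(raw_sd[mask], sd_floor_quantile)
        if floor == 0.0:
            # degenerate track (e.g. exactly constant groups): keep t finite
            positive = raw_sd[mask][raw_sd[mask] > 0]
            floor = positive.min() if positive.size else 1e-8
        floored = np.maximum(raw_sd, floor)
        chroms = smoothed.sites["chrom"].to_numpy()
        sd_masked = np.full(raw_sd.shape, np.nan)
        for chrom in pd.unique(chroms):
            sel = np.flatnonzero((chroms == chrom) & mask)
            if sel.size == 0:
                continue
            sd_masked[sel] = _running_mean(floored[sel], sd_smooth_window)
        sd = sd_masked

    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_diff / (sd * scale)
    t[~mask] = np.nan
    return TStatTrack(mean1, mean2, mean_diff, sd, t, mask, smoothed.sites)


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with window truncation at the ends."""
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def find_regions(tstat: TStatTrack, params: DmrParams = DmrParams()) -> list[CandidateRegion]:
    """Segment maximal same-sign runs of masked sites with |t| >= cutoff and
    inter-site gaps <= max_gap; keep those meeting the CpG-count and
    mean-difference minima."""
    chroms = tstat.sites["chrom"].to_numpy()
    pos = tstat.sites["pos"].to_numpy()
    masked = np.flatnonzero(tstat.mask)
    regions: list[CandidateRegion] = []
    run: list[int] = []

    def flush():
        if not run:
            return
        members = np.array(run, dtype=np.int64)
        if members.size < params.min_cpgs:
            run.clear()
            return
        md = float(tstat.mean_diff[members].mean())
        if abs(md) < params.min_meandiff:
            run.clear()
            return
        area = float(tstat.t[members].sum())
        regions.append(
            CandidateRegion(
                chrom=str(chroms[members[0]]),
                start=int(pos[members[0]]),
                end=int(pos[members[-1]]),
                n_cpgs=int(members.size),
                mean_diff=md,
                area_stat=area,
                direction=int(np.sign(area)),
                member_idx=members,
            )
        )
        run.clear()

    prev = -1
    for j in masked:
        t = tstat.t[j]
        passing = np.isfinite(t) and abs(t) >= params.cutoff
        if not passing:
            flush()
            prev = j
            continue
        if run:
            same_chrom = chroms[j] == chroms[run[-1]]
            same_sign = np.sign(t) == np.sign(tstat.t[run[-1]])
            close = same_chrom and pos[j] - pos[run[-1]] <= params.max_gap
            contiguous = prev == run[-1]  # no sub-cutoff masked site between
            if not (same_sign and close and contiguous):
                flush()
        run.append(j)
        prev = j
    flush()
    return regions


def balanced_permutations(design: GroupDesign) -> list[GroupDesign]:
    """All genotype-balanced relabelings of the samples.

    Each pseudo-group receives exactly half of every genotype's samples;
    assignments equivalent under a group-label swap are counted once, and the
    observed assignment (or its swap) is excluded if it happens to be
    balanced.  For a 4+4 genotype-vs-genotype design this enumerates
    C(4,2) * C(4,2) / 2 = 18 permutations.
    """
    genotypes = np.array(design.genotypes)
    n = len(genotypes)
    counts = pd.Series(genotypes).value_counts()
    if (counts % 2).any():
        raise ValueError(f"genotype counts must be even for balancing: {counts.to_dict()}")
    n1 = len(design.group_indices(1))
    if n1 * 2 != n:
        raise ValueError("balanced permutations require equal group sizes")

    observed = frozenset(design.group_indices(1).tolist())
    observed_swap = frozenset(range(n)) - observed
    out: list[GroupDesign] = []
    for combo in combinations(range(n), n1):
        group1 = frozenset(combo)
        if 0 not in group1:  # canonical representative under label swap
            continue
        balanced = all(
            sum(1 for i in group1 if genotypes[i] == g) * 2 == c for g, c in counts.items()
        )
        if not balanced or group1 in (observed, observed_swap):
            continue
        groups = tuple(1 if i in group1 else 2 for i in range(n))
        out.append(design.with_groups(groups))
    return out


def null_regions(
    smoothed: SmoothedTrack,
    permuted_design: GroupDesign,
    mask: np.ndarray,
    params: DmrParams = DmrParams(),
    **tstat_kwargs,
) -> list[CandidateRegion]:
    """Candidate regions under a permuted labeling (smoothing is label-free
    and reused; the sd floor and smoothing are recomputed under the permuted
    labels, mimicking the observed procedure)."""
    t = compute_tstat(smoothed, permuted_design, mask, **tstat_kwargs)
    return find_regions(t, params)


def assign_gfwer(
    observed: Sequence[CandidateRegion],
    nulls: Sequence[Sequence[CandidateRegion]],
) -> list[CandidateRegion]:
    """gFWER per observed region: fraction of permutations containing a null
    region at least as good on both CpG count and |areaStat| (ties count
    against the observed region)."""
    if len(nulls) < 1:
        raise ValueError("need at least one permutation")
    null_stats = [
        np.array([[b.n_cpgs, abs(b.area_stat)] for b in perm]).reshape(-1, 2) for perm in nulls
    ]
    out = []
    for d in observed:
        n_better = sum(
            1
            for stats in null_stats
            if stats.size and ((stats[:, 0] >= d.n_cpgs) & (stats[:, 1] >= abs(d.area_stat))).any()
        )
        out.append(replace(d, gfwer=n_better / len(nulls), member_idx=d.member_idx))
    return out


def regions_to_dataframe(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_cpgs": r.n_cpgs,
                "meanDiff": r.mean_diff,
                "areaStat": r.area_stat,
                "direction": r.direction,
                "gFWER": r.gfwer,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "n_cpgs", "meanDiff", "areaStat", "direction", "gFWER"],
    )


def write_regions(regions: Sequence[CandidateRegion], path: str | Path, fmt: str = "tsv") -> None:
    """Write regions as TSV (1-based inclusive) or BED (0-based half-open,
    spanning the C of the first site through the G of the last)."""
    df = regions_to_dataframe(regions)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif fmt == "bed":
        bed = df.assign(start=df["start"] - 1, end=df["end"] + 1)
        bed.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
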