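"""Kernel-weighted local polynomial smoothing of methylation proportions.

Each sample's observed proportions M/Cov are fit, site by site, with a
weighted local quadratic regression on genomic position.  The window around a
site extends ``max(h, distance to the ns-th nearest covered site)`` to each
side, so it always holds at least ``ns`` informative CpGs and is at least
``2h`` wide; weights are read coverage times a tricube kernel of scaled
distance.  Sites with zero coverage in a sample — CpGs that do not exist in
that sample's genome, or were simply unmeasured — get kernel weight zero but
still receive a fitted value, which is how genotype-unique CpGs contribute to
(and are imputed at) positions shared across genotypes.

Gaps larger than ``max_gap`` split the genome into independent clusters;
windows never cross cluster boundaries.  Fitted values are clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .meth_io import MethMatrix

__all__ = [
    "SmoothingParams",
    "BLOCK_PRESET",
    "SmoothedTrack",
    "cluster_sites",
    "smooth_sample",
    "smooth_matrix",
]


@dataclass(frozen=True)
class SmoothingParams:
    """ns: minimum covered CpGs per window; h: minimum half-width in bp;
    max_gap: bp gap splitting smoothing clusters.

    Defaults are the standard small-DMR preset; :data:`BLOCK_PRESET` widens
    the window for large-block analysis.
    """

    ns: int = 70
    h: float = 1000.0
    max_gap: int = 10**8

    def __post_init__(self):
        if self.ns < 1 or self.h <= 0 or self.max_gap <= 0:
            raise ValueError("require ns >= 1, h > 0, max_gap > 0")


BLOCK_PRESET = SmoothingParams(ns=500, h=20_000.0, max_gap=10**8)


@dataclass
class SmoothedTrack:
    """Per-sample fitted methylation at every union site.

    ``values`` is (n_samples, n_sites) in [0, 1] (NaN where a sample had no
    covered site in the whole cluster); ``imputed`` flags cells with zero
    observed coverage.
    """

    sites: pd.DataFrame
    values: np.ndarray
    imputed: np.ndarray
    samples: list[str]
    genotypes: list[str]
    params: SmoothingParams

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tsample\tsmoothed\timputed\n")
            chroms = self.sites["chrom"].to_numpy()
            pos = self.sites["pos"].to_numpy()
            for i, sample in enumerate(self.samples):
                for j in range(len(pos)):
                    fh.write(
                        f"{chroms[j]}\t{pos[j]}\t{sample}\t{self.values[i, j]:.6g}"
                        f"\t{int(self.imputed[i, j])}\n"
                    )

    def to_bedgraph(self, sample_id: str, path: str | Path) -> None:
        i = self.samples.index(sample_id)
        chroms = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        with open(path, "w") as fh:
            for j in range(len(pos)):
                v = self.values[i, j]
                if np.isfinite(v):
                    fh.write(f"{chroms[j]}\t{pos[j] - 1}\t{pos[j] + 1}\t{v:.6g}\n")


def cluster_sites(positions: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Partition sorted positions into half-open index ranges such that
    consecutive sites within a range are <= max_gap apart."""
    positions = np.asarray(positions)
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
    bounds = np.concatenate([[0], breaks, [positions.size]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def _half_widths(cpos: np.ndarray, targets: np.ndarray, ns: int, h: float) -> np.ndarray:
    """Per-target half-width: max(h, distance to the ns-th nearest covered
    site), with ns capped at the number of covered sites in the cluster."""
    ns_eff = min(ns, cpos.size)
    i = np.searchsorted(cpos, targets)
    best = np.full(targets.shape, np.inf)
    lo_k = np.clip(i - ns_eff, 0, cpos.size - ns_eff)
    hi_k = np.clip(i, 0, cpos.size - ns_eff)
    for off in range(ns_eff + 1):
        k = np.minimum(lo_k + off, hi_k)
        span = np.maximum(targets - cpos[k], cpos[k + ns_eff - 1] - targets)
        best = np.minimum(best, span)
    return np.maximum(best, h)


def smooth_sample(
    m_row: np.ndarray,
    cov_row: np.ndarray,
    positions: np.ndarray,
    params: SmoothingParams = SmoothingParams(),
) -> np.ndarray:
    """Smooth one sample's counts over all sites (covered or not).

    Returns fitted values in [0, 1]; NaN for sites in clusters where the
    sample has no covered site at all.  On rank-deficient windows the
    polynomial degree drops 2 -> 1 -> 0 rather than failing.
    """
    positions = np.asarray(positions, dtype=np.float64)
    m_row = np.asarray(m_row, dtype=np.float64)
    cov_row = np.asarray(cov_row, dtype=np.float64)
    out = np.full(positions.shape, np.nan)

    for a, b in cluster_sites(positions, params.max_gap):
        pos_c = positions[a:b]
        cov_c = cov_row[a:b]
        covered = cov_c > 0
        if not covered.any():
            continue
        cpos = pos_c[covered]
        prop = m_row[a:b][covered] / cov_c[covered]
        wcov = cov_c[covered]
        widths = _half_widths(cpos, pos_c, params.ns, params.h)
        fitted = np.empty(pos_c.shape)
        for j, x in enumerate(pos_c):
            w = widths[j]
            lo = np.searchsorted(cpos, x - w, side="left")
            hi = np.searchsorted(cpos, x + w, side="right")
            d = (cpos[lo:hi] - x) / w
            u = np.abs(d)
            kern = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0) * wcov[lo:hi]
            if kern.sum() <= 0.0:
                # only boundary sites (u == 1) in range: coverage-weighted mean
                kern = wcov[lo:hi] * (u <= 1.0)
            fitted[j] = _wls_fit(d, prop[lo:hi], kern)
        out[a:b] = np.clip(fitted, 0.0, 1.0)
    return out


def _wls_fit(d: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted polynomial fit of y on centered scaled distance d, evaluated
    at d = 0 (the intercept).  Degree 2 when the window holds >= 3 distinct
    weighted positions, else 1, else 0."""
    active = w > 0
    n_distinct = np.unique(d[active]).size
    degree = 2 if n_distinct >= 3 else (1 if n_distinct == 2 else 0)
    if degree == 0:
        ws = w[active].sum()
        return float((w[active] * y[active]).sum() / ws) if ws > 0 else np.nan
    cols = [np.ones_like(d), d] if degree == 1 else [np.ones_like(d), d, d * d]
    X = np.stack(cols, axis=1)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return float(beta[0])


def smooth_matrix(matrix: MethMatrix, params: SmoothingParams = SmoothingParams()) -> SmoothedTrack:
    """Smooth every sample over the full union site list.

    Per-sample zero-coverage sites (including CpGs unique to other
    genotypes) receive imputed values, so nearby genotype-unique CpGs
    influence the fitted curve at shared sites.  Clusters are computed per
    chromosome.
    """
    n_samples, n_sites = matrix.n_samples, matrix.n_sites
    values = np.full((n_samples, n_sites), np.nan)
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        for i in range(n_samples):
            values[i, sel] = smooth_sample(
                matrix.M[i, sel], matrix.Cov[i, sel], pos[sel], params
            )
    return SmoothedTrack(
        matrix.sites,
        values,
        matrix.Cov == 0,
        list(matrix.samples),
        list(matrix.genotypes),
        params,
    )
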