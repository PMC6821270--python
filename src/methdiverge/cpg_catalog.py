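"""CpG enumeration and cross-genome classification.

A CpG site is identified by the 1-based position of the C of a forward-strand
CG dinucleotide; the reverse-strand C at ``pos + 1`` belongs to the same site
(read counts from both strands are combined per site in :mod:`meth_io`).

Classifying every CpG of genome A by its dinucleotide status in genome B
partitions A's CpG set into four categories:

``COMMON_CG``
    the mapped dinucleotide in B is still CG (site shared by both genomes);
``TG_CA``
    the mapped dinucleotide is TG or CA — the signature of C>T deamination on
    either strand, the dominant CpG mutation class, and the one that silently
    yields 0%-methylation calls under wrong-reference alignment;
``OTHER_MUT``
    any other mapped dinucleotide (the CpG is lost in B some other way);
``UNMAPPABLE``
    the site could not be carried across (C or G position falls inside an
    indel, or the two images are no longer adjacent).

The fraction of non-common CpGs is the *CpG mutation rate* between the two
genomes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genomes import CoordinateMap

__all__ = [
    "COMMON_CG",
    "TG_CA",
    "OTHER_MUT",
    "UNMAPPABLE_CAT",
    "CATEGORIES",
    "find_cpgs",
    "classify_cross_genome",
    "mutation_rate",
    "mutation_rate_from_counts",
    "binned_mutation_rate",
    "feature_mutation_rate",
    "read_bed",
]

COMMON_CG = "COMMON_CG"
TG_CA = "TG_CA"
OTHER_MUT = "OTHER_MUT"
UNMAPPABLE_CAT = "UNMAPPABLE"
CATEGORIES = (COMMON_CG, TG_CA, OTHER_MUT, UNMAPPABLE_CAT)

_UNIQUE_CATEGORIES = (TG_CA, OTHER_MUT, UNMAPPABLE_CAT)

#: Published genome-wide census of CpG category counts between the mouse
#: reference strain C57BL/6J (BL6, mm9 assembly) and the wild-derived
#: CAST/EiJ strain, tabulated separately for autosomes and sex chromosomes.
#: Each strain's CpGs are classified against the other strain's genome; the
#: common-CG count is shared between the two strains by construction.
BL6_CAST_CPG_CENSUS: dict[str, dict[str, dict[str, int]]] = {
    "autosomes": {
        "BL6": {COMMON_CG: 18_140_628, TG_CA: 1_601_446, OTHER_MUT: 522_845, UNMAPPABLE_CAT: 99_781},
        "CAST": {COMMON_CG: 18_140_628, TG_CA: 1_669_901, OTHER_MUT: 535_219, UNMAPPABLE_CAT: 90_356},
    },
    "allosomes": {
        "BL6": {COMMON_CG: 916_392, TG_CA: 43_330, OTHER_MUT: 15_394, UNMAPPABLE_CAT: 2_676},
        "CAST": {COMMON_CG: 916_392, TG_CA: 45_041, OTHER_MUT: 15_838, UNMAPPABLE_CAT: 2_438},
    },
}

#: Printed per-column totals of the same census, for partition checks.
BL6_CAST_CPG_TOTALS: dict[str, dict[str, int]] = {
    "autosomes": {"BL6": 20_364_700, "CAST": 20_436_104},
    "allosomes": {"BL6": 977_792, "CAST": 979_709},
}


def find_cpgs(sequence: str) -> np.ndarray:
    """1-based positions of every forward-strand CG dinucleotide, ascending.

    Dinucleotides containing N (or any non-ACGT code) never qualify.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.array([], dtype=np.int64)
    is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(is_cg).astype(np.int64) + 1


def classify_cross_genome(
    cpgs_a: Mapping[str, np.ndarray],
    cmap: CoordinateMap,
    genome_b: Mapping[str, str],
    direction: str = "to_personal",
) -> pd.DataFrame:
    """Label every CpG of genome A by its dinucleotide status in genome B.

    ``cpgs_a`` maps chromosome -> sorted C positions from :func:`find_cpgs`
    on genome A.  ``cmap`` relates A and B coordinates (``direction`` chooses
    which side of the map A is on).  Returns a DataFrame with columns
    ``chrom, pos, category, mapped_pos`` (mapped_pos = -1 when unmappable);
    the categories partition the input CpG set.
    """
    frames = []
    for chrom, positions in cpgs_a.items():
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in cmap.blocks:
            raise KeyError(f"chromosome {chrom!r} missing from coordinate map")
        mapped_c = cmap.map_positions(chrom, positions, direction)
        src_len = cmap.chrom_lengths[chrom][0 if direction == "to_personal" else 1]
        g_pos = positions + 1
        mapped_g = np.full(positions.shape, -1, dtype=np.int64)
        ok_g = g_pos <= src_len
        if ok_g.any():
            mapped_g[ok_g] = cmap.map_positions(chrom, g_pos[ok_g], direction)

        # both positions must map and stay adjacent, else the site straddles
        # an indel and cannot be carried across
        mappable = (mapped_c >= 0) & (mapped_g == mapped_c + 1)
        category = np.full(positions.shape, UNMAPPABLE_CAT, dtype=object)

        if chrom not in genome_b:
            raise KeyError(f"chromosome {chrom!r} missing from genome B")
        seq_b = np.frombuffer(genome_b[chrom].upper().encode("ascii"), dtype=np.uint8)
        idx = mapped_c[mappable] - 1
        first = seq_b[idx]
        second = seq_b[idx + 1]
        is_cg = (first == ord("C")) & (second == ord("G"))
        is_tg = (first == ord("T")) & (second == ord("G"))
        is_ca = (first == ord("C")) & (second == ord("A"))
        sub = np.full(idx.shape, OTHER_MUT, dtype=object)
        sub[is_cg] = COMMON_CG
        sub[is_tg | is_ca] = TG_CA
        category[mappable] = sub

        mapped_out = np.where(mappable, mapped_c, -1)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": positions, "category": category, "mapped_pos": mapped_out}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "category", "mapped_pos"])
    return pd.concat(frames, ignore_index=True)


def mutation_rate(classifications: pd.DataFrame) -> float:
    """Fraction of CpGs that are unique to genome A (mutated, lost or
    unmappable in B)."""
    if len(classifications) == 0:
        raise ValueError("mutation_rate of an empty classification set is undefined")
    unique = classifications["category"].isin(_UNIQUE_CATEGORIES).sum()
    return float(unique) / float(len(classifications))


def mutation_rate_from_counts(counts: Mapping[str, int]) -> float:
    """Mutation rate from tabulated per-category counts (e.g. a published
    genome-wide census)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty counts")
    unique = sum(counts.get(c, 0) for c in _UNIQUE_CATEGORIES)
    return unique / total


def binned_mutation_rate(
    classifications: pd.DataFrame,
    bin_size: int,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """CpG mutation rate in fixed-width bins tiling each chromosome from
    position 1 (last bin may be short).  Bins without CpGs get rate NaN.

    Returns columns ``chrom, bin_start, n_total, n_unique, rate``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = classifications[classifications["chrom"] == chrom]
        n_bins = max(1, -(-length // bin_size))
        bin_idx = (sub["pos"].to_numpy() - 1) // bin_size
        total = np.bincount(bin_idx, minlength=n_bins).astype(np.int64)
        uniq_mask = sub["category"].isin(_UNIQUE_CATEGORIES).to_numpy()
        uniq = np.bincount(bin_idx[uniq_mask], minlength=n_bins).astype(np.int64)
        rate = np.where(total > 0, uniq / np.maximum(total, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": np.arange(n_bins, dtype=np.int64) * bin_size + 1,
                    "n_total": total,
                    "n_unique": uniq,
                    "rate": rate,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def feature_mutation_rate(
    classifications: pd.DataFrame,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Mutation rate per feature label.

    ``features`` is BED-style: columns ``chrom, start, end, label`` with
    0-based half-open intervals.  A CpG counts toward a label when its C
    position lies in any interval of that label; overlapping labels each
    count the CpG.  Labels covering no CpG get rate NaN.
    """
    if (features["end"] <= features["start"]).any():
        bad = features[features["end"] <= features["start"]].iloc[0]
        raise ValueError(f"malformed interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    rows = []
    for label, feat in features.groupby("label", sort=True):
        n_total = 0
        n_unique = 0
        for chrom, intervals in feat.groupby("chrom"):
            sub = classifications[classifications["chrom"] == chrom]
            if len(sub) == 0:
                continue
            pos = sub["pos"].to_numpy()
            uniq = sub["category"].isin(_UNIQUE_CATEGORIES).to_numpy()
            member = np.zeros(len(pos), dtype=bool)
            # merge intervals so overlapping features of one label count once
            ivs = sorted(zip(intervals["start"], intervals["end"]))
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                member |= (pos >= s + 1) & (pos <= e)  # 1-based C inside [s, e)
            n_total += int(member.sum())
            n_unique += int((member & uniq).sum())
        rate = n_unique / n_total if n_total else np.nan
        rows.append({"label": label, "n_total": n_total, "n_unique": n_unique, "rate": rate})
    return pd.DataFrame(rows)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of labeled intervals (chrom, start, end[, label])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(label=".")
    df.columns = ["chrom", "start", "end", "label"]
    return df
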