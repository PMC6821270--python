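"""Personal (pseudo)genome construction and coordinate maps.

A personal genome is built by applying a curated set of SNVs and indels to a
reference sequence.  Because indels change sequence length, positions in the
reference and the personal genome are related by a monotone piecewise map:
runs of colinear sequence map by a constant offset, while positions inside an
insertion or deletion have no image in the other genome and are *unmappable*.
This is the same contract as UCSC liftOver restricted to maps induced by a
variant set.

Coordinates are 1-based inclusive throughout the API (the convention of
Bismark and most methylation tooling); BED output elsewhere in the package is
0-based half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "UNMAPPABLE",
    "Variant",
    "VariantSet",
    "CoordinateMap",
    "PersonalGenome",
    "build_pseudogenome",
    "map_position",
    "map_sites",
    "identity_map",
    "read_fasta",
    "write_fasta",
    "read_vcf",
]

Direction = Literal["to_personal", "to_reference"]

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"

_VALID_BASES = frozenset("ACGT")


class _Unmappable:
    """Sentinel for positions that fall inside an indel in the other genome.

    Falsy and unequal to every integer; serialized as -1 in the liftover TSV
    dialect for interoperability with modmap-style output.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNMAPPABLE"

    def __bool__(self) -> bool:
        return False


UNMAPPABLE = _Unmappable()


class PositionError(ValueError):
    """Raised for out-of-bounds positions; distinct from the UNMAPPABLE result."""


@dataclass(frozen=True)
class Variant:
    """A single SNV or indel in VCF padding convention.

    ``pos`` is the 1-based reference position of the first base of
    ``ref_allele``.  An empty ``alt_allele`` with ``len(ref_allele) > 1``
    denotes a full deletion of the ref span.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    zygosity: str = HOMOZYGOUS

    def __post_init__(self):
        if not self.ref_allele or set(self.ref_allele) - _VALID_BASES:
            raise ValueError(f"bad ref allele {self.ref_allele!r} at {self.chrom}:{self.pos}")
        if set(self.alt_allele) - _VALID_BASES:
            raise ValueError(f"bad alt allele {self.alt_allele!r} at {self.chrom}:{self.pos}")
        if self.zygosity not in (HOMOZYGOUS, HETEROZYGOUS):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def end(self) -> int:
        """Last 1-based reference position covered by the ref allele."""
        return self.pos + len(self.ref_allele) - 1


class VariantSet:
    """Per-chromosome, position-sorted, non-overlapping variants."""

    def __init__(self, variants: Iterable[Variant]):
        by_chrom: dict[str, list[Variant]] = {}
        for v in variants:
            by_chrom.setdefault(v.chrom, []).append(v)
        for chrom, vs in by_chrom.items():
            vs.sort(key=lambda v: v.pos)
            for a, b in zip(vs, vs[1:]):
                if b.pos <= a.end:
                    raise ValueError(
                        f"overlapping variants at {chrom}:{a.pos} and {chrom}:{b.pos}"
                    )
        self._by_chrom = by_chrom

    def __iter__(self):
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def for_chrom(self, chrom: str) -> list[Variant]:
        return self._by_chrom.get(chrom, [])

    def validate_against(self, reference: Mapping[str, str]) -> None:
        for chrom, vs in self._by_chrom.items():
            if chrom not in reference:
                raise ValueError(f"variant chromosome {chrom!r} not in reference")
            seq = reference[chrom]
            for v in vs:
                if v.end > len(seq):
                    raise PositionError(f"variant at {chrom}:{v.pos} exceeds chromosome end")
                observed = seq[v.pos - 1 : v.end]
                if observed != v.ref_allele:
                    raise ValueError(
                        f"ref mismatch at {chrom}:{v.pos}: expected "
                        f"{v.ref_allele!r}, reference has {observed!r}"
                    )


@dataclass
class CoordinateMap:
    """Monotone piecewise map between reference and personal coordinates.

    ``blocks[chrom]`` is an (n, 3) int array of colinear blocks
    ``(ref_start, personal_start, length)``, 1-based, strictly increasing and
    non-overlapping in both coordinate systems.  Positions between blocks are
    unmappable.
    """

    blocks: dict[str, np.ndarray]
    chrom_lengths: dict[str, tuple[int, int]]  # (ref_len, personal_len)

    def map_position(self, chrom: str, pos: int, direction: Direction = "to_personal"):
        return map_position(self, chrom, pos, direction)

    def map_positions(
        self, chrom: str, positions: np.ndarray, direction: Direction = "to_personal"
    ) -> np.ndarray:
        """Vectorized mapping; returns -1 for unmappable positions."""
        if chrom not in self.blocks:
            raise KeyError(f"chromosome {chrom!r} not in coordinate map")
        src_col, dst_col = (0, 1) if direction == "to_personal" else (1, 0)
        src_len = self.chrom_lengths[chrom][0 if direction == "to_personal" else 1]
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size and (positions.min() < 1 or positions.max() > src_len):
            bad = positions[(positions < 1) | (positions > src_len)][0]
            raise PositionError(f"position {chrom}:{bad} outside chromosome (len {src_len})")
        blk = self.blocks[chrom]
        if blk.shape[0] == 0:
            return np.full(positions.shape, -1, dtype=np.int64)
        starts = blk[:, src_col]
        idx = np.searchsorted(starts, positions, side="right") - 1
        idx_c = np.clip(idx, 0, blk.shape[0] - 1)
        inside = (idx >= 0) & (positions < starts[idx_c] + blk[idx_c, 2])
        out = np.full(positions.shape, -1, dtype=np.int64)
        out[inside] = blk[idx_c[inside], dst_col] + (positions[inside] - starts[idx_c[inside]])
        return out

    def reversed(self) -> "CoordinateMap":
        """The same map with the personal genome as the reference side, so
        personal coordinates can serve as the target system."""
        blocks = {}
        for chrom, blk in self.blocks.items():
            swapped = blk[:, [1, 0, 2]]
            blocks[chrom] = swapped[np.argsort(swapped[:, 0])]
        lengths = {c: (pl, rl) for c, (rl, pl) in self.chrom_lengths.items()}
        return CoordinateMap(blocks, lengths)

    # --- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tref_start\tpersonal_start\tlength\tref_len\tpersonal_len\n")
            for chrom in sorted(self.blocks):
                rl, pl = self.chrom_lengths[chrom]
                blk = self.blocks[chrom]
                if blk.shape[0] == 0:
                    fh.write(f"{chrom}\t.\t.\t.\t{rl}\t{pl}\n")
                for r, p, ln in blk:
                    fh.write(f"{chrom}\t{r}\t{p}\t{ln}\t{rl}\t{pl}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoordinateMap":
        blocks: dict[str, list[tuple[int, int, int]]] = {}
        lengths: dict[str, tuple[int, int]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                chrom, r, p, ln, rl, pl = line.rstrip("\n").split("\t")
                lengths[chrom] = (int(rl), int(pl))
                blocks.setdefault(chrom, [])
                if r != ".":
                    blocks[chrom].append((int(r), int(p), int(ln)))
        return cls(
            {c: np.array(b, dtype=np.int64).reshape(-1, 3) for c, b in blocks.items()},
            lengths,
        )


@dataclass
class PersonalGenome:
    """A reference with one genotype's variants applied.

    ``het_sites`` holds, per chromosome, the sorted reference positions
    spanned by heterozygous variant ref alleles, for downstream per-sample
    filtering.
    """

    sequences: dict[str, str]
    reference_id: str = ""
    variant_set_id: str = ""
    het_policy: str = "reference"
    het_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def identity_map(chrom_lengths: Mapping[str, int]) -> CoordinateMap:
    """The coordinate map of a genome against itself (or after SNVs only)."""
    return CoordinateMap(
        {c: np.array([[1, 1, n]], dtype=np.int64) for c, n in chrom_lengths.items()},
        {c: (n, n) for c, n in chrom_lengths.items()},
    )


def build_pseudogenome(
    reference: Mapping[str, str],
    variants: VariantSet,
    het_policy: Literal["reference", "alternate", "exclude"] = "reference",
    reference_id: str = "",
    variant_set_id: str = "",
) -> tuple[PersonalGenome, CoordinateMap]:
    """Apply a variant set to a reference and derive the coordinate map.

    Homozygous variants are always applied.  Heterozygous variants follow
    ``het_policy``: ``reference`` and ``exclude`` keep the reference allele
    (so only homozygous indels move coordinates); ``alternate`` applies the
    alt allele.  Heterozygous sites are recorded for downstream filtering
    under every policy.

    Returns the personal genome and the reference->personal CoordinateMap.
    """
    if het_policy not in ("reference", "alternate", "exclude"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    variants.validate_against(reference)

    sequences: dict[str, str] = {}
    blocks: dict[str, np.ndarray] = {}
    lengths: dict[str, tuple[int, int]] = {}
    het_sites: dict[str, np.ndarray] = {}

    for chrom, seq in reference.items():
        pieces: list[str] = []
        chrom_blocks: list[tuple[int, int, int]] = []
        het_pos: list[int] = []
        cursor = 0  # 0-based index of next unconsumed reference base
        offset = 0  # personal_pos - ref_pos inside the open block
        block_ref_start = 1

        for v in variants.for_chrom(chrom):
            apply_alt = v.zygosity == HOMOZYGOUS or het_policy == "alternate"
            if v.zygosity == HETEROZYGOUS:
                het_pos.extend(range(v.pos, v.end + 1))
            if not apply_alt:
                continue
            pieces.append(seq[cursor : v.pos - 1])
            pieces.append(v.alt_allele)
            cursor = v.end  # consumed through the ref allele
            if v.is_indel:
                k = min(len(v.ref_allele), len(v.alt_allele))
                colinear_end = v.pos + k - 1  # may be pos-1 when alt is empty
                length = colinear_end - block_ref_start + 1
                if length > 0:
                    chrom_blocks.append((block_ref_start, block_ref_start + offset, length))
                offset += len(v.alt_allele) - len(v.ref_allele)
                block_ref_start = v.end + 1

        pieces.append(seq[cursor:])
        personal_seq = "".join(pieces)
        tail = len(seq) - block_ref_start + 1
        if tail > 0:
            chrom_blocks.append((block_ref_start, block_ref_start + offset, tail))

        sequences[chrom] = personal_seq
        blocks[chrom] = np.array(chrom_blocks, dtype=np.int64).reshape(-1, 3)
        lengths[chrom] = (len(seq), len(personal_seq))
        if het_pos:
            het_sites[chrom] = np.unique(np.array(het_pos, dtype=np.int64))

    genome = PersonalGenome(
        sequences,
        reference_id=reference_id,
        variant_set_id=variant_set_id,
        het_policy=het_policy,
        het_sites=het_sites,
    )
    return genome, CoordinateMap(blocks, lengths)


def map_position(cmap: CoordinateMap, chrom: str, pos: int, direction: Direction = "to_personal"):
    """Map a single 1-based position; returns UNMAPPABLE inside indel gaps.

    Out-of-bounds positions raise :class:`PositionError` instead.
    """
    if chrom not in cmap.blocks:
        raise KeyError(f"chromosome {chrom!r} not in coordinate map")
    src_len = cmap.chrom_lengths[chrom][0 if direction == "to_personal" else 1]
    if not 1 <= pos <= src_len:
        raise PositionError(f"position {chrom}:{pos} outside chromosome (len {src_len})")
    src_col, dst_col = (0, 1) if direction == "to_personal" else (1, 0)
    blk = cmap.blocks[chrom]
    starts = blk[:, src_col]
    i = bisect.bisect_right(starts.tolist(), pos) - 1
    if i < 0 or pos >= starts[i] + blk[i, 2]:
        return UNMAPPABLE
    return int(blk[i, dst_col] + (pos - starts[i]))


def map_sites(
    cmap: CoordinateMap,
    chrom: str,
    positions: Sequence[int] | np.ndarray,
    direction: Direction = "to_personal",
    dinucleotide: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a sorted list of site positions, discarding unmappable ones.

    With ``dinucleotide=True`` (the CpG convention) a site at ``pos`` is kept
    only when both the C position and the following G position (``pos + 1``)
    map — a CpG straddling an indel edge is discarded, mirroring the rule of
    dropping liftover output with negative positions on either strand.

    Returns ``(kept_source_positions, mapped_positions, discarded_source_positions)``,
    order-preserving.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        e = np.array([], dtype=np.int64)
        return e, e.copy(), e.copy()
    mapped_c = cmap.map_positions(chrom, positions, direction)
    ok = mapped_c >= 0
    if dinucleotide:
        src_len = cmap.chrom_lengths[chrom][0 if direction == "to_personal" else 1]
        g_pos = positions + 1
        in_bounds = g_pos <= src_len
        mapped_g = np.full(positions.shape, -1, dtype=np.int64)
        if in_bounds.any():
            mapped_g[in_bounds] = cmap.map_positions(chrom, g_pos[in_bounds], direction)
        ok &= mapped_g >= 0
    return positions[ok], mapped_c[ok], positions[~ok]


# --- file formats ---------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_vcf(path: str | Path, sample: str | None = None) -> VariantSet:
    """Read SNVs and indels from a VCF; GT of the first (or named) sample
    determines zygosity.  Multi-allelic records must be pre-split
    (``bcftools norm -m-``) and are rejected."""
    import pysam

    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if sample is None and sample_names:
            sample = sample_names[0]
        for rec in vcf:
            if rec.alts is None:
                continue
            if len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; split with bcftools norm first"
                )
            alt = rec.alts[0]
            if set(rec.ref) - _VALID_BASES or set(alt) - _VALID_BASES:
                continue  # symbolic / spanning alleles are not sequence edits
            zyg = HOMOZYGOUS
            if sample is not None:
                gt = rec.samples[sample].get("GT")
                if gt is not None and len(set(a for a in gt if a is not None)) > 1:
                    zyg = HETEROZYGOUS
            variants.append(Variant(rec.chrom, rec.pos, rec.ref, alt, zyg))
    return VariantSet(variants)


def write_vcf(variants: VariantSet, path: str | Path, sample: str = "SAMPLE") -> None:
    """Write a minimal single-sample VCF with GT encoding zygosity."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = variants.chroms
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in variants:
            gt = "1/1" if v.zygosity == HOMOZYGOUS else "0/1"
            alt = v.alt_allele if v.alt_allele else "<DEL>"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def write_liftover_tsv(
    cmap: CoordinateMap,
    chrom: str,
    positions: Sequence[int],
    path: str | Path,
    direction: Direction = "to_personal",
) -> None:
    """Per-site liftover table `chrom pos_src pos_dst` with -1 for unmappable."""
    mapped = cmap.map_positions(chrom, np.asarray(positions, dtype=np.int64), direction)
    with open(path, "w") as fh:
        for p, m in zip(positions, mapped):
            fh.write(f"{chrom}\t{p}\t{m}\n")
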