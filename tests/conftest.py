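"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methdiverge.genomes import Variant, VariantSet, build_pseudogenome


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def random_variant_set(
    rng: np.random.Generator,
    seq: str,
    chrom: str = "chr1",
    n_snv: int = 20,
    n_indel: int = 5,
    het_fraction: float = 0.0,
) -> VariantSet:
    """Random non-overlapping SNVs and small indels against ``seq``.

    Independent of the synth module: positions are drawn, sorted, and
    greedily accepted when they do not overlap the previous acceptance.
    """
    L = len(seq)
    events = []
    for _ in range(n_snv):
        p = int(rng.integers(1, L + 1))
        ref = seq[p - 1]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        events.append((p, ref, alt))
    for _ in range(n_indel):
        length = int(rng.integers(1, 5))
        if rng.random() < 0.5:  # deletion
            p = int(rng.integers(1, L - length))
            events.append((p, seq[p - 1 : p + length], seq[p - 1]))
        else:  # insertion
            p = int(rng.integers(1, L))
            ins = random_sequence(rng, length)
            events.append((p, seq[p - 1], seq[p - 1] + ins))
    events.sort(key=lambda e: e[0])
    accepted: list[Variant] = []
    last_end = 0
    for p, ref, alt in events:
        if p <= last_end:
            continue
        zyg = "heterozygous" if rng.random() < het_fraction else "homozygous"
        accepted.append(Variant(chrom, p, ref, alt, zyg))
        last_end = p + len(ref) - 1
    return VariantSet(accepted)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def small_genome_pair(rng):
    """A 10 kb reference, a random variant set, and the derived personal
    genome and coordinate map."""
    seq = random_sequence(rng, 10_000)
    variants = random_variant_set(rng, seq, n_snv=40, n_indel=10)
    personal, cmap = build_pseudogenome({"chr1": seq}, variants)
    return {"chr1": seq}, variants, personal, cmap
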