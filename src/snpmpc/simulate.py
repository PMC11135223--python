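"""Synthetic panels, VCFs, and families for testing and evaluation.

The generator emulates the structure of the tool's intended inputs at desk
scale: a toy reference genome (two chromosomes of 1 Mbp by default, standing
in for a real human reference), individuals whose variant sets are uniform
random SNPs over that reference (the analogue of a simuG-style simulation),
and parent-child trios with Mendelian-style inheritance emulating family
reference datasets such as the GIAB Ashkenazim and Chinese trios.

The reference allele at a site is a deterministic hash of (chromosome,
position), so every simulated individual and panel agrees on Ref at a
position, as real call sets against a shared reference do; the alternate
allele is drawn uniformly from the remaining three bases.

Inheritance is an independent per-site Bernoulli draw: a child receives
each parental variant with probability h (default 0.5, the expectation for
a heterozygous site), plus a small de novo fraction. There is no linkage or
recombination structure — sufficient for Jaccard-level kinship signal,
which is all the comparison protocols consume.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from math import sqrt
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import ProtocolConfig
from .encoding import Panel, VariantKey, encode
from .protocols import JaccardResult, secure_compare

_BASES = "ACGT"


@dataclass(frozen=True)
class ToyReference:
    """A miniature reference genome: named chromosomes with lengths in bp."""

    chromosomes: tuple = (("1", 1_000_000), ("2", 1_000_000))

    def __post_init__(self) -> None:
        chroms = tuple((str(label), int(length)) for label, length in self.chromosomes)
        if any(length < 1 for _, length in chroms):
            raise ValueError("chromosome lengths must be >= 1")
        labels = [label for label, _ in chroms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate chromosome labels in {labels}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def total_positions(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def position_at(self, offset: int) -> tuple[str, int]:
        """Map a global 0-based offset to (chromosome, 1-based position)."""
        for label, length in self.chromosomes:
            if offset < length:
                return label, offset + 1
            offset -= length
        raise IndexError("offset beyond reference end")

    def ref_base(self, chrom: str, pos: int) -> str:
        """Deterministic reference allele at a site (stable across runs)."""
        return _BASES[zlib.crc32(f"{chrom}:{pos}".encode()) & 3]


@dataclass
class SimulatedIndividual:
    """An individual's variant set, with optional recorded parentage."""

    id: str
    variant_set: set = field(default_factory=set)
    parents: Optional[tuple[str, str]] = None


def _random_variant(ref: ToyReference, offset: int, rng: random.Random) -> VariantKey:
    chrom, pos = ref.position_at(offset)
    ref_base = ref.ref_base(chrom, pos)
    alt = rng.choice([b for b in _BASES if b != ref_base])
    return VariantKey.snp(chrom, pos, ref_base, alt)


def _sample_variants(ref: ToyReference, count: int, rng: random.Random) -> set[VariantKey]:
    if count > ref.total_positions:
        raise ValueError(
            f"cannot place {count} variants on {ref.total_positions} positions"
        )
    offsets = rng.sample(range(ref.total_positions), count)
    return {_random_variant(ref, off, rng) for off in offsets}


def simulate_panel(reference: ToyReference, size: int, rng: random.Random) -> Panel:
    """A public panel of ``size`` distinct SNPs at uniform positions,
    sorted by (chromosome, position)."""
    keys = sorted(_sample_variants(reference, size, rng))
    return Panel(tuple(keys))


def panel_from_variants(
    variants: Iterable[VariantKey], size: int, rng: random.Random
) -> Panel:
    """A panel sampled from an observed variant universe.

    Emulates an informative published panel: every entry is a variant that
    segregates in some cohort, so panel bits carry signal instead of being
    almost surely zero for everyone.
    """
    universe = sorted(set(variants))
    if size > len(universe):
        raise ValueError(f"requested {size} entries from a universe of {len(universe)}")
    return Panel(tuple(sorted(rng.sample(universe, size))))


def simulate_individual(
    reference: ToyReference,
    n_variants: int,
    rng: random.Random,
    individual_id: str = "sim",
    out_vcf: Optional[str | Path] = None,
) -> SimulatedIndividual:
    """One individual with ``n_variants`` uniform SNPs; optionally write a VCF."""
    ind = SimulatedIndividual(individual_id, _sample_variants(reference, n_variants, rng))
    if out_vcf is not None:
        write_vcf(ind, reference, out_vcf, rng)
    return ind


def write_vcf(
    individual: SimulatedIndividual,
    reference: ToyReference,
    path: str | Path,
    rng: Optional[random.Random] = None,
) -> None:
    """Write a SNP-only VCF 4.2 file that round-trips through the strict reader.

    Genotypes are 0/1 or 1/1 (random when an rng is given, 0/1 otherwise);
    the comparison protocols are presence-only, so GT carries no weight
    unless the genotype-aware reading flag is used.
    """
    recs = sorted(individual.variant_set)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snpmpc-simulate\n")
        for label, length in reference.chromosomes:
            fh.write(f"##contig=<ID={label},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{individual.id}\n"
        )
        for k in recs:
            gt = "0/1" if rng is None else rng.choice(["0/1", "1/1"])
            fh.write(f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\tGT\t{gt}\n")


def simulate_trio(
    reference: ToyReference,
    n_variants: int = 10_000,
    inheritance_rate: float = 0.5,
    de_novo_rate: float = 0.001,
    rng: Optional[random.Random] = None,
    prefix: str = "trio",
) -> tuple[SimulatedIndividual, SimulatedIndividual, SimulatedIndividual]:
    """Simulate (father, mother, child) with per-site Bernoulli inheritance.

    Each parent carries ``n_variants`` uniform SNPs; the child inherits each
    parental variant independently with probability ``inheritance_rate``
    (a variant present in both parents gets two independent chances), plus
    ``round(de_novo_rate * n_variants)`` de novo variants at sites absent
    from both parents.
    """
    if not 0.0 <= inheritance_rate <= 1.0:
        raise ValueError(f"inheritance rate must be in [0, 1], got {inheritance_rate}")
    if rng is None:
        rng = random.Random()
    father = simulate_individual(reference, n_variants, rng, f"{prefix}-father")
    mother = simulate_individual(reference, n_variants, rng, f"{prefix}-mother")
    child_set: set[VariantKey] = set()
    for parent in (father, mother):
        for k in sorted(parent.variant_set):  # sorted: determinism under a fixed seed
            if rng.random() < inheritance_rate:
                child_set.add(k)
    n_de_novo = round(de_novo_rate * n_variants)
    parental = father.variant_set | mother.variant_set
    while n_de_novo > 0:
        k = _random_variant(ref=reference, offset=rng.randrange(reference.total_positions), rng=rng)
        if k not in parental and k not in child_set:
            child_set.add(k)
            n_de_novo -= 1
    child = SimulatedIndividual(
        f"{prefix}-child", child_set, parents=(father.id, mother.id)
    )
    return father, mother, child


def simulate_cohort(
    reference: ToyReference,
    n_trios: int,
    n_variants: int = 10_000,
    inheritance_rate: float = 0.5,
    de_novo_rate: float = 0.001,
    rng: Optional[random.Random] = None,
) -> list[SimulatedIndividual]:
    """``n_trios`` independent families, flattened to a list of individuals."""
    if rng is None:
        rng = random.Random()
    out: list[SimulatedIndividual] = []
    for i in range(n_trios):
        out.extend(
            simulate_trio(
                reference,
                n_variants=n_variants,
                inheritance_rate=inheritance_rate,
                de_novo_rate=de_novo_rate,
                rng=rng,
                prefix=f"trio{i:03d}",
            )
        )
    return out


# -- plaintext similarity and the panel-vs-whole evaluation ----------------


def jaccard_sets(a: set, b: set) -> Optional[Fraction]:
    """Plaintext Jaccard of two sets; None when both are empty."""
    union = len(a | b)
    if union == 0:
        return None
    return Fraction(len(a & b), union)


def related(x: SimulatedIndividual, y: SimulatedIndividual) -> bool:
    """Parent-child or sibling relationship, from recorded parentage."""
    if x.parents and y.id in x.parents:
        return True
    if y.parents and x.id in y.parents:
        return True
    if x.parents and y.parents and set(x.parents) & set(y.parents):
        return True
    return False


def panel_vs_whole_jaccard(
    individuals: Sequence[SimulatedIndividual],
    panel: Panel,
    config: Optional[ProtocolConfig] = None,
    pairs: Optional[Sequence[tuple[int, int]]] = None,
    secure: bool = True,
) -> pd.DataFrame:
    """Paired similarity table: whole-set vs panel-restricted Jaccard per pair.

    For every pair the whole-VCF Jaccard (on exact variant tuples) and the
    panel-restricted Jaccard are computed in plaintext; when ``secure`` is
    set the panel Jaccard is additionally computed through the full secure
    pipeline (encode, share, multiply, open) and must agree exactly —
    any disagreement raises.

    ``pairs`` restricts the table to the given index pairs; by default all
    pairs are compared, which is quadratic in the cohort size.
    """
    if len(individuals) < 2:
        raise ValueError("need at least two individuals to compare")
    if config is None:
        config = ProtocolConfig(scheme="additive", n_parties=2, seed=0)
    encoded = [encode(panel, ind.variant_set) for ind in individuals]
    if pairs is None:
        pairs = [
            (i, j)
            for i in range(len(individuals))
            for j in range(i + 1, len(individuals))
        ]
    panel_set = set(panel.entries)
    rows = []
    for i, j in pairs:
        x, y = individuals[i], individuals[j]
        whole = jaccard_sets(x.variant_set, y.variant_set)
        panel_a = x.variant_set & panel_set
        panel_b = y.variant_set & panel_set
        plain = jaccard_sets(panel_a, panel_b)
        row = {
            "id_a": x.id,
            "id_b": y.id,
            "related": related(x, y),
            "whole_jaccard": float(whole) if whole is not None else float("nan"),
            "panel_jaccard": float(plain) if plain is not None else float("nan"),
        }
        if secure:
            res: JaccardResult = secure_compare(
                encoded[i].bits, encoded[j].bits, config, op="jaccard",
                panel_digest=panel.digest,
            )
            if res.jaccard != plain:
                raise AssertionError(
                    f"secure Jaccard {res.jaccard} != plaintext {plain} "
                    f"for pair ({x.id}, {y.id})"
                )
            row["panel_jaccard_secure"] = (
                float(res.jaccard) if res.jaccard is not None else float("nan")
            )
            row["panel_intersection"] = res.intersection_size
            row["panel_union"] = res.union_size
        rows.append(row)
    return pd.DataFrame(rows)


def expected_unrelated_overlap(reference: ToyReference, n_variants: int) -> dict:
    """Closed-form overlap statistics for two independent individuals.

    The number of shared positions is hypergeometric (draws of size n from
    G positions); a shared position yields the same variant only when the
    two alternate alleles agree, probability 1/3. Returns the expectation
    and standard deviation of the shared-variant count and the
    corresponding (delta-method) expectation and SE of the Jaccard index.
    """
    G = reference.total_positions
    n = n_variants
    mean_h = n * n / G
    var_h = n * (n / G) * (1 - n / G) * (G - n) / (G - 1)
    mean_i = mean_h / 3.0
    var_i = (2.0 / 9.0) * mean_h + var_h / 9.0
    sd_i = sqrt(var_i)
    expected_j = mean_i / (2 * n - mean_i)
    se_j = sd_i * (2 * n) / (2 * n - mean_i) ** 2
    return {
        "expected_intersection": mean_i,
        "sd_intersection": sd_i,
        "expected_jaccard": expected_j,
        "se_jaccard": se_j,
    }
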