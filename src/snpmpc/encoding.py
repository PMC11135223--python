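"""Encode a genome as a binary presence vector against a public SNP panel.

Two parties who wish to compare genomes first agree on a public, ordered
panel of variants. Each variant is identified by the tuple
(chromosome, position, reference allele, alternate allele) — the Chr, Pos,
Ref and Alt columns of a VCF record. A genome's VCF is reduced to its set
of such tuples, and the m-entry panel then defines an m-bit vector a with
a_i = 1 iff panel variant i occurs in the genome. Set operations between
two genomes, restricted to the panel, become elementwise arithmetic on
these vectors, which is what the secure protocols compute on secret shares.

Matching is presence-only: a record matches on the tuple regardless of
genotype. An optional flag additionally requires at least one alternate
allele in the GT field.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from cyvcf2 import VCF

from .config import ProtocolConfig
from .sharing import ShareVector, genshare_vector

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class PanelFormatError(ValueError):
    """Malformed or inconsistent panel file."""


class VcfFormatError(ValueError):
    """Unparseable or invalid VCF record (strict mode)."""


def normalize_chrom(label: str) -> str:
    """Case-fold a chromosome label and strip any leading ``chr`` prefix,
    so e.g. ``chr1``, ``Chr1`` and ``1`` all compare equal."""
    label = str(label).strip().casefold()
    if label.startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True, order=True)
class VariantKey:
    """One SNP as the tuple (chromosome, position, ref allele, alt allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be nonempty")

    @classmethod
    def snp(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Construct a validated single-nucleotide variant key."""
        ref, alt = ref.upper(), alt.upper()
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(f"SNP alleles must be single bases in ACGT, got {ref}>{alt}")
        if ref == alt:
            raise ValueError(f"ref and alt alleles are identical ({ref}) at {chrom}:{pos}")
        return cls(normalize_chrom(chrom), int(pos), ref, alt)

    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _BASES
            and self.alt in _BASES
        )


@dataclass(frozen=True)
class Panel:
    """An ordered public panel of variants: the comparison set S.

    The order of entries is the order of vector positions and must be
    identical for both input providers; the content digest binds encoded
    vectors (and their sharings) to this exact panel.
    """

    entries: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        seen = set()
        for k in self.entries:
            if k in seen:
                raise PanelFormatError(f"duplicate panel entry {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def digest(self) -> str:
        h = hashlib.sha256()
        for k in self.entries:
            h.update(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n".encode())
        return h.hexdigest()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("Chr\tPos\tRef\tAlt\n")
            for k in self.entries:
                fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")


@dataclass(frozen=True)
class PresenceVector:
    """The m-bit encoding of one genome against a panel."""

    bits: tuple
    panel_digest: str

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("presence vector entries must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    def write(self, path: str | Path) -> None:
        header = {"m": len(self.bits), "panel_digest": self.panel_digest}
        with open(path, "w") as fh:
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            fh.write("".join(str(b) for b in self.bits) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PresenceVector":
        with open(path) as fh:
            header = json.loads(fh.readline())
            bitstr = fh.readline().strip()
        if len(bitstr) != header["m"]:
            raise ValueError(
                f"{path}: header declares m={header['m']}, found {len(bitstr)} bits"
            )
        return cls(tuple(int(c) for c in bitstr), header["panel_digest"])


def read_panel(path: str | Path) -> Panel:
    """Read a panel from a 4-column TSV with header Chr/Pos/Ref/Alt.

    Extra columns are ignored; entry order is file order. Chromosome labels
    are normalized, and duplicate keys (after normalization) are rejected
    with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("Chr", "Pos", "Ref", "Alt") if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing required columns {missing}")
    entries: list[VariantKey] = []
    seen: dict[VariantKey, int] = {}
    for row_idx, row in enumerate(df.itertuples(index=False)):
        line_no = row_idx + 2  # 1-based, after the header line
        try:
            key = VariantKey.snp(row.Chr, int(row.Pos), row.Ref, row.Alt)
        except (ValueError, TypeError) as exc:
            raise PanelFormatError(f"{path}:{line_no}: {exc}") from exc
        if key in seen:
            raise PanelFormatError(
                f"{path}:{line_no}: duplicate panel entry {key} "
                f"(first seen at line {seen[key]})"
            )
        seen[key] = line_no
        entries.append(key)
    return Panel(tuple(entries))


def read_vcf_variant_set(
    path: str | Path,
    snps_only: bool = True,
    require_alt_gt: bool = False,
    strict_filter: bool = False,
    strict: bool = False,
) -> set[VariantKey]:
    """Extract a genome's variant set A from a VCF 4.x file (plain or bgzipped).

    Multi-allelic records contribute one key per alternate allele. By
    default only SNPs are kept (indels/MNVs are counted and skipped), the
    FILTER column is ignored, and presence does not depend on genotype.

    Parameters
    ----------
    snps_only
        Keep only single-base ref/alt substitutions (default). Skipped
        non-SNP records are counted and logged.
    require_alt_gt
        Keep a record only if at least one sample carries an alternate
        allele in its GT field.
    strict_filter
        Keep only records with FILTER of PASS or '.'.
    strict
        Raise on records that cannot be turned into a valid key instead of
        logging and skipping them.
    """
    variants: set[VariantKey] = set()
    skipped_non_snp = 0
    for rec in VCF(str(path)):
        if strict_filter and rec.FILTER is not None:  # cyvcf2: None == PASS/'.'
            continue
        if require_alt_gt:
            # gt_types: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            if not any(g in (1, 2) for g in rec.gt_types):
                continue
        for alt in rec.ALT:
            if snps_only and not (
                len(rec.REF) == 1 and len(alt) == 1
                and rec.REF.upper() in _BASES and alt.upper() in _BASES
            ):
                skipped_non_snp += 1
                continue
            try:
                if len(rec.REF) == 1 and len(alt) == 1:
                    key = VariantKey.snp(rec.CHROM, rec.POS, rec.REF, alt)
                else:
                    key = VariantKey(
                        normalize_chrom(rec.CHROM), rec.POS, rec.REF.upper(), alt.upper()
                    )
            except ValueError as exc:
                if strict:
                    raise VcfFormatError(
                        f"{path}: record {rec.CHROM}:{rec.POS} {rec.REF}>{alt}: {exc}"
                    ) from exc
                logger.warning("%s: skipping record %s:%s (%s)", path, rec.CHROM, rec.POS, exc)
                continue
            variants.add(key)
    if skipped_non_snp:
        logger.info("%s: skipped %d non-SNP allele(s)", path, skipped_non_snp)
    return variants


def encode(panel: Panel, variants: Iterable[VariantKey]) -> PresenceVector:
    """Encode a variant set against a panel: bit i = 1 iff panel entry i ∈ A."""
    if len(panel) == 0:
        logger.warning("encoding against an empty panel (m=0)")
    vset = set(variants)
    bits = tuple(1 if k in vset else 0 for k in panel.entries)
    return PresenceVector(bits, panel.digest)


def share_vector(
    vec: PresenceVector,
    config: ProtocolConfig,
    rng: Optional[random.Random] = None,
) -> list[ShareVector]:
    """Secret-share a presence vector elementwise: one ShareVector per party.

    Each ShareVector carries the panel digest, so downstream protocols can
    refuse to combine vectors encoded against different panels.
    """
    if len(vec) > config.prime:
        raise ValueError(
            f"panel length {len(vec)} exceeds field modulus {config.prime}; "
            "cardinalities would wrap"
        )
    return genshare_vector(
        list(vec.bits),
        config,
        rng if rng is not None else config.rng(),
        panel_digest=vec.panel_digest,
    )
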