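"""Versioned HLA allele protein-sequence registries.

An :class:`AlleleRegistry` maps two-field allele names (``A*01:01``) at the
five loci used for T-cell molecular mismatch analysis (HLA-A, -B, -C, -DRB1,
-DQB1) to mature protein sequences, emulating a release of a reference allele
database. Registries can be loaded from FASTA (headers carrying allele names)
or synthesized for testing: per locus one base protein is drawn and alleles
differ only at a designated set of polymorphic sites.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from Bio import SeqIO

__all__ = [
    "SUPPORTED_LOCI",
    "CLASS_I_LOCI",
    "CLASS_II_LOCI",
    "AMINO_ACIDS",
    "AlleleName",
    "AlleleRecord",
    "AlleleRegistry",
    "parse_allele_name",
    "load_registry",
    "synthesize_registry",
    "mutate_registry",
]

SUPPORTED_LOCI: Tuple[str, ...] = ("A", "B", "C", "DRB1", "DQB1")
CLASS_I_LOCI: Tuple[str, ...] = ("A", "B", "C")
CLASS_II_LOCI: Tuple[str, ...] = ("DRB1", "DQB1")

#: The 20 standard one-letter amino-acid codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: Dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_NAME_RE = re.compile(r"^([A-Z0-9]+)\*(\d{2,3}):(\d{2,3})$")


class AlleleParseError(ValueError):
    """Raised when an allele-name string cannot be parsed."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """Two-field HLA allele name: locus, allele-group field, protein field."""

    locus: str
    field1: str
    field2: str

    def __post_init__(self) -> None:
        if self.locus not in SUPPORTED_LOCI:
            raise AlleleParseError(
                f"unsupported locus {self.locus!r}; expected one of {SUPPORTED_LOCI}"
            )

    def __str__(self) -> str:
        return f"{self.locus}*{self.field1}:{self.field2}"

    @property
    def hla_class(self) -> str:
        """'I' for HLA-A/B/C, 'II' for DRB1/DQB1."""
        return "I" if self.locus in CLASS_I_LOCI else "II"


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``"LOCUS*ff:ss"`` into an :class:`AlleleName`.

    Only two-field names at the five supported loci are accepted; higher
    fields (``A*01:01:01``) and expression suffixes (``A*01:01N``) are
    rejected.
    """
    if not text:
        raise AlleleParseError("empty allele name")
    m = _NAME_RE.match(text.strip())
    if m is None:
        if "*" not in text:
            raise AlleleParseError(f"missing '*' separator in allele name {text!r}")
        raise AlleleParseError(f"malformed allele name {text!r}")
    locus, f1, f2 = m.groups()
    if locus not in SUPPORTED_LOCI:
        raise AlleleParseError(
            f"unsupported locus {locus!r} in {text!r}; expected one of {SUPPORTED_LOCI}"
        )
    return AlleleName(locus, f1, f2)


@dataclass(frozen=True)
class AlleleRecord:
    """An allele name together with its mature protein sequence."""

    name: AlleleName
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.name}: sequence contains non-standard characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlleleRegistry:
    """A versioned collection of allele protein sequences.

    Emulates one release of a reference HLA sequence database: the same
    allele name may map to different sequences in different versions.
    """

    version_tag: str
    records: Dict[AlleleName, AlleleRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, rec in self.records.items():
            if rec.name != key:
                raise ValueError(f"record key {key} does not match record name {rec.name}")

    def add(self, record: AlleleRecord) -> None:
        if record.name in self.records:
            raise ValueError(f"duplicate allele name {record.name}")
        if record.length < 15:
            raise ValueError(
                f"{record.name}: sequence length {record.length} < 15; cannot yield any 15-mer"
            )
        self.records[record.name] = record

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: AlleleName) -> bool:
        return name in self.records

    def get(self, name: AlleleName) -> AlleleRecord:
        try:
            return self.records[name]
        except KeyError:
            raise KeyError(
                f"allele {name} not found in registry version {self.version_tag}"
            ) from None

    def alleles_at(self, locus: str) -> list[AlleleName]:
        return sorted(n for n in self.records if n.locus == locus)

    def summary(self) -> dict:
        per_locus = {loc: len(self.alleles_at(loc)) for loc in SUPPORTED_LOCI}
        return {
            "version_tag": self.version_tag,
            "n_records": len(self),
            "per_locus": per_locus,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.records):
                fh.write(f">{name}\n")
                seq = self.records[name].sequence
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def load_registry(path: str | Path, version_tag: str) -> AlleleRegistry:
    """Load an allele registry from FASTA.

    The first whitespace-delimited token of each header must be a two-field
    allele name at a supported locus. Duplicate names, non-amino-acid
    characters and sequences shorter than 15 residues are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reg = AlleleRegistry(version_tag=version_tag)
    for entry in SeqIO.parse(str(path), "fasta"):
        name = parse_allele_name(entry.id.split()[0])
        reg.add(AlleleRecord(name=name, sequence=str(entry.seq).upper()))
    return reg


def _locus_rng(seed: int, locus: str, salt: str = "") -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32((locus + salt).encode())])
    )


def synthesize_registry(
    n_alleles_per_locus: int,
    n_polymorphic_sites: int,
    seed: int,
    version_tag: str = "synthetic-1",
    length_range: Tuple[int, int] = (180, 270),
) -> AlleleRegistry:
    """Generate a synthetic registry for testing.

    Per locus, one random base protein (length drawn from ``length_range``)
    is generated; allele ``i`` is the base with random substitutions at a
    random subset of ``n_polymorphic_sites`` designated sites. Allele 01 of
    the group is the unmodified base. Deterministic given ``seed``.
    """
    if n_alleles_per_locus < 1:
        raise ValueError("n_alleles_per_locus must be >= 1")
    if n_polymorphic_sites < 0:
        raise ValueError("n_polymorphic_sites must be >= 0")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    reg = AlleleRegistry(version_tag=version_tag)
    for locus in SUPPORTED_LOCI:
        rng = _locus_rng(seed, locus)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        base = rng.integers(0, 20, size=length)
        n_sites = min(n_polymorphic_sites, length)
        sites = rng.choice(length, size=n_sites, replace=False)
        for i in range(n_alleles_per_locus):
            seq = base.copy()
            if i > 0 and n_sites > 0:
                k = int(rng.integers(1, n_sites + 1))
                chosen = rng.choice(sites, size=k, replace=False)
                # substitute with a different residue at each chosen site
                shift = rng.integers(1, 20, size=k)
                seq[chosen] = (seq[chosen] + shift) % 20
            f1 = f"{(i // 99) + 1:02d}"
            f2 = f"{(i % 99) + 1:02d}"
            name = AlleleName(locus, f1, f2)
            reg.add(AlleleRecord(name=name, sequence="".join(aa[seq])))
    return reg


def mutate_registry(
    registry: AlleleRegistry,
    edits: Mapping[AlleleName, Iterable[Tuple[int, str]]],
    version_tag: str,
) -> AlleleRegistry:
    """Return a copy of ``registry`` with point substitutions applied.

    ``edits`` maps allele names to ``(position, residue)`` pairs (0-based).
    Used to construct a second registry version for sensitivity analysis.
    """
    out = AlleleRegistry(version_tag=version_tag)
    for name in sorted(registry.records):
        rec = registry.records[name]
        seq = rec.sequence
        if name in edits:
            chars = list(seq)
            for pos, res in edits[name]:
                if not 0 <= pos < len(chars):
                    raise IndexError(f"edit position {pos} out of range for {name}")
                if res not in AA_INDEX:
                    raise ValueError(f"invalid residue {res!r}")
                chars[pos] = res
            seq = "".join(chars)
        out.add(AlleleRecord(name=name, sequence=seq))
    return out
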