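"""Derivation of T-cell molecular mismatches (TcEMMs) from HLA genotypes.

For one donor:recipient pair, a TcEMM is a 9-amino-acid core that

1. occurs as a core of some 15-mer window of a donor HLA protein (any of the
   ten donor alleles at HLA-A/B/C/DRB1/DQB1),
2. is absent from the recipient's own repertoire of HLA-derived 9-mer cores,
   and
3. is presented by at least one recipient HLA-DRB1 allele under the
   presentation model.

The per-pair mismatch load (the PIRCHE-II-style score) is by default the
number of distinct such cores; a weighted mode counts (core, presenting
allele) combinations instead. Across a population of pairs the cores are
collected into a sparse binary pairs x cores matrix; the population identity
of a TcEMM is the 9-mer string alone.

Because every donor protein here is at least 15 residues long, the set of
9-mer cores of all 15-mer windows equals the set of all 9-mer windows of the
protein; the derivation exploits this identity, while
:func:`enumerate_15mers` / :func:`enumerate_cores` expose the window chain
explicitly (and back the brute-force oracle used in tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .presentation import DefaultPresentationModel, encode_cores
from .registry import SUPPORTED_LOCI, AlleleName, AlleleRecord, AlleleRegistry, parse_allele_name

logger = logging.getLogger(__name__)

__all__ = [
    "PairGenotype",
    "TcEMMSet",
    "TcEMMMatrix",
    "enumerate_15mers",
    "enumerate_cores",
    "self_repertoire",
    "derive_tcemm",
    "build_matrix",
    "TcEMMEncoder",
    "pairs_to_tsv",
    "pairs_from_tsv",
]

Genotype = Mapping[str, Tuple[AlleleName, AlleleName]]


@dataclass(frozen=True)
class PairGenotype:
    """Donor and recipient allele-level genotypes at the five loci."""

    pair_id: str
    donor_alleles: Mapping[str, Tuple[AlleleName, AlleleName]]
    recipient_alleles: Mapping[str, Tuple[AlleleName, AlleleName]]

    def __post_init__(self) -> None:
        for label, geno in (("donor", self.donor_alleles), ("recipient", self.recipient_alleles)):
            missing = set(SUPPORTED_LOCI) - set(geno)
            if missing:
                raise ValueError(f"pair {self.pair_id}: {label} genotype missing loci {sorted(missing)}")
            for locus, pair in geno.items():
                if len(pair) != 2:
                    raise ValueError(f"pair {self.pair_id}: {label} {locus} must carry two alleles")
                for a in pair:
                    if a.locus != locus:
                        raise ValueError(
                            f"pair {self.pair_id}: allele {a} listed under locus {locus}"
                        )


def enumerate_15mers(record: AlleleRecord) -> List[str]:
    """All contiguous 15-mer windows of a protein, left to right (0-based starts)."""
    seq = record.sequence
    if len(seq) < 15:
        logger.warning("%s: sequence shorter than 15 residues; no 15-mers", record.name)
        return []
    return [seq[i : i + 15] for i in range(len(seq) - 14)]


def enumerate_cores(peptide15: str) -> List[str]:
    """The 7 contiguous 9-mer windows of a 15-mer."""
    if len(peptide15) != 15:
        raise ValueError(f"expected a 15-mer, got length {len(peptide15)}")
    return [peptide15[i : i + 9] for i in range(7)]


def _kmers(registry: AlleleRegistry, name: AlleleName, k: int = 9) -> Tuple[str, ...]:
    """All k-mer windows of an allele's protein, cached on the registry."""
    cache = getattr(registry, "_kmer_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(registry, "_kmer_cache", cache)
    key = (name, k)
    if key not in cache:
        seq = registry.get(name).sequence
        cache[key] = tuple(seq[i : i + k] for i in range(len(seq) - k + 1))
    return cache[key]


def self_repertoire(recipient: Genotype, registry: AlleleRegistry) -> Set[str]:
    """Union of all 9-mer windows of the recipient's HLA proteins (five loci).

    No binding filter is applied: any core occurring in a recipient HLA
    protein is treated as self, regardless of whether the recipient's DRB1
    would present it.
    """
    rep: Set[str] = set()
    for locus in SUPPORTED_LOCI:
        for allele in recipient[locus]:
            rep.update(_kmers(registry, allele, 9))
    return rep


@dataclass
class TcEMMSet:
    """Per-pair derivation result."""

    pair_id: str
    cores: Set[str]
    presentations: Dict[str, Set[AlleleName]]
    class_origin: Dict[str, FrozenSet[str]]
    pirche_score: int

    def __post_init__(self) -> None:
        if set(self.presentations) != self.cores or set(self.class_origin) != self.cores:
            raise ValueError("presentations/class_origin keys must equal the core set")


def derive_tcemm(
    pair: PairGenotype,
    registry: AlleleRegistry,
    model: DefaultPresentationModel,
    scoring: str = "distinct_core",
    self_repertoire_binding_filtered: bool = False,
) -> TcEMMSet:
    """Derive the TcEMM set and mismatch score for one donor:recipient pair.

    Parameters
    ----------
    scoring:
        ``"distinct_core"`` (default): score = number of distinct presented
        non-self cores. ``"core_presenter"``: score = number of
        (core, presenting DRB1 allele) combinations.
    self_repertoire_binding_filtered:
        When True, only recipient cores presented by the recipient's DRB1
        count as self before subtraction (alternative reading of the
        repertoire definition; default off).
    """
    if scoring not in ("distinct_core", "core_presenter"):
        raise ValueError(f"unknown scoring mode {scoring!r}")

    drb1 = sorted(set(pair.recipient_alleles["DRB1"]))

    # donor cores with their source-locus classes
    origin: Dict[str, Set[str]] = {}
    for locus in SUPPORTED_LOCI:
        cls = "I" if locus in ("A", "B", "C") else "II"
        for allele in set(pair.donor_alleles[locus]):
            for core in _kmers(registry, allele, 9):
                origin.setdefault(core, set()).add(cls)

    self_rep = self_repertoire(pair.recipient_alleles, registry)
    if self_repertoire_binding_filtered:
        rep_list = sorted(self_rep)
        idx = encode_cores(rep_list)
        mask = np.zeros(len(rep_list), dtype=bool)
        for d in drb1:
            mask |= model.presented_mask(idx, d)
        self_rep = {c for c, m in zip(rep_list, mask) if m}

    candidates = sorted(set(origin) - self_rep)
    idx = encode_cores(candidates)
    presenter_masks = {d: model.presented_mask(idx, d) for d in drb1}

    cores: Set[str] = set()
    presentations: Dict[str, Set[AlleleName]] = {}
    class_origin: Dict[str, FrozenSet[str]] = {}
    for j, core in enumerate(candidates):
        presenters = {d for d in drb1 if presenter_masks[d][j]}
        if presenters:
            cores.add(core)
            presentations[core] = presenters
            class_origin[core] = frozenset(origin[core])

    if scoring == "distinct_core":
        score = len(cores)
    else:
        score = sum(len(p) for p in presentations.values())
    return TcEMMSet(
        pair_id=pair.pair_id,
        cores=cores,
        presentations=presentations,
        class_origin=class_origin,
        pirche_score=score,
    )


@dataclass
class TcEMMMatrix:
    """Sparse binary pairs x cores presence matrix plus per-pair scores."""

    pair_ids: List[str]
    tcemm_ids: List[str]
    entries: sparse.csr_matrix
    scores: np.ndarray
    class_origin: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def support(self) -> np.ndarray:
        """Per-core pair counts (column sums)."""
        return np.asarray(self.entries.sum(axis=0)).ravel().astype(int)

    def frequencies(self) -> np.ndarray:
        return self.support() / self.n_pairs

    def to_dense_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries.toarray(), index=self.pair_ids, columns=self.tcemm_ids, dtype=np.int8
        )

    def column(self, core: str) -> np.ndarray:
        j = self.tcemm_ids.index(core)
        return np.asarray(self.entries[:, j].todense()).ravel().astype(np.int8)

    def write_triplets(self, path: str | Path) -> None:
        coo = self.entries.tocoo()
        with open(path, "w") as fh:
            fh.write("pair_id\tcore\tpresent\n")
            order = np.lexsort((coo.col, coo.row))
            for i, j in zip(coo.row[order], coo.col[order]):
                fh.write(f"{self.pair_ids[i]}\t{self.tcemm_ids[j]}\t1\n")

    def write_scores(self, path: str | Path) -> None:
        pd.DataFrame({"pair_id": self.pair_ids, "pirche_score": self.scores}).to_csv(
            path, sep="\t", index=False
        )


def build_matrix(tcemm_sets: Sequence[TcEMMSet]) -> TcEMMMatrix:
    """Collect per-pair TcEMM sets into the population binary matrix."""
    pair_ids = [s.pair_id for s in tcemm_sets]
    if len(set(pair_ids)) != len(pair_ids):
        dupes = sorted({p for p in pair_ids if pair_ids.count(p) > 1})
        raise ValueError(f"duplicate pair_id(s): {dupes}")
    all_cores = sorted(set().union(*(s.cores for s in tcemm_sets)) if tcemm_sets else set())
    col = {c: j for j, c in enumerate(all_cores)}
    rows, cols = [], []
    class_origin: Dict[str, Set[str]] = {c: set() for c in all_cores}
    for i, s in enumerate(tcemm_sets):
        for c in s.cores:
            rows.append(i)
            cols.append(col[c])
            class_origin[c] |= set(s.class_origin[c])
    entries = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(pair_ids), len(all_cores)),
    )
    scores = np.array([s.pirche_score for s in tcemm_sets], dtype=int)
    return TcEMMMatrix(
        pair_ids=pair_ids,
        tcemm_ids=all_cores,
        entries=entries,
        scores=scores,
        class_origin={c: frozenset(v) for c, v in class_origin.items()},
    )


class TcEMMEncoder(BaseEstimator, TransformerMixin):
    """Transformer from donor:recipient pair genotypes to the binary TcEMM matrix.

    ``fit`` derives the population core vocabulary (and per-pair scores) from
    the training pairs; ``transform`` encodes pairs over that vocabulary.

    Parameters
    ----------
    registry : AlleleRegistry
    q_bind : float
        Presentation-model binding fraction for random cores.
    seed : int
        Presentation-model seed.
    scoring : str
        ``"distinct_core"`` or ``"core_presenter"``.
    self_repertoire_binding_filtered : bool
        Optional binding filter on the recipient self-repertoire.
    """

    def __init__(
        self,
        registry: AlleleRegistry = None,
        q_bind: float = 0.2,
        seed: int = 0,
        scoring: str = "distinct_core",
        self_repertoire_binding_filtered: bool = False,
    ):
        self.registry = registry
        self.q_bind = q_bind
        self.seed = seed
        self.scoring = scoring
        self.self_repertoire_binding_filtered = self_repertoire_binding_filtered

    def _derive_all(self, pairs: Sequence[PairGenotype]) -> List[TcEMMSet]:
        return [
            derive_tcemm(
                p,
                self.registry,
                self.model_,
                scoring=self.scoring,
                self_repertoire_binding_filtered=self.self_repertoire_binding_filtered,
            )
            for p in pairs
        ]

    def fit(self, X: Sequence[PairGenotype], y=None) -> "TcEMMEncoder":
        if self.registry is None:
            raise ValueError("registry must be provided")
        self.model_ = DefaultPresentationModel(self.registry, self.q_bind, self.seed)
        sets = self._derive_all(X)
        self.matrix_ = build_matrix(sets)
        self.tcemm_ids_ = list(self.matrix_.tcemm_ids)
        self.sets_ = sets
        return self

    def transform(self, X: Sequence[PairGenotype]) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            raise RuntimeError("TcEMMEncoder is not fitted")
        sets = self._derive_all(X)
        col = {c: j for j, c in enumerate(self.tcemm_ids_)}
        out = np.zeros((len(sets), len(col)), dtype=np.int8)
        for i, s in enumerate(sets):
            for c in s.cores:
                if c in col:
                    out[i, col[c]] = 1
        return pd.DataFrame(out, index=[s.pair_id for s in sets], columns=self.tcemm_ids_)


# --- pair genotype TSV round-trip -------------------------------------------

def pairs_to_tsv(pairs: Sequence[PairGenotype], path: str | Path) -> None:
    cols = ["pair_id"]
    for who in ("donor", "recip"):
        for locus in SUPPORTED_LOCI:
            cols += [f"{who}_{locus}_1", f"{who}_{locus}_2"]
    rows = []
    for p in pairs:
        row = [p.pair_id]
        for geno in (p.donor_alleles, p.recipient_alleles):
            for locus in SUPPORTED_LOCI:
                row += [str(geno[locus][0]), str(geno[locus][1])]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def pairs_from_tsv(path: str | Path) -> List[PairGenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = []
    for _, row in df.iterrows():
        donor = {
            locus: (parse_allele_name(row[f"donor_{locus}_1"]), parse_allele_name(row[f"donor_{locus}_2"]))
            for locus in SUPPORTED_LOCI
        }
        recip = {
            locus: (parse_allele_name(row[f"recip_{locus}_1"]), parse_allele_name(row[f"recip_{locus}_2"]))
            for locus in SUPPORTED_LOCI
        }
        pairs.append(PairGenotype(pair_id=row["pair_id"], donor_alleles=donor, recipient_alleles=recip))
    return pairs
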