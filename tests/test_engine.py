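"""Peptide windowing, self-repertoire subtraction and mismatch derivation.

The central check is oracle equivalence: `derive_tcemm` must reproduce a
deliberately naive implementation that walks every (donor protein, 15-mer,
9-mer core, recipient DRB1 allele) combination one at a time.
"""

import numpy as np
import pytest

from tcemm.engine import (
    PairGenotype,
    TcEMMEncoder,
    build_matrix,
    derive_tcemm,
    enumerate_15mers,
    enumerate_cores,
    pairs_from_tsv,
    pairs_to_tsv,
    self_repertoire,
)
from tcemm.presentation import DefaultPresentationModel
from tcemm.registry import (
    SUPPORTED_LOCI,
    AlleleName,
    AlleleRecord,
    AlleleRegistry,
    synthesize_registry,
)


def brute_force_tcemm(pair, registry, model):
    """Independent reference: explicit 15-mer -> core -> presenter loops."""
    self_cores = set()
    for locus in SUPPORTED_LOCI:
        for allele in pair.recipient_alleles[locus]:
            seq = registry.get(allele).sequence
            for i in range(len(seq) - 8):
                self_cores.add(seq[i : i + 9])
    result = set()
    drb1 = set(pair.recipient_alleles["DRB1"])
    for locus in SUPPORTED_LOCI:
        for allele in pair.donor_alleles[locus]:
            record = registry.get(allele)
            for pep in enumerate_15mers(record):
                for core in enumerate_cores(pep):
                    if core in self_cores:
                        continue
                    for d in drb1:
                        if model.presented(core, d):
                            result.add(core)
                            break
    return result


def _identical_pair(registry, pair_id="pid"):
    geno = {loc: (registry.alleles_at(loc)[0], registry.alleles_at(loc)[0])
            for loc in SUPPORTED_LOCI}
    return PairGenotype(pair_id=pair_id, donor_alleles=geno, recipient_alleles=geno)


class TestWindows:
    def test_15mer_window_counts_and_content(self):
        rec = AlleleRecord(AlleleName("A", "01", "01"), "ACDEFGHIKLMNPQR")
        assert enumerate_15mers(rec) == ["ACDEFGHIKLMNPQR"]
        rec20 = AlleleRecord(AlleleName("A", "01", "01"), "ACDEFGHIKLMNPQRSTVWY")
        assert len(enumerate_15mers(rec20)) == 6

    def test_windows_match_independent_slicing(self, rng):
        from tcemm.registry import AMINO_ACIDS

        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        rec = AlleleRecord(AlleleName("B", "07", "02"), seq)
        expected = [seq[i : i + 15] for i in range(len(seq) - 14)]
        assert enumerate_15mers(rec) == expected
        pep = seq[:15]
        assert enumerate_cores(pep) == [pep[i : i + 9] for i in range(7)]

    def test_core_count_and_degenerate(self):
        assert enumerate_cores("A" * 15) == ["A" * 9] * 7
        with pytest.raises(ValueError):
            enumerate_cores("A" * 14)

    def test_short_sequence_yields_no_15mers(self):
        rec = AlleleRecord.__new__(AlleleRecord)  # bypass length validation
        object.__setattr__(rec, "name", AlleleName("A", "01", "01"))
        object.__setattr__(rec, "sequence", "ACDEFGHIK")
        assert enumerate_15mers(rec) == []


class TestSelfRepertoire:
    def test_union_of_windows(self, small_registry):
        geno = {loc: (small_registry.alleles_at(loc)[0], small_registry.alleles_at(loc)[1])
                for loc in SUPPORTED_LOCI}
        rep = self_repertoire(geno, small_registry)
        expected = set()
        for loc in SUPPORTED_LOCI:
            for a in geno[loc]:
                seq = small_registry.get(a).sequence
                expected |= {seq[i : i + 9] for i in range(len(seq) - 8)}
        assert rep == expected

    def test_unresolvable_allele_raises(self, small_registry):
        geno = {loc: (small_registry.alleles_at(loc)[0], small_registry.alleles_at(loc)[0])
                for loc in SUPPORTED_LOCI}
        geno["A"] = (AlleleName("A", "99", "99"), geno["A"][1])
        with pytest.raises(KeyError, match="A\\*99:99"):
            self_repertoire(geno, small_registry)


class TestDeriveTcEMM:
    def test_identical_genotypes_yield_empty_set(self, small_registry, small_model):
        pair = _identical_pair(small_registry)
        res = derive_tcemm(pair, small_registry, small_model)
        assert res.cores == set()
        assert res.pirche_score == 0

    def test_qbind_zero_yields_empty_set(self, small_registry, small_pairs):
        model0 = DefaultPresentationModel(small_registry, q_bind=0.0, seed=11)
        for pair in small_pairs[:5]:
            assert derive_tcemm(pair, small_registry, model0).cores == set()

    def test_single_substitution_with_full_binding(self):
        # donor differs from recipient by one residue in one protein;
        # with everything presented, TcEMMs are exactly the non-self donor
        # cores overlapping the substituted site (at most 9)
        reg = synthesize_registry(1, 0, seed=5, length_range=(40, 40))
        a0 = reg.alleles_at("A")[0]
        seq = reg.get(a0).sequence
        pos = 20
        new = "W" if seq[pos] != "W" else "Y"
        mutated = seq[:pos] + new + seq[pos + 1 :]
        donor_reg = AlleleRegistry("v-mut")
        for name, rec in reg.records.items():
            donor_reg.add(rec)
        donor_name = AlleleName("A", "02", "01")
        donor_reg.add(AlleleRecord(donor_name, mutated))
        geno_r = {loc: (reg.alleles_at(loc)[0], reg.alleles_at(loc)[0]) for loc in SUPPORTED_LOCI}
        geno_d = dict(geno_r)
        geno_d["A"] = (donor_name, donor_name)
        pair = PairGenotype("m", donor_alleles=geno_d, recipient_alleles=geno_r)
        model = DefaultPresentationModel(donor_reg, q_bind=1.0, seed=5)
        res = derive_tcemm(pair, donor_reg, model)
        expected = {
            mutated[i : i + 9]
            for i in range(len(mutated) - 8)
            if i <= pos <= i + 8
        } - self_repertoire(geno_r, donor_reg)
        assert res.cores == expected
        assert len(res.cores) <= 9

    def test_oracle_equivalence_on_random_pairs(self, small_registry, small_model, small_pairs):
        for pair in small_pairs[:12]:
            fast = derive_tcemm(pair, small_registry, small_model)
            assert fast.cores == brute_force_tcemm(pair, small_registry, small_model)
            assert all(len(p) >= 1 for p in fast.presentations.values())
            assert fast.pirche_score == len(fast.cores)

    def test_monotone_in_qbind(self, small_registry, small_pairs):
        lo = DefaultPresentationModel(small_registry, q_bind=0.1, seed=11)
        hi = DefaultPresentationModel(small_registry, q_bind=0.5, seed=11)
        for pair in small_pairs[:8]:
            s_lo = derive_tcemm(pair, small_registry, lo).cores
            s_hi = derive_tcemm(pair, small_registry, hi).cores
            assert s_lo <= s_hi

    def test_core_presenter_scoring_at_least_distinct(self, small_registry, small_model, small_pairs):
        for pair in small_pairs[:5]:
            a = derive_tcemm(pair, small_registry, small_model, scoring="distinct_core")
            b = derive_tcemm(pair, small_registry, small_model, scoring="core_presenter")
            assert b.pirche_score >= a.pirche_score
            assert a.cores == b.cores


class TestMatrix:
    def test_column_sums_and_score_invariant(self, small_registry, small_model, small_pairs):
        sets = [derive_tcemm(p, small_registry, small_model) for p in small_pairs]
        mat = build_matrix(sets)
        # column sums equal recomputed per-core pair counts
        recount = {c: sum(c in s.cores for s in sets) for c in mat.tcemm_ids}
        np.testing.assert_array_equal(
            mat.support(), [recount[c] for c in mat.tcemm_ids]
        )
        # under default scoring, sum of scores equals number of nonzeros
        assert mat.scores.sum() == mat.entries.nnz
        freqs = mat.frequencies()
        assert np.all((freqs > 0) & (freqs <= 1))

    def test_disjoint_singletons_identity_pattern(self, small_registry):
        from tcemm.engine import TcEMMSet

        s1 = TcEMMSet("p1", {"AAAAAAAAA"}, {"AAAAAAAAA": {AlleleName("DRB1", "01", "01")}},
                      {"AAAAAAAAA": frozenset({"I"})}, 1)
        s2 = TcEMMSet("p2", {"CCCCCCCCC"}, {"CCCCCCCCC": {AlleleName("DRB1", "01", "01")}},
                      {"CCCCCCCCC": frozenset({"II"})}, 1)
        mat = build_matrix([s1, s2])
        assert mat.entries.toarray().tolist() == [[1, 0], [0, 1]]

    def test_duplicate_pair_id_rejected(self, small_registry, small_model, small_pairs):
        sets = [derive_tcemm(small_pairs[0], small_registry, small_model)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(sets)

    def test_triplet_export_consistent(self, tmp_path, small_registry, small_model, small_pairs):
        import pandas as pd

        sets = [derive_tcemm(p, small_registry, small_model) for p in small_pairs[:10]]
        mat = build_matrix(sets)
        out = tmp_path / "trip.tsv"
        mat.write_triplets(out)
        df = pd.read_csv(out, sep="\t")
        assert len(df) == mat.entries.nnz


class TestEncoder:
    def test_fit_transform_matches_matrix(self, small_registry, small_pairs):
        enc = TcEMMEncoder(registry=small_registry, q_bind=0.25, seed=11)
        enc.fit(small_pairs)
        df = enc.transform(small_pairs)
        np.testing.assert_array_equal(df.to_numpy(), enc.matrix_.entries.toarray())

    def test_get_params_round_trip(self, small_registry):
        enc = TcEMMEncoder(registry=small_registry, q_bind=0.3, seed=2)
        params = enc.get_params()
        assert params["q_bind"] == 0.3
        enc.set_params(q_bind=0.4)
        assert enc.q_bind == 0.4


def test_pair_tsv_round_trip(tmp_path, small_pairs):
    path = tmp_path / "pairs.tsv"
    pairs_to_tsv(small_pairs, path)
    back = pairs_from_tsv(path)
    assert len(back) == len(small_pairs)
    for a, b in zip(small_pairs, back):
        assert a.pair_id == b.pair_id
        assert a.donor_alleles == b.donor_alleles
        assert a.recipient_alleles == b.recipient_alleles
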