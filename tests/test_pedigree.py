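"""Pedigree parsing, Mendelian checking and recombination counting."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedphase.pedigree import (
    Genotype,
    HaplotypePair,
    Member,
    MendelianError,
    Pedigree,
    PedigreeError,
    PedigreeParseError,
    RecombinationEvent,
    check_mendelian_consistency,
    count_recombinations,
    parse_pedigree,
    write_haplotypes,
    write_pedigree,
    HaplotypeConfiguration,
)
from pedphase.simulate import SimulationSpec, simulate_pedigree
from tests.conftest import pedigree_from_rows


class TestParsing:
    def test_compact_row_recodes_genotype(self):
        p = parse_pedigree("F1 f 0 0 1 202\nF1 v 0 0 2 202\nF1 c f v 1 202\n",
                           dialect="compact")
        assert list(p.by_id["c"].genotype) == [2, 0, 2]
        assert p.by_id["c"].father_id == "f" and p.by_id["c"].mother_id == "v"
        assert [m.member_id for m in p.members] == ["f", "v", "c"]

    def test_linkage_allele_pairs_recode(self):
        p = parse_pedigree("F u 0 0 1 1 2 1 1 2 2\n", dialect="linkage")
        assert list(p.by_id["u"].genotype) == [2, 0, 1]

    @pytest.mark.parametrize(
        "rows, dialect, fragment",
        [
            ("F c f 0 1 22\nF f 0 0 1 22\n", "compact", "one known parent"),
            ("F u 0 0 1 2x2\n", "compact", "invalid genotype code"),
            ("F u 0 0 1 22\nF v 0 0 1 222\n", "compact", "expected 2"),
            ("F c f v 1 22\n", "compact", "unknown parent"),
            ("F u 0 0 1\n", "compact", "at least 6 columns"),
            ("F u 0 0 1 0 1 1 2\n", "linkage", "missing allele"),
            ("F u 0 0 1 1 3 1 2\n", "linkage", "invalid allele"),
        ],
    )
    def test_malformed_input_raises_located_error(self, rows, dialect, fragment):
        with pytest.raises(PedigreeParseError) as err:
            parse_pedigree(rows, dialect=dialect)
        assert fragment in str(err.value)
        assert err.value.line is not None or "unknown parent" in fragment

    @pytest.mark.parametrize("dialect", ["compact", "linkage"])
    def test_roundtrip_preserves_genotypes_and_structure(self, dialect, corpus):
        for item in corpus[:10]:
            buf = io.StringIO()
            write_pedigree(item.pedigree, buf, dialect=dialect)
            back = parse_pedigree(buf.getvalue(), dialect=dialect)
            assert [m.member_id for m in back.members] == [
                m.member_id for m in item.pedigree.members
            ]
            for mem in item.pedigree.members:
                assert back.by_id[mem.member_id].genotype == mem.genotype
                assert back.by_id[mem.member_id].father_id == mem.father_id

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=8))
    @settings(max_examples=50, derandomize=True)
    def test_roundtrip_single_member_genotype(self, codes):
        mem = Member("u", None, None, "unknown", Genotype(codes))
        buf = io.StringIO()
        write_pedigree(Pedigree([mem]), buf, dialect="linkage")
        back = parse_pedigree(buf.getvalue(), dialect="linkage")
        assert list(back.by_id["u"].genotype) == codes

    def test_parent_cycle_rejected(self):
        with pytest.raises(PedigreeError):
            Pedigree(
                [
                    Member("a", "b", "c", "male", Genotype([0])),
                    Member("b", "a", "c", "male", Genotype([0])),
                    Member("c", None, None, "female", Genotype([0])),
                ]
            )


class TestMendelian:
    @pytest.mark.parametrize(
        "f, m, c, violates",
        [
            (0, 0, 2, True),
            (2, 2, 0, False),
            (2, 2, 1, False),
            (2, 2, 2, False),
            (1, 0, 2, False),
            (1, 0, 0, True),
            (1, 1, 2, True),
            (0, 2, 1, True),
        ],
    )
    def test_site_level_rules(self, f, m, c, violates):
        p = pedigree_from_rows(f"F f 0 0 1 {f}\nF m 0 0 2 {m}\nF c f m 1 {c}\n")
        assert bool(check_mendelian_consistency(p)) == violates

    def test_simulated_pedigrees_always_consistent(self):
        for seed in range(25):
            spec = SimulationSpec(
                n_founder_couples=2, children_per_couple=2, m=5,
                planted_recombinations=seed % 4, seed=seed,
            )
            p, _ = simulate_pedigree(spec)
            assert check_mendelian_consistency(p) == []


def _phases(**kw):
    return {k: HaplotypePair.from_strings(*v) for k, v in kw.items()}


class TestCountRecombinations:
    def trio(self, f, m, c):
        return pedigree_from_rows(f"F f 0 0 1 {f}\nF m 0 0 2 {m}\nF c f m 1 {c}\n")

    def test_single_switch_detected_with_interval(self):
        p = self.trio("22", "00", "20")
        phases = _phases(f=("11", "00"), m=("00", "00"), c=("10", "00"))
        k, events = count_recombinations(p, phases)
        assert k == 1
        assert events == [RecombinationEvent("c", frozenset({"f"}), (1, 2))]

    def test_full_parental_haplotypes_cost_nothing(self):
        p = self.trio("22", "00", "20")
        phases = _phases(f=("10", "01"), m=("00", "00"), c=("10", "00"))
        assert count_recombinations(p, phases) == (0, [])

    def test_assignment_minimized_over_both_routings(self):
        # child haplotypes must be matched to parents in the cheaper way
        p = self.trio("22", "22", "22")
        phases = _phases(f=("10", "01"), m=("01", "10"), c=("10", "01"))
        assert count_recombinations(p, phases)[0] == 0

    def test_swap_invariance_single_member(self, corpus):
        for item in corpus[:8]:
            k0, _ = count_recombinations(item.pedigree, item.truth.phases)
            for mid in item.truth.phases:
                phases = dict(item.truth.phases)
                phases[mid] = phases[mid].swapped()
                assert count_recombinations(item.pedigree, phases)[0] == k0

    def test_truth_cost_at_most_planted(self):
        for seed in range(30):
            spec = SimulationSpec(
                n_founder_couples=1, children_per_couple=2, m=4,
                planted_recombinations=seed % 3, seed=1000 + seed,
            )
            p, truth = simulate_pedigree(spec)
            assert truth.k <= spec.planted_recombinations

    def test_inconsistent_phase_rejected(self):
        p = self.trio("22", "00", "20")
        phases = _phases(f=("11", "00"), m=("00", "00"), c=("01", "00"))
        with pytest.raises(MendelianError):
            count_recombinations(p, phases)


class TestWriters:
    def test_haplotype_table_and_event_block(self):
        cfg = HaplotypeConfiguration(
            phases={"u": HaplotypePair.from_strings("10", "01")},
            events=[RecombinationEvent("c", frozenset({"f"}), (1, 2))],
            k=1,
        )
        buf = io.StringIO()
        write_haplotypes(cfg, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "u\t10\t01"
        assert lines[1].startswith("#events\t1")
        assert lines[2] == "c\tf\t(1,2)"

    def test_empty_event_block(self):
        cfg = HaplotypeConfiguration(
            phases={"u": HaplotypePair.from_strings("0", "0")}, events=[], k=0
        )
        buf = io.StringIO()
        write_haplotypes(cfg, buf)
        assert buf.getvalue().splitlines()[-1] == "#events\t0\tk=0"
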