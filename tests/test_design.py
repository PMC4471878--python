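import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna, random_registry

from mirsponge import (DesignConfig, DesignError, LinkerExhaustionError,
                       MatchType, MatureMiRNA, Registry, assemble_cassette,
                       design_bulged_site, generate_scramble,
                       legacy_assemble, naive_scan, reverse_complement,
                       select_linker)
from mirsponge.design import pairs_watson_crick, pairs_wobble
from mirsponge.registry import seed_kmers


class TestBulgedSite:
    def test_homopolymer_hand_construction(self):
        # miRNA positions 9-12 map to site positions 1-4 (antiparallel)
        site = design_bulged_site(MatureMiRNA("m", "AAAAAAAAAAAA"))
        assert site.site_seq == "AAAATTTTTTTT"
        assert site.pairing == ("WC",) * 8 + ("mismatch",) * 4

    def test_short_mirna_clips_span_with_warning(self):
        m = MatureMiRNA("m9", "UGAGGUAGU")
        with pytest.warns(UserWarning, match="clipped"):
            site = design_bulged_site(m)
        assert site.site_seq == "TCTACCTCA"
        assert site.mismatch_span == (9, 9)

    def test_empty_span_is_perfect_reverse_complement(self, let7):
        site = design_bulged_site(let7, mismatch_span=(25, 30))
        assert site.site_seq == reverse_complement(let7.sequence, "DNA")
        assert site.mismatch_span is None

    @settings(derandomize=True, max_examples=200)
    @given(seq=st.text(alphabet="ACGU", min_size=12, max_size=30))
    def test_pairing_oracle_base_by_base(self, seq):
        """Outside the span every base WC-pairs; inside, neither WC nor
        G.U wobble (checked position-by-position against the miRNA)."""
        m = MatureMiRNA("m", seq)
        site = design_bulged_site(m)
        length = m.length
        for pos in range(1, length + 1):  # miRNA position, 1-based
            site_base = site.site_seq[length - pos]
            mirna_base = m.sequence[pos - 1]
            if 9 <= pos <= 12:
                assert not pairs_watson_crick(site_base, mirna_base)
                assert not pairs_wobble(site_base, mirna_base)
                assert site.pairing[pos - 1] == "mismatch"
            else:
                assert pairs_watson_crick(site_base, mirna_base)
                assert site.pairing[pos - 1] == "WC"


class TestSelectLinker:
    def test_empty_registry_returns_lexicographic_first(self):
        linker = select_linker("T" * 7, "A" * 7, Registry(), set(),
                               DesignConfig())
        assert linker == "AAAA"

    def test_brute_force_oracle_agreement(self):
        """The accepted linker is the first of the 256 candidates whose
        junction has zero overlapping collisions under the naive scanner."""
        # 7mer-m8 k-mer TTTTAAA <=> m[2..8] = UUUAAAA
        m = MatureMiRNA("trap", "GUUUAAAAUUUUUUUUUU")
        reg = Registry([m])
        config = DesignConfig(
            enabled_match_types=frozenset({MatchType.MER7_M8}))
        left, right = "GGGGTTTT", "AAAGGGG"
        chosen = select_linker(left, right, reg, set(), config)

        def junction_clean(cand):
            junction = left + cand + right
            report = naive_scan(junction, reg, config.enabled_match_types)
            ls, le = len(left), len(left) + len(cand)
            return not any(h.start < le and h.end > ls for h in report.hits)

        import itertools
        candidates = ["".join(p) for p in
                      itertools.product("ACGT", repeat=4)]
        first_clean = next(c for c in candidates if junction_clean(c))
        assert chosen == first_clean
        assert not junction_clean("AAAA")  # TTTT|AAAA|AAA completes the site

    def test_never_recreates_flank_enzyme_at_junction(self):
        # left+linker can complete NotI (GCGGCCGC); those must be skipped
        chosen = select_linker("AAAGCGG", "CAAAAAA", Registry(), set(),
                               DesignConfig())
        junction = "AAAGCGG" + chosen + "CAAAAAA"
        for site in ("GCGGCCGC", "TCTAGA"):
            pos = junction.find(site)
            while pos != -1:
                assert not (pos < 7 + 4 and pos + len(site) > 7)
                pos = junction.find(site, pos + 1)

    def test_exhaustion_lists_a_reason_per_candidate(self):
        # single-base linkers between poly-T contexts; four trap miRNAs
        # block each of A/C/G/T via their 7mer-m8 k-mers T6{A,C,G,T}
        traps = Registry([
            MatureMiRNA("tA", "AUAAAAAAA"),  # k-mer TTTTTTA
            MatureMiRNA("tC", "AGAAAAAAA"),  # k-mer TTTTTTC
            MatureMiRNA("tG", "ACAAAAAAA"),  # k-mer TTTTTTG
            MatureMiRNA("tT", "AAAAAAAAA"),  # k-mer TTTTTTT
        ])
        config = DesignConfig(
            linker_length=1,
            enabled_match_types=frozenset({MatchType.MER7_M8}))
        with pytest.raises(LinkerExhaustionError) as err:
            select_linker("T" * 7, "T" * 7, traps, set(), config)
        assert set(err.value.rejections) == {"A", "C", "G", "T"}


class TestAssemble:
    def test_default_architecture_from_block_table(self, small_registry):
        cassette = assemble_cassette(small_registry["dme-miR-8-3p"],
                                     small_registry)
        sites = [b for b in cassette.blocks if b.kind == "site"]
        linkers = [b for b in cassette.blocks if b.kind == "linker"]
        flanks = [b for b in cassette.blocks if b.kind == "flank"]
        assert len(sites) == 20
        assert len(linkers) == 19
        assert all(b.end - b.start == 4 for b in linkers)
        assert [cassette.full_seq[b.start:b.end] for b in flanks] == \
            ["GCGGCCGC", "TCTAGA"]

    def test_single_repeat_has_no_linkers(self, small_registry, let7):
        cassette = assemble_cassette(
            let7, small_registry, DesignConfig(n_repeats=1))
        assert cassette.linkers == ()
        assert cassette.full_seq == ("GCGGCCGC"
                                     + cassette.sites[0].site_seq
                                     + "TCTAGA")

    def test_deterministic_byte_for_byte(self, small_registry, let7):
        config = DesignConfig(linker_order="seeded_random", rng_seed=42)
        first = assemble_cassette(let7, small_registry, config)
        second = assemble_cassette(let7, small_registry, config)
        assert first.full_seq == second.full_seq
        assert first.linkers == second.linkers

    def test_family_members_are_exempt(self, small_registry, let7):
        # the cassette is saturated with the target's own seed sites;
        # neither they nor the family member may block or be reported
        cassette = assemble_cassette(let7, small_registry)
        exempt = small_registry.family_of(let7)
        report = naive_scan(cassette.full_seq, small_registry,
                            exempt=exempt, region_map=cassette.blocks)
        assert not report.in_region("junction")

    def test_block_table_reconstructs_sequence(self, small_registry):
        cassette = assemble_cassette(small_registry["dme-miR-2a-3p"],
                                     small_registry)
        rebuilt = "".join(cassette.full_seq[b.start:b.end]
                          for b in cassette.blocks)
        assert rebuilt == cassette.full_seq
        # blocks tile the sequence without gaps or overlaps
        pos = 0
        for block in cassette.blocks:
            assert block.start == pos
            pos = block.end
        assert pos == len(cassette.full_seq)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_junction_windows_clean_on_random_registries(self, seed):
        rng = np.random.default_rng(seed)
        reg = random_registry(rng, int(rng.integers(5, 30)))
        target = reg[reg.ids[int(rng.integers(len(reg)))]]
        cassette = assemble_cassette(target, reg)
        report = naive_scan(cassette.full_seq, reg,
                            exempt=reg.family_of(target),
                            region_map=cassette.blocks)
        assert not report.in_region("junction")


class TestLegacyAssemble:
    def test_mir1_worked_example(self):
        cassette = legacy_assemble("GGTACGTTTAGCGTAAGTTAT", "CGCG", 10)
        assert sum(b.kind == "site" for b in cassette.blocks) == 10
        # 10 x 21-nt sites + 9 x 4-nt linkers
        assert len(cassette.full_seq) == 10 * 21 + 9 * 4 == 246
        assert cassette.full_seq == \
            "GGTACGTTTAGCGTAAGTTATCGCG" * 9 + "GGTACGTTTAGCGTAAGTTAT"

    def test_single_repeat_is_the_site(self):
        cassette = legacy_assemble("GGTAC", "CGCG", 1)
        assert cassette.full_seq == "GGTAC"

    def test_invalid_inputs(self):
        with pytest.raises(DesignError):
            legacy_assemble("", "CGCG", 3)
        with pytest.raises(DesignError):
            legacy_assemble("GGTAC", "CGCG", 0)


class TestScramble:
    def test_tiny_template_preserves_composition(self):
        out = generate_scramble("ACGT", Registry())
        assert sorted(out) == list("ACGT")

    def test_defining_property_zero_collisions(self, small_registry, let7):
        from mirsponge import design_bulged_site
        template = design_bulged_site(let7).site_seq
        out = generate_scramble(template, small_registry)
        assert sorted(out) == sorted(template)
        report = naive_scan(out, small_registry)
        assert not report.hits
        assert "GCGGCCGC" not in out and "TCTAGA" not in out

    def test_seed_determinism(self, small_registry, let7):
        template = design_bulged_site(let7).site_seq
        config = DesignConfig(rng_seed=123)
        assert generate_scramble(template, small_registry, config) == \
            generate_scramble(template, small_registry, config)
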