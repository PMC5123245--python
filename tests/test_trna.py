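"""Structural annotation of tRNA positions and structure-map construction."""

import pytest
from hypothesis import given, settings, strategies as st

from mtanno import (
    TrnaAnnotation,
    annotate_trna_position,
    build_structure_map,
    format_trna_annotation,
    parse_trna_annotation,
)
from mtanno.trna import (
    StructureBuildError,
    canonical_domains,
    tertiary_groups_for_type,
)
from mtanno.fixtures import generate_trna_map
from mtanno.reference import TRNA_DOMAINS, TRNA_TYPES


class TestFormatting:
    def test_worked_example_string(self):
        a = TrnaAnnotation(53, "II", "TS", "G", False)
        assert format_trna_annotation(a) == "53;II;TS;G;N"

    def test_modified_anticodon_wobble_string(self):
        # queuosine at the wobble position of a quasi-canonical tRNA
        a = TrnaAnnotation(34, "0", "CL", "Q", False)
        assert format_trna_annotation(a) == "34;0;CL;Q;N"

    def test_unmapped_renders_dash(self):
        a = TrnaAnnotation(None, "0", "-", "A", False)
        assert format_trna_annotation(a).split(";")[0] == "-"

    def test_unknown_domain_rejected(self):
        with pytest.raises(ValueError):
            format_trna_annotation(TrnaAnnotation(10, "II", "XX", "A", False))

    @given(
        sprinzl=st.one_of(st.none(), st.integers(1, 73)),
        trna_type=st.sampled_from(TRNA_TYPES),
        domain=st.sampled_from(TRNA_DOMAINS),
        mature=st.sampled_from(list("ACGU") + ["P", "Q", "Ê", "Ǝ", '"', "?"]),
        folding=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_parse_format_round_trip(self, sprinzl, trna_type, domain, mature, folding):
        a = TrnaAnnotation(sprinzl, trna_type, domain, mature, folding)
        s = format_trna_annotation(a)
        assert parse_trna_annotation(s) == a
        assert format_trna_annotation(parse_trna_annotation(s)) == s


class TestAnnotateBundled:
    def test_m4450_annotation(self, bundle):
        a = annotate_trna_position(4450, bundle)
        assert (a.sprinzl, a.trna_type, a.domain, a.mature_nt, a.folding) == \
            (53, "II", "TS", "G", False)

    def test_non_trna_position_is_none(self, bundle):
        assert annotate_trna_position(4000, bundle) is None   # MT-ND1
        assert annotate_trna_position(16400, bundle) is None  # control region

    def test_exhaustive_over_all_trna_genes(self, bundle):
        domains = canonical_domains()
        for gene in bundle.loci_by_biotype("tRNA"):
            for off in range(1, gene.length() + 1):
                pos = gene.position_at(off)
                a = annotate_trna_position(pos, bundle)
                assert a is not None, (gene.name, pos)
                if a.sprinzl is not None and gene.name == \
                        [g.name for g in bundle.loci_at(pos) if g.biotype == "tRNA"][0]:
                    assert a.domain == domains[a.sprinzl]

    def test_monotone_sprinzl_every_bundled_map(self, bundle):
        for struct in bundle.structures.values():
            mapped = [p.sprinzl for p in struct.positions if p.sprinzl is not None]
            assert mapped == sorted(mapped) and len(set(mapped)) == len(mapped)

    def test_anticodon_domain_every_bundled_map(self, bundle):
        for struct in bundle.structures.values():
            for p in struct.positions:
                if p.sprinzl in (34, 35, 36):
                    assert p.domain == "CL"

    def test_folding_matches_tertiary_sets(self, bundle):
        for struct in bundle.structures.values():
            folded = {p.sprinzl for p in struct.positions if p.folding}
            assert folded == {n for g in struct.tertiary for n in g}

    def test_one_type_I_and_one_type_III(self, bundle):
        types = [m.trna_type for m in bundle.structures.values()]
        assert types.count("I") == 1
        assert types.count("III") == 1
        assert types.count("II") > types.count("0")  # type II most common


class TestBuildStructureMap:
    def _alignment(self, n=73, skip=()):
        mapped = [s for s in range(1, 74) if s not in skip]
        return [(i + 1, s) for i, s in enumerate(mapped[:n])]

    def test_first_position_of_gapfree_map(self):
        align = self._alignment()
        struct = build_structure_map("SYN", "0", align, "A" * len(align),
                                     tertiary=tertiary_groups_for_type("0"))
        first = struct.positions[0]
        assert (first.sprinzl, first.domain) == (1, "AS")

    def test_anticodon_forced_to_cl(self):
        align = self._alignment()
        domains = dict(canonical_domains())
        domains[34] = domains[35] = domains[36] = "CS"
        with pytest.raises(StructureBuildError):
            build_structure_map("SYN", "0", align, "A" * len(align),
                                domains=domains)

    def test_non_monotone_alignment_rejected(self):
        align = self._alignment()
        align[5], align[6] = (6, align[6][1]), (7, align[5][1])
        with pytest.raises(StructureBuildError):
            build_structure_map("SYN", "0", align, "A" * len(align))

    def test_triplet_tertiary_sets_folding(self):
        align = self._alignment()
        struct = build_structure_map("SYN", "II", align, "A" * len(align),
                                     tertiary=[{10, 25, 45}])
        folded = {p.sprinzl for p in struct.positions if p.folding}
        assert folded == {10, 25, 45}

    def test_unmapped_gap_count(self):
        # 68-nt tRNA with 5 unmapped D-loop offsets: 63 mapped + 5 unmapped
        mapped = [s for s in range(1, 74) if s not in (16, 17, 18, 19, 20)]
        entries = mapped[:13] + [None] * 5 + mapped[13:]
        align = [(i + 1, s) for i, s in enumerate(entries)]
        struct = build_structure_map("SYN", "II", align, "A" * len(align))
        assert sum(1 for p in struct.positions if p.sprinzl is None) == 5
        assert sum(1 for p in struct.positions if p.sprinzl is not None) == 68

    def test_mature_base_overridden_by_modification(self):
        from mtanno.reference import ModificationRecord

        align = self._alignment()
        mods = [ModificationRecord(34, "queuosine", "Q", "Asp", "human")]
        struct = build_structure_map("MT-TD", "0", align, "A" * len(align),
                                     mods=mods)
        by_sprinzl = {p.sprinzl: p for p in struct.positions}
        assert by_sprinzl[34].mature_nt == "Q"
        assert by_sprinzl[35].mature_nt == "A"


class TestSyntheticOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_annotation_matches_raw_alignment(self, seed):
        trna_type = ("0", "I", "II", "III")[seed % 4]
        struct, raw = generate_trna_map(seed, trna_type, gap_count=seed % 4)
        assert len(raw) == len(struct.positions)
        for (off, sprinzl, domain, base, folding), rec in zip(raw, struct.positions):
            assert rec.offset == off
            assert rec.sprinzl == sprinzl
            assert rec.domain == domain
            assert rec.mature_nt == base
            assert rec.folding == folding
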