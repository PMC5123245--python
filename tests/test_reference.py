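"""Reference-bundle loading, validation and position resolution."""

import dataclasses

import pytest

from mtanno import (
    BundleLoadError,
    BundleValidationError,
    GeneLocus,
    load_reference_bundle,
    locate_position,
)
from mtanno.reference import GENOME_LENGTH, RangeError


class TestGeneLocus:
    def test_offset_follows_transcription_direction(self):
        h = GeneLocus("G1", 101, 110, "H", "tRNA")
        l = GeneLocus("G2", 101, 110, "L", "tRNA")
        assert h.offset_of(101) == 1 and h.offset_of(110) == 10
        assert l.offset_of(110) == 1 and l.offset_of(101) == 10
        for off in range(1, 11):
            assert h.offset_of(h.position_at(off)) == off
            assert l.offset_of(l.position_at(off)) == off

    def test_wrapping_locus_spans_origin(self):
        ctrl = GeneLocus("CR", 16024, 576, "H", "control")
        assert ctrl.wraps
        assert ctrl.length() == GENOME_LENGTH - 16024 + 1 + 576
        assert ctrl.contains(16500) and ctrl.contains(100)
        assert not ctrl.contains(600)
        assert ctrl.offset_of(16024) == 1
        assert ctrl.offset_of(1) == GENOME_LENGTH - 16024 + 2
        assert ctrl.position_at(ctrl.length()) == 576


class TestBundledMap:
    def test_bundled_gene_counts(self, bundle):
        assert len(bundle.loci_by_biotype("tRNA")) == 22
        assert len(bundle.loci_by_biotype("rRNA")) == 2
        assert len(bundle.loci_by_biotype("protein_coding")) == 13

    def test_locate_4450_is_mt_tm(self, bundle):
        assert [g.name for g in locate_position(4450, bundle)] == ["MT-TM"]

    def test_overlapping_genes_both_returned_ordered(self, bundle):
        names = [g.name for g in bundle.loci_at(4330)]
        assert names == ["MT-TI", "MT-TQ"]

    def test_control_region_wraps(self, bundle):
        assert "MT-CR" in [g.name for g in bundle.loci_at(16400)]
        assert "MT-CR" in [g.name for g in bundle.loci_at(250)]

    def test_intergenic_position_empty(self, bundle):
        # between MT-TY (ends 5891) and MT-CO1 (starts 5904)
        assert bundle.loci_at(5895) == []

    def test_out_of_range_position_rejected(self, bundle):
        with pytest.raises(RangeError):
            bundle.loci_at(0)
        with pytest.raises(RangeError):
            bundle.loci_at(GENOME_LENGTH + 1)

    def test_every_position_resolves(self, bundle):
        # locate_position is total over the genome; tRNA position count
        # matches the manifest declaration
        n_trna = 0
        for pos in range(1, GENOME_LENGTH + 1):
            loci = bundle.loci_at(pos)
            n_trna += sum(1 for g in loci if g.biotype == "tRNA")
        assert n_trna == bundle.manifest["counts"]["trna_positions"]

    def test_manifest_counts_self_consistent(self, bundle):
        counts = bundle.manifest["counts"]
        assert counts["trna_positions"] == bundle.position_count("tRNA")
        assert counts["rrna_positions"] == bundle.position_count("rRNA") == 2513


class TestLoadErrors:
    def test_empty_directory_lists_all_required_files(self, tmp_path):
        with pytest.raises(BundleLoadError) as err:
            load_reference_bundle(tmp_path)
        for name in ("genes.tsv", "trna_structure.tsv", "modifications.tsv",
                     "rna_patho.tsv", "manifest.json"):
            assert name in str(err.value)

    def test_anticodon_domain_corruption_rejected(self, toy, tmp_path):
        toy.save_bundle(tmp_path / "b")
        struct = (tmp_path / "b" / "trna_structure.tsv").read_text().splitlines()
        corrupted = []
        done = False
        for line in struct:
            fields = line.split("\t")
            if not done and len(fields) == 7 and fields[3] == "20":
                fields[4] = "CL"  # a CL-domain record away from the anticodon
                done = True
            corrupted.append("\t".join(fields))
        assert done
        (tmp_path / "b" / "trna_structure.tsv").write_text("\n".join(corrupted) + "\n")
        with pytest.raises(BundleValidationError):
            load_reference_bundle(tmp_path / "b")

    def test_sprinzl_monotonicity_violation_rejected(self, toy, tmp_path):
        toy.save_bundle(tmp_path / "b")
        path = tmp_path / "b" / "trna_structure.tsv"
        lines = path.read_text().splitlines()
        fields = lines[3].split("\t")
        fields[3] = "70"  # early offset jumps ahead, later rows must decrease
        lines[3] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(BundleValidationError) as err:
            load_reference_bundle(tmp_path / "b")
        assert "increasing" in str(err.value) or "anticodon" in str(err.value)

    def test_manifest_count_mismatch_rejected(self, toy, tmp_path):
        import json

        toy.save_bundle(tmp_path / "b")
        mpath = tmp_path / "b" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["counts"]["trna_positions"] += 1
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(BundleValidationError) as err:
            load_reference_bundle(mpath.parent)
        assert "manifest" in str(err.value)


class TestRoundTrip:
    def test_save_load_save_is_stable(self, bundle, tmp_path):
        bundle.save(tmp_path / "one")
        again = load_reference_bundle(tmp_path / "one")
        assert again.genes == bundle.genes
        assert set(again.structures) == set(bundle.structures)
        for name, struct in bundle.structures.items():
            assert again.structures[name].positions == struct.positions
            assert again.structures[name].tertiary == struct.tertiary
        assert set(again.modifications) == set(bundle.modifications)
        assert again.rna_patho == bundle.rna_patho
        again.save(tmp_path / "two")
        for f in (tmp_path / "one").iterdir():
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()
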