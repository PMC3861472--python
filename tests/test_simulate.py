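"""Synthetic-data generator: determinism, mass conservation, planted truth."""

import numpy as np
import pytest

from supersage import LibraryContrast, find_sisters, match_tag
from supersage.anchoring import INTERGENIC, ReferenceSet, classify_region
from supersage.tagging import extract_tags
from supersage.simulate import (
    SimulationConfig,
    simulate_ct_tables,
    simulate_libraries,
    simulate_references,
)


def small_cfg(seed=0, **kw):
    defaults = dict(n_transcripts=300, seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults).scaled(0.02)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            cfg = small_cfg(seed=7)
            refs = simulate_references(cfg)
            d = tmp_path / sub
            d.mkdir()
            refs.write_fasta(d / "t.fasta", "transcripts")
            refs.write_fasta(d / "c.fasta", "chromosomes")
            refs.write_gff3(d / "g.gff3")
            libs, truth = simulate_libraries(cfg, refs)
            for lib_id, lib in sorted(libs.items()):
                lib.to_tsv(d / f"{lib_id}.tsv")
            truth.to_json(d / "truth.json")
            outs.append(d)
        for name in [p.name for p in outs[0].iterdir()]:
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_different_seed_differs(self):
        libs_a, _ = simulate_libraries(small_cfg(seed=1), simulate_references(small_cfg(seed=1)))
        libs_b, _ = simulate_libraries(small_cfg(seed=2), simulate_references(small_cfg(seed=2)))
        assert libs_a["ET0"].counts != libs_b["ET0"].counts


class TestReferences:
    def test_every_transcript_yields_a_tag(self):
        cfg = small_cfg(n_transcripts=50)
        refs = simulate_references(cfg)
        assert len(refs.transcripts) == 50
        for tid, seq in refs.transcripts.items():
            tags = extract_tags(seq, mode="three_prime_most")
            assert tags == [refs.tag_of_transcript[tid]]

    def test_gene_models_on_chromosome_are_consistent(self):
        refs = simulate_references(small_cfg())
        assert refs.gene_models
        for gm in refs.gene_models:
            chrom = refs.chromosomes[gm.target_id]
            assert gm.span[1] <= len(chrom)
            # exonic sequence reassembles the source transcript
            tid = gm.gene_id.removeprefix("gene_")
            spliced = "".join(chrom[s:e] for s, e in gm.exons)
            assert spliced == refs.transcripts[tid]

    def test_embedded_tags_classify_non_intergenic(self):
        refs = simulate_references(small_cfg())
        chrom_refs = ReferenceSet(dict(refs.chromosomes), kind="chromosome")
        found_genic = 0
        for gm in refs.gene_models[:10]:
            tid = gm.gene_id.removeprefix("gene_")
            tag = refs.tag_of_transcript[tid]
            for hit in match_tag(tag, chrom_refs, max_mismatch=0):
                if classify_region(hit, refs.gene_models) != INTERGENIC:
                    found_genic += 1
        assert found_genic > 0


class TestLibraries:
    def test_count_mass_equals_library_size(self):
        cfg = small_cfg()
        libs, _ = simulate_libraries(cfg, simulate_references(cfg))
        for lib_id, lib in libs.items():
            assert (
                sum(lib.counts.values()) + lib.n_singlets_excluded
                == lib.total_sequenced
                == cfg.library_sizes[lib_id]
            )
            assert all(c >= 2 for c in lib.counts.values())

    def test_null_generator_calibrated(self):
        cfg = small_cfg(de_fraction=0.0, error_rate=0.0, n_transcripts=1000).scaled(2.0)
        libs, truth = simulate_libraries(cfg, simulate_references(cfg))
        assert not truth.de_transcripts
        res = LibraryContrast(libs["ET1-6"], libs["ET0"]).fit()
        frac_sig = (res.frame["p_value"] < 0.05).mean()
        assert frac_sig <= 0.08

    def test_no_errors_no_foreign_sisters(self):
        cfg = small_cfg(error_rate=0.0)
        refs = simulate_references(cfg)
        libs, truth = simulate_libraries(cfg, refs)
        assert not truth.sister_parents
        all_tags = set().union(*(set(l.counts) for l in libs.values()))
        reference_tags = set(refs.tag_of_transcript.values())
        assert all_tags <= reference_tags
        ref_pairs = set(
            (p.tag_a, p.tag_b) for p in find_sisters(reference_tags)
        )
        for pair in find_sisters(all_tags):
            assert (pair.tag_a, pair.tag_b) in ref_pairs

    def test_errors_spawn_sister_tags(self):
        cfg = small_cfg(error_rate=0.005)
        refs = simulate_references(cfg)
        libs, truth = simulate_libraries(cfg, refs)
        assert truth.sister_parents
        for sis, (parent, pos) in list(truth.sister_parents.items())[:20]:
            assert sis[:4] == "CATG" and parent[:4] == "CATG"
            assert sis[pos] != parent[pos] and pos >= 4

    def test_recovery_of_planted_de(self):
        sens, fdp = [], []
        for seed in range(3):
            cfg = SimulationConfig(seed=seed).scaled(0.1)
            refs = simulate_references(cfg)
            libs, truth = simulate_libraries(cfg, refs)
            res = LibraryContrast(libs["ET1-6"], libs["ET0"]).fit()
            called = res.tags_called("UR") | res.tags_called("DR")
            strong = {
                truth.tag_of_transcript[t]
                for t in truth.de_transcripts
                if max(truth.effect_size[t], 1 / truth.effect_size[t]) >= 4
            }
            sens.append(len(strong & called) / len(strong))
            fdp.append(len(called - truth.de_tags()) / max(1, len(called)))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdp) <= 0.1

    def test_planted_direction_matches_call(self):
        cfg = SimulationConfig(seed=11).scaled(0.1)
        refs = simulate_references(cfg)
        libs, truth = simulate_libraries(cfg, refs)
        res = LibraryContrast(libs["ET1-6"], libs["ET0"]).fit()
        frame = res.frame.set_index("tag")
        wrong = 0
        checked = 0
        for tid, status in truth.de_transcripts.items():
            eff = truth.effect_size[tid]
            if max(eff, 1 / eff) < 8:
                continue
            tag = truth.tag_of_transcript[tid]
            if tag not in frame.index:
                continue
            call = frame.loc[tag, "call"]
            checked += 1
            if call != "NS" and call != status:
                wrong += 1
        assert checked > 20
        assert wrong <= 0.02 * checked


class TestCtTables:
    def test_noise_free_exact_recovery(self):
        from supersage.qpcr import QpcrAssay, rest_ratio

        ct, _ = simulate_ct_tables({"g": 1.0}, noise_sd=0.0, seed=0)
        assays = {x: QpcrAssay(x, 1.0) for x in ("g", "actin", "rna18S")}
        assert rest_ratio(ct, "g", ["actin", "rna18S"], assays) == pytest.approx(1.0)
        ct2, _ = simulate_ct_tables({"g": 3.0}, noise_sd=0.0, seed=0)
        assert rest_ratio(ct2, "g", ["actin", "rna18S"], assays) == pytest.approx(3.0)

    def test_design_shape(self):
        ct, truth = simulate_ct_tables({"g": 2.0}, n_bio=3, n_tech=3, seed=1)
        assert set(ct["gene"]) == {"g", "actin", "rna18S"}
        per_group = ct.groupby(["gene", "group"]).size()
        assert (per_group == 9).all()  # 3 biological x 3 technical
        assert truth["g"] == 2.0 and truth["actin"] == 1.0
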