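"""TLA simulator: circle purity, amplicon structure, read error models."""

import numpy as np
import pandas as pd
import pytest

from tlaphase.locus_model import ValidationError
from tlaphase.tla_simulator import (LONG_PROFILE, SHORT_PROFILE, ConfigError,
                                    ContactModel, ReadProfile, Viewpoint,
                                    amplify, digest_haplotypes, generate_reads,
                                    simulate_circle, simulate_dataset,
                                    simulate_run, synthesize_locus)


@pytest.fixture(scope="module")
def sim_setup():
    rng = np.random.default_rng(21)
    locus = synthesize_locus(12000, rng)
    pos = min((v.pos for v in locus.het_variants),
              key=lambda p: abs(p - 6000))
    vp = Viewpoint.at_position(locus.reference, pos)
    haps = digest_haplotypes(locus, vp)
    return locus, vp, haps


class TestCircles:
    def test_viewpoint_always_present_and_haplotype_pure(self, sim_setup):
        locus, vp, haps = sim_setup
        rng = np.random.default_rng(1)
        for i in range(200):
            c = simulate_circle(haps, ContactModel(), rng, circle_id=i)
            assert len({f.hap for f in c.fragments}) == 1
            vp_idx = haps[c.hap].viewpoint_index
            assert any(f.index == vp_idx for f in c.fragments)

    def test_same_seed_identical_circles(self, sim_setup):
        _, _, haps = sim_setup
        c1 = simulate_circle(haps, ContactModel(), np.random.default_rng(5))
        c2 = simulate_circle(haps, ContactModel(), np.random.default_rng(5))
        assert c1 == c2

    def test_haplotype_balance(self, sim_setup):
        _, _, haps = sim_setup
        rng = np.random.default_rng(3)
        n = 2000
        h0 = sum(simulate_circle(haps, ContactModel(), rng).hap == 0
                 for _ in range(n))
        sd = (n * 0.25) ** 0.5
        assert abs(h0 - n / 2) <= 3 * sd

    def test_impossible_bounds_raise(self, sim_setup):
        _, _, haps = sim_setup
        cm = ContactModel(min_amplicon_len=90, max_amplicon_len=100)
        with pytest.raises(Exception, match="bounds"):
            simulate_circle(haps, cm, np.random.default_rng(0))


class TestAmplicons:
    def test_lengths_within_default_bounds(self, sim_setup):
        _, vp, haps = sim_setup
        rng = np.random.default_rng(2)
        circles = [simulate_circle(haps, ContactModel(), rng, circle_id=i)
                   for i in range(50)]
        amps = amplify(circles, vp, haps)
        assert len(amps) == 50
        assert all(4000 <= len(a) <= 10000 for a in amps)

    def test_provenance_tiles_every_base(self, sim_setup):
        _, vp, haps = sim_setup
        rng = np.random.default_rng(4)
        circles = [simulate_circle(haps, ContactModel(), rng, circle_id=i)
                   for i in range(20)]
        for amp in amplify(circles, vp, haps):
            offs = sorted((s.offset, s.length) for s in amp.provenance)
            cursor = 0
            for off, length in offs:
                assert off == cursor
                cursor += length
            assert cursor == len(amp)

    def test_circle_without_viewpoint_dropped(self, sim_setup):
        _, vp, haps = sim_setup
        rng = np.random.default_rng(6)
        c = simulate_circle(haps, ContactModel(), rng, circle_id=0)
        from tlaphase.tla_simulator import Circle
        vp_idx = haps[c.hap].viewpoint_index
        stripped = Circle(circle_id=1, hap=c.hap,
                          fragments=tuple(f for f in c.fragments
                                          if f.index != vp_idx),
                          viewpoint_index=0)
        amps = amplify([c, stripped], vp, haps)
        assert [a.circle_id for a in amps] == [0]


@pytest.fixture(scope="module")
def amplicons(sim_setup):
    _, vp, haps = sim_setup
    rng = np.random.default_rng(8)
    circles = [simulate_circle(haps, ContactModel(), rng, circle_id=i)
               for i in range(30)]
    return amplify(circles, vp, haps)


class TestReads:
    def test_zero_error_long_read_equals_amplicon(self, amplicons):
        rng = np.random.default_rng(1)
        reads, prov = generate_reads(amplicons, ReadProfile(platform="long"),
                                     rng, 10)
        by_id = {a.circle_id: a for a in amplicons}
        for r in reads:
            cid = prov.loc[prov.read_id == r.read_id, "circle_id"].iloc[0]
            assert r.seq == by_id[cid].seq

    def test_short_mates_are_150bp_pairs(self, amplicons):
        rng = np.random.default_rng(2)
        reads, _ = generate_reads(amplicons, SHORT_PROFILE, rng, 20)
        assert len(reads) == 40
        assert all(len(r.seq) == 150 for r in reads)
        assert sorted({r.mate for r in reads}) == [1, 2]

    def test_substitution_count_within_binomial_band(self, amplicons):
        profile = ReadProfile(platform="long", sub_error_rate=0.01)
        rng = np.random.default_rng(3)
        reads, prov = generate_reads(amplicons, profile, rng, 20)
        by_id = {a.circle_id: a for a in amplicons}
        total = 0
        total_len = 0
        for r in reads:
            cid = prov.loc[prov.read_id == r.read_id, "circle_id"].iloc[0]
            amp = by_id[cid].seq
            total += sum(a != b for a, b in zip(r.seq, amp))
            total_len += len(amp)
        expected = total_len * 0.01
        sd = (total_len * 0.01 * 0.99) ** 0.5
        assert abs(total - expected) <= 3 * sd

    def test_provenance_rows_cover_all_reads(self, amplicons):
        rng = np.random.default_rng(4)
        reads, prov = generate_reads(amplicons, LONG_PROFILE, rng, 15)
        assert set(prov.read_id) == {r.read_id for r in reads}

    def test_empty_amplicon_list_rejected(self):
        with pytest.raises(ValidationError):
            generate_reads([], LONG_PROFILE, np.random.default_rng(0), 5)


class TestSimulateRun:
    @pytest.fixture()
    def run_config(self, tmp_path, small_locus):
        from tlaphase import io as tio
        tio.write_fasta(tmp_path / "ref.fasta", [small_locus.reference])
        tio.write_vcf(tmp_path / "truth.vcf", small_locus.reference,
                      list(small_locus.variants), phased=True)
        v = small_locus.het_variants[0]
        tio.write_bed(tmp_path / "vp.bed",
                      [(small_locus.reference.name, v.pos, v.pos + 1, "vp")])
        return {
            "reference_fasta": str(tmp_path / "ref.fasta"),
            "truth_vcf": str(tmp_path / "truth.vcf"),
            "viewpoint_bed": str(tmp_path / "vp.bed"),
            "platform": "long", "n_circles": 20, "n_reads": 30, "seed": 5,
        }

    def test_malformed_config_lists_offending_keys(self, run_config, tmp_path):
        bad = dict(run_config)
        del bad["platform"]
        bad["bogus"] = 1
        with pytest.raises(ConfigError) as exc:
            simulate_run(bad, str(tmp_path / "o"))
        assert "platform" in str(exc.value) and "bogus" in str(exc.value)

    def test_zero_circles_gives_empty_outputs(self, run_config, tmp_path):
        cfg = dict(run_config, n_circles=0, n_reads=0)
        paths = simulate_run(cfg, str(tmp_path / "zero"))
        assert open(paths["reads"]).read() == ""
        prov = open(paths["provenance"]).read().strip().splitlines()
        assert len(prov) == 1  # header only

    def test_rerun_byte_identical(self, run_config, tmp_path):
        p1 = simulate_run(run_config, str(tmp_path / "a"))
        p2 = simulate_run(run_config, str(tmp_path / "b"))
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_provenance_rows_match_reads(self, run_config, tmp_path):
        paths = simulate_run(run_config, str(tmp_path / "c"))
        from tlaphase import io as tio
        reads = tio.read_fastq(paths["reads"])
        prov = pd.read_csv(paths["provenance"], sep="\t")
        assert set(prov.read_id) == {r.read_id for r in reads}
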