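"""VCF round trips, dialect rules, sample exclusion, genetic-map formats."""

import numpy as np
import pytest

import snpimpute as si
from snpimpute import vcf_io
from snpimpute.imputation_engine import SOURCE_IMPUTED, CalledGenotypes, PosteriorField
from snpimpute.types import MISSING, OBSERVED_ERRONEOUS

from helpers import make_obs, make_panel, make_sites


def _random_panel(rng, k_samples=None, L=None):
    k_samples = k_samples or int(rng.integers(1, 6))
    L = L if L is not None else int(rng.integers(1, 30))
    alleles = rng.integers(0, 2, size=(2 * k_samples, L)).astype(np.uint8)
    pos = np.cumsum(rng.integers(1, 5000, size=L))
    pops = np.repeat([f"pop{i % 2 + 1}" for i in range(k_samples)], 2)
    return make_panel(alleles, positions=pos, pops=pops)


class TestPanelRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        for trial in range(10):
            panel = _random_panel(rng)
            path = str(tmp_path / f"panel{trial}.vcf")
            vcf_io.write_panel_vcf(panel, path)
            back = vcf_io.read_panel_vcf(path)
            assert np.array_equal(back.alleles, panel.alleles)
            assert back.sites.equals(panel.sites)
            assert np.array_equal(back.sites.cm, panel.sites.cm)
            assert list(back.pop_labels) == list(panel.pop_labels)
            assert list(back.hap_ids) == list(panel.hap_ids)

    def test_three_samples_give_six_haplotypes(self, tmp_path, rng):
        panel = _random_panel(rng, k_samples=3, L=8)
        path = str(tmp_path / "p.vcf")
        vcf_io.write_panel_vcf(panel, path)
        assert vcf_io.read_panel_vcf(path).K == 6

    def test_multiallelic_record_skipped(self, tmp_path, rng):
        panel = _random_panel(rng, k_samples=2, L=10)
        path = str(tmp_path / "p.vcf")
        vcf_io.write_panel_vcf(panel, path)
        lines = open(path).read().splitlines()
        # corrupt one record into a multiallelic site
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                parts = line.split("\t")
                parts[4] = "C,G"
                lines[i + 3] = lines[i + 3]
                lines[i] = "\t".join(parts)
                break
        open(path, "w").write("\n".join(lines) + "\n")
        back = vcf_io.read_panel_vcf(path)
        assert back.L == 9

    def test_unphased_panel_record_is_hard_error(self, tmp_path, rng):
        panel = _random_panel(rng, k_samples=2, L=5)
        path = str(tmp_path / "p.vcf")
        vcf_io.write_panel_vcf(panel, path)
        text = open(path).read().replace("|", "/", 1)
        open(path, "w").write(text)
        with pytest.raises(ValueError, match="unphased"):
            vcf_io.read_panel_vcf(path)

    def test_region_filter(self, tmp_path, rng):
        panel = _random_panel(rng, k_samples=2, L=20)
        path = str(tmp_path / "p.vcf")
        vcf_io.write_panel_vcf(panel, path)
        lo, hi = int(panel.sites.pos[5]), int(panel.sites.pos[14])
        back = vcf_io.read_panel_vcf(path, region=(panel.sites.chrom, lo, hi))
        assert back.L == 10


class TestObservedRoundTrip:
    def test_genotypes_and_provenance_survive(self, tmp_path, rng):
        for trial in range(10):
            L = int(rng.integers(1, 40))
            truth = rng.integers(0, 3, L).astype(np.int8)
            g = truth.copy()
            g[rng.random(L) < 0.4] = MISSING
            typed = g != MISSING
            flip = typed & (rng.random(L) < 0.3)
            g[flip] = (g[flip] + 1) % 3
            sites = make_sites(np.cumsum(rng.integers(1, 4000, size=L)))
            obs = si.ObservedGenotypes(sites, g, truth=truth)
            path = str(tmp_path / f"obs{trial}.vcf")
            vcf_io.write_observed_vcf(obs, path)
            back = vcf_io.read_observed_vcf(path)
            assert np.array_equal(back.g_obs, obs.g_obs)
            assert np.array_equal(back.provenance(), obs.provenance())
            assert back.sites.equals(obs.sites)

    def test_missing_encoded_as_dot_slash_dot(self, tmp_path):
        sites = make_sites([100, 200])
        obs = make_obs(sites, [MISSING, 2])
        path = str(tmp_path / "o.vcf")
        vcf_io.write_observed_vcf(obs, path)
        body = [l for l in open(path) if not l.startswith("#")]
        assert body[0].split("\t")[9].startswith("./.")
        assert body[1].split("\t")[9].startswith("1/1")


class TestImputedRoundTrip:
    def _called(self, rng, L):
        p = rng.dirichlet([1, 1, 1], size=L)
        post = PosteriorField(p)
        sites = make_sites(np.cumsum(rng.integers(1, 4000, size=L)))
        g_obs = np.full(L, MISSING, np.int8)
        obs = make_obs(sites, g_obs)
        return si.call_imputed(post, obs, 0.5), post

    def test_round_trip_within_print_precision(self, tmp_path, rng):
        for trial in range(10):
            L = int(rng.integers(1, 30))
            called, post = self._called(rng, L)
            path = str(tmp_path / f"imp{trial}.vcf")
            vcf_io.write_imputed_vcf(called, post, path)
            back_called, back_post = vcf_io.read_imputed_vcf(path)
            assert np.array_equal(back_called.genotype, called.genotype)
            assert np.array_equal(back_called.source, called.source)
            assert np.abs(back_post.p - post.p).max() <= 5e-5
            assert back_called.q_gp == called.q_gp

    def test_formatting_of_given_values(self, tmp_path):
        post = PosteriorField(np.array([[0.01, 0.95, 0.04]]))
        sites = make_sites([500])
        obs = make_obs(sites, [MISSING])
        called = si.call_imputed(post, obs, 0.95)
        path = str(tmp_path / "fmt.vcf")
        vcf_io.write_imputed_vcf(called, post, path)
        field = [l for l in open(path) if not l.startswith("#")][0].split("\t")[9].strip()
        gt, ds, gp, src = field.split(":")
        assert gt == "0/1"
        assert ds == "1.0300"
        assert gp == "0.0100,0.9500,0.0400"
        assert src == "I"

    def test_uncalled_site_written_with_ds_gp(self, tmp_path):
        post = PosteriorField(np.array([[0.4, 0.35, 0.25]]))
        sites = make_sites([500])
        obs = make_obs(sites, [MISSING])
        called = si.call_imputed(post, obs, 0.95)
        path = str(tmp_path / "unc.vcf")
        vcf_io.write_imputed_vcf(called, post, path)
        field = [l for l in open(path) if not l.startswith("#")][0].split("\t")[9].strip()
        gt, ds, gp, src = field.split(":")
        assert gt == "./." and src == "N"
        assert float(ds) == pytest.approx(0.85, abs=1e-3)

    def test_gp_rows_sum_to_one_after_rounding(self, tmp_path, rng):
        called, post = self._called(rng, 25)
        path = str(tmp_path / "sum.vcf")
        vcf_io.write_imputed_vcf(called, post, path)
        for line in open(path):
            if line.startswith("#"):
                continue
            gp = line.split("\t")[9].split(":")[2]
            assert abs(sum(float(x) for x in gp.split(",")) - 1.0) <= 2e-4


class TestExcludeSamples:
    def test_exclude_none_identity(self, rng):
        panel = _random_panel(rng, k_samples=3, L=6)
        out = vcf_io.exclude_samples(panel, [])
        assert out.K == panel.K

    def test_exclude_one_drops_two_haplotypes(self, rng):
        panel = _random_panel(rng, k_samples=5, L=6)
        sid = str(panel.hap_ids[2])[:-2]
        out = vcf_io.exclude_samples(panel, [sid])
        assert out.K == panel.K - 2
        assert not any(str(h).startswith(sid + "_") for h in out.hap_ids)

    def test_unknown_sample_rejected(self, rng):
        panel = _random_panel(rng, k_samples=2, L=4)
        with pytest.raises(ValueError):
            vcf_io.exclude_samples(panel, ["NOPE"])

    def test_excluded_individual_absent_from_reference(self, small_panel):
        panel, _ = small_panel
        ind = si.sample_truth_individual(panel, seed=77)
        ref = panel.exclude_rows(ind.panel_rows)
        for row in ind.panel_rows:
            hid = str(panel.hap_ids[row])
            assert hid not in set(map(str, ref.hap_ids))


class TestGeneticMapIO:
    def test_knot_format_round_trip(self, tmp_path):
        gmap = si.GeneticMap([100.0, 5000.0, 90000.0], [0.0, 0.01, 0.2])
        path = str(tmp_path / "map.txt")
        vcf_io.write_genetic_map(gmap, path)
        back = vcf_io.read_genetic_map(path)
        assert np.array_equal(back.pos, gmap.pos)
        assert np.array_equal(back.cm, gmap.cm)

    def test_hapmap_style_format(self, tmp_path):
        path = str(tmp_path / "hapmap.txt")
        with open(path, "w") as fh:
            fh.write("Chromosome Position(bp) Rate(cM/Mb) Map(cM)\n")
            fh.write("chr22 16050000 1.5 0.0\n")
            fh.write("chr22 16150000 2.0 0.15\n")
        gmap = vcf_io.read_genetic_map(path)
        assert gmap.cm_at(16150000) == pytest.approx(0.15)
        assert gmap.cm_at(16100000) == pytest.approx(0.075)
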