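import numpy as np
import pytest

from cnvpop.consensus import Cnvr
from cnvpop.genotypes import (
    AllMissingError,
    allele_frequency,
    extract_cnvr_loci,
    filter_loci,
    read_genotype_vcf_text,
    read_population_map,
    site_frequency_spectrum,
    write_dosage_tsv,
)
from cnvpop.intervals import GenomicInterval, overlap_length
from cnvpop.simulate import write_genotype_vcf

from conftest import make_matrix

NA = np.nan


def region(start, end, chrom="chr1"):
    return Cnvr(GenomicInterval(chrom, start, end), members=(),
                approaches=frozenset(), cnvr_class="deletion", level="meta")


class TestAlleleFrequency:
    def test_worked_example(self):
        alt, maf, call_rate = allele_frequency([0, 0, 1, 2, NA])
        assert alt == pytest.approx(3 / 8)
        assert maf == pytest.approx(3 / 8)
        assert call_rate == pytest.approx(0.8)

    def test_fixed_locus(self):
        alt, maf, _ = allele_frequency([2, 2, 2])
        assert (alt, maf) == (1.0, 0.0)

    def test_all_missing_flagged(self):
        with pytest.raises(AllMissingError):
            allele_frequency([NA, NA])

    def test_matches_counting_oracle(self, rng):
        d = rng.choice([0, 1, 2, NA], size=50, p=[0.4, 0.3, 0.2, 0.1])
        alt, maf, call_rate = allele_frequency(d)
        obs = [x for x in d if not np.isnan(x)]
        assert alt == pytest.approx(sum(obs) / (2 * len(obs)))
        assert call_rate == pytest.approx(len(obs) / 50)

    def test_invariant_under_permutation(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=30)
        assert allele_frequency(d) == allele_frequency(d[rng.permutation(30)])


class TestFilterLoci:
    def test_maf_boundary_inclusive(self):
        # 10 samples: one het -> alt freq 0.05 exactly (kept); all-ref dropped
        m = make_matrix([[1] + [0] * 9, [0] * 10])
        out = filter_loci(m, maf_min=0.05)
        assert list(out.loci["locus_id"]) == ["L0"]

    def test_missingness_boundary_inclusive(self):
        # 10% missing kept, 20% missing dropped (max_missing = 0.10)
        m = make_matrix([[1, 1, 0, 0, 0, 0, 0, 0, 0, NA],
                         [1, 1, 0, 0, 0, 0, 0, 0, NA, NA]])
        out = filter_loci(m)
        assert list(out.loci["locus_id"]) == ["L0"]

    def test_matches_predicate_oracle(self, rng):
        d = rng.choice([0, 1, 2, NA], size=(60, 20), p=[0.5, 0.2, 0.2, 0.1])
        m = make_matrix(d)
        out = filter_loci(m)
        exp = []
        for i in range(60):
            row = d[i]
            obs = row[~np.isnan(row)]
            if len(obs) == 0 or np.isnan(row).mean() > 0.10:
                continue
            p = obs.sum() / (2 * len(obs))
            if min(p, 1 - p) >= 0.05:
                exp.append(f"L{i}")
        assert list(out.loci["locus_id"]) == exp

    def test_idempotent_and_subset(self, rng):
        m = make_matrix(rng.choice([0, 1, 2, NA], size=(40, 10)))
        once = filter_loci(m)
        twice = filter_loci(once)
        assert list(twice.loci["locus_id"]) == list(once.loci["locus_id"])
        assert set(once.loci["locus_id"]) <= set(m.loci["locus_id"])
        assert once.n_samples == m.n_samples  # samples untouched


class TestExtractCnvrLoci:
    def test_overlap_kept_disjoint_dropped(self):
        m = make_matrix([[1] * 4, [1] * 4], spacing=1000)  # loci at [0,100), [1000,1100)
        out = extract_cnvr_loci(m, [region(50, 400)])
        assert list(out.loci["locus_id"]) == ["L0"]

    def test_abutment_is_not_overlap(self):
        m = make_matrix([[1] * 4])  # locus [0, 100)
        assert extract_cnvr_loci(m, [region(100, 200)]).n_loci == 0

    def test_matches_all_pairs_oracle(self, rng):
        d = rng.choice([0.0, 1.0], size=(50, 5))
        m = make_matrix(d, spacing=200)
        regions = [region(int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 10_000, 15), rng.integers(50, 500, 15))]
        out = extract_cnvr_loci(m, regions)
        exp = []
        for row in m.loci.itertuples():
            iv = GenomicInterval(row.chrom, row.start0, row.end0)
            if any(overlap_length(iv, r.interval) >= 1 for r in regions):
                exp.append(row.locus_id)
        assert list(out.loci["locus_id"]) == exp


class TestSiteFrequencySpectrum:
    def test_four_locus_example(self):
        # MAFs 0.02, 0.04, 0.10, 0.50 across 50 diploids
        rows = []
        for n_alt in (2, 4, 10, 50):
            rows.append([1] * n_alt + [0] * (50 - n_alt))
        m = make_matrix(rows)
        sfs = site_frequency_spectrum(m)
        first_bin = sfs[(sfs.bin_low == 0.0) & (sfs.bin_high == 0.05)]
        assert float(first_bin["fraction"].iloc[0]) == pytest.approx(0.5)

    def test_all_half_goes_to_last_bin(self):
        m = make_matrix([[1] * 10, [1] * 10])
        sfs = site_frequency_spectrum(m)
        assert float(sfs["fraction"].iloc[-1]) == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        d = rng.choice([0, 1, 2], size=(200, 30), p=[0.6, 0.3, 0.1])
        sfs = site_frequency_spectrum(make_matrix(d))
        assert abs(sfs["fraction"].iloc[1:].sum() - 1.0) <= 1e-12

    def test_monomorphic_in_zero_class(self):
        m = make_matrix([[0] * 10, [1] * 10])
        sfs = site_frequency_spectrum(m)
        assert int(sfs["n_loci"].iloc[0]) == 1  # zero class
        assert abs(sfs["fraction"].iloc[1:].sum() - 1.0) <= 1e-12

    def test_matches_direct_binning_oracle(self, rng):
        d = rng.choice([0, 1, 2], size=(1000, 40), p=[0.55, 0.3, 0.15])
        m = make_matrix(d)
        sfs = site_frequency_spectrum(m)
        mafs = []
        for row in d:
            p = row.sum() / (2 * len(row))
            mafs.append(min(p, 1 - p))
        mafs = np.array([x for x in mafs if x > 0])
        for k in range(10):
            lo, hi = k * 0.05, (k + 1) * 0.05
            exp = ((mafs > lo) & (mafs <= hi + 1e-12)).sum() / len(mafs)
            assert float(sfs["fraction"].iloc[k + 1]) == pytest.approx(exp, abs=1e-12)

    def test_high_missingness_excluded(self):
        m = make_matrix([[1, 1, 0, 0, 0, 0, 0, 0, NA, NA],  # 20% missing: excluded
                         [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]])
        sfs = site_frequency_spectrum(m)
        assert int(sfs["n_loci"].iloc[1:].sum()) == 1

    def test_svtype_restriction(self):
        m = make_matrix([[1] * 10, [1] * 10], svtypes=["DEL", "DUP"])
        sfs = site_frequency_spectrum(m, svtype="DUP")
        assert int(sfs["n_loci"].iloc[1:].sum()) == 1

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            site_frequency_spectrum(make_matrix([[1] * 4]), bin_width=0.07)

    def test_empty_after_exclusion_is_error(self):
        m = make_matrix([[NA, NA, 1, 1]])  # 50% missing
        with pytest.raises(ValueError):
            site_frequency_spectrum(m)


class TestIo:
    def test_vcf_round_trip(self, tmp_path, rng):
        d = rng.choice([0, 1, 2, NA], size=(20, 6), p=[0.5, 0.2, 0.2, 0.1])
        m = make_matrix(d, populations=["P1"] * 3 + ["P2"] * 3)
        path = tmp_path / "g.vcf"
        write_genotype_vcf(path, m)
        pops = dict(zip(m.samples["sample_id"], m.samples["population"]))
        back = read_genotype_vcf_text(path, pops)
        assert list(back.samples["sample_id"]) == list(m.samples["sample_id"])
        assert np.array_equal(back.dosage, m.dosage, equal_nan=True)
        assert list(back.loci["start0"]) == list(m.loci["start0"])
        assert list(back.loci["svtype"]) == list(m.loci["svtype"])

    def test_population_map(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("sample_id\tpopulation\nS1\tTC\nS2\tCB\n")
        assert read_population_map(path) == {"S1": "TC", "S2": "CB"}

    def test_dosage_export(self, tmp_path):
        m = make_matrix([[0, 1, NA]])
        path = tmp_path / "d.tsv"
        write_dosage_tsv(path, m)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[5:] == ["S0", "S1", "S2"]
        assert lines[1].split("\t")[5:] == ["0", "1", "."]
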