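"""FFPE, copy-number-neutrality and impact filters, and effect priority."""

import numpy as np
import pytest

from clonepair.io_formats import GermlineSNP
from clonepair.synthetic_cohort import SimulationConfig, simulate_cohort
from clonepair.variant_filters import (
    cn_neutral_filter,
    ffpe_filter,
    find_imbalanced_snps,
    impact_filter,
    prioritise_effect,
)

from conftest import make_call


def snp(pos=10_000, vn=0.5, vt=0.25, chrom="chr1"):
    return GermlineSNP(chrom, pos, vn, {"TU1": vt})


class TestFfpeFilter:
    @pytest.mark.parametrize(
        "ref,alt,vaf_counts,removed",
        [
            ("C", "T", (5, 100), True),    # deamination change in artifact range
            ("G", "A", (9, 100), True),
            ("C", "T", (10, 100), False),  # boundary: VAF < 10% is strict
            ("A", "G", (2, 100), False),   # not a deamination change
            ("C", "T", (50, 100), False),  # high VAF
        ],
    )
    def test_rule(self, ref, alt, vaf_counts, removed):
        v = make_call(ref=ref, alt=alt, alt_count=vaf_counts[0], depth=vaf_counts[1])
        rep = ffpe_filter([v])
        assert (len(rep.removed) == 1) is removed
        if removed:
            assert rep.removed[0][1] == "ffpe_artifact"

    def test_indels_exempt(self):
        v = make_call(ref="C", alt="CT", alt_count=2, depth=100)
        assert ffpe_filter([v]).retained == [v]

    def test_idempotent(self):
        vs = [make_call(pos=p, ref="C", alt="T", alt_count=a, depth=100)
              for p, a in [(1, 5), (2, 15), (3, 9)]]
        once = ffpe_filter(vs)
        twice = ffpe_filter(once.retained)
        assert twice.retained == once.retained and not twice.removed


class TestImbalancedSnps:
    @pytest.mark.parametrize(
        "vn,vt,imbalanced",
        [
            (0.50, 0.25, True),
            (0.50, 0.55, False),   # tumour inside bounds
            (0.30, 0.10, False),   # not heterozygous in the normal
            (0.40, 0.61, True),    # normal boundary inclusive, tumour outside
            (0.60, 0.40, False),   # tumour exactly at the bound is inside
        ],
    )
    def test_rule(self, vn, vt, imbalanced):
        found = find_imbalanced_snps([snp(vn=vn, vt=vt)], "TU1")
        assert (len(found) == 1) is imbalanced

    def test_missing_tumour_vaf_errors(self):
        with pytest.raises(ValueError, match="chr1:10000"):
            find_imbalanced_snps([snp()], "TU2")


class TestCnNeutralFilter:
    @pytest.mark.parametrize(
        "vpos,spos,schrom,removed",
        [
            (10_000, 13_999, "chr1", True),   # distance 3999
            (10_000, 14_000, "chr1", True),   # boundary: within is inclusive
            (10_000, 14_001, "chr1", False),  # distance 4001
            (10_000, 10_000, "chr2", False),  # different chromosome
        ],
    )
    def test_window(self, vpos, spos, schrom, removed):
        v = make_call(pos=vpos)
        imb = [GermlineSNP(schrom, spos, 0.5, {"TU1": 0.2})]
        rep = cn_neutral_filter([v], imb)
        assert (len(rep.removed) == 1) is removed
        if removed:
            assert rep.removed[0][1] == "near_imbalanced_snp"

    def test_filter_composition_commutes(self, rng):
        variants = []
        for i in range(200):
            ref, alt = ("C", "T") if i % 3 == 0 else ("A", "G")
            depth = 100
            variants.append(make_call(
                pos=int(rng.integers(1, 100_000)) + i * 100_000, ref=ref, alt=alt,
                alt_count=int(rng.integers(0, 30)), depth=depth,
            ))
        imb = [GermlineSNP("chr1", int(rng.integers(1, 20_000_000)), 0.5,
                           {"TU1": 0.2}) for _ in range(20)]
        a = cn_neutral_filter(ffpe_filter(variants).retained, imb).retained
        b = ffpe_filter(cn_neutral_filter(variants, imb).retained).retained
        assert a == b


class TestImpactFilter:
    @pytest.mark.parametrize(
        "effect,kept",
        [
            ("frameshift_indel", True),   # HIGH
            ("missense", True),           # MODERATE
            ("splice_site", True),        # LOW, non-silent
            ("synonymous", False),        # LOW but silent
            ("three_prime_utr", False),   # MODIFIER
            ("intronic", False),
        ],
    )
    def test_rule(self, effect, kept):
        ref, alt = ("C", "CAT") if "indel" in effect else ("A", "C")
        v = make_call(ref=ref, alt=alt, effect=effect)
        rep = impact_filter([v])
        assert (len(rep.retained) == 1) is kept

    def test_unknown_impact_errors(self):
        v = make_call(effect="missense")
        object.__setattr__(v, "impact", "BOGUS")
        with pytest.raises(ValueError, match="BOGUS"):
            impact_filter([v])


class TestPrioritiseEffect:
    @pytest.mark.parametrize(
        "effects,expected",
        [
            ({"missense", "synonymous"}, "missense"),
            ({"stop_gained", "frameshift_indel"}, "stop_gained"),
            ({"synonymous"}, "synonymous"),
            ({"three_prime_utr", "five_prime_utr"}, "five_prime_utr"),
            ({"inframe_indel", "missense", "splice_site"}, "inframe_indel"),
        ],
    )
    def test_ordering(self, effects, expected):
        assert prioritise_effect(effects) == expected

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            prioritise_effect(set())


class TestOnSyntheticCohort:
    def test_planted_artifacts_removed_and_true_variants_kept(self, pathway_db):
        """Noise-controlled cohort: every planted artifact is removed by the
        FFPE filter and no true variant with expected VAF >= 0.15 is lost."""
        cfg = SimulationConfig(n_patients=3, depth=500, noise="none",
                               ffpe_artifact_count=8, cnv_region_count=0,
                               seed=7)
        truth, calls, _ = simulate_cohort(cfg)
        for pid, pt in truth.patients.items():
            for s, sample in enumerate(("TU1", "TU2")):
                sample_calls = [c for c in calls
                                if c.patient_id == pid and c.sample_id == sample]
                rep = ffpe_filter(sample_calls)
                removed_keys = {v.key for v in rep.removed_calls}
                assert pt.artifacts[sample] <= removed_keys
                high = {k for k, vv in pt.expected_vaf.items() if vv[s] >= 0.15}
                assert not (high & removed_keys)

    def test_cn_filter_hits_planted_cnv_mutations_only(self, pathway_db):
        cfg = SimulationConfig(n_patients=3, depth=500, noise="none",
                               ffpe_artifact_count=0, cnv_region_count=2,
                               p_mutation_in_cnv=0.3, seed=8)
        truth, calls, snps = simulate_cohort(cfg)
        for pid, pt in truth.patients.items():
            psnps = [s for s in snps if s.patient_id == pid]
            imb = find_imbalanced_snps(psnps, "TU1")
            assert imb, "CNV regions must yield imbalanced SNPs"
            sample_calls = [c for c in calls
                            if c.patient_id == pid and c.sample_id == "TU1"]
            rep = cn_neutral_filter(sample_calls, imb)
            removed = {v.key for v in rep.removed_calls}
            in_cnv_present = {c.key for c in sample_calls} & pt.mutations_in_cnv
            # every present in-CNV mutation near an imbalanced SNP is removed
            for key in in_cnv_present:
                near = any(abs(key[1] - s.pos) <= 4000 for s in imb)
                assert (key in removed) == near
            # nothing outside the CNV windows is removed
            assert removed <= pt.mutations_in_cnv

    def test_negative_control_removes_nothing(self, pathway_db):
        """No artifacts and no CNV regions: both filters pass everything."""
        cfg = SimulationConfig(n_patients=2, ffpe_artifact_count=0,
                               cnv_region_count=0, seed=9)
        truth, calls, snps = simulate_cohort(cfg)
        for pid in truth.patients:
            for sample in ("TU1", "TU2"):
                sc = [c for c in calls
                      if c.patient_id == pid and c.sample_id == sample]
                psnps = [s for s in snps if s.patient_id == pid]
                assert not ffpe_filter(sc).removed
                imb = find_imbalanced_snps(psnps, sample)
                assert not imb
                assert not cn_neutral_filter(sc, imb).removed
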