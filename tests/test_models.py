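"""Unit and property tests of the purity-mixture allelic model."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from masikit.models import (
    AllelicConfiguration,
    InfeasibleModelError,
    ModelFit,
    MutantPhase,
    Observations,
    PurityEstimate,
    enumerate_configs,
    enumerate_total_cn_candidates,
    expected_major_baf,
    expected_vaf,
    purity_from_vaf,
    select_model,
    to_percent,
    validate_purity,
)


def cfg(total, major, minor, phase="major"):
    return AllelicConfiguration(total, major, minor, MutantPhase(phase))


@st.composite
def any_config(draw):
    n = draw(st.integers(1, 6))
    major = draw(st.integers((n + 1) // 2, n))
    minor = n - major
    phases = ["major"] + (["minor"] if 0 < minor < major else [])
    return cfg(n, major, minor, draw(st.sampled_from(phases)))


class TestConfigurationInvariants:
    def test_copies_sum_and_mutant_present(self):
        c = cfg(3, 2, 1, "minor")
        assert c.mutant_copies == 1
        assert c.wild_copies == 2
        assert not c.is_masi

    def test_masi_flag(self):
        assert cfg(3, 3, 0).is_masi  # wild-type lost
        assert cfg(3, 2, 1).is_masi  # mutant gained
        assert not cfg(2, 1, 1).is_masi  # balanced heterozygous

    @pytest.mark.parametrize(
        "args",
        [(0, 0, 0), (2, 0, 2), (3, 2, 2), (2, 2, 0, "minor")],
    )
    def test_invalid_configurations_rejected(self, args):
        with pytest.raises(ValueError):
            cfg(*args)


class TestExpectedFractions:
    @pytest.mark.parametrize(
        "purity, config, pct",
        [
            (0.642, cfg(3, 3, 0), 72.9),
            (1.0, cfg(2, 1, 1), 50.0),
            (0.641, cfg(2, 2, 0), 64.1),
            (0.906, cfg(1, 1, 0), 82.8),
            (0.988, cfg(3, 2, 1), 66.1),
            (0.0, cfg(3, 3, 0), 0.0),
        ],
    )
    def test_expected_vaf(self, purity, config, pct):
        assert to_percent(expected_vaf(purity, config)) == pct

    @pytest.mark.parametrize(
        "purity, config, pct",
        [
            (0.642, cfg(3, 3, 0), 86.4),
            (0.988, cfg(3, 2, 1), 66.5),
            (0.3, cfg(2, 1, 1), 50.0),
            (0.95, cfg(2, 1, 1), 50.0),
            (0.906, cfg(1, 1, 0), 91.4),
        ],
    )
    def test_expected_major_baf(self, purity, config, pct):
        assert to_percent(expected_major_baf(purity, config)) == pct

    def test_purity_bounds_enforced(self):
        with pytest.raises(ValueError):
            expected_vaf(1.2, cfg(2, 1, 1))

    @given(p=st.floats(0.01, 1.0), config=any_config())
    def test_vaf_monotone_in_mutant_copies(self, p, config):
        """At fixed total CN, more mutant copies means higher expected VAF."""
        n = config.total_cn
        vafs = []
        for major in range((n + 1) // 2, n + 1):
            c = cfg(n, major, n - major)
            vafs.append(expected_vaf(p, c))
        assert all(b > a for a, b in zip(vafs, vafs[1:]))

    @given(p=st.floats(0.01, 1.0), config=any_config())
    def test_baf_monotone_in_major_copies(self, p, config):
        n = config.total_cn
        bafs = [
            expected_major_baf(p, cfg(n, major, n - major))
            for major in range((n + 1) // 2, n + 1)
        ]
        assert all(b > a for a, b in zip(bafs, bafs[1:]))

    @given(p=st.floats(0.0, 0.999), n=st.integers(1, 6))
    def test_baf_vaf_gap_under_full_loh(self, p, n):
        """With all copies mutant, BAF - VAF = (1-p)/(pN + 2(1-p))."""
        c = cfg(n, n, 0)
        gap = expected_major_baf(p, c) - expected_vaf(p, c)
        denom = p * n + 2 * (1 - p)
        assert math.isclose(gap, (1 - p) / denom, abs_tol=1e-12)
        if p < 1:
            assert gap > 0

    @given(config=any_config(), p=st.floats(0.0, 1.0))
    def test_phase_symmetry_of_baf(self, config, p):
        """Which haplotype carries the mutation cannot move the SNP BAF."""
        if config.minor_copies == 0 or config.minor_copies == config.major_copies:
            return
        mirrored = cfg(
            config.total_cn,
            config.major_copies,
            config.minor_copies,
            "minor" if config.mutant_on is MutantPhase.MAJOR else "major",
        )
        assert expected_major_baf(p, config) == expected_major_baf(p, mirrored)


class TestPurityBackCalculation:
    @pytest.mark.parametrize(
        "vaf, config, pct",
        [
            (0.732, cfg(3, 3, 0), 64.6),
            (0.68, cfg(2, 2, 0), 68.0),
            (0.5, cfg(2, 1, 1), 100.0),
            (0.659, cfg(3, 2, 1), 98.3),
            (0.799, cfg(1, 1, 0), 88.8),
        ],
    )
    def test_printed_back_calculations(self, vaf, config, pct):
        est = purity_from_vaf(vaf, config)
        assert est.source == "vaf_backcalc"
        assert to_percent(est.fraction) == pct

    def test_infeasible_raises(self):
        # a heterozygous model can never exceed 50% VAF
        with pytest.raises(InfeasibleModelError):
            purity_from_vaf(0.68, cfg(3, 2, 1, "minor"))

    @given(p=st.floats(1e-6, 1.0), config=any_config())
    def test_round_trip_identity(self, p, config):
        """purity_from_vaf inverts expected_vaf to near machine precision."""
        v = expected_vaf(p, config)
        if not 0 < v < 1:
            return
        assert abs(purity_from_vaf(v, config).fraction - p) < 1e-12


class TestCandidateEnumeration:
    @pytest.mark.parametrize(
        "mean, expected",
        [
            (3.4, {3, 4}),
            (1.6, {1, 2}),
            (2.0, {2, 3}),
            (2.4, {2, 3}),
            (1.9, {1, 2}),
            (2.5, {3, 4}),  # exact half rounds away from two
            (1.5, {1}),  # i-1 = 0 dropped
            (0.4, {1}),  # never empty
        ],
    )
    def test_candidate_totals(self, mean, expected):
        assert enumerate_total_cn_candidates(mean) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            enumerate_total_cn_candidates(bad)

    def test_enumerate_configs_examples(self):
        assert enumerate_configs({2}) == [cfg(2, 2, 0), cfg(2, 1, 1)]
        assert enumerate_configs({1}) == [cfg(1, 1, 0)]
        assert enumerate_configs({3}) == [
            cfg(3, 3, 0),
            cfg(3, 2, 1),
            cfg(3, 2, 1, "minor"),
        ]

    @given(totals=st.sets(st.integers(1, 6), min_size=1, max_size=4))
    def test_every_config_valid_and_unique(self, totals):
        configs = enumerate_configs(totals)
        assert len(set(configs)) == len(configs)
        for c in configs:
            assert c.mutant_copies >= 1
            assert c.major_copies + c.minor_copies == c.total_cn


def obs(vaf, baf, purity, mean_cn=None):
    return Observations(
        observed_vaf=vaf,
        observed_baf_upper=baf,
        tumor_content=PurityEstimate(purity, source="ihc_counts"),
        mean_segment_cn=mean_cn,
    )


class TestModelSelection:
    def test_loh_triple_mutant_case(self):
        """High BAF + high VAF at moderate purity: 3 mutant, 0 wild-type."""
        fits = select_model(obs(0.732, 0.910, 0.642), enumerate_configs({3, 4}))
        top = fits[0]
        assert top.selected
        assert (top.config.total_cn, top.config.mutant_copies) == (3, 3)
        assert to_percent(top.expected_vaf) == 72.9
        assert to_percent(top.expected_baf) == 86.4
        assert to_percent(top.backcalc_purity.fraction) == 64.6
        shortlisted = sorted(
            {to_percent(f.expected_baf) for f in fits if f.baf_shortlisted}
        )
        assert shortlisted == [86.4, 89.1]

    def test_gained_mutant_retained_wild_case(self):
        """Near-pure tumor with BAF ~2/3: two mutant plus one wild copy."""
        fits = select_model(obs(0.659, 0.660, 0.988), enumerate_configs({3, 4}))
        top = fits[0]
        assert (top.config.mutant_copies, top.config.wild_copies) == (2, 1)
        assert to_percent(top.expected_vaf) == 66.1
        assert to_percent(top.backcalc_purity.fraction) == 98.3

    def test_double_mutant_no_wild_case(self):
        fits = select_model(obs(0.680, 0.710, 0.641), enumerate_configs({2, 3}))
        top = fits[0]
        assert (top.config.total_cn, top.config.mutant_copies) == (2, 2)
        assert to_percent(top.expected_vaf) == 64.1
        assert to_percent(top.backcalc_purity.fraction) == 68.0

    def test_wild_type_loss_single_copy_case(self):
        fits = select_model(obs(0.799, 0.850, 0.906), enumerate_configs({1, 2}))
        top = fits[0]
        assert (top.config.total_cn, top.config.mutant_copies) == (1, 1)
        assert to_percent(top.expected_vaf) == 82.8
        assert to_percent(top.backcalc_purity.fraction) == 88.8

    def test_heterozygous_diploid_recognised(self):
        p = 0.8
        fits = select_model(
            obs(p / 2, 0.5, p), enumerate_configs({2, 3})
        )
        top = fits[0]
        assert (top.config.major_copies, top.config.minor_copies) == (1, 1)
        assert not top.config.is_masi

    def test_selected_implies_shortlisted_and_sorted_first(self):
        fits = select_model(obs(0.732, 0.910, 0.642), enumerate_configs({3, 4}))
        assert fits[0].selected and fits[0].baf_shortlisted
        assert sum(f.selected for f in fits) == 1

    def test_empty_configs_rejected(self):
        with pytest.raises(ValueError):
            select_model(obs(0.5, 0.6, 0.8), [])

    def test_all_infeasible_raises(self):
        # VAF 0.9 is unreachable for every heterozygous-or-lower model here
        with pytest.raises(InfeasibleModelError):
            select_model(obs(0.9, 0.5, 0.5), [cfg(2, 1, 1)])


class TestPurityValidation:
    def test_agreement_within_tolerance(self):
        fit = ModelFit(
            config=cfg(3, 3, 0), expected_baf=0.86, expected_vaf=0.73,
            baf_distance=0, vaf_distance=0, selected=True,
            backcalc_purity=PurityEstimate(0.646, source="vaf_backcalc"),
        )
        assert validate_purity(fit, PurityEstimate(0.642), tolerance=0.05)
        assert not validate_purity(fit, PurityEstimate(0.90), tolerance=0.05)

    def test_missing_backcalc_rejected(self):
        fit = ModelFit(
            config=cfg(3, 3, 0), expected_baf=0.86, expected_vaf=0.73,
            baf_distance=0, vaf_distance=0,
        )
        with pytest.raises(ValueError):
            validate_purity(fit, PurityEstimate(0.642))
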