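"""Cohort simulator: determinism, transmission law, ascertainment, hazards."""

import numpy as np
import pytest

import mendelscan as ms
from mendelscan.pedigree import Individual, Pedigree, parse_pedigrees
from mendelscan.simulate import (
    HazardConfig,
    SimulationConfig,
    SiteSpec,
    _streams,
    default_sites,
    drop_variant,
    simulate_cohort,
    simulate_pedigree_set,
    simulate_phenotypes,
    simulate_site,
    write_cohort,
)


class TestPedigreeSet:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=17)
        a = simulate_pedigree_set(cfg)
        b = simulate_pedigree_set(cfg)
        assert [p.member_ids for p in a] == [p.member_ids for p in b]
        assert [p.typed_members for p in a] == [p.typed_members for p in b]

    def test_structural_contracts(self):
        cfg = SimulationConfig(seed=4, n_families=8)
        peds = simulate_pedigree_set(cfg)
        assert len(peds) == 8
        for ped in peds:
            assert len(ped.founders) >= 2  # founder couple at minimum
            assert set(ped.typed_members) <= set(ped.member_ids)
            assert 2 <= len(ped.typed_members) <= cfg.max_typed_per_family
            # validation happens in the Pedigree constructor; priors must build
            ms.precompute_family_priors([ped], 0.01)

    def test_impossible_config_errors(self):
        with pytest.raises(ValueError):
            simulate_pedigree_set(SimulationConfig(seed=0, n_families=0))


class TestDropVariant:
    def test_transmission_frequency_half(self):
        """Children of carrier × non-carrier matings inherit with
        probability 1/2 (10,000 offspring, 95% binomial band)."""
        father = Individual("F", "X", sex="male")
        mother = Individual("M", "X", sex="female")
        kids = tuple(
            Individual(f"K{i}", "X", "F", "M", "female") for i in range(10)
        )
        ped = Pedigree("X", (father, mother) + kids)
        rng = np.random.default_rng(0)
        n = carried = 0
        while n < 10_000:
            carriers = drop_variant(ped, 0.5, rng)
            if carriers["F"] + carriers["M"] == 1:
                for k in kids:
                    carried += carriers[k.individual_id]
                    n += 1
        assert 0.49 <= carried / n <= 0.51

    def test_noncarrier_parents_never_transmit(self, trio):
        rng = np.random.default_rng(1)
        for _ in range(200):
            carriers = drop_variant(trio, 0.3, rng)
            if carriers["F1"] == 0 and carriers["M1"] == 0:
                assert carriers["C1"] == 0

    def test_founder_frequency_matches_prior(self):
        """Empirical founder carrier rate ≈ α(1−α)^(F−1)/Z within 3 SE."""
        cfg = SimulationConfig(seed=2, n_families=1)
        (ped,) = simulate_pedigree_set(cfg)
        f0 = ped.founders[0]
        a = 0.1
        expected = ms.config_prior(ped, {f0: 1}, a)
        rng = np.random.default_rng(3)
        hits = sum(drop_variant(ped, a, rng)[f0] for _ in range(40_000))
        se = np.sqrt(expected * (1 - expected) / 40_000)
        assert abs(hits / 40_000 - expected) <= 3 * se


class TestSimulateSite:
    def test_sigma_zero_limit(self, trio):
        ped = trio.with_typed(("F1", "M1", "C1"))
        rng = np.random.default_rng(0)
        vals = simulate_site(
            [ped], {m: 0 for m in ped.member_ids}, SiteSpec("mendelian", sigma0=1e-12, sigma1=1e-12), rng
        )
        assert all(v == pytest.approx(-3.0, abs=1e-9) for v in vals.values())

    def test_mendelian_minor_mode_tracks_carriers(self):
        cfg = SimulationConfig(seed=9, n_families=40)
        peds = simulate_pedigree_set(cfg)
        rngs = _streams(9)
        carriers = {}
        for p in peds:
            carriers.update(drop_variant(p, 0.2, rngs[1]))
        vals = simulate_site(peds, carriers, SiteSpec("mendelian"), rngs[2])
        typed = [t for p in peds for t in p.typed_members]
        x = np.array([vals[t] for t in typed])
        frac_minor = (x > -1.5).mean()  # midpoint between the modes
        frac_carrier = np.mean([carriers[t] for t in typed])
        assert frac_minor == pytest.approx(frac_carrier, abs=0.02)

    def test_mixture_ignores_pedigree(self):
        """Mixture sites have no family clustering: the between-family
        variance of carrier counts matches the binomial expectation."""
        cfg = SimulationConfig(seed=5, n_families=50)
        peds = simulate_pedigree_set(cfg)
        rng = np.random.default_rng(5)
        vals = simulate_site(peds, None, SiteSpec("mixture"), rng, alpha1=0.2)
        counts = [
            sum(vals[t] > -1.5 for t in p.typed_members) for p in peds
        ]
        sizes = [len(p.typed_members) for p in peds]
        # dispersion index of binomial counts ~ (1-p); family clustering
        # would push it well above 1
        p_hat = sum(counts) / sum(sizes)
        disp = np.var(counts) / np.mean(
            [n * p_hat * (1 - p_hat) for n in sizes]
        )
        assert disp < 2.0


class TestPhenotypes:
    @pytest.fixture(scope="class")
    def peds(self):
        return simulate_pedigree_set(SimulationConfig(seed=21, n_families=15))

    def test_ascertainment_contract(self, peds):
        rngs = _streams(21)
        carriers = {p.family_id: {m: 0 for m in p.member_ids} for p in peds}
        recs, retained = simulate_phenotypes(
            peds, carriers, HazardConfig(hazard_ratio=1.0), 2, rngs[3]
        )
        assert retained == [p.family_id for p in peds]
        by_fam = {p.family_id: p for p in peds}
        for fam in retained:
            ped = by_fam[fam]
            n_affected = sum(
                r.affected
                for r in recs
                if r.individual_id in ped and r.sex == "female"
            )
            assert n_affected >= 2

    def test_null_hazard_no_carrier_shift(self, peds):
        """At hazard ratio 1 carriers and non-carriers have the same onset
        distribution (log-rank p approximately uniform: here just not tiny)."""
        from lifelines.statistics import logrank_test

        rngs = _streams(99)
        carriers_by_fam = {}
        flat = {}
        for p in peds:
            c = drop_variant(p, 0.3, rngs[1])
            carriers_by_fam[p.family_id] = c
            flat.update(c)
        recs, _ = simulate_phenotypes(
            peds, carriers_by_fam, HazardConfig(hazard_ratio=1.0), 1, rngs[3]
        )
        females = [r for r in recs if r.sex == "female"]
        t = [r.event_or_censor_age for r in females]
        e = [r.affected for r in females]
        g = [flat[r.individual_id] for r in females]
        res = logrank_test(
            [ti for ti, gi in zip(t, g) if gi],
            [ti for ti, gi in zip(t, g) if not gi],
            [ei for ei, gi in zip(e, g) if gi],
            [ei for ei, gi in zip(e, g) if not gi],
        )
        assert res.p_value > 1e-3

    def test_strong_hazard_raises_carrier_risk_and_advances_onset(self, peds):
        """Hazard ratio 5: carrier females are affected far more often in
        every replicate, and their pooled onset ages are earlier."""
        rngs = _streams(13)
        risk_higher = 0
        onset_c, onset_n = [], []
        for _ in range(20):
            carriers_by_fam = {}
            flat = {}
            for p in peds:
                c = drop_variant(p, 0.4, rngs[1])
                carriers_by_fam[p.family_id] = c
                flat.update(c)
            recs, _ = simulate_phenotypes(
                peds, carriers_by_fam, HazardConfig(hazard_ratio=5.0), 1, rngs[3]
            )
            females = [r for r in recs if r.sex == "female"]
            aff_c = [r for r in females if flat[r.individual_id]]
            aff_n = [r for r in females if not flat[r.individual_id]]
            if aff_c and np.mean([r.affected for r in aff_c]) > np.mean(
                [r.affected for r in aff_n]
            ):
                risk_higher += 1
            onset_c += [r.event_or_censor_age for r in aff_c if r.affected]
            onset_n += [r.event_or_censor_age for r in aff_n if r.affected]
        assert risk_higher >= 19
        assert np.median(onset_c) < np.median(onset_n)

    def test_unreachable_ascertainment_errors(self, peds):
        carriers = {p.family_id: {m: 0 for m in p.member_ids} for p in peds}
        with pytest.raises(RuntimeError, match="ascertainment"):
            simulate_phenotypes(
                peds,
                carriers,
                HazardConfig(hazard_ratio=1.0),
                min_affected=12,
                rng=np.random.default_rng(0),
                retry_budget=5,
            )


class TestCohortRoundTrip:
    def test_files_reload_cleanly(self, tmp_path):
        cfg = SimulationConfig(seed=30, n_families=6, sites=default_sites(2, 2, 2))
        cohort = simulate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path)
        peds = parse_pedigrees(paths["pedigree"])
        matrix = ms.load_matrix(paths["m_values"], scale="m")
        peds = ms.attach_typed_members(peds, matrix.sample_ids)
        assert [p.typed_members for p in peds] == [
            p.typed_members for p in cohort.pedigrees
        ]
        ann = ms.load_annotation(paths["annotation"])
        assert set(matrix.probe_ids) <= set(ann.index)
        phen = ms.parse_phenotypes(paths["phenotypes"])
        assert len(phen) == sum(len(p) for p in cohort.pedigrees)

    def test_byte_identical_rerun(self, tmp_path):
        cfg = SimulationConfig(seed=31, n_families=5, sites=default_sites(1, 1, 1))
        write_cohort(simulate_cohort(cfg), tmp_path / "a")
        write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for name in ("pedigree.tsv", "m_values.tsv", "phenotypes.tsv", "annotation.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
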