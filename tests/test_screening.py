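"""Screening, trend validation, Cox association, and the pipeline."""

import numpy as np
import pandas as pd
import pytest

import mendelscan as ms
from mendelscan.pedigree import PhenotypeRecord
from mendelscan.screening import bonferroni_alpha, cox_lrt, snp_trend_test
from mendelscan.simulate import (
    SimulationConfig,
    default_sites,
    simulate_cohort,
    write_cohort,
)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected", [(0.05, 1000, 5e-5), (0.05, 1, 0.05), (0.01, 20, 5e-4)]
    )
    def test_values(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_zero_tests_errors(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_significant_set_matches_threshold(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0, 1e-3, 50)
        thr = bonferroni_alpha(0.05, 1000)
        assert {i for i, p in enumerate(ps) if p < thr} == {
            i for i, p in enumerate(ps) if p < 5e-5
        }


@pytest.fixture(scope="module")
def mini_cohort():
    cfg = SimulationConfig(
        seed=6, n_families=10, sites=default_sites(3, 3, 4)
    )
    return simulate_cohort(cfg)


class TestScreen:
    def test_top_k_ordering(self, mini_cohort):
        sr = ms.screen_sites(mini_cohort.matrix, mini_cohort.pedigrees, k=2)
        dl = sr.table["delta_l"].to_numpy()
        assert np.all(np.diff(dl) <= 1e-12)
        assert len(sr.top) == 2
        assert sr.top["delta_l"].iloc[0] == sr.table["delta_l"].max()

    def test_tie_break_lexicographic(self):
        df = pd.DataFrame(
            {"probe_id": ["b", "a"], "delta_l": [1.0, 1.0]}
        ).sort_values(["delta_l", "probe_id"], ascending=[False, True])
        # the screen sorts with the same key; spot-check the convention
        assert list(df["probe_id"]) == ["a", "b"]

    def test_k_larger_than_probes_warns(self, mini_cohort):
        with pytest.warns(UserWarning, match="returning all"):
            sr = ms.screen_sites(mini_cohort.matrix, mini_cohort.pedigrees, k=10_000)
        assert sr.top_k == len(sr.table)

    def test_constant_probe_skipped(self, mini_cohort):
        mat = mini_cohort.matrix
        vals = mat.values.copy()
        vals.loc["cg_const"] = 0.0
        sr = ms.screen_sites(
            ms.MethylationMatrix(values=vals, scale="m"),
            mini_cohort.pedigrees,
            k=3,
        )
        assert "cg_const" in sr.skipped


class TestSnpTrend:
    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            snp_trend_test(np.arange(10.0), np.ones(10, dtype=bool))

    def test_detects_monotone_trend(self):
        rng = np.random.default_rng(8)
        dl = rng.gamma(2, 2, 5000)
        p_near = 1 / (1 + np.exp(-(-3 + 0.6 * dl)))
        near = rng.random(5000) < p_near
        rep = snp_trend_test(dl, near)
        assert rep["p_value"] < 1e-6
        props = [b["prop_near_snp"] for b in rep["bins"].to_dict("records")]
        assert props[-1] > props[0]

    def test_null_is_not_rejected_typically(self):
        rng = np.random.default_rng(9)
        dl = rng.gamma(2, 2, 4000)
        rejections = 0
        for _ in range(20):
            near = rng.random(4000) < 0.1
            rejections += snp_trend_test(dl, near)["p_value"] < 0.05
        assert rejections <= 4


def _phen(n, events, rng, q=None):
    onset = 120 * rng.exponential(size=n) ** (1 / 4.5)
    censor = rng.uniform(40, 80, n)
    recs, qd = [], {}
    for i in range(n):
        recs.append(
            PhenotypeRecord(
                f"i{i}",
                bool(onset[i] <= censor[i]),
                float(min(onset[i], censor[i])),
                "female",
            )
        )
        qd[f"i{i}"] = float(q[i]) if q is not None else float(rng.uniform())
    return recs, qd


class TestCoxLrt:
    def test_constant_covariate(self):
        rng = np.random.default_rng(1)
        recs, _ = _phen(100, None, rng)
        res = cox_lrt({f"i{i}": 0.5 for i in range(100)}, recs)
        assert res.lrt_statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_events_errors(self):
        recs = [PhenotypeRecord(f"i{i}", False, 50.0, "female") for i in range(10)]
        with pytest.raises(ValueError, match="events"):
            cox_lrt({f"i{i}": float(i) for i in range(10)}, recs)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        q = rng.uniform(0, 1, 120)
        recs, qd = _phen(120, None, rng, q)
        base = cox_lrt(qd, recs)
        scaled = cox_lrt({k: 10 * v - 3 for k, v in qd.items()}, recs)
        assert scaled.lrt_statistic == pytest.approx(base.lrt_statistic, abs=1e-6)

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(0, 1, 150)
        recs, qd = _phen(150, None, rng, q)
        a = cox_lrt(qd, recs, ties="efron")
        b = cox_lrt(qd, recs, ties="breslow")
        assert a.lrt_statistic == pytest.approx(b.lrt_statistic, rel=1e-5, abs=1e-6)

    def test_males_excluded_by_default(self):
        rng = np.random.default_rng(4)
        recs, qd = _phen(50, None, rng)
        males = [
            PhenotypeRecord(f"m{i}", True, 50.0, "male") for i in range(5)
        ]
        qd.update({f"m{i}": 1.0 for i in range(5)})
        res = cox_lrt(qd, recs + males)
        assert res.n_at_risk == 50

    def test_strong_effect_detected(self):
        """Carriers with hazard ratio ~8 in a moderate cohort give a tiny
        LRT p-value."""
        rng = np.random.default_rng(5)
        carrier = rng.random(200) < 0.3
        hr = np.where(carrier, 8.0, 1.0)
        onset = 120 * (rng.exponential(size=200) / hr) ** (1 / 4.5)
        censor = rng.uniform(40, 80, 200)
        recs = [
            PhenotypeRecord(
                f"i{i}",
                bool(onset[i] <= censor[i]),
                float(min(onset[i], censor[i])),
                "female",
            )
            for i in range(200)
        ]
        res = cox_lrt({f"i{i}": float(carrier[i]) for i in range(200)}, recs)
        assert res.p_value < 1e-6


class TestPipeline:
    def test_end_to_end_outputs(self, tmp_path, mini_cohort):
        paths = write_cohort(mini_cohort, tmp_path / "cohort")
        cfg = {
            "m_values": str(paths["m_values"]),
            "values_scale": "m",
            "pedigree": str(paths["pedigree"]),
            "annotation": str(paths["annotation"]),
            "phenotypes": str(paths["phenotypes"]),
            "top_k": 3,
            "alpha_carrier": 0.01,
            "seed": 1,
        }
        out = tmp_path / "run"
        manifest = ms.run_pipeline(cfg, out)
        for fname in (
            "filter_report.tsv",
            "delta_l.tsv",
            "top_probes.tsv",
            "carriers.tsv",
            "associations.tsv",
            "manifest.json",
        ):
            assert (out / fname).exists(), fname
        top = pd.read_csv(out / "top_probes.tsv", sep="\t")
        assert len(top) <= 3
        assoc = pd.read_csv(out / "associations.tsv", sep="\t")
        assert set(assoc["probe_id"]) == set(top["probe_id"])
        assert manifest["associate"]["threshold"] == pytest.approx(0.05 / 3)

    def test_rerun_is_bit_identical(self, tmp_path, mini_cohort):
        paths = write_cohort(mini_cohort, tmp_path / "cohort")
        cfg = {
            "m_values": str(paths["m_values"]),
            "pedigree": str(paths["pedigree"]),
            "annotation": str(paths["annotation"]),
            "top_k": 2,
            "seed": 3,
        }
        ms.run_pipeline(cfg, tmp_path / "a")
        ms.run_pipeline(cfg, tmp_path / "b")
        for f in ("delta_l.tsv", "carriers.tsv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_end_to_end_recovers_causal_site(self, tmp_path):
        """Strong-effect cohort (carrier hazard ratio 5, high-risk familial
        baseline): the causal site reaches the top-20 screen and carries
        the smallest association p-value, below the Bonferroni threshold."""
        from mendelscan.simulate import HazardConfig

        cfg = SimulationConfig(
            seed=800,
            sites=default_sites(20, 90, 90),
            hazard=HazardConfig(weibull_scale=65.0, hazard_ratio=5.0),
        )
        cohort = simulate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path / "cohort")
        out = tmp_path / "run"
        ms.run_pipeline(
            {
                "m_values": str(paths["m_values"]),
                "pedigree": str(paths["pedigree"]),
                "annotation": str(paths["annotation"]),
                "phenotypes": str(paths["phenotypes"]),
                "top_k": 20,
                "seed": 800,
            },
            out,
        )
        assoc = pd.read_csv(out / "associations.tsv", sep="\t")
        causal = "cg00000000"  # the first Mendelian site drives the hazard
        top = pd.read_csv(out / "top_probes.tsv", sep="\t")
        assert causal in set(top["probe_id"])
        row = assoc.set_index("probe_id").loc[causal]
        assert row["p_value"] == assoc["p_value"].min()
        assert bool(row["significant"])

    def test_missing_phenotypes_stage_error(self, tmp_path, mini_cohort):
        paths = write_cohort(mini_cohort, tmp_path / "cohort")
        cfg = {
            "m_values": str(paths["m_values"]),
            "pedigree": str(paths["pedigree"]),
            "annotation": str(paths["annotation"]),
            "top_k": 2,
            "stages": ["associate"],
        }
        with pytest.raises(RuntimeError, match="associate"):
            ms.run_pipeline(cfg, tmp_path / "x")
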