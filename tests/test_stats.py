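"""Nested mixed models: degenerate oracles, recovery, and an independent
cross-check against R lmerTest on the same data."""

import subprocess
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fluorox.stats import (
    descriptive_summary,
    fit_full_model,
    fit_posthoc_model,
    unpaired_ttest,
)
from fluorox.synthetic import PhantomConfig, simulate_records


def _single_level(records, oxy=30.0):
    return records[records.oxygen_percent == oxy]


class TestPosthocModel:
    def test_zero_variance_groups_recover_exact_means(self):
        df = pd.DataFrame(
            {
                "mother_id": ["W1", "W1", "W2", "W2", "K1", "K1", "K2", "K2"],
                "genotype": ["WT"] * 4 + ["KO"] * 4,
                "placenta_id": [f"P{i}" for i in range(8)],
                "oxygen_percent": 30.0,
                "po2_mmhg": [102.0] * 4 + [38.0] * 4,
            }
        )
        r = fit_posthoc_model(df, "po2_mmhg")
        emm = r.emmeans.set_index("genotype")
        assert emm.loc["WT", "estimate"] == pytest.approx(102.0)
        assert emm.loc["KO", "estimate"] == pytest.approx(38.0)

    def test_one_placenta_per_mother_equals_t_test(self):
        """With a single placenta per mother and no within factor, the
        mixed model must collapse to the two-sample t-test."""
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "mother_id": [f"M{i}" for i in range(12)],
                "genotype": ["WT"] * 6 + ["KO"] * 6,
                "placenta_id": [f"Q{i}" for i in range(12)],
                "oxygen_percent": 30.0,
                "po2_mmhg": np.r_[rng.normal(100, 25, 6), rng.normal(70, 25, 6)],
            }
        )
        r = fit_posthoc_model(df, "po2_mmhg")
        t, p = sps.ttest_ind(df.po2_mmhg[:6], df.po2_mmhg[6:])
        row = r.anova.iloc[0]
        assert row.p == pytest.approx(p, abs=1e-3)
        assert abs(row.den_df - 10) <= 1.0

    def test_genotype_gap_recovery_at_study_size(self):
        """Over repeated study-sized simulations with a true 64 mmHg WT-KO gap
        at 30% O2, the mean estimated gap is within 10 mmHg of the truth."""
        cfg = PhantomConfig()
        gaps = []
        for s in range(100):
            rec = _single_level(simulate_records(cfg, seed=40_000 + s))
            emm = fit_posthoc_model(rec, "po2_mmhg").emmeans.set_index("genotype")
            gaps.append(emm.loc["WT", "estimate"] - emm.loc["KO", "estimate"])
        assert np.mean(gaps) == pytest.approx(64.0, abs=10.0)

    def test_requires_single_oxygen_level_and_both_genotypes(self, default_records):
        with pytest.raises(ValueError, match="single oxygen"):
            fit_posthoc_model(default_records, "po2_mmhg")
        only_wt = _single_level(default_records)
        only_wt = only_wt[only_wt.genotype == "WT"]
        with pytest.raises(ValueError, match="genotype"):
            fit_posthoc_model(only_wt, "po2_mmhg")


class TestFullModel:
    def test_constant_outcome_gives_degenerate_diagnostic(self, default_records):
        rec = default_records.copy()
        rec["po2_mmhg"] = 50.0
        r = fit_full_model(rec, "po2_mmhg")
        assert r.degenerate and r.singular

    def test_detects_configured_interaction(self, default_records):
        """The default study carries a KO deficit only at 30% O2, which the
        interaction term must detect; EMMs must mirror the group structure."""
        r = fit_full_model(default_records, "po2_mmhg")
        a = r.anova.set_index("source")
        assert a.loc["oxygen", "p"] < 1e-6
        assert a.loc["genotype_x_oxygen", "p"] < 0.01
        emm = r.emmeans
        cell = emm.dropna(subset=["oxygen_percent"]).set_index(
            ["genotype", "oxygen_percent"]
        )
        assert (
            cell.loc[("WT", 30.0), "estimate"] > cell.loc[("KO", 30.0), "estimate"]
        )
        for g in ("WT", "KO"):
            sub = cell.loc[g].sort_index()
            assert sub.estimate.is_monotonic_increasing
        assert (emm.ci_lo <= emm.estimate).all() and (emm.estimate <= emm.ci_hi).all()

    def test_requires_two_mothers_per_genotype_and_two_levels(self, default_records):
        single_mother = default_records[
            default_records.mother_id.isin(["WT1", "KO1", "KO2"])
        ]
        with pytest.raises(ValueError, match="mothers"):
            fit_full_model(single_mother, "po2_mmhg")
        one_level = _single_level(default_records)
        with pytest.raises(ValueError, match="oxygen levels"):
            fit_full_model(one_level, "po2_mmhg")

    def test_qc_flagged_rows_are_excluded(self, default_records):
        rec = default_records.copy()
        rec["qc_unusable"] = False
        rec["qc_nonconverged"] = False
        poison = rec.index[:5]
        rec.loc[poison, "po2_mmhg"] = 1e9
        rec.loc[poison, "qc_unusable"] = True
        r = fit_full_model(rec, "po2_mmhg")
        assert r.method["n_obs"] == len(rec) - 5
        assert abs(r.emmeans.estimate.max()) < 1e4


class TestDescriptives:
    def test_hand_arithmetic(self):
        df = pd.DataFrame(
            {
                "mother_id": ["M1", "M1", "M2"],
                "genotype": ["WT", "WT", "KO"],
                "placenta_id": ["a", "b", "c"],
                "oxygen_percent": 30.0,
                "po2_mmhg": [0.0, 10.0, 55.0],
            }
        )
        out = descriptive_summary(df, "po2_mmhg").set_index("genotype")
        assert out.loc["WT", "mean"] == pytest.approx(5.0)
        assert out.loc["WT", "sd"] == pytest.approx(np.sqrt(50.0), abs=1e-9)
        # singleton group: SD and CI reported as missing
        assert np.isnan(out.loc["KO", "sd"])
        assert np.isnan(out.loc["KO", "ci_lo"])

    def test_group_means_match_configured_baselines(self, default_records):
        """Truth-table group means track the configured per-condition
        baselines within the jitter's standard error."""
        cfg = PhantomConfig()
        out = descriptive_summary(default_records, "po2_mmhg")
        wt = out[out.genotype == "WT"].set_index("oxygen_percent")
        total_sd = np.sqrt(
            cfg.sd_mother_mmhg**2 + cfg.sd_placenta_mmhg**2 + cfg.sd_residual_mmhg**2
        )
        for oxy, base in zip(cfg.oxygen_levels, cfg.baseline_po2_mmhg):
            se = total_sd / np.sqrt(wt.loc[oxy, "n"])
            # mother/placenta effects are shared across rows, so the
            # effective SE is larger than the naive one; allow 4x
            assert wt.loc[oxy, "mean"] == pytest.approx(base, abs=4 * se + 5)

    def test_unpaired_ttest_matches_scipy(self, default_records):
        sub = _single_level(default_records)
        out = unpaired_ttest(sub, "po2_mmhg")
        wt = sub[sub.genotype == "WT"].po2_mmhg
        ko = sub[sub.genotype == "KO"].po2_mmhg
        t, p = sps.ttest_ind(wt, ko)
        assert out["t"] == pytest.approx(t) and out["p"] == pytest.approx(p)


class TestAgainstLmerTest:
    def test_matches_lmertest_satterthwaite(self, tmp_path, default_records):
        """Independent oracle: R lmerTest on the identical dataset must give
        the same genotype F test (Satterthwaite) and the same fixed-effect
        structure for the full nested model."""
        csv = tmp_path / "records.csv"
        default_records.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(po2_mmhg ~ genotype*factor(oxygen_percent)
                      + (1|mother_id) + (1|placenta_id), data=d)
            a <- anova(m)
            cat(a["genotype","F value"], a["genotype","DenDF"],
                a["genotype","Pr(>F)"],
                a["genotype:factor(oxygen_percent)","Pr(>F)"], sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        f_r, df_r, p_r, p_int_r = map(float, out.stdout.strip().splitlines())

        r = fit_full_model(default_records, "po2_mmhg")
        a = r.anova.set_index("source")
        assert a.loc["genotype", "F"] == pytest.approx(f_r, rel=0.02)
        assert a.loc["genotype", "den_df"] == pytest.approx(df_r, rel=0.1)
        assert a.loc["genotype", "p"] == pytest.approx(p_r, abs=2e-3)
        assert a.loc["genotype_x_oxygen", "p"] == pytest.approx(p_int_r, abs=2e-3)
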