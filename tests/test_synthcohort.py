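"""Synthetic cohort and twin-trait generators: determinism, coupling control,
manifest structure, and the statistical properties the downstream stages rely on."""

import numpy as np
import pytest

from megnet_vns.connectivity import TimeSeriesRun, band_plv_matrix
from megnet_vns.heritability import build_kinship, estimate_h2
from megnet_vns.synthcohort import (
    CohortSpec,
    DEFAULT_GROUP_PROFILES,
    GroupProfile,
    PedigreeSpec,
    generate_cohort,
    generate_run,
    generate_twin_traits,
    load_manifest,
    load_run,
    subject_profile,
    write_cohort,
)

SMALL = dict(
    n_channels=8, n_modules=2, fs_hz=128.0, run_length_s=12.0,
    control_run_length_s=12.0, n_runs=1,
)


def _uniform_profile(within, glob, seed=1, **over):
    spec = CohortSpec(
        n_per_group=(1, 0, 0),
        group_profiles={
            **DEFAULT_GROUP_PROFILES,
            "non-responder": GroupProfile(within, glob),
        },
        **{**SMALL, **over},
    )
    return subject_profile("s", "non-responder", spec, np.random.default_rng(seed))


class TestGenerateRun:
    def test_full_within_coupling_gives_unit_plv(self):
        prof = _uniform_profile(1.0, 0.0)
        run = generate_run(prof, 0, seed=42)
        m = band_plv_matrix(run, "theta").matrix
        # channels 0 and 2 share module 0 (round-robin assignment)
        assert m[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_uncoupled_channels_match_independent_phase_oracle(self):
        """Zero coupling must be indistinguishable from independently built signals.

        Oracle: direct simulation of independent phase random walks with the
        same diffusion, summed over the same carrier bins, through the same
        PLV statistic.
        """
        fs, dur, d = 128.0, 30.0, 4.0
        spec_over = dict(run_length_s=dur, control_run_length_s=dur)

        gen_vals = []
        for s in range(6):
            prof = _uniform_profile(0.0, 0.0, seed=s, **spec_over)
            run = generate_run(prof, 0, seed=100 + s)
            m = band_plv_matrix(run, "theta").matrix
            gen_vals.append(m[np.triu_indices(8, 1)].mean())

        rng = np.random.default_rng(77)
        n = int(dur * fs)
        t = np.arange(n) / fs
        oracle_vals = []
        for _ in range(6):
            chans = []
            for _c in range(8):
                x = np.zeros(n)
                for f in np.arange(4.0, 29.0):
                    walk = rng.uniform(-np.pi, np.pi) + np.cumsum(
                        rng.normal(0, np.sqrt(d / fs), n)
                    )
                    x += np.cos(2 * np.pi * f * t + walk)
                chans.append(x)
            m = band_plv_matrix(TimeSeriesRun(np.array(chans), fs_hz=fs), "theta").matrix
            oracle_vals.append(m[np.triu_indices(8, 1)].mean())

        se = np.hypot(
            np.std(gen_vals) / np.sqrt(len(gen_vals)),
            np.std(oracle_vals) / np.sqrt(len(oracle_vals)),
        )
        assert abs(np.mean(gen_vals) - np.mean(oracle_vals)) < 2 * se + 5e-3

    def test_same_seed_bit_identical(self):
        prof = _uniform_profile(0.4, 0.2)
        r1 = generate_run(prof, 1, seed=9)
        r2 = generate_run(prof, 1, seed=9)
        np.testing.assert_array_equal(r1.data, r2.data)
        r3 = generate_run(prof, 2, seed=9)
        assert not np.array_equal(r1.data, r3.data)

    def test_within_coupling_monotone_in_plv(self):
        """Mean within-module PLV strictly increases over a 3-point coupling grid."""
        means = []
        for w in (0.1, 0.5, 0.9):
            vals = []
            for s in range(3):  # fixed seed bank
                prof = _uniform_profile(w, 0.0, seed=s)
                run = generate_run(prof, 0, seed=50 + s)
                m = band_plv_matrix(run, "theta").matrix
                same = prof.module_of[:, None] == prof.module_of[None, :]
                iu = np.triu_indices(8, 1)
                vals.append(m[iu][same[iu]].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_invalid_run_length_rejected(self):
        prof = _uniform_profile(0.4, 0.2)
        prof.duration_s = 0.0
        with pytest.raises(ValueError):
            generate_run(prof, 0, seed=1)


class TestGenerateCohort:
    def test_manifest_has_expected_group_counts(self):
        spec = CohortSpec(n_per_group=(9, 14, 14), **SMALL)
        cohort = generate_cohort(spec)
        assert len(cohort.manifest) == 37
        counts = cohort.manifest.group.value_counts()
        assert counts["non-responder"] == 9
        assert counts["responder"] == 14
        assert counts["control"] == 14
        assert all(len(v) == spec.n_runs for v in cohort.runs.values())

    def test_half_of_patients_sedated_no_controls(self):
        spec = CohortSpec(n_per_group=(10, 10, 10), sedation_fraction=0.5, **SMALL)
        m = generate_cohort(spec).manifest
        patients = m[m.group != "control"]
        assert patients.sedation.sum() == 10  # exactly half of 20
        assert m[m.group == "control"].sedation.sum() == 0

    def test_single_subject_cohort(self):
        cohort = generate_cohort(CohortSpec(n_per_group=(0, 0, 1), **SMALL))
        assert len(cohort.manifest) == 1
        assert cohort.manifest.group.iloc[0] == "control"

    def test_same_seed_reproducible(self):
        spec = CohortSpec(n_per_group=(1, 1, 1), seed=5, **SMALL)
        c1, c2 = generate_cohort(spec), generate_cohort(spec)
        assert c1.manifest.equals(c2.manifest)
        for sid in c1.runs:
            np.testing.assert_array_equal(c1.runs[sid][0].data, c2.runs[sid][0].data)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(fs_hz=50.0, **{k: v for k, v in SMALL.items() if k != "fs_hz"})
        with pytest.raises(ValueError):
            CohortSpec(n_modules=1, **{k: v for k, v in SMALL.items() if k != "n_modules"})
        with pytest.raises(ValueError):
            GroupProfile(1.2, 0.0)

    def test_write_and_load_roundtrip(self, tmp_path):
        spec = CohortSpec(n_per_group=(1, 0, 1), seed=2, **SMALL)
        cohort = generate_cohort(spec)
        mpath = write_cohort(cohort, tmp_path)
        manifest = load_manifest(mpath)
        assert set(manifest.subject_id) == set(cohort.manifest.subject_id)
        first = manifest.iloc[0]
        run = load_run(first.run_paths.split(";")[0])
        np.testing.assert_allclose(
            run.data, cohort.runs[first.subject_id][0].data, atol=1e-4
        )  # float32 on disk
        assert run.fs_hz == spec.fs_hz


class TestTwinTraits:
    def test_mz_genetic_component_identical_within_pair(self):
        tw = generate_twin_traits(PedigreeSpec(10, 0, 0, h2_true=1.0, seed=3))
        g = tw.genetic_component.to_numpy()
        np.testing.assert_allclose(g[0::2], g[1::2], atol=1e-10)

    def test_zero_heritability_gives_uncorrelated_mz_pairs(self):
        n_pairs = 120
        tw = generate_twin_traits(PedigreeSpec(n_pairs, 0, 0, h2_true=0.0, seed=4))
        y = tw.traits.to_numpy()
        r = np.corrcoef(y[0::2], y[1::2])[0, 1]
        assert abs(r) < 3 / np.sqrt(n_pairs)

    def test_mz_correlation_exceeds_dz_when_heritable(self):
        wins = 0
        reps = 50
        for s in range(reps):
            tw = generate_twin_traits(PedigreeSpec(30, 30, 0, h2_true=0.7, seed=s))
            y = tw.traits.to_numpy()
            mz = np.corrcoef(y[0:60:2], y[1:60:2])[0, 1]
            dz = np.corrcoef(y[60::2], y[61::2])[0, 1]
            wins += mz > dz
        # sign test: under no difference wins ~ Binomial(50, .5)
        assert wins >= 35

    def test_heritability_recovery_loop(self):
        """The estimator recovers the generative h2 (small replicate version)."""
        ests = []
        for s in range(20):
            tw = generate_twin_traits(PedigreeSpec(40, 40, 0, h2_true=0.6, seed=s))
            kin = build_kinship(tw.pedigree)
            fit = estimate_h2(
                tw.traits.to_numpy(),
                tw.covariates.age.to_numpy(),
                tw.covariates.sex.to_numpy(),
                kin,
            )
            ests.append(fit.h2)
        assert 0.45 < np.mean(ests) < 0.75

    def test_covariate_effects_enter_trait(self):
        tw0 = generate_twin_traits(PedigreeSpec(20, 20, 10, h2_true=0.5, seed=6))
        tw1 = generate_twin_traits(
            PedigreeSpec(20, 20, 10, h2_true=0.5, seed=6, covariate_betas={"sex": 2.0})
        )
        sex = tw1.covariates.sex.to_numpy()
        delta = tw1.traits.to_numpy() - tw0.traits.to_numpy()
        np.testing.assert_allclose(delta, 2.0 * sex, atol=1e-10)

    def test_h2_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PedigreeSpec(h2_true=1.2)


class TestSedationEffect:
    def test_zero_effect_ignores_sedation_flag(self):
        spec = CohortSpec(n_per_group=(1, 0, 0), **SMALL)
        p0 = subject_profile("s", "non-responder", spec, np.random.default_rng(3), sedated=False)
        p1 = subject_profile("s", "non-responder", spec, np.random.default_rng(3), sedated=True)
        np.testing.assert_array_equal(p0.global_load, p1.global_load)

    def test_positive_effect_scales_sedated_global_coupling(self):
        spec = CohortSpec(n_per_group=(1, 0, 0), sedation_effect=0.5, **SMALL)
        p0 = subject_profile("s", "non-responder", spec, np.random.default_rng(3), sedated=False)
        p1 = subject_profile("s", "non-responder", spec, np.random.default_rng(3), sedated=True)
        assert p1.global_load.mean() > p0.global_load.mean()
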