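"""Synthetic LC-MS generator: ground truth, determinism, mzML output."""

import subprocess

import numpy as np
import pytest

from qconkit.isotopes import envelope, mono_fraction
from qconkit.masses import LabeledSpecies, Peptide, composition
from qconkit.mzml_io import read_mzml, write_mzml
from qconkit.quantify import XICRequest, extract_xic, integrate_peak, measure_pair
from qconkit.simulate import (
    CohortSpec,
    RunSpec,
    SpeciesSpec,
    simulate_cohort,
    simulate_run,
    simulate_spike_series,
)


class TestIsotopeEnvelope:
    def test_mono_peak_dominates_small_peptide(self):
        env = envelope(composition("LLQALR"))
        assert env[0] > env[1] > env[2]

    def test_heavy_envelope_narrower_than_light(self):
        comp = composition("LLQALR")
        assert mono_fraction(comp, "heavy") > mono_fraction(comp, "light")

    def test_unnormalized_zeroth_term_equals_mono_fraction(self):
        comp = composition("LLQALR")
        env = envelope(comp, normalize=False)
        assert env[0] == pytest.approx(mono_fraction(comp), rel=1e-12)


class TestSimulateRun:
    def test_noiseless_area_recovers_amount_times_response(self):
        spec = RunSpec(
            species=(SpeciesSpec("LLQALR", "light", 2, 30.0),),
            seed=1,
            noise_cv=0.0,
            response_factor=1e4,
        )
        run = simulate_run(spec)
        species = LabeledSpecies(
            peptide=Peptide(sequence="LLQALR"), label_state="light", charge=2
        )
        peak = integrate_peak(extract_xic(run, XICRequest(species.mz, 20.0)))
        expected = 30.0 * 1e4 * mono_fraction(composition("LLQALR"), "light")
        assert peak.area == pytest.approx(expected, rel=0.01)

    def test_symmetric_light_heavy_amounts_give_unit_ratio(self):
        spec = RunSpec(
            species=(
                SpeciesSpec("LLQALR", "light", 2, 50.0),
                SpeciesSpec("LLQALR", "heavy", 2, 50.0),
            ),
            seed=2,
            noise_cv=0.0,
        )
        m = measure_pair(simulate_run(spec), "LLQALR", 2, spike_fmol=50.0)
        assert m.ratio == pytest.approx(1.0, rel=0.01)

    def test_same_seed_reproduces_identical_runs(self):
        spec = RunSpec(
            species=(SpeciesSpec("LLQALR", "light", 2, 30.0),), seed=9, noise_cv=0.05
        )
        a, b = simulate_run(spec), simulate_run(spec)
        for sa, sb in zip(a.scans, b.scans):
            assert sa.rt == sb.rt
            assert np.array_equal(sa.mz, sb.mz)
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_distinct_seeds_give_distinct_noise(self):
        def total(seed):
            spec = RunSpec(
                species=(SpeciesSpec("LLQALR", "light", 2, 30.0),),
                seed=seed,
                noise_cv=0.05,
            )
            return sum(float(s.intensity.sum()) for s in simulate_run(spec).scans)

        assert total(1) != total(2)

    def test_recovery_across_amount_range_noiseless(self):
        for amount in (10.0, 30.0, 100.0, 300.0):
            spec = RunSpec(
                species=(
                    SpeciesSpec("LLQALR", "light", 2, amount),
                    SpeciesSpec("LLQALR", "heavy", 2, 50.0),
                ),
                seed=3,
                noise_cv=0.0,
            )
            m = measure_pair(simulate_run(spec), "LLQALR", 2, spike_fmol=50.0)
            assert abs(m.analyte_fmol - amount) / amount <= 0.01


class TestSpikeSeries:
    def test_noiseless_series_exactly_proportional(self):
        runs = simulate_spike_series(cv=0.0, seed=0)
        pep = Peptide(sequence="LLQALR")
        light = LabeledSpecies(peptide=pep, label_state="light", charge=2)
        heavy = LabeledSpecies(peptide=pep, label_state="heavy", charge=2)
        ratios = []
        for level, run in runs:
            al = integrate_peak(extract_xic(run, XICRequest(light.mz, 20.0))).area
            ah = integrate_peak(extract_xic(run, XICRequest(heavy.mz, 20.0))).area
            ratios.append(ah / al / level)
        assert np.std(ratios) / np.mean(ratios) < 1e-6

    def test_levels_must_ascend(self):
        with pytest.raises(ValueError):
            simulate_spike_series(levels=(100.0, 10.0), seed=0)

    def test_zero_endogenous_propagates_no_peak(self):
        runs = simulate_spike_series(endogenous_fmol=0.0, levels=(10.0,), cv=0.0, seed=0)
        _, run = runs[0]
        light = LabeledSpecies(
            peptide=Peptide(sequence="LLQALR"), label_state="light", charge=2
        )
        peak = integrate_peak(extract_xic(run, XICRequest(light.mz, 20.0)))
        assert peak.flag == "no-peak"


class TestCohort:
    def test_zero_sd_collapses_to_group_mean(self):
        from qconkit.simulate import CohortAnalyte, CohortGroup

        spec = CohortSpec(
            seed=1,
            analytes={
                "X": CohortAnalyte(
                    healthy=CohortGroup(27.23, 0.0),
                    tumour=CohortGroup(116.94, 0.0),
                    peptide="LLQALR",
                )
            },
            n_healthy=3,
            n_tumour=2,
            noise_cv=0.0,
        )
        samples, _ = simulate_cohort(spec)
        healthy = samples[samples.group == "healthy"]["true_fmol_per_ml"]
        assert np.allclose(healthy, 27.23)

    def test_tumour_mean_exceeds_healthy_with_default_parameters(self):
        spec = CohortSpec(seed=12, n_healthy=8, n_tumour=8, noise_cv=0.0)
        samples, _ = simulate_cohort(spec)
        for analyte, grp in samples.groupby("analyte"):
            h = grp[grp.group == "healthy"]["true_fmol_per_ml"].mean()
            t = grp[grp.group == "tumour"]["true_fmol_per_ml"].mean()
            assert t > h

    def test_quantification_recovers_generated_concentrations(self):
        spec = CohortSpec(seed=4, n_healthy=3, n_tumour=5, noise_cv=0.05)
        samples, runs = simulate_cohort(spec)
        recovered, truth = [], []
        for _, row in samples.iterrows():
            analyte = spec.analytes[row["analyte"]]
            m = measure_pair(
                runs[(row["sample"], row["analyte"])],
                analyte.peptide,
                analyte.charge,
                spike_fmol=spec.spike_fmol,
                ledger=spec.ledger,
            )
            recovered.append(m.concentration_fmol_per_ml)
            truth.append(row["true_fmol_per_ml"])
        r = np.corrcoef(recovered, truth)[0, 1]
        assert r >= 0.9


class TestMzmlOutput:
    def test_round_trip_is_exact(self, paired_run, tmp_path):
        _, run = paired_run
        path = tmp_path / "run.mzml"
        write_mzml(run, path)
        back = read_mzml(path)
        assert len(back) == len(run)
        for a, b in zip(run.scans, back.scans):
            assert a.rt == b.rt
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_external_mzml_implementation_reads_our_output(self, paired_run, tmp_path):
        """Independent oracle: Bioconductor mzR parses the writer's mzML."""
        _, run = paired_run
        path = tmp_path / "run.mzml"
        write_mzml(run, path)
        script = (
            'suppressMessages(library(mzR));'
            f'h <- openMSfile("{path}");'
            "cat(nrow(header(h)), sum(sapply(peaks(h), function(p) sum(p[,2]))))"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        n_scans, total = proc.stdout.split()
        assert int(n_scans) == len(run)
        expected_total = sum(float(s.intensity.sum()) for s in run.scans)
        assert float(total) == pytest.approx(expected_total, rel=1e-6)
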