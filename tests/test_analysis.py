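"""Pairwise decomposition, partial correlation, AIS-TE analysis, I/O, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from phiid import (
    DegenerateConditioningError,
    ais_te_analysis,
    make_copy_system,
    pairwise_decompose,
    partial_correlation,
    phiid_decompose,
    read_report,
    read_timeseries,
    sample_transition_pairs,
    write_report,
    measure_report,
)
from phiid.analysis import AisTeSummary
from phiid.cli import main as cli_main


class TestPartialCorrelation:
    def test_uncorrelated_conditioner_reduces_to_plain_r(self, rng):
        x = rng.standard_normal(2000)
        y = 0.5 * x + rng.standard_normal(2000)
        z = rng.standard_normal(2000)
        r = np.corrcoef(x, y)[0, 1]
        assert partial_correlation(x, y, z) == pytest.approx(r, abs=0.05)

    def test_common_cause_partialled_to_zero(self, rng):
        z = rng.standard_normal(20_000)
        x = z + rng.standard_normal(20_000)
        y = z + rng.standard_normal(20_000)
        assert abs(partial_correlation(x, y, z)) < 0.03

    def test_identical_arguments_give_one(self, rng):
        x = rng.standard_normal(100)
        z = rng.standard_normal(100)
        assert partial_correlation(x, x, z) == pytest.approx(1.0)

    def test_degenerate_conditioning_raises(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        with pytest.raises(DegenerateConditioningError):
            partial_correlation(x, y, x)

    def test_too_few_points_raises(self):
        from phiid import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            partial_correlation([1, 2, 3], [2, 1, 3], [1, 3, 2])


class TestPairwiseDecompose:
    def test_copy_sampler_two_columns(self):
        series = sample_transition_pairs(make_copy_system(), 30_000, seed=2)
        # interleaved (past, future) rows form a valid discrete series at
        # lag 1 only pairwise; feed the rollout-style estimator directly
        result = pairwise_decompose(series, lag=1, model="discrete")
        # sliding pairs mix true and spurious transitions, so just check shape
        assert len(result.table) == 2
        assert result.model == "discrete"

    def test_copy_estimated_system_te(self):
        series = sample_transition_pairs(make_copy_system(), 30_000, seed=2)
        from phiid import estimate_discrete
        from phiid.decompose import _te_direct

        system = estimate_discrete(series, lag=1, step=2)
        assert _te_direct(system, 1, 2) == pytest.approx(1.0, abs=0.02)

    def test_independent_noise_atoms_near_zero(self, rng):
        series = rng.standard_normal((5000, 5))
        result = pairwise_decompose(series, lag=1, model="gaussian")
        assert len(result.table) == 20  # 5*4 ordered pairs
        assert result.table[["ais_source", "te", "un_to_red"]].abs().max().max() < 0.01

    def test_constant_column_skipped_with_warning(self, rng):
        series = rng.standard_normal((500, 3))
        series[:, 1] = 2.5
        with pytest.warns(UserWarning, match="skipping pair"):
            result = pairwise_decompose(series, lag=1, model="gaussian")
        assert set(result.skipped) == {(0, 1), (1, 2)}
        assert sorted(set(result.table["source"])) == [0, 2]


class TestAisTeAnalysis:
    def test_duplication_library_correlation_collapses(self):
        """Across duplication-dominated systems with small independent
        storage and transfer admixtures, AIS and TE correlate near-perfectly,
        but the association collapses once the un1->red atom is partialled
        out (the admixtures are the only residual variation and they are
        independent by construction)."""
        from conftest import three_channel_system
        from phiid import ais_from_atoms, te_from_atoms

        lib_rng = np.random.default_rng(17)
        ais, te, dup = [], [], []
        for p0 in np.linspace(0.03, 0.42, 24):
            q, s = lib_rng.uniform(0.30, 0.45, 2)
            atoms = phiid_decompose(three_channel_system(p0, q, s), "mmi")
            ais.append(ais_from_atoms(atoms, 1))
            te.append(te_from_atoms(atoms, 1, 2))
            dup.append(atoms["un1->red"])
        r = np.corrcoef(ais, te)[0, 1]
        pr = partial_correlation(ais, te, dup)
        assert r > 0.95
        assert abs(pr) < 0.4 * r

    def test_duplication_atom_isolates_shared_channel(self):
        """In the three-channel construction the un1->red atom equals the
        duplication channel's capacity exactly, and AIS/TE are that plus
        their private channels."""
        from conftest import three_channel_system
        from phiid import ais_from_atoms, te_from_atoms

        def f(p):
            return 1 + p * np.log2(p) + (1 - p) * np.log2(1 - p)

        p0, q, s = 0.1, 0.35, 0.4
        atoms = phiid_decompose(three_channel_system(p0, q, s), "mmi")
        assert atoms["un1->red"] == pytest.approx(f(p0), abs=1e-10)
        assert ais_from_atoms(atoms, 1) == pytest.approx(f(p0) + f(q), abs=1e-10)
        assert te_from_atoms(atoms, 1, 2) == pytest.approx(f(p0) + f(s), abs=1e-10)

    def test_mixed_library_partial_below_plain(self):
        """With storage-only and transfer-only systems mixed in, the plain
        AIS-TE correlation is moderate and the duplication-partialled one is
        strictly smaller in magnitude."""
        from conftest import three_channel_system
        from phiid import ais_from_atoms, te_from_atoms

        lib_rng = np.random.default_rng(23)
        rows = []

        def measure(p0, q, s):
            atoms = phiid_decompose(three_channel_system(p0, q, s), "mmi")
            rows.append(
                (ais_from_atoms(atoms, 1), te_from_atoms(atoms, 1, 2), atoms["un1->red"])
            )

        for p0 in np.linspace(0.05, 0.42, 10):
            q, s = lib_rng.uniform(0.15, 0.45, 2)
            measure(p0, q, s)
        for q in np.linspace(0.05, 0.4, 6):  # storage only: duplication channel off
            measure(0.5, q, lib_rng.uniform(0.15, 0.45))
        for s in np.linspace(0.05, 0.4, 6):  # transfer only
            measure(0.5, lib_rng.uniform(0.15, 0.45), s)
        ais, te, dup = map(np.array, zip(*rows))
        r = np.corrcoef(ais, te)[0, 1]
        pr = partial_correlation(ais, te, dup)
        assert r > 0.3
        assert abs(pr) < abs(r)

    def test_multivariate_series_partial_below_plain(self):
        """End-to-end on an estimated Gaussian series with duplication
        blocks: regressing out the duplication atom shrinks the AIS-TE
        association."""
        from conftest import duplication_gaussian_series

        summary = ais_te_analysis(
            duplication_gaussian_series(seed=7), lag=1, model="gaussian"
        )
        assert isinstance(summary, AisTeSummary)
        assert summary.correlation > 0.2
        assert abs(summary.partial_correlation) < 0.15
        assert abs(summary.partial_correlation) < abs(summary.correlation)

    def test_insufficient_pairs_raise(self, rng):
        from phiid import InsufficientDataError

        series = np.column_stack([np.ones(100), rng.standard_normal(100)])
        with pytest.raises(InsufficientDataError):
            ais_te_analysis(series, model="gaussian")


class TestIO:
    def test_report_round_trip(self, tmp_path, copy_system):
        rep = measure_report(copy_system)
        path = tmp_path / "report.json"
        write_report(rep, path, "json")
        back = read_report(path)
        assert back.to_dict() == rep.to_dict()

    def test_csv_report(self, tmp_path, copy_system):
        path = tmp_path / "report.csv"
        write_report(measure_report(copy_system), path, "csv")
        df = pd.read_csv(path)
        assert df.set_index("measure").loc["tdmi", "bits"] == pytest.approx(1.0)

    def test_headerless_csv_accepted(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("1.0,2.0\n2.0,1.0\n0.5,0.5\n")
        df = read_timeseries(path)
        assert list(df.columns) == ["v0", "v1"]
        assert df.shape == (3, 2)

    def test_header_detected(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("alpha,beta\n1,2\n3,4\n")
        df = read_timeseries(path)
        assert list(df.columns) == ["alpha", "beta"]

    def test_ragged_csv_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,2\n3,4\n5,6,7\n")
        with pytest.raises(ValueError, match="line 3"):
            read_timeseries(path)

    def test_missing_value_rejected(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("a,b\n1,2\n3,\n")
        with pytest.raises(ValueError, match="missing value"):
            read_timeseries(path)


class TestCLI:
    def test_demo_matches_analytic_decomposition(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["demo", "copy"])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["atoms"]["un1->un2"] == pytest.approx(1.0)
        assert payload["phi_wms"] == pytest.approx(1.0)

    def test_ar_sweep_monotone(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sweep.csv"
        result = runner.invoke(cli_main, ["ar-sweep", "--output", str(out)])
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert (df["phi_wms"].diff().dropna() < 0).all()
        assert (df["phi_r"] >= -1e-9).all()

    def test_decompose_command_on_csv(self, tmp_path):
        series = sample_transition_pairs(make_copy_system(), 5000, seed=4)
        csv_path = tmp_path / "ts.csv"
        np.savetxt(csv_path, series, fmt="%d", delimiter=",")
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["decompose", str(csv_path), "--model", "discrete"]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert set(payload["atoms"]) == {f"{p}->{f}" for p in ("red", "un1", "un2", "syn") for f in ("red", "un1", "un2", "syn")}

    def test_repeat_runs_bit_identical(self, tmp_path):
        runner = CliRunner()
        outs = [runner.invoke(cli_main, ["demo", "ppr"]).output for _ in range(2)]
        assert outs[0] == outs[1]
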