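import logging

import numpy as np
import pytest
from click.testing import CliRunner

from screenfunnel import (
    CriterionSpec,
    FunnelConfig,
    MolecularGraph,
    Pose,
    RmsdConsistencyStage,
    ScoreTable,
    ScoreThresholdStage,
    VoteStage,
    apply_rmsd_stage,
    apply_score_stage,
    default_config,
    default_criteria,
    run_funnel,
    vote,
    write_hitlist,
)
from screenfunnel.cli import main as cli_main
from screenfunnel.funnel import RMSD_CRITERION, StageRecord, StageReport, load_config
from screenfunnel.synthetic_screen import SyntheticConfig, generate_library

from conftest import make_table


def library(seed=0, n=400, delta=1.0, **kw):
    cfg = SyntheticConfig(
        n=n, k=4, rho=0.5, prevalence=0.05, delta=delta, seed=seed,
        criteria=default_criteria(), **kw,
    )
    return generate_library(cfg)


class TestApplyScoreStage:
    def test_strict_threshold(self):
        t = make_table({"g": {"A": 4.9, "B": 5.0, "C": 5.1, "D": -6.0}},
                       {"g": "lower_better"})
        out, rec = apply_score_stage(t, ScoreThresholdStage("g", 5.0, "lt"))
        assert set(out.compounds) == {"A", "D"}
        assert rec.dropped == {"missing_score": 0, "threshold": 2}

    def test_le_comparator_keeps_boundary(self):
        t = make_table({"g": {"A": 5.0, "B": 5.1}}, {"g": "lower_better"})
        out, _ = apply_score_stage(t, ScoreThresholdStage("g", 5.0, "le"))
        assert out.compounds == ["A"]

    def test_all_below_unchanged(self):
        t = make_table({"g": {"A": 1.0, "B": 2.0}}, {"g": "lower_better"})
        out, rec = apply_score_stage(t, ScoreThresholdStage("g", 5.0))
        assert out.compounds == t.compounds and rec.n_in == rec.n_out == 2

    def test_missing_values_dropped_and_counted(self):
        t = make_table({"g": {"A": 1.0, "B": float("nan")}}, {"g": "lower_better"})
        out, rec = apply_score_stage(t, ScoreThresholdStage("g", 5.0))
        assert out.compounds == ["A"]
        assert rec.dropped["missing_score"] == 1

    def test_empty_input_degenerate(self):
        t = make_table({"g": {"A": 1.0}}, {"g": "lower_better"}).subset([])
        out, rec = apply_score_stage(t, ScoreThresholdStage("g", 5.0))
        assert len(out) == 0 and rec.n_in == 0 and rec.n_out == 0

    def test_unknown_criterion(self):
        t = make_table({"g": {"A": 1.0}}, {"g": "lower_better"})
        with pytest.raises(KeyError):
            apply_score_stage(t, ScoreThresholdStage("nope", 5.0))

    def test_threshold_stages_commute(self):
        lib = library()
        s1 = ScoreThresholdStage("glide", 0.5, "lt")
        s2 = ScoreThresholdStage("ehits", 0.0, "lt")
        ab, _ = apply_score_stage(apply_score_stage(lib.score_table, s1)[0], s2)
        ba, _ = apply_score_stage(apply_score_stage(lib.score_table, s2)[0], s1)
        assert set(ab.compounds) == set(ba.compounds)


class TestApplyRmsdStage:
    def _pose(self, shift=0.0):
        g = MolecularGraph(("C", "C", "O"), ((0, 1, 1), (1, 2, 1)))
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0]]) + shift
        return Pose(g, coords)

    def test_identical_pose_survives(self):
        a = {"x": self._pose()}
        survivors, rmsds, drops = apply_rmsd_stage(a, dict(a))
        assert survivors == ["x"] and rmsds["x"] == 0.0

    def test_exact_cutoff_translation_dropped(self):
        survivors, rmsds, drops = apply_rmsd_stage(
            {"x": self._pose()}, {"x": self._pose(shift=np.array([2.0, 0, 0]))},
            cutoff=2.0,
        )
        assert survivors == [] and drops["cutoff"] == 1
        assert rmsds["x"] == pytest.approx(2.0)

    def test_unpaired_dropped_with_reason(self):
        survivors, _, drops = apply_rmsd_stage({"x": self._pose()}, {})
        assert survivors == [] and drops["unpaired"] == 1

    def test_non_comparable_tallied_not_passed(self):
        ring = MolecularGraph(("C",) * 3, ((0, 1, 1), (1, 2, 1), (0, 2, 1)))
        b = {"x": Pose(ring, np.zeros((3, 3)) + np.arange(3)[:, None])}
        survivors, rmsds, drops = apply_rmsd_stage({"x": self._pose()}, b)
        assert survivors == [] and drops["not_comparable"] == 1 and "x" not in rmsds


class TestStageReport:
    def test_monotone_chain_enforced(self):
        rep = StageReport()
        rep.add(StageRecord("a", 10, 5, {}, {}))
        with pytest.raises(ValueError, match="input count"):
            rep.add(StageRecord("b", 7, 3, {}, {}))

    def test_stage_cannot_create_compounds(self):
        with pytest.raises(ValueError):
            StageRecord("a", 3, 5, {}, {})


class TestRunFunnel:
    def test_counts_non_increasing_and_chained(self):
        lib = library()
        config = default_config(shortlist=50)
        hits, report = run_funnel(config, lib.score_table, lib.poses_a, lib.poses_b)
        counts = report.counts()
        assert counts[0] == 400
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert len(hits) == min(50, counts[-1]) == counts[-1]
        # rmsd column fed into the vote: 5 criteria in the hit list
        assert hits.criteria == ("glide", "ehits", "ligx", "pki", "rmsd")

    def test_four_criterion_switch(self):
        lib = library()
        hits, _ = run_funnel(default_config(include_rmsd_vote=False, shortlist=50),
                             lib.score_table, lib.poses_a, lib.poses_b)
        assert hits.criteria == ("glide", "ehits", "ligx", "pki")

    def test_determinism_byte_identical(self, tmp_path):
        lib1, lib2 = library(seed=3), library(seed=3)
        config = default_config(shortlist=40)
        h1, _ = run_funnel(config, lib1.score_table, lib1.poses_a, lib1.poses_b)
        h2, _ = run_funnel(config, lib2.score_table, lib2.poses_a, lib2.poses_b)
        p1, p2 = tmp_path / "1.csv", tmp_path / "2.csv"
        write_hitlist(h1, p1)
        write_hitlist(h2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_vote_stage_matches_consensus_vote(self):
        lib = library()
        config = FunnelConfig((VoteStage(("glide", "ehits", "ligx", "pki"),
                                         shortlist=30),))
        hits, report = run_funnel(config, lib.score_table)
        direct, _ = vote(lib.score_table, ("glide", "ehits", "ligx", "pki"),
                         shortlist=30)
        assert hits == direct
        assert report.counts() == [400, 30]

    def test_total_elimination_warns_not_crashes(self, caplog):
        lib = library()
        config = FunnelConfig((
            ScoreThresholdStage("glide", -1e9, "lt"),
            VoteStage(("glide", "ehits"), shortlist=10),
        ))
        with caplog.at_level(logging.WARNING, logger="screenfunnel.funnel"):
            hits, report = run_funnel(config, lib.score_table)
        assert len(hits) == 0
        assert report.counts() == [400, 0, 0]
        assert any("eliminated" in r.message for r in caplog.records)

    def test_rmsd_stage_without_poses_raises(self):
        lib = library()
        with pytest.raises(ValueError, match="pose sets"):
            run_funnel(FunnelConfig((RmsdConsistencyStage(),)), lib.score_table)

    def test_no_stage_introduces_compounds(self):
        lib = library(seed=9)
        hits, report = run_funnel(default_config(shortlist=25),
                                  lib.score_table, lib.poses_a, lib.poses_b)
        assert set(hits.ids()) <= set(lib.score_table.compounds)

    @pytest.mark.parametrize("deltas", [(0.0, 0.5, 1.0, 2.0)])
    def test_enrichment_monotone_in_effect_size(self, deltas):
        fractions = []
        for delta in deltas:
            lib = library(seed=7, n=2000, delta=delta)
            hits, _ = run_funnel(default_config(shortlist=150),
                                 lib.score_table, lib.poses_a, lib.poses_b)
            labels = lib.labels
            frac = labels[hits.ids()].mean()
            fractions.append(float(frac))
        prevalence = 0.05
        assert all(f >= fractions[i] - 1e-12 for i, f in enumerate(fractions[1:]))
        assert all(f > prevalence for f in fractions[1:])


class TestConfigAndCli:
    CONFIG = """\
schema_version: 1
seed: 5
criteria:
  - {name: glide, direction: lower_better}
  - {name: ehits, direction: lower_better}
  - {name: ligx, direction: lower_better}
  - {name: pki, direction: higher_better}
stages:
  - {kind: score_threshold, criterion: glide, threshold: 5.0}
  - {kind: score_threshold, criterion: ehits, threshold: 3.0}
  - {kind: rmsd_consistency, cutoff: 2.0}
  - kind: consensus_vote
    criteria: [glide, ehits, ligx, pki, rmsd]
    f: 0.1
    shortlist: 60
"""

    def test_load_config(self, tmp_path):
        p = tmp_path / "funnel.yml"
        p.write_text(self.CONFIG)
        config, criteria = load_config(p)
        assert len(config.stages) == 4
        assert config.stages[0] == ScoreThresholdStage("glide", 5.0, "lt")
        assert config.stages[2].cutoff == 2.0
        assert [c.name for c in criteria] == ["glide", "ehits", "ligx", "pki"]

    def test_load_config_requires_schema_version(self, tmp_path):
        p = tmp_path / "funnel.yml"
        p.write_text("stages: []\n")
        with pytest.raises(ValueError, match="schema_version"):
            load_config(p)

    def test_cli_end_to_end(self, tmp_path):
        runner = CliRunner()
        synth_cfg = tmp_path / "synth.yml"
        synth_cfg.write_text(
            "n: 300\nk: 4\nrho: 0.5\nseed: 2\n"
            "criteria:\n"
            "  - {name: glide, direction: lower_better}\n"
            "  - {name: ehits, direction: lower_better}\n"
            "  - {name: ligx, direction: lower_better}\n"
            "  - {name: pki, direction: higher_better}\n"
        )
        out_dir = tmp_path / "lib"
        r = runner.invoke(cli_main, ["synth", "make", "--config", str(synth_cfg),
                                     "--out-dir", str(out_dir)])
        assert r.exit_code == 0, r.output
        for f in ("scores.csv", "poses_a.sdf", "poses_b.sdf", "labels.csv", "log.json"):
            assert (out_dir / f).exists()

        funnel_cfg = tmp_path / "funnel.yml"
        funnel_cfg.write_text(self.CONFIG)
        hits_csv = tmp_path / "hits.csv"
        report_json = tmp_path / "report.json"
        r = runner.invoke(cli_main, [
            "funnel", "run", "--config", str(funnel_cfg),
            "--scores", str(out_dir / "scores.csv"),
            "--poses-a", str(out_dir / "poses_a.sdf"),
            "--poses-b", str(out_dir / "poses_b.sdf"),
            "--out", str(hits_csv), "--report", str(report_json),
        ])
        assert r.exit_code == 0, r.output
        assert hits_csv.exists() and report_json.exists()
        import json

        rep = json.loads(report_json.read_text())
        counts = [rep["stages"][0]["input"]] + [s["surviving"] for s in rep["stages"]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cli_rmsd_subcommand(self, tmp_path):
        lib = library(n=20, seed=4)
        from screenfunnel import PoseRecord, write_sdf_poses

        pa = tmp_path / "a.sdf"
        pb = tmp_path / "b.sdf"
        write_sdf_poses([PoseRecord(c, p) for c, p in lib.poses_a.items()], pa)
        write_sdf_poses([PoseRecord(c, p) for c, p in lib.poses_b.items()], pb)
        out = tmp_path / "rmsd.csv"
        r = CliRunner().invoke(cli_main, ["rmsd", str(pa), str(pb),
                                          "--cutoff", "2.0", "--out", str(out)])
        assert r.exit_code == 0, r.output
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "id,rmsd,comparable,pass"
        assert len(lines) == 21

    def test_cli_vote_subcommand(self, tmp_path):
        lib = library(n=50, seed=6)
        from screenfunnel import write_score_csv

        scores = tmp_path / "scores.csv"
        write_score_csv(lib.score_table, scores)
        cfg = tmp_path / "vote.yml"
        cfg.write_text(
            "schema_version: 1\nf: 0.1\nshortlist: 10\n"
            "criteria:\n"
            "  - {name: glide, direction: lower_better}\n"
            "  - {name: ehits, direction: lower_better}\n"
            "  - {name: ligx, direction: lower_better}\n"
            "  - {name: pki, direction: higher_better}\n"
        )
        out = tmp_path / "hits.csv"
        r = CliRunner().invoke(cli_main, ["vote", "--scores", str(scores),
                                          "--config", str(cfg), "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert len(out.read_text().strip().splitlines()) == 11
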