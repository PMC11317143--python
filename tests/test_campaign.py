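import json

import numpy as np
import pandas as pd
import pytest

from loopcat.campaign import (CampaignSpec, events_from_frame,
                              run_campaign, run_replica)
from loopcat.io import EVENT_COLUMNS, config_hash, load_config
from loopcat.units import Species


def _tiny_spec(**over):
    base = dict(
        system={"kind": "single_loop", "N": 40, "loop_len": 0,
                "viral_len": 8, "box": 8.0},
        n_replicas=2, n_equil=2_000, n_push=1_000, n_max=30_000,
        mode="bypass", attempt_every=2, base_seed=7)
    base.update(over)
    return CampaignSpec(**base)


class TestRunReplica:
    def test_zero_cap_times_out(self):
        res = run_replica(_tiny_spec(n_max=0), 0)
        assert res.row["outcome"] == "timeout"
        assert res.event is None

    def test_same_seed_identical_rows(self):
        a = run_replica(_tiny_spec(), 3)
        b = run_replica(_tiny_spec(), 3)
        assert a.row == b.row

    def test_bypass_dense_contact_nearly_always_integrates(self):
        """In a small box with bypass acceptance, virtually every replica
        integrates well before the step cap."""
        n_int = 0
        for k in range(15):
            res = run_replica(_tiny_spec(), k)
            n_int += res.row["outcome"] == "integrated"
        assert n_int >= 14

    def test_integrated_replica_passes_conservation_audits(self):
        spec = _tiny_spec()
        res = run_replica(spec, 1)
        assert res.row["outcome"] == "integrated"
        system, topo = res.system, res.topology
        assert system.n_particles == 48
        # backbone bond count conserved: (N-1) + l_viral before and after
        assert len(topo.backbone_bonds()) == 39 + 8
        comps = [c for c in topo.connected_components() if len(c) > 1]
        assert len(comps) == 1 and len(comps[0]) == 48
        # union chain is linear: exactly two ends
        ends = sum(1 for b in comps[0]
                   if (topo.neighbours[b] >= 0).sum() == 1)
        assert ends == 2
        # the viral chain has been absorbed into the substrate chain id
        assert len(set(system.chain_id.tolist())) == 1
        assert 0 <= res.row["site_bead"] < 40


class TestRunCampaign:
    def test_aggregate_equals_manual_merge(self):
        spec = _tiny_spec(n_replicas=2)
        df = run_campaign(spec)
        rows = [run_replica(spec, k).row for k in range(2)]
        manual = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        pd.testing.assert_frame_equal(df[EVENT_COLUMNS], manual)

    def test_carries_config_hash(self):
        spec = _tiny_spec()
        df = run_campaign(spec)
        assert df.attrs["config_hash"] == config_hash(spec.to_dict())

    def test_events_round_trip_to_loop_stats(self):
        """Campaign output feeds the loop statistics and theory fit
        without transformation."""
        from loopcat.builders import LoopSpec
        from loopcat.observables import loop_stats
        spec = _tiny_spec(system={"kind": "single_loop", "N": 40,
                                  "loop_len": 7, "viral_len": 8,
                                  "box": 8.0},
                          n_replicas=4)
        df = run_campaign(spec)
        loops = [LoopSpec(16, 23)]
        events = events_from_frame(df, loops)
        st = loop_stats(events, loops, 40)
        assert st.I_tot == int((df["outcome"] == "integrated").sum())

    def test_writes_event_log(self, tmp_path):
        spec = _tiny_spec(out_dir=str(tmp_path / "camp"))
        run_campaign(spec)
        df = pd.read_csv(tmp_path / "camp" / "events.tsv", sep="\t")
        assert list(df.columns)[: len(EVENT_COLUMNS)] == EVENT_COLUMNS


class TestSpecValidation:
    def test_bad_mode(self):
        with pytest.raises(ValueError):
            _tiny_spec(mode="nonsense")

    def test_bad_replica_count(self):
        with pytest.raises(ValueError):
            _tiny_spec(n_replicas=0)


class TestCli:
    def test_run_and_report(self, tmp_path):
        import yaml
        from click.testing import CliRunner
        from loopcat.cli import main
        cfg = dict(system={"kind": "single_loop", "N": 30, "loop_len": 0,
                           "viral_len": 6, "box": 7.0},
                   n_replicas=2, n_equil=1_000, n_push=500,
                   n_max=20_000, mode="bypass", base_seed=1)
        cfg_path = tmp_path / "c.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        runner = CliRunner()
        out_dir = tmp_path / "out"
        r = runner.invoke(main, ["run", str(cfg_path), "--out",
                                 str(out_dir)])
        assert r.exit_code == 0, r.output
        assert (out_dir / "events.tsv").exists()
        r2 = runner.invoke(main, ["report", str(out_dir / "events.tsv")])
        assert r2.exit_code == 0
        assert "replicas: 2" in r2.output

    def test_config_error_exit_code(self, tmp_path):
        from click.testing import CliRunner
        from loopcat.cli import main
        bad = tmp_path / "bad.yaml"
        bad.write_text("mode: nonsense\nsystem: {kind: single_loop, N: 10}\n")
        r = CliRunner().invoke(main, ["run", str(bad)])
        assert r.exit_code == 2

    def test_regdist(self, tmp_path):
        from click.testing import CliRunner
        from loopcat.cli import main
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t0\t100\nchr1\t400\t500\nchr1\t2000\t2100\n")
        out = tmp_path / "d.tsv"
        r = CliRunner().invoke(main, ["regdist", str(bed), "--out",
                                      str(out)])
        assert r.exit_code == 0, r.output
        d = pd.read_csv(out, sep="\t")["distance_bp"].tolist()
        assert sorted(d) == [300, 300, 1500]

    def test_fit(self, tmp_path):
        from click.testing import CliRunner
        from loopcat.cli import main
        from loopcat.theory import FinModelParams, f_in_model
        p = FinModelParams(594.0, 356.0, 735.0, 147.0)
        ell = np.array([30, 60, 120, 250, 500.0])
        tab = tmp_path / "fin.tsv"
        pd.DataFrame({"ell_bp": ell,
                      "f_in": f_in_model(ell, p)}).to_csv(
            tab, sep="\t", index=False)
        out = tmp_path / "fit.json"
        r = CliRunner().invoke(main, ["fit", str(tab), "--n-bp", "735",
                                      "--out", str(out)])
        assert r.exit_code == 0, r.output
        rep = json.loads(out.read_text())
        assert rep["a_bp"] == pytest.approx(594.0, rel=1e-3)

    def test_fixture_dump(self, tmp_path):
        from click.testing import CliRunner
        from loopcat.cli import main
        r = CliRunner().invoke(
            main, ["fixtures", "polygon", "--n", "12", "--out",
                   str(tmp_path / "poly")])
        assert r.exit_code == 0
        xyz = (tmp_path / "poly.xyz").read_text().splitlines()
        assert xyz[0].strip() == "12"


class TestChromatinCampaign:
    def test_integration_into_chromatinized_substrate(self):
        """A bypass campaign on a small chromatinized fibre (nucleosome
        core particles self-assembled onto nucleosomal blocks, with a
        central loop) runs end to end and records in-range sites."""
        spec = CampaignSpec(
            system={"kind": "chromatin",
                    "chromatin": {"n_ncp": 2, "block_beads": 8,
                                  "linker_beads": 5,
                                  "loop_region": ()},
                    "viral_len": 8, "box": 12.0},
            n_replicas=3, n_equil=4_000, n_push=1_500, n_max=60_000,
            mode="bypass", attempt_every=2, base_seed=11)
        n_dna = 5 + 2 * (8 + 5)  # 31 DNA beads
        n_int = 0
        for k in range(3):
            res = run_replica(spec, k)
            assert not res.row["outcome"].startswith("failed")
            if res.row["outcome"] == "integrated":
                n_int += 1
                assert 0 <= res.row["site_bead"] < n_dna
                # NCPs stay unbonded through the swap
                from loopcat.units import BeadType
                ncp = np.nonzero(res.system.btype
                                 == int(BeadType.NCP))[0]
                assert (res.topology.neighbours[ncp] == -1).all()
        assert n_int >= 1
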