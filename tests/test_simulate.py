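"""Synthetic library generation, scan simulation and ground truth."""

import numpy as np
import pandas as pd
import pytest

import glymotif as gm

mk = gm.MotifPattern.from_string


class TestLibrary:
    def test_deterministic(self):
        cfg = gm.SimulationConfig(n_glycans=60, seed=9)
        assert gm.generate_library(cfg) == gm.generate_library(cfg)

    def test_unique_and_parseable(self):
        lib = gm.generate_library(gm.SimulationConfig(n_glycans=100, seed=2))
        strings = [s for _, s in lib]
        assert len(set(strings)) == 100
        for s in strings:
            gm.parse_condensed(s)

    def test_exact_category_allocation(self):
        cfg = gm.SimulationConfig(n_glycans=200, seed=0, n_glycan_fraction=0.25)
        lib = gm.generate_library(cfg)
        core = mk("N-core", "Manb1-4GlcNAcb1-4GlcNAc", anchor="root")
        n_count = sum(gm.match_motif(gm.parse_condensed(s), core) > 0
                      for _, s in lib)
        assert n_count == 50  # largest-remainder allocation is exact

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            gm.generate_library(gm.SimulationConfig(n_glycans=19))

    def test_infeasible_request_errors(self):
        cfg = gm.SimulationConfig(n_glycans=2000, seed=0,
                                  n_glycan_fraction=0.0, o_glycan_fraction=0.9)
        with pytest.raises(ValueError, match="exhausted"):
            gm.generate_library(cfg)


class TestScans:
    def _noiseless(self, **kw):
        defaults = dict(n_glycans=30, seed=1, spot_noise_cv=0.0)
        defaults.update(kw)
        return gm.SimulationConfig(**defaults)

    def test_half_saturation_closed_form(self):
        cfg = self._noiseless(concentrations=(1.0, 100.0))
        lec = gm.SyntheticLectin("L", mk("chitobiose", "GlcNAcb1-4GlcNAc"),
                                 kd_scale=1.0, max_rfu=30000)
        lib = gm.generate_library(cfg)
        scans = gm.simulate_scans(lec, lib, cfg)
        truth, _ = gm.ground_truth(lec, lib)
        binder = truth[truth == 1].index[0]
        row = scans[(scans.glycan_id == binder) & (scans.concentration == 1.0)]
        assert row["spot1"].iloc[0] == pytest.approx(cfg.baseline_rfu + 15000)

    def test_saturation_limit(self):
        cfg = self._noiseless(concentrations=(1.0, 1e9))
        lec = gm.SyntheticLectin("L", mk("chitobiose", "GlcNAcb1-4GlcNAc"),
                                 kd_scale=1.0, max_rfu=30000)
        lib = gm.generate_library(cfg)
        scans = gm.simulate_scans(lec, lib, cfg)
        truth, _ = gm.ground_truth(lec, lib)
        binder = truth[truth == 1].index[0]
        top = scans[(scans.glycan_id == binder) & (scans.concentration == 1e9)]
        assert top["spot1"].iloc[0] == pytest.approx(cfg.baseline_rfu + 30000,
                                                     rel=1e-6)

    def test_hard_inhibitor_knocks_to_baseline(self):
        cfg = self._noiseless()
        lec = gm.SyntheticLectin(
            "L", mk("chitobiose", "GlcNAcb1-4GlcNAc"),
            inhibitors=((mk("chitobiose", "GlcNAcb1-4GlcNAc"), 0.0),))
        lib = gm.generate_library(cfg)
        scans = gm.simulate_scans(lec, lib, cfg)
        assert (scans.filter(like="spot").to_numpy()
                == cfg.baseline_rfu).all()

    def test_spot_noise_mean_preserving(self):
        cfg = gm.SimulationConfig(n_glycans=30, seed=3, spot_noise_cv=0.3,
                                  spots_per_glycan=6)
        lec = gm.SyntheticLectin("L", mk("chitobiose", "GlcNAcb1-4GlcNAc"))
        lib = gm.generate_library(cfg)
        scans = gm.simulate_scans(lec, lib, cfg)
        truth, _ = gm.ground_truth(lec, lib)
        binders = truth[truth == 1].index
        top = scans[(scans.concentration == 100.0)
                    & scans.glycan_id.isin(binders)]
        observed = top.filter(like="spot").to_numpy().mean()
        expected = cfg.baseline_rfu + lec.max_rfu * (100 / 101)
        assert observed == pytest.approx(expected, rel=0.1)


class TestGroundTruth:
    def test_labels_match_motif_presence(self):
        cfg = gm.SimulationConfig(n_glycans=50, seed=4)
        lib = gm.generate_library(cfg)
        pat = mk("Fuca1-2Gal", "Fuca1-2Gal")
        lec = gm.SyntheticLectin("L", pat)
        truth, expected = gm.ground_truth(lec, lib)
        for gid, s in lib:
            assert truth[gid] == int(
                gm.match_motif(gm.parse_condensed(s), pat) > 0)
        assert "Fuca1-2Gal" in expected

    def test_absent_motif_all_unbound(self):
        cfg = gm.SimulationConfig(n_glycans=40, seed=5)
        lib = gm.generate_library(cfg)
        lec = gm.SyntheticLectin("L", mk("MurNAc dimer", "MurNAcb1-4MurNAc"))
        truth, _ = gm.ground_truth(lec, lib)
        assert truth.sum() == 0

    def test_enhancers_do_not_change_labels(self):
        cfg = gm.SimulationConfig(n_glycans=50, seed=6)
        lib = gm.generate_library(cfg)
        base = gm.SyntheticLectin("L", mk("chitobiose", "GlcNAcb1-4GlcNAc"))
        boosted = gm.SyntheticLectin(
            "L", mk("chitobiose", "GlcNAcb1-4GlcNAc"),
            enhancers=((mk("core fucose", "Fuca1-6GlcNAc", anchor="root"), 5.0),))
        a, _ = gm.ground_truth(base, lib)
        b, _ = gm.ground_truth(boosted, lib)
        assert a.equals(b)


class TestEndToEndRecovery:
    def test_noiseless_pipeline_recovers_truth(self):
        cfg = gm.SimulationConfig(n_glycans=120, seed=7, spot_noise_cv=0.0)
        panel = gm.planted_rule_panel(label_noise=0.0)
        scans, lib, truth = gm.simulate_dataset(panel, cfg)
        matrix, _ = gm.process_arrays(scans)
        for lec in panel:
            t = truth[lec.name]
            if t.sum() < 10:
                continue
            called = matrix.labels[lec.name].reindex(t.index).fillna(0).astype(int)
            assert (called == t).all(), lec.name

    def test_noise_degrades_accuracy_monotonically(self):
        accs = []
        for cv in (0.1, 0.8, 2.5):
            acc = []
            for seed in (0, 1, 2):
                cfg = gm.SimulationConfig(n_glycans=80, seed=seed,
                                          spot_noise_cv=cv)
                panel = gm.planted_rule_panel(label_noise=0.0)
                scans, lib, truth = gm.simulate_dataset(panel, cfg)
                matrix, _ = gm.process_arrays(scans)
                t = truth["TGT"]
                called = matrix.labels["TGT"].reindex(t.index).fillna(0).astype(int)
                acc.append((called == t).mean())
            accs.append(np.mean(acc))
        assert accs[0] >= accs[1] >= accs[2] - 1e-9

    def test_metadata_fixture_defaults(self):
        meta = gm.synthetic_metadata()
        assert len(meta) == 116
        assert (meta["duplicate_of"].str.len() > 0).sum() == 42
        assert (meta["exclude_reason"] == "low_binding_activity").sum() == 15
        assert (meta["exclude_reason"] == "literature_incongruent").sum() == 2
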