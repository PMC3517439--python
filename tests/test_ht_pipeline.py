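"""HT evidence synthesis: ratio statistic, Dollo losses, full pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tehop.core_io import SpeciesTree, write_newick
from tehop.dating import CalibrationWindow
from tehop.ht_pipeline import (
    calibrate_rate,
    consensus_divergence_pct,
    dollo_losses,
    expected_divergence,
    ht_verdict,
    run_pipeline,
)
from tehop.synthetic_data import BurstScenario, HTScenario, random_ancestor, simulate_ht_scenario

from conftest import random_binary_tree


class TestExpectedDivergence:
    def test_zero_split(self):
        assert expected_divergence(0.0, 0.1).value == 0.0

    def test_linear_regime(self):
        exp = expected_divergence(100, 0.1)
        assert exp.value == pytest.approx(20.0) and not exp.saturated

    def test_deep_split_saturates(self):
        exp = expected_divergence(1000, 0.1)
        assert exp.saturated and exp.value == 75.0 and exp.raw == pytest.approx(200.0)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            expected_divergence(100, 0.0)


class TestCalibrateRate:
    def test_window_midpoint_rate(self):
        calib = CalibrationWindow("TIGGER1", "g", 100, 190)
        assert calibrate_rate(calib, 21.2) == pytest.approx(21.2 / 145, abs=1e-9)

    def test_point_window_rate(self):
        calib = CalibrationWindow("old", "g", 140, 140)
        assert calibrate_rate(calib, 20.1) == pytest.approx(0.1436, abs=1e-4)

    def test_zero_width_window_at_zero_is_error(self):
        with pytest.raises(ValueError):
            calibrate_rate(CalibrationWindow("x", "g", 0, 0), 5.0)


class TestHTVerdict:
    def test_high_identity_against_saturated_expectation(self):
        # ~96% identity (4% divergence) across a deep split: decisive
        exp = expected_divergence(1000, 0.1)
        verdict, ratio = ht_verdict(4.0, exp)
        assert verdict == "HT-supported" and ratio == pytest.approx(4 / 75, abs=1e-9)

    def test_observed_equal_expected_is_vertical(self):
        exp = expected_divergence(100, 0.1)
        verdict, ratio = ht_verdict(20.0, exp)
        assert verdict == "vertical-plausible" and ratio == pytest.approx(1.0)

    def test_middle_band_indeterminate(self):
        exp = expected_divergence(1000, 0.1)
        verdict, ratio = ht_verdict(40.0, exp)
        assert verdict == "indeterminate" and ratio == pytest.approx(40 / 75)

    def test_unknown_split_blocks_ht_call(self):
        exp = expected_divergence(1000, 0.1)
        verdict, _ = ht_verdict(4.0, exp, split_known=False)
        assert verdict != "HT-supported"

    @given(st.floats(0, 70), st.floats(0.001, 5))
    def test_verdict_monotone_in_observed_divergence(self, obs, delta):
        # lowering observed divergence never flips HT-supported -> vertical
        exp = expected_divergence(500, 0.1)
        rank = {"HT-supported": 0, "indeterminate": 1, "vertical-plausible": 2}
        lo, _ = ht_verdict(max(obs - delta, 0.0), exp)
        hi, _ = ht_verdict(obs, exp)
        assert rank[lo] <= rank[hi]


def brute_force_dollo(species_tree: SpeciesTree, present: set[str]) -> int:
    """Exhaustive minimum losses: single gain at the MRCA, no regain.

    Enumerate presence/absence states of every internal node under the
    MRCA (root fixed present); a state is valid if absence propagates to
    all descendants and leaf states match the observed pattern. Losses
    are edges whose parent is present and child absent.
    """
    mrca = species_tree.mrca(sorted(present))
    if mrca.is_leaf():
        return 0
    internals = [n for n in mrca.preorder_iter() if not n.is_leaf() and n is not mrca]
    leaves = [n for n in mrca.leaf_iter()]
    best = None
    for assignment in itertools.product([True, False], repeat=len(internals)):
        state = {mrca: True}
        state.update(dict(zip(internals, assignment)))
        for lf in leaves:
            state[lf] = lf.taxon.label in present
        valid = True
        losses = 0
        for node in list(internals) + leaves:
            parent = node.parent_node
            if not state[parent] and state[node]:
                valid = False  # regain forbidden
                break
            if state[parent] and not state[node]:
                losses += 1
        if valid and (best is None or losses < best):
            best = losses
    return best


class TestDolloLosses:
    def _ultrametric(self, rng, n):
        # random topology stretched into an ultrametric tree
        t = random_binary_tree([f"s{k}" for k in range(n)], rng)
        t.is_rooted = True
        depths = {}
        for node in t.postorder_node_iter():
            depths[node] = 0.0 if node.is_leaf() else max(depths[c] + 1 for c in node.child_nodes())
        for node in t.preorder_node_iter():
            for c in node.child_nodes():
                c.edge.length = depths[node] - depths[c]
        return SpeciesTree(t)

    def test_all_leaves_present_is_zero(self):
        st_ = SpeciesTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert dollo_losses(st_, ["a", "b", "c", "d"]) == 0

    def test_single_presence_is_zero(self):
        st_ = SpeciesTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert dollo_losses(st_, ["a"]) == 0

    def test_balanced_eight_leaf_opposite_halves(self):
        nwk = "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        st_ = SpeciesTree.from_newick(nwk)
        assert dollo_losses(st_, ["a", "e"]) == 4

    def test_unknown_leaf_rejected(self):
        st_ = SpeciesTree.from_newick("((a:1,b:1):1,c:2);")
        with pytest.raises(ValueError, match="unknown leaf"):
            dollo_losses(st_, ["zz"])

    def test_agrees_with_exhaustive_minimization(self):
        # random trees up to 10 leaves, random presence subsets
        rng = np.random.default_rng(77)
        for n in (4, 6, 8, 10):
            st_ = self._ultrametric(rng, n)
            leaves = st_.leaf_labels()
            for _ in range(8):
                k = int(rng.integers(1, n + 1))
                present = set(rng.choice(leaves, size=k, replace=False).tolist())
                assert dollo_losses(st_, present) == brute_force_dollo(st_, present)


class TestConsensusDivergence:
    def test_unrelated_pair_declared_saturated(self, rng):
        a = random_ancestor(1000, rng, "a")
        b = random_ancestor(1000, rng, "b")
        obs, saturated = consensus_divergence_pct(a, b)
        assert saturated and obs == 75.0

    def test_similar_pair_measured(self, rng):
        from tehop.synthetic_data import mutate_sequence

        a = random_ancestor(1000, rng, "a")
        b = mutate_sequence(a, 0.05, 2.0, rng)
        obs, saturated = consensus_divergence_pct(a, b)
        assert not saturated and obs == pytest.approx(5.0, abs=1.5)


def ht_config(tmp_path, ds, nwk, bootstrap=0):
    (tmp_path / "sp.nwk").write_text(nwk + "\n")
    ds.write(tmp_path / "data")
    return dict(
        families=[
            dict(genome=g, family=f, copies=str(tmp_path / "data" / f"{g}.{f}.copies.fasta"))
            for (g, f) in ds.copies
        ],
        calibrations=[
            dict(genome="i1", family="calib", age_min=145, age_max=145),
            dict(genome="m1", family="calib", age_min=145, age_max=145),
        ],
        focal_families=["focal"],
        species_tree=str(tmp_path / "sp.nwk"),
        presence={"focal": ["i1", "m1"]},
        bootstrap=bootstrap,
    )


NWK = "((i1:100,i2:100):900,(m1:95,m2:95):905);"


def simulate_default(seed=0, ncop=30, L=1500):
    st_ = SpeciesTree.from_newick(NWK)
    cal = {g: BurstScenario(ancestral_length=L, burst_age=145, copy_count=ncop, rate=0.001)
           for g in ["i1", "m1"]}
    sc = HTScenario(
        species_tree=st_, native_lineage="i1", recipient_lineages=["m1"],
        transfer_age=80, calibration_bursts=cal,
        focal_burst=BurstScenario(ancestral_length=L, burst_age=150, copy_count=ncop, rate=0.001),
    )
    return simulate_ht_scenario(sc, seed=seed)


class TestRunPipeline:
    def test_empty_config_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no families configured"):
            run_pipeline({}, tmp_path)

    def test_synthetic_ht_scenario_verdicts_and_age(self, tmp_path):
        ds = simulate_default(seed=4)
        summary = run_pipeline(ht_config(tmp_path, ds, NWK), tmp_path / "out", seed=4)
        verdicts = {r["pair"]: r["verdict"] for r in summary["ht"]}
        assert verdicts["focal@i1 vs focal@m1"] == "HT-supported"
        assert verdicts["calib@i1 vs calib@m1"] == "vertical-plausible"
        age = [r for r in summary["ages"] if r["family"] == "focal" and r["genome"] == "m1"][0]
        assert abs(age["raw_max"] - 80) / 80 < 0.15
        assert summary["dollo_losses"]["focal"] == 2

    def test_report_bundle_files_written(self, tmp_path):
        ds = simulate_default(seed=5)
        run_pipeline(ht_config(tmp_path, ds, NWK), tmp_path / "out", seed=5)
        for name in ("families.tsv", "identity.tsv", "ages.tsv", "ht.tsv", "summary.json"):
            assert (tmp_path / "out" / name).exists()

    def test_end_to_end_determinism(self, tmp_path):
        ds = simulate_default(seed=6)
        cfg = ht_config(tmp_path, ds, NWK)
        run_pipeline(cfg, tmp_path / "o1", seed=6)
        run_pipeline(cfg, tmp_path / "o2", seed=6)
        for name in ("families.tsv", "identity.tsv", "ages.tsv", "ht.tsv"):
            assert (tmp_path / "o1" / name).read_bytes() == (tmp_path / "o2" / name).read_bytes()

    def test_unaligned_copies_rejected_with_stage_context(self, tmp_path):
        (tmp_path / "bad.fasta").write_text(">a\nACGT\n>b\nACGTA\n>c\nAC\n")
        cfg = dict(families=[dict(genome="g", family="f", copies=str(tmp_path / "bad.fasta"))])
        with pytest.raises(ValueError, match="family-stats stage"):
            run_pipeline(cfg, tmp_path / "out")
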