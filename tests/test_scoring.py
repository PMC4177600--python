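"""Score combination, classification rules, calibration and the full
per-complex pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hotspotter.conservation import read_alignment
from hotspotter.fixtures import FixtureSpec, make_case
from hotspotter.scoring import (RULE_BASE_ACCEPT, RULE_BASE_REJECT,
                                RULE_SER_THR_VETO, RULE_TRP_PHE_RESCUE,
                                ParameterSet, ScoreVector, calibrate,
                                classify, combined_score, score_complex)
from hotspotter.structure import read_complex

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def sv(E=0.0, C=0.0, MI=0.0, SC=0.0, F=0.0):
    return ScoreVector(E=E, C=C, MI=MI, SC=SC, F=F)


class TestCombinedScore:
    def test_published_weights(self, default_params):
        p = default_params
        assert (p.w_e, p.w_c, p.w_mi, p.w_sc) == (0.3, 0.9, 0.4, 0.4)
        assert (p.t_e, p.t_c, p.t_mi, p.t_sc, p.t_f) == \
            (0.58, 0.68, 0.50, 0.54, 0.80)

    def test_zero_and_saturated(self):
        p = ParameterSet(f_max=2.0)
        assert combined_score(sv(), p) == 0.0
        assert combined_score(sv(1, 1, 1, 1), p) == pytest.approx(1.0)

    def test_hand_value(self):
        p = ParameterSet(f_max=2.0)
        assert combined_score(sv(E=1, C=1), p) == pytest.approx(0.6)

    def test_invalid_f_max(self):
        with pytest.raises(ValueError):
            combined_score(sv(), ParameterSet(f_max=0.0))

    @settings(max_examples=200, derandomize=True)
    @given(e=unit, c=unit, mi=unit, sc=unit, delta=st.floats(0.001, 0.5))
    def test_bounded_and_monotone_in_each_subscore(self, e, c, mi, sc, delta):
        p = ParameterSet(f_max=2.0)
        base = combined_score(sv(e, c, mi, sc), p)
        assert 0.0 <= base <= 1.0
        for bumped in (sv(min(e + delta, 1), c, mi, sc),
                       sv(e, min(c + delta, 1), mi, sc),
                       sv(e, c, min(mi + delta, 1), sc),
                       sv(e, c, mi, min(sc + delta, 1))):
            assert combined_score(bumped, p) >= base - 1e-12

    def test_conservation_weighs_three_times_energy(self):
        # a unit change in C must move the raw combination exactly 3x more
        # than a unit change in E (0.9 vs 0.3)
        p = ParameterSet(f_max=1e9)  # avoid the clamp
        d_c = combined_score(sv(C=1), p) - combined_score(sv(), p)
        d_e = combined_score(sv(E=1), p) - combined_score(sv(), p)
        assert d_c / d_e == pytest.approx(3.0)


class TestClassify:
    def test_threshold_is_inclusive(self, default_params):
        hot, rule = classify("A", sv(F=0.80), default_params)
        assert hot and rule == RULE_BASE_ACCEPT
        hot, rule = classify("A", sv(F=0.799), default_params)
        assert not hot and rule == RULE_BASE_REJECT

    def test_ser_thr_veto(self, default_params):
        for aa in "ST":
            hot, rule = classify(aa, sv(MI=0.40, F=0.85), default_params)
            assert not hot and rule == RULE_SER_THR_VETO
            hot, rule = classify(aa, sv(MI=0.51, F=0.85), default_params)
            assert hot and rule == RULE_BASE_ACCEPT
            # the veto gate is strict: MI exactly 0.5 still demotes
            hot, rule = classify(aa, sv(MI=0.50, F=0.85), default_params)
            assert not hot and rule == RULE_SER_THR_VETO

    def test_trp_phe_rescue(self, default_params):
        for aa in "WF":
            hot, rule = classify(aa, sv(MI=0.60, C=0.70, F=0.70), default_params)
            assert hot and rule == RULE_TRP_PHE_RESCUE
            hot, rule = classify(aa, sv(MI=0.60, C=0.50, F=0.70), default_params)
            assert not hot and rule == RULE_BASE_REJECT
            hot, rule = classify(aa, sv(MI=0.40, C=0.70, F=0.70), default_params)
            assert not hot and rule == RULE_BASE_REJECT

    def test_rescue_can_be_disabled(self):
        p = ParameterSet(trp_phe_rescue=False)
        hot, rule = classify("W", sv(MI=0.60, C=0.70, F=0.70), p)
        assert not hot and rule == RULE_BASE_REJECT

    @settings(max_examples=300, derandomize=True)
    @given(aa=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
           mi=unit, c=unit, f=unit)
    def test_exactly_one_rule_fires(self, aa, mi, c, f, default_params):
        hot, rule = classify(aa, sv(MI=mi, C=c, F=f), default_params)
        assert rule in {RULE_BASE_ACCEPT, RULE_BASE_REJECT,
                        RULE_SER_THR_VETO, RULE_TRP_PHE_RESCUE}
        if rule in (RULE_BASE_ACCEPT, RULE_TRP_PHE_RESCUE):
            assert hot
        else:
            assert not hot


class TestParameterSet:
    def test_config_round_trip(self, tmp_path):
        p = ParameterSet(ne_max=0.123, t_f=0.9, trp_phe_rescue=False)
        path = tmp_path / "params.cfg"
        p.to_file(path)
        q = ParameterSet.from_file(path)
        assert q == p

    def test_unknown_override_rejected(self, default_params):
        with pytest.raises(KeyError):
            default_params.with_overrides({"nonsense": 1.0})


def _load(seed):
    case = make_case(FixtureSpec(seed=seed))
    cm = read_complex(case["pdb"], "A:B", source_id=f"fix{seed}")
    aln = {cid: read_alignment(t, "fasta", "query")
           for cid, t in case["alignments"].items()}
    return cm, aln, case["manifest"]


class TestCalibrate:
    def test_percentile_convention_is_linear_interpolation(self):
        pool = np.arange(1, 101, dtype=float)
        assert np.percentile(pool, 95.0) == pytest.approx(95.05)

    def test_recalibration_is_idempotent(self):
        items = [_load(s)[:2] for s in (0, 1)]
        p1 = calibrate(items, ParameterSet())
        p2 = calibrate(items, p1)
        for name in ("ne_max", "mi_max", "sc_max", "f_max"):
            assert getattr(p2, name) == pytest.approx(getattr(p1, name))

    def test_degenerate_pool_uses_common_value(self):
        # a complex with a single interface contact pair: every pooled raw
        # value appears twice (once per side), so any percentile returns it
        case = make_case(FixtureSpec(seed=3, n_strong_sites=0,
                                     with_salt_bridge=False,
                                     with_hbond_pair=False,
                                     n_contact_pairs=1, with_loner=False,
                                     jitter=0.0))
        cm = read_complex(case["pdb"], "A:B")
        p = calibrate([(cm, None)], ParameterSet())
        df = score_complex(cm, None, p)
        assert len(df) == 2
        assert df["ne"].abs().max() == pytest.approx(p.ne_max)

    def test_empty_interface_pool_rejected(self):
        case = make_case(FixtureSpec(seed=0, n_strong_sites=0,
                                     with_salt_bridge=False,
                                     with_hbond_pair=False,
                                     n_contact_pairs=0, with_loner=False))
        cm = read_complex(case["pdb"], "A:B")
        with pytest.raises(ValueError):
            calibrate([(cm, None)], ParameterSet())


class TestScoreComplex:
    def test_planted_strong_residues_are_hotspots(self, default_params):
        cm, aln, man = _load(7)
        df = score_complex(cm, aln, default_params).set_index(["chain", "resnum"])
        for s in man["strong"]:
            row = df.loc[(s["chain"], s["resnum"])]
            assert row.hotspot == 1
            # each planted subscore clears its published threshold
            assert row.E >= default_params.t_e
            assert row.C >= default_params.t_c
            assert row.MI >= default_params.t_mi
            assert row.SC >= default_params.t_sc

    def test_exposed_loner_is_not_a_hotspot(self, default_params):
        cm, aln, man = _load(7)
        df = score_complex(cm, aln, default_params).set_index(["chain", "resnum"])
        loner = man["loner"]
        row = df.loc[(loner["chain"], loner["resnum"])]
        assert row.hotspot == 0
        assert row.F < default_params.t_f

    def test_subscores_bounded(self, default_params):
        cm, aln, _ = _load(2)
        df = score_complex(cm, aln, default_params)
        for col in ("E", "C", "MI", "SC", "F"):
            assert df[col].between(0, 1).all(), col

    def test_deterministic(self, default_params):
        cm, aln, _ = _load(1)
        df1 = score_complex(cm, aln, default_params)
        cm2, aln2, _ = _load(1)
        df2 = score_complex(cm2, aln2, default_params)
        pd.testing.assert_frame_equal(df1, df2)

    def test_rigid_motion_invariance_of_score_table(self, default_params):
        from scipy.spatial.transform import Rotation
        cm, aln, _ = _load(4)
        df1 = score_complex(cm, aln, default_params)
        rot = Rotation.from_euler("zyx", [17, 203, -41], degrees=True)
        shift = np.array([-4.0, 7.5, 19.0])
        cm2, aln2, _ = _load(4)
        for res in cm2.residues:
            for atom in res.atoms:
                atom.coords = rot.apply(atom.coords) + shift
        cm2.invalidate_index()
        df2 = score_complex(cm2, aln2, default_params)
        assert list(df1.resnum) == list(df2.resnum)
        for col in ("E", "C", "MI", "SC", "F"):
            assert np.allclose(df1[col], df2[col], rtol=1e-6, atol=1e-9), col
        assert list(df1.hotspot) == list(df2.hotspot)

    def test_missing_alignments_give_zero_conservation(self, default_params):
        cm, aln, _ = _load(5)
        df = score_complex(cm, None, default_params)
        assert (df.C == 0.0).all()

    def test_raising_combined_threshold_shrinks_hotspot_set(self, default_params):
        cm, aln, _ = _load(6)
        base = score_complex(cm, aln, default_params)
        strict = score_complex(cm, aln,
                               default_params.with_overrides({"t_f": 0.95}))
        assert strict.hotspot.sum() <= base.hotspot.sum()
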