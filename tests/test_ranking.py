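"""Reliability indices, filtering, ranking and the trial-order protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vligand.descriptors import LigandRecord
from vligand.ranking import (
    FilterSpec,
    LOOSE_FILTER,
    STRICT_FILTER,
    apply_filter,
    delta_p_norm,
    rank,
    trial_order,
)
from vligand.vl_model import DEFAULT_BOUNDS, ParamBounds, VLParams

P_STAR_INTERNAL = np.array([1.35, 2.13, 1.64])


class TestDeltaPNorm:
    def test_zero_at_reference(self):
        p = np.array([1.5, 2.5, 2.0])
        assert delta_p_norm(p, p, DEFAULT_BOUNDS) == 0.0

    def test_one_full_range_in_one_component(self):
        p_star = np.array([1.4, 2.5, 2.0])
        p = p_star + np.array([DEFAULT_BOUNDS.width[0], 0.0, 0.0])
        assert delta_p_norm(p, p_star, DEFAULT_BOUNDS) == pytest.approx(1.0)

    def test_reference_ligand_value(self):
        """High-precision arithmetic oracle for PEt3 against the first
        internal-validation reference point."""
        from decimal import Decimal

        p = (Decimal("1.424"), Decimal("2.620"), Decimal("1.364"))
        ps = (Decimal("1.35"), Decimal("2.13"), Decimal("1.64"))
        widths = (Decimal("0.6"), Decimal("1.5"), Decimal("1.5"))
        acc = sum(((a - b) / w) ** 2 for a, b, w in zip(p, ps, widths))
        oracle = float(acc) ** 0.5
        got = delta_p_norm(np.array([1.424, 2.620, 1.364]), P_STAR_INTERNAL,
                           DEFAULT_BOUNDS)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(0.395, abs=5e-4)

    def test_zero_width_bounds_rejected(self):
        bad = ParamBounds(np.array([1.0]), np.array([2.0]))
        object.__setattr__(bad, "upper", np.array([1.0]))
        with pytest.raises(ValueError):
            delta_p_norm(np.array([1.5]), np.array([1.2]), bad)


class TestApplyFilter:
    def test_strict_selection_matches_reported_membership(self, phosphine_db):
        subset = apply_filter(phosphine_db, P_STAR_INTERNAL, DEFAULT_BOUNDS,
                              STRICT_FILTER)
        assert sorted(r.id for r in subset) == sorted(
            ["L7", "L10", "L11", "L12", "L18", "L20"]
        )

    def test_loose_selection_count(self, phosphine_db):
        subset = apply_filter(phosphine_db, P_STAR_INTERNAL, DEFAULT_BOUNDS,
                              LOOSE_FILTER)
        assert len(subset) == 12

    def test_zero_thresholds_select_nothing(self, phosphine_db):
        empty = apply_filter(phosphine_db, P_STAR_INTERNAL, DEFAULT_BOUNDS,
                             FilterSpec(0.0, 0.0, name="none"))
        assert empty == []

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            apply_filter([], P_STAR_INTERNAL, DEFAULT_BOUNDS, STRICT_FILTER)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        dl=st.floats(0.0, 3.0),
        dd=st.floats(0.0, 1.0),
        base_l=st.floats(0.1, 2.5),
        base_d=st.floats(0.05, 0.8),
    )
    def test_loosening_thresholds_never_removes_ligands(
        self, phosphine_db, dl, dd, base_l, base_d
    ):
        tight = FilterSpec(base_l, base_d, name="tight")
        loose = FilterSpec(base_l + dl, base_d + dd, name="loose")
        in_tight = {
            r.id for r in apply_filter(phosphine_db, P_STAR_INTERNAL,
                                       DEFAULT_BOUNDS, tight)
        }
        in_loose = {
            r.id for r in apply_filter(phosphine_db, P_STAR_INTERNAL,
                                       DEFAULT_BOUNDS, loose)
        }
        assert in_tight <= in_loose


def _toy_db(values):
    """Records with p chosen so dp_norm distinguishes ties deterministically."""
    db = []
    for i, (ident, r0) in enumerate(values):
        db.append(
            LigandRecord(ident, ident, VLParams(r0, 2.5, 2.0), l_min=0.5)
        )
    return db


class TestRank:
    p_star = np.array([1.5, 2.5, 2.0])

    def test_minimize_orders_ascending(self):
        db = _toy_db([("A", 1.5), ("B", 1.6)])
        predict = {1.5: 1.0, 1.6: 2.0}
        report = rank(db, lambda p: predict[round(p[0], 4)], "minimize",
                      self.p_star, DEFAULT_BOUNDS)
        ordered = report.passing("strict")["id"].tolist()
        assert ordered == ["A", "B"]

    def test_sense_flip_reverses_order(self):
        db = _toy_db([("A", 1.5), ("B", 1.6)])
        predict = {1.5: 1.0, 1.6: 2.0}
        report = rank(db, lambda p: predict[round(p[0], 4)], "maximize",
                      self.p_star, DEFAULT_BOUNDS)
        assert report.passing("strict")["id"].tolist() == ["B", "A"]

    def test_ties_broken_by_dp_norm_then_id(self):
        db = _toy_db([("B", 1.7), ("A", 1.6), ("C", 1.6)])
        report = rank(db, lambda p: 1.0, "minimize", self.p_star, DEFAULT_BOUNDS)
        # A and C tie on prediction and dp_norm -> id order; B is farther
        assert report.passing("strict")["id"].tolist() == ["A", "C", "B"]

    def test_ranks_are_a_permutation_within_each_filter(self, phosphine_db):
        report = rank(phosphine_db, lambda p: float(p[0]), "minimize",
                      P_STAR_INTERNAL, DEFAULT_BOUNDS)
        for name in ("strict", "loose"):
            sub = report.passing(name)
            assert sorted(sub[f"rank_{name}"]) == list(
                range(1, len(sub) + 1)
            )

    def test_report_csv_is_byte_identical_across_runs(self, phosphine_db, tmp_path):
        paths = []
        for i in range(2):
            report = rank(phosphine_db, lambda p: float(p @ p), "minimize",
                          P_STAR_INTERNAL, DEFAULT_BOUNDS)
            path = tmp_path / f"report{i}.csv"
            report.to_csv(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_end_to_end_best_ligand_ranked_first_with_exact_surrogate(
        self, bump_spec, phosphine_db
    ):
        """With direct (error-free) predictions the truly best filtered
        ligand must come first."""
        report = rank(
            phosphine_db, lambda p: bump_spec.objective(p), "minimize",
            P_STAR_INTERNAL, DEFAULT_BOUNDS,
        )
        sub = report.passing("loose")
        truth = {
            r.id: bump_spec.objective(r.p.as_array())
            for r in phosphine_db
            if r.id in set(sub["id"])
        }
        best = min(truth, key=lambda k: truth[k])
        assert sub["id"].iloc[0] == best


class TestTrialOrder:
    p_star = np.array([1.5, 2.5, 2.0])

    def _report(self, db, predict, sense="minimize"):
        return rank(db, predict, sense, self.p_star, DEFAULT_BOUNDS)

    def test_perfect_surrogate_finds_best_first(self):
        db = _toy_db([("A", 1.5), ("B", 1.55), ("C", 1.6)])
        truth = {"A": 3.0, "B": 1.0, "C": 2.0}
        report = self._report(db, lambda p: truth[{1.5: "A", 1.55: "B", 1.6: "C"}[round(p[0], 4)]])
        out = trial_order(report, truth, "strict")
        assert out.position == 1 and not out.filtered_out

    def test_anticorrelated_surrogate_finds_best_last(self):
        db = _toy_db([("A", 1.5), ("B", 1.55), ("C", 1.6)])
        truth = {"A": 3.0, "B": 1.0, "C": 2.0}
        report = self._report(db, lambda p: -truth[{1.5: "A", 1.55: "B", 1.6: "C"}[round(p[0], 4)]])
        out = trial_order(report, truth, "strict")
        assert out.position == 3

    def test_filtered_out_best_ligand_is_flagged(self, phosphine_db):
        # L1 fails both reliability thresholds at the internal reference point
        report = rank(phosphine_db, lambda p: float(p[0]), "minimize",
                      P_STAR_INTERNAL, DEFAULT_BOUNDS)
        truth = {r.id: 1.0 for r in phosphine_db}
        truth["L1"] = -5.0  # pretend the excluded ligand is truly best
        out = trial_order(report, truth, "strict")
        assert out.filtered_out and out.position is None and out.best_id == "L1"
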