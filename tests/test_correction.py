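"""Skewed/classical correction matrices and the deconvolution itself."""

import numpy as np
import pandas as pd
import pytest

import skewcor as sc
from skewcor.errors import InvalidLabelError, MeasurementError
from skewcor.simulate import forward_observe

TABLE = sc.default_isotope_table()
LABELS = ["No label", "2C13", "4C13"]


def all_light_probability(formula):
    return float(
        np.prod(
            [TABLE.principal(el).abundance ** n for el, n in formula.items()]
        )
    )


class TestTransitionProbability:
    def test_diagonal_is_residual_all_light(self, peptide_formula_2ac, orbitrap_60k):
        p = sc.transition_probability(
            peptide_formula_2ac, sc.NO_LABEL, sc.NO_LABEL, orbitrap_60k, 2
        )
        assert p == pytest.approx(
            all_light_probability(peptide_formula_2ac), rel=1e-9
        )
        assert p == pytest.approx(0.553, abs=0.001)

    def test_m0_to_m2_spillover(self, peptide_formula_2ac, orbitrap_60k):
        """Natural +2 Da species (13C2, 18O, 13C 15N, ...) under one merged peak."""
        l2 = sc.LabelSpec.parse("2C13")
        p = sc.transition_probability(
            peptide_formula_2ac, sc.NO_LABEL, l2, orbitrap_60k, 2
        )
        # oracle: full fine structure of the intact formula near +2.0067 Da
        from skewcor.finestructure import fine_structure

        window = orbitrap_60k.min_separable_mass_diff(
            sc.monoisotopic_mz(peptide_formula_2ac, 2), 2
        )
        fs = fine_structure(peptide_formula_2ac, 3, prune=1e-12)
        expected = fs.probability_near(l2.exact_shift(), window)
        assert p == pytest.approx(expected, rel=1e-6)
        assert 0.08 < p < 0.13

    def test_downward_transitions_are_zero(self, peptide_formula_2ac, orbitrap_60k):
        l2 = sc.LabelSpec.parse("2C13")
        assert (
            sc.transition_probability(
                peptide_formula_2ac, l2, sc.NO_LABEL, orbitrap_60k, 2
            )
            == 0.0
        )


class TestBuildMatrix:
    def test_single_label(self, orbitrap_60k):
        f = sc.parse_formula("C6H12O6")
        m = sc.build_matrix(f, ["No label"], orbitrap_60k, 1)
        assert m.T.shape == (1, 1)
        assert m.T[0, 0] == pytest.approx(all_light_probability(f), rel=1e-9)

    def test_lower_triangular_and_column_sums(self, histone_matrix):
        T = histone_matrix.T
        assert np.allclose(T, np.tril(T))
        assert (np.diag(T) > 0).all() and (np.diag(T) <= 1).all()
        assert (T.sum(axis=0) <= 1 + 1e-12).all()

    def test_skew_fewer_residual_carbons_spill_less(self, histone_matrix):
        """T[2,1] is built from 44 carbons, T[1,0] from 46: strictly smaller."""
        T = histone_matrix.T
        assert T[2, 1] < T[1, 0]

    def test_fully_labelled_column_has_exhausted_tracer(self, orbitrap_60k):
        """One residual carbon left: next-step spillover is exactly a1/a0."""
        glc = sc.parse_formula("C6H12O6")
        labels = ["No label"] + [f"{k}C13" for k in range(1, 7)]
        m = sc.build_matrix(
            glc, labels, sc.ResolutionModel(1e6, 200, "constant"), 1
        )
        a0 = TABLE.principal("C").abundance
        a1 = TABLE.isotope("C", 13).abundance
        assert m.T[6, 5] / m.T[5, 5] == pytest.approx(a1 / a0, rel=1e-9)
        # fully carbon-labelled small molecule: no residual carbon at all
        acetyl = sc.parse_formula("C2H3O")
        ma = sc.build_matrix(
            acetyl,
            ["No label", "1C13", "2C13"],
            sc.ResolutionModel(1e7, 200, "constant", separation_coefficient=1.0),
            1,
        )
        # the 2C13 column's diagonal is the residual H3O all-light probability
        assert ma.T[2, 2] == pytest.approx(
            all_light_probability(sc.parse_formula("H3O")), rel=1e-9
        )

    def test_duplicate_and_invalid_labels_rejected(self, orbitrap_60k):
        f = sc.parse_formula("C6H12O6")
        with pytest.raises(InvalidLabelError):
            sc.build_matrix(f, ["No label", "2C13", "2C13"], orbitrap_60k, 1)
        with pytest.raises(InvalidLabelError):
            sc.build_matrix(f, ["No label", "7C13"], orbitrap_60k, 1)

    def test_order_invariance(self, peptide_formula_2ac, orbitrap_60k):
        a = sc.build_matrix(peptide_formula_2ac, LABELS, orbitrap_60k, 2)
        b = sc.build_matrix(peptide_formula_2ac, LABELS[::-1], orbitrap_60k, 2)
        assert a.label_names == b.label_names
        assert np.array_equal(a.T, b.T)

    def test_offdiagonals_nonincreasing_in_resolution(self, peptide_formula_2ac):
        prev = None
        for r in (15000, 60000, 240000, 1000000):
            T = sc.build_matrix(
                peptide_formula_2ac, LABELS, sc.ResolutionModel(r, 200), 2
            ).T
            off = T[np.tril_indices(3, k=-1)]
            if prev is not None:
                assert (off <= prev + 1e-15).all()
            prev = off


class TestClassicalMatrix:
    def test_agrees_with_skewed_on_unlabelled_column(
        self, peptide_formula_2ac, orbitrap_60k, histone_matrix
    ):
        c = sc.classical_matrix(peptide_formula_2ac, LABELS, orbitrap_60k, 2)
        assert np.allclose(c.T[:, 0], histone_matrix.T[:, 0], rtol=1e-9)

    def test_equal_spacing_gives_equal_classical_entries(
        self, peptide_formula_2ac, orbitrap_60k, histone_matrix
    ):
        c = sc.classical_matrix(peptide_formula_2ac, LABELS, orbitrap_60k, 2)
        assert c.T[1, 0] == pytest.approx(c.T[2, 1], rel=1e-9)
        assert histone_matrix.T[2, 1] < histone_matrix.T[1, 0]

    def test_classical_biases_toward_heavy_isotopologues(self, orbitrap_60k):
        """Observations generated by the skewed physics, corrected classically,
        overestimate the heavy species: the heavy-isotopologue bias."""
        glc = sc.parse_formula("C6H12O6")
        labels = ["No label"] + [f"{k}C13" for k in range(1, 7)]
        model = sc.ResolutionModel.nominal()
        skew = sc.build_matrix(glc, labels, model, 1)
        clas = sc.classical_matrix(glc, labels, model, 1)
        x = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.3, 0.7])
        obs = forward_observe(x, skew)
        df = pd.DataFrame([obs], columns=skew.label_names, index=["s"])
        ours = sc.correct(df, skew, normalize=False).corrected.to_numpy()[0]
        theirs = sc.correct(df, clas, normalize=False).corrected.to_numpy()[0]
        assert ours == pytest.approx(x, abs=1e-9)
        # classical inflates the nearly- and fully-labelled species
        assert theirs[6] > x[6] + 0.01
        assert theirs[5] > x[5] + 0.01


class TestCorrect:
    def make_df(self, values, labels=LABELS, index=None):
        arr = np.atleast_2d(values)
        index = index or [f"s{i}" for i in range(len(arr))]
        return pd.DataFrame(arr, columns=labels, index=index)

    def test_degenerate_table_yields_identity(self, degenerate_table, orbitrap_60k):
        f = sc.parse_formula("C6H12O6")
        m = sc.build_matrix(
            f, ["No label", "1C13", "2C13"], orbitrap_60k, 1, degenerate_table
        )
        assert np.allclose(m.T, np.eye(3))
        df = self.make_df([10.0, 5.0, 2.0], m.label_names)
        out = sc.correct(df, m, normalize=False).corrected.to_numpy()
        assert np.allclose(out, [[10.0, 5.0, 2.0]])

    def test_roundtrip_recovers_truth(self, histone_matrix):
        rng = np.random.default_rng(7)
        x = rng.dirichlet([1, 1, 1], size=5)
        obs = forward_observe(x, histone_matrix)
        df = self.make_df(obs)
        res = sc.correct(df, histone_matrix, normalize=True)
        assert np.abs(res.corrected.to_numpy() - x).max() < 1e-9
        assert np.abs(res.fractions.to_numpy() - x).max() < 1e-9
        assert not res.clip_events

    def test_total_never_shrinks_without_clipping(self, histone_matrix):
        rng = np.random.default_rng(11)
        x = rng.dirichlet([2, 2, 2], size=8)
        obs = forward_observe(x, histone_matrix)
        res = sc.correct(self.make_df(obs), histone_matrix, normalize=False)
        assert not res.clip_events
        assert (
            res.corrected.sum(axis=1).to_numpy() >= obs.sum(axis=1) - 1e-9
        ).all()

    def test_histone_t0_removes_unexpected_m2(self, histone_matrix):
        """At t=0 all abundance is unlabelled; natural M+2 must vanish."""
        res = sc.correct(self.make_df([84.1, 15.9, 0.0]), histone_matrix)
        frac = res.fractions.to_numpy()[0] * 100
        assert frac[0] == pytest.approx(100.0, abs=0.7)
        assert frac[1] == pytest.approx(0.0, abs=0.7)
        assert frac[2] == pytest.approx(0.0, abs=0.7)

    def test_histone_t24_relative_abundances(self, histone_matrix):
        res = sc.correct(self.make_df([28.3, 46.2, 25.6]), histone_matrix)
        frac = res.fractions.to_numpy()[0] * 100
        assert frac == pytest.approx([33.9, 46.7, 19.4], abs=1.5)

    def test_negative_solutions_clipped_and_logged(self, histone_matrix):
        res = sc.correct(self.make_df([84.1, 15.9, 0.0]), histone_matrix)
        assert res.clip_events
        ev = res.clip_events[0]
        assert ev.label == "4C13" and ev.magnitude > 0
        assert any("clipped" in w for w in res.warnings)
        assert (res.corrected.to_numpy() >= 0).all()

    def test_fractions_sum_to_one(self, histone_matrix):
        res = sc.correct(self.make_df([[50.0, 30.0, 20.0], [5.0, 1.0, 0.5]]),
                         histone_matrix)
        assert res.fractions.sum(axis=1).to_numpy() == pytest.approx(
            [1.0, 1.0], abs=1e-9
        )

    def test_all_zero_sample_flagged(self, histone_matrix):
        res = sc.correct(self.make_df([0.0, 0.0, 0.0]), histone_matrix)
        assert np.allclose(res.corrected.to_numpy(), 0.0)
        assert res.fractions.isna().all(axis=None)
        assert any("all-zero" in w for w in res.warnings)

    def test_missing_intermediates_warned(self, histone_matrix):
        res = sc.correct(self.make_df([10.0, 5.0, 1.0]), histone_matrix)
        assert any("1C13" in w and "3C13" in w for w in res.warnings)

    def test_invalid_inputs_rejected(self, histone_matrix):
        with pytest.raises(MeasurementError):
            sc.correct(self.make_df([1.0, np.nan, 0.0]), histone_matrix)
        with pytest.raises(MeasurementError):
            sc.correct(self.make_df([1.0, -2.0, 0.0]), histone_matrix)
        with pytest.raises(MeasurementError):
            sc.correct(
                pd.DataFrame([[1.0, 2.0]], columns=["No label", "2C13"]),
                histone_matrix,
            )

    def test_column_order_irrelevant(self, histone_matrix):
        a = sc.correct(self.make_df([28.3, 46.2, 25.6]), histone_matrix)
        df = self.make_df([[25.6, 28.3, 46.2]], labels=["4C13", "No label", "2C13"])
        b = sc.correct(df, histone_matrix)
        assert np.array_equal(a.corrected.to_numpy(), b.corrected.to_numpy())


def test_matrix_text_export_roundtrips(histone_matrix, tmp_path):
    text = histone_matrix.to_text()
    p = tmp_path / "matrix.tsv"
    p.write_text(text)
    body = "\n".join(
        line for line in text.splitlines() if not line.startswith("#")
    )
    import io

    df = pd.read_csv(io.StringIO(body), sep="\t", index_col=0)
    assert np.allclose(df.to_numpy(), histone_matrix.T, atol=1e-6)
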