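import pytest

import skewcor as sc


@pytest.fixture(scope="session")
def peptide_formula_2ac():
    """Twice-acetylated H3(18-26) peptide KQLATKAAR: C46H83N15O14."""
    return sc.peptide_formula("KQLATKAAR", ["acetyl", "acetyl"])


@pytest.fixture(scope="session")
def orbitrap_60k():
    """60,000 resolving power at m/z 200, Orbitrap scaling."""
    return sc.ResolutionModel(resolution=60000, mz_ref=200, scaling="orbitrap")


@pytest.fixture(scope="session")
def histone_matrix(peptide_formula_2ac, orbitrap_60k):
    """Skewed matrix for the acetylation series M+0 / M+2 / M+4 at 2+."""
    return sc.build_matrix(
        peptide_formula_2ac, ["No label", "2C13", "4C13"], orbitrap_60k, charge=2
    )


@pytest.fixture(scope="session")
def degenerate_table():
    """Abundance table with no natural heavy isotopes (correction = identity)."""
    return sc.IsotopeTable(
        {
            el: [
                sc.Isotope(el, iso.mass_number, iso.mass,
                           1.0 if iso is sc.default_isotope_table().principal(el) else 0.0)
                for iso in sc.default_isotope_table().isotopes(el)
            ]
            for el in sc.default_isotope_table().elements()
        }
    )
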