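"""Forward simulation and brute-force oracles.

Everything the package computes can be tested without external data:

* :func:`forward_observe` is the adjoint of the correction (obs = T x),
  so correction of a noiseless forward observation must return the true
  fractions exactly.
* :func:`brute_force_fine_structure` enumerates every per-atom isotope
  assignment of a tiny formula — an exponential-time but exact oracle for
  the multinomial fine-structure computation.
* :func:`simulate_timecourse` emulates a metabolic labelling experiment:
  a media switch at t=0, per-site exponential replacement of the light
  modification by the labelled one, natural-abundance contamination via
  the forward model, and multiplicative Gaussian measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .chem import Formula, IsotopeTable, default_isotope_table
from .correction import CorrectionMatrix
from .errors import SimulationError
from .finestructure import FineStructureSpecies, FineStructureSpectrum

_MAX_BRUTE_ATOMS = 8


def forward_observe(x: np.ndarray, matrix: CorrectionMatrix) -> np.ndarray:
    """Observed peak intensities produced by true species abundances *x*.

    ``obs = T x``: each true species spreads over its own and heavier
    peak positions according to the transition matrix.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(matrix.labels):
        raise SimulationError(
            f"fraction vector has length {x.shape[-1]}, matrix has "
            f"{len(matrix.labels)} labels"
        )
    return x @ matrix.T.T


def brute_force_fine_structure(
    formula: Formula, table: IsotopeTable | None = None
) -> FineStructureSpectrum:
    """Exact fine structure by enumerating every per-atom isotope choice.

    Exponential in the atom count, hence limited to formulas with at most
    8 atoms; exact up to float rounding, independent of the multinomial
    path it cross-checks.
    """
    table = table or default_isotope_table()
    if formula.total_atoms() > _MAX_BRUTE_ATOMS:
        raise SimulationError(
            f"brute-force oracle limited to {_MAX_BRUTE_ATOMS} atoms, "
            f"formula {formula} has {formula.total_atoms()}"
        )
    atoms: list[str] = []
    for el, n in formula.items():
        atoms.extend([el] * n)
    choices = [table.isotopes(el) for el in atoms]
    acc: dict[tuple, tuple[float, float]] = {}
    for assignment in product(*choices):
        prob = 1.0
        shift = 0.0
        heavy: dict[tuple[str, int], int] = {}
        for el, iso in zip(atoms, assignment):
            prob *= iso.abundance
            if iso is not table.principal(el):
                shift += iso.mass - table.principal(el).mass
                heavy[(el, iso.mass_number)] = heavy.get((el, iso.mass_number), 0) + 1
        sig = tuple(sorted(heavy.items()))
        old = acc.get(sig)
        acc[sig] = (shift, prob + old[1]) if old else (shift, prob)
    species = [
        FineStructureSpecies(sig, sh, p) for sig, (sh, p) in acc.items()
    ]
    species.sort(key=lambda s: (s.exact_shift, s.heavy_counts))
    return FineStructureSpectrum(formula, tuple(species), 0.0, float("inf"))


@dataclass(frozen=True)
class SimulationSpec:
    """A synthetic two-site labelling time course.

    Models a compound with ``n_sites`` independently labelled sites (two
    acetyl groups by default), each replaced by the tracer-labelled form
    with first-order kinetics: the labelled fraction per site is
    f(t) = 1 - exp(-rate * t).  With two sites the species fractions are
    the binomial (1-f)^2, 2f(1-f), f^2 for 0, 1 and 2 labelled sites.

    Noise is multiplicative Gaussian per observed peak (coefficient of
    variation ``noise_cv``), truncated at zero.
    """

    matrix: CorrectionMatrix
    rate: float = 0.014  # per-site replacement rate, 1/h
    n_sites: int = 2
    times: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 24.0)
    n_replicates: int = 3
    noise_cv: float = 0.02
    total_intensity: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.noise_cv < 0:
            raise SimulationError("rate and noise_cv must be >= 0")
        if self.n_replicates < 1 or len(self.times) < 1:
            raise SimulationError("need >= 1 replicate and >= 1 time point")
        if self.n_sites + 1 != len(self.matrix.labels):
            raise SimulationError(
                f"{self.n_sites} sites produce {self.n_sites + 1} species "
                f"but matrix has {len(self.matrix.labels)} labels"
            )

    def true_fractions(self, t: float) -> np.ndarray:
        """Binomial species fractions at time *t* (no noise, no contamination)."""
        f = 1.0 - np.exp(-self.rate * t)
        k = np.arange(self.n_sites + 1)
        from math import comb

        return np.array(
            [
                comb(self.n_sites, int(i)) * f**i * (1 - f) ** (self.n_sites - i)
                for i in k
            ]
        )


def simulate_timecourse(spec: SimulationSpec) -> pd.DataFrame:
    """Simulate observed (contaminated, noisy) isotopologue intensities.

    Returns one row per replicate per time point, with a ``time`` column
    and one intensity column per measured isotopologue.  Reproducible for
    a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.matrix.label_names
    rows = []
    index = []
    for t in spec.times:
        truth = spec.true_fractions(t) * spec.total_intensity
        expected = forward_observe(truth, spec.matrix)
        for rep in range(spec.n_replicates):
            noise = rng.normal(1.0, spec.noise_cv, size=expected.shape)
            obs = np.clip(expected * noise, 0.0, None)
            rows.append({"time": t, **dict(zip(names, obs))})
            index.append(f"t{t:g}_rep{rep + 1}")
    return pd.DataFrame(rows, index=index)
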