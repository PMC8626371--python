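"""Skewed correction matrix and natural-abundance deconvolution.

Measured isotopologue intensities are contaminated by natural heavy
isotopes: a molecule truly carrying label j can appear at the peak
position of a heavier isotopologue i whenever its *unlabelled residual*
atoms pick up natural heavy isotopes whose exact shift is unresolvable
from shift(i) - shift(j) at the instrument's resolving power.

The skewed matrix computes each column j from the residual formula after
removing the labelled atoms, so a fully labelled species has no residual
tracer-element atoms left and cannot leak to heavier masses.  The
classical matrix (provided for comparison) instead reuses the full
unlabelled molecule's distribution for every column, which overestimates
upward spillover and biases corrected values toward heavy isotopologues.

The linear system obs = T c is lower-triangular in shift order and is
solved by forward substitution; negative solutions (noise) are clipped to
zero and logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import (
    Formula,
    IsotopeTable,
    LabelSpec,
    default_isotope_table,
    monoisotopic_mz,
    residual_formula,
)
from .errors import InvalidLabelError, MeasurementError
from .finestructure import fine_structure
from .resolution import ResolutionModel

_PRUNE = 1e-10  # fine-structure species below this probability are dropped


def transition_probability(
    formula: Formula,
    label_from: LabelSpec,
    label_to: LabelSpec,
    model: ResolutionModel,
    charge: int,
    table: IsotopeTable | None = None,
) -> float:
    """P(molecule with *label_from* detected at the peak of *label_to*).

    Sums the natural fine-structure probabilities of the residual formula
    (formula minus the labelled atoms) over all species whose exact shift
    is unresolvable from ``shift(label_to) - shift(label_from)``.  The
    resolution window is evaluated at the unlabelled compound's m/z, a
    single representative point for the whole label series.
    """
    table = table or default_isotope_table()
    delta = label_to.exact_shift(table) - label_from.exact_shift(table)
    if delta < 0:
        return 0.0
    residual = residual_formula(formula, label_from)
    mz = monoisotopic_mz(formula, charge, table=table)
    window = model.min_separable_mass_diff(mz, charge)
    spectrum = fine_structure(residual, max_shift=delta + window, prune=_PRUNE,
                              table=table)
    return spectrum.probability_near(delta, window)


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular transition matrix over the measured isotopologues.

    ``T[i, j]`` is the probability that a molecule truly carrying label j
    is detected at the peak position of isotopologue i.  Labels are in
    ascending exact-shift order, so T is lower-triangular.
    """

    labels: tuple[LabelSpec, ...]
    T: np.ndarray
    formula: Formula
    model: ResolutionModel
    charge: int
    kind: str = "skewed"

    @property
    def label_names(self) -> tuple[str, ...]:
        return tuple(lb.name for lb in self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        names = self.label_names
        return pd.DataFrame(self.T, index=names, columns=names)

    def to_text(self) -> str:
        """Plain-text rendering of the matrix for audit."""
        head = (
            f"# {self.kind} correction matrix for {self.formula}, "
            f"charge {self.charge}\n"
        )
        return head + self.to_dataframe().to_csv(sep="\t", float_format="%.6e")


def _sorted_labels(
    labels: list[LabelSpec | str],
    formula: Formula,
    table: IsotopeTable,
) -> tuple[LabelSpec, ...]:
    parsed = [
        LabelSpec.parse(lb, table) if isinstance(lb, str) else lb for lb in labels
    ]
    if len(set(parsed)) != len(parsed):
        raise InvalidLabelError("duplicate labels in measurement set")
    for lb in parsed:
        lb.validate_for(formula)
    return tuple(sorted(parsed, key=lambda lb: (lb.exact_shift(table), lb.name)))


def build_matrix(
    formula: Formula,
    labels: list[LabelSpec | str],
    model: ResolutionModel,
    charge: int,
    table: IsotopeTable | None = None,
) -> CorrectionMatrix:
    """Skewed correction matrix over the measured label set.

    Only the supplied labels enter the system; missing intermediate
    isotopologues are neither required nor imputed.
    """
    table = table or default_isotope_table()
    ordered = _sorted_labels(labels, formula, table)
    n = len(ordered)
    T = np.zeros((n, n))
    for j, lj in enumerate(ordered):
        for i in range(j, n):
            T[i, j] = transition_probability(
                formula, lj, ordered[i], model, charge, table
            )
    return CorrectionMatrix(ordered, T, formula, model, charge, "skewed")


def classical_matrix(
    formula: Formula,
    labels: list[LabelSpec | str],
    model: ResolutionModel,
    charge: int,
    table: IsotopeTable | None = None,
) -> CorrectionMatrix:
    """Classical correction matrix: one distribution for every column.

    Every column reuses the full unlabelled formula's fine structure,
    shifted by the column's label shift.  Provided for comparison; it
    leaks probability above fully labelled species, which cannot happen
    physically.
    """
    table = table or default_isotope_table()
    ordered = _sorted_labels(labels, formula, table)
    mz = monoisotopic_mz(formula, charge, table=table)
    window = model.min_separable_mass_diff(mz, charge)
    shifts = [lb.exact_shift(table) for lb in ordered]
    spectrum = fine_structure(
        formula, max_shift=(shifts[-1] - shifts[0]) + window, prune=_PRUNE,
        table=table,
    )
    n = len(ordered)
    T = np.zeros((n, n))
    for j in range(n):
        for i in range(j, n):
            T[i, j] = spectrum.probability_near(shifts[i] - shifts[j], window)
    return CorrectionMatrix(ordered, T, formula, model, charge, "classical")


@dataclass(frozen=True)
class ClipEvent:
    """One negative corrected intensity clipped to zero."""

    sample: str
    label: str
    magnitude: float  # absolute value of the clipped negative


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected intensities plus per-sample relative fractions."""

    corrected: pd.DataFrame
    fractions: pd.DataFrame | None
    warnings: tuple[str, ...]
    clip_events: tuple[ClipEvent, ...]
    matrix: CorrectionMatrix


def plausible_missing_labels(
    formula: Formula,
    labels: tuple[LabelSpec, ...],
    table: IsotopeTable | None = None,
) -> list[str]:
    """Intermediate label counts the measurement set skips.

    Only meaningful for single-tracer experiments: if all labels use one
    tracer isotope, every count between 0 and the maximum measured count
    is a plausible isotopologue; missing ones are reported so the user can
    judge whether their absence is intentional.
    """
    table = table or default_isotope_table()
    tracers = {key for lb in labels for key, _ in lb.items()}
    if len(tracers) != 1:
        return []
    (el, mn) = next(iter(tracers))
    measured = {sum(n for _, n in lb.items()) for lb in labels}
    missing = [
        f"{k}{el}{mn}"
        for k in range(0, max(measured))
        if k not in measured and k > 0
    ]
    return missing


def correct(
    measurements: pd.DataFrame,
    matrix: CorrectionMatrix,
    normalize: bool = True,
) -> CorrectionResult:
    """Remove natural-isotope contamination from measured intensities.

    Parameters
    ----------
    measurements:
        Samples x isotopologues table; column names must parse to the
        matrix's label set (order-independent).
    matrix:
        Correction matrix from :func:`build_matrix` or
        :func:`classical_matrix`.
    normalize:
        Also return relative fractions per sample (summing to 1).

    Per sample the triangular system obs = T c is solved by forward
    substitution in ascending shift order; each corrected value found
    negative is clipped to zero (and logged) before heavier isotopologues
    are corrected.
    """
    table = default_isotope_table()
    colmap: dict[str, object] = {}
    for col in measurements.columns:
        try:
            name = LabelSpec.parse(str(col), table).name
        except InvalidLabelError as exc:
            raise MeasurementError(
                f"column {col!r} is not a valid isotopologue label: {exc}"
            ) from exc
        colmap[name] = col
    wanted = matrix.label_names
    missing = [n for n in wanted if n not in colmap]
    if missing:
        raise MeasurementError(
            f"measurement table lacks columns for labels {missing}"
        )
    obs = measurements[[colmap[n] for n in wanted]].to_numpy(dtype=float)
    if not np.isfinite(obs).all():
        raise MeasurementError("non-finite intensity in measurement table")
    if (obs < 0).any():
        bad = np.argwhere(obs < 0)[0]
        raise MeasurementError(
            f"negative intensity at sample {measurements.index[bad[0]]!r}, "
            f"column {wanted[bad[1]]!r}"
        )

    T = matrix.T
    n = len(wanted)
    corrected = np.zeros_like(obs)
    warnings: list[str] = []
    clips: list[ClipEvent] = []
    for r, sample in enumerate(measurements.index):
        if obs[r].sum() == 0:
            warnings.append(
                f"sample {sample!r}: all-zero intensities; corrected values "
                "set to zero, relative fractions undefined"
            )
            continue
        c = np.zeros(n)
        for j in range(n):
            resid = obs[r, j] - T[j, :j] @ c[:j]
            value = resid / T[j, j]
            if value < 0:
                clips.append(ClipEvent(str(sample), wanted[j], -value))
                value = 0.0
            c[j] = value
        corrected[r] = c

    corr_df = pd.DataFrame(corrected, index=measurements.index, columns=wanted)
    frac_df = None
    if normalize:
        totals = corr_df.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_df = corr_df.div(totals.where(totals > 0), axis=0)
    for ev in clips:
        warnings.append(
            f"sample {ev.sample!r}, isotopologue {ev.label!r}: negative "
            f"corrected intensity {-ev.magnitude:.4g} clipped to 0"
        )
    skipped = plausible_missing_labels(matrix.formula, matrix.labels)
    if skipped:
        warnings.append(
            "possible unmeasured intermediate isotopologues: "
            + ", ".join(skipped)
        )
    return CorrectionResult(
        corrected=corr_df,
        fractions=frac_df,
        warnings=tuple(warnings),
        clip_events=tuple(clips),
        matrix=matrix,
    )
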