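"""Isotopic fine structure of a molecular formula.

A fine-structure species is one combination of natural heavy-isotope
counts (e.g. two 13C, or one 18O), with an exact mass shift relative to
the all-light molecule and a multinomial probability.  Exact shifts are
kept as real masses throughout; whether two species merge into one
observed peak is decided later by the resolution model, never here.

Enumeration is per-element (bounded by the requested maximum shift)
followed by cross-element convolution with probability pruning.  Because
each convolution factor is <= 1, pruning partial products below the
threshold can never discard a species whose final probability would
exceed it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

from .chem import Formula, IsotopeTable, default_isotope_table
from .errors import InvalidLabelError

# signature = sorted tuple of ((element, mass_number), heavy count)
Signature = tuple[tuple[tuple[str, int], int], ...]


@dataclass(frozen=True)
class FineStructureSpecies:
    """One combination of heavy natural isotopes of a formula."""

    heavy_counts: Signature
    exact_shift: float  # Da, relative to the all-light species
    probability: float

    @property
    def name(self) -> str:
        if not self.heavy_counts:
            return "light"
        return " ".join(f"{n}{el}{mn}" for (el, mn), n in self.heavy_counts)


@dataclass(frozen=True)
class FineStructureSpectrum:
    """Fine-structure species of a formula, ascending in exact shift."""

    formula: Formula
    species: tuple[FineStructureSpecies, ...]
    prune: float
    max_shift: float

    def __iter__(self):
        return iter(self.species)

    def __len__(self) -> int:
        return len(self.species)

    def total_probability(self) -> float:
        return sum(s.probability for s in self.species)

    def probability_near(self, shift: float, window: float) -> float:
        """Summed probability of species within ``window`` Da of *shift*."""
        return sum(
            s.probability
            for s in self.species
            if abs(s.exact_shift - shift) < window
        )


def _multinomial_probability(
    n: int, abundances: tuple[float, ...], heavy: tuple[int, ...]
) -> float:
    """P(k1.. heavy isotopes among n atoms); abundances[0] is principal."""
    k0 = n - sum(heavy)
    coef = math.factorial(n) // (
        math.factorial(k0) * math.prod(math.factorial(k) for k in heavy)
    )
    p = float(coef) * abundances[0] ** k0
    for a, k in zip(abundances[1:], heavy):
        p *= a**k
    return p


def species_probability(
    formula: Formula,
    heavy_counts: dict[tuple[str, int], int],
    table: IsotopeTable | None = None,
) -> float:
    """Exact probability of one heavy-isotope combination.

    Independent multinomial draws per element: with n atoms of an element
    whose isotope abundances are a0 (principal), a1, a2, ..., the chance of
    seeing k1, k2, ... heavy atoms is  multinomial(n; k) a0^(n-sum k)
    prod a_i^k_i.  Elements multiply.
    """
    table = table or default_isotope_table()
    per_element: dict[str, dict[int, int]] = {}
    for (el, mn), k in heavy_counts.items():
        if k < 0:
            raise InvalidLabelError(f"negative heavy count for {el}{mn}")
        if k:
            per_element.setdefault(el, {})[mn] = k
    prob = 1.0
    for el, n in formula.items():
        heavies = table.heavy_isotopes(el)
        ks = tuple(per_element.get(el, {}).get(h.mass_number, 0) for h in heavies)
        if sum(ks) > n:
            raise InvalidLabelError(
                f"{sum(ks)} heavy atoms requested but formula has only "
                f"{n} {el} atoms"
            )
        abund = (table.principal(el).abundance,) + tuple(h.abundance for h in heavies)
        prob *= _multinomial_probability(n, abund, ks)
    for el in per_element:
        if el not in formula:
            raise InvalidLabelError(f"element {el} not in formula {formula}")
    return prob


def _element_patterns(
    element: str, n: int, table: IsotopeTable, shift_bound: float
) -> list[tuple[float, float, Signature]]:
    """(shift, probability, signature) for all heavy-count combos of one element."""
    heavies = table.heavy_isotopes(element)
    abund = (table.principal(element).abundance,) + tuple(
        h.abundance for h in heavies
    )
    shifts = tuple(table.shift(element, h.mass_number) for h in heavies)
    ranges = [
        range(0, min(n, int(shift_bound / s) if s > 0 else n) + 1) for s in shifts
    ]
    out: list[tuple[float, float, Signature]] = []
    for ks in product(*ranges):
        if sum(ks) > n:
            continue
        shift = sum(k * s for k, s in zip(ks, shifts))
        if shift > shift_bound:
            continue
        p = _multinomial_probability(n, abund, ks)
        sig: Signature = tuple(
            ((element, h.mass_number), k)
            for h, k in zip(heavies, ks)
            if k
        )
        out.append((shift, p, sig))
    return out


def fine_structure(
    formula: Formula,
    max_shift: float = 10.0,
    prune: float = 1e-10,
    table: IsotopeTable | None = None,
) -> FineStructureSpectrum:
    """Enumerate the natural fine structure of *formula*.

    Every heavy-isotope combination with exact shift up to
    ``max_shift + 0.5`` Da and probability >= ``prune`` is returned (the
    all-light species is always kept).  Output order is ascending exact
    shift, ties broken by the heavy-count signature, so the spectrum is
    deterministic for a fixed input.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if not 0.0 <= prune < 1.0:
        raise ValueError("prune must be in [0, 1)")
    table = table or default_isotope_table()
    bound = max_shift + 0.5
    # accumulate by signature to guard against duplicates
    acc: dict[Signature, tuple[float, float]] = {(): (0.0, 1.0)}
    for el, n in formula.items():
        patterns = _element_patterns(el, n, table, bound)
        nxt: dict[Signature, tuple[float, float]] = {}
        for sig0, (sh0, p0) in acc.items():
            for sh1, p1, sig1 in patterns:
                shift = sh0 + sh1
                if shift > bound:
                    continue
                p = p0 * p1
                if p < prune and (sig0 or sig1):
                    continue
                sig = tuple(sorted(sig0 + sig1))
                old = nxt.get(sig)
                nxt[sig] = (shift, p + old[1]) if old else (shift, p)
        acc = nxt
    species = [
        FineStructureSpecies(sig, sh, p)
        for sig, (sh, p) in acc.items()
        if p >= prune or not sig
    ]
    species.sort(key=lambda s: (s.exact_shift, s.heavy_counts))
    return FineStructureSpectrum(formula, tuple(species), prune, max_shift)


def nominal_aggregate(
    spectrum: FineStructureSpectrum,
) -> list[tuple[int, float]]:
    """Group species probabilities by rounded (nominal) mass shift.

    This is the low-resolution limit: every species within one nominal
    mass unit collapses into a single M+n peak.
    """
    groups: dict[int, float] = {}
    for s in spectrum:
        n = round(s.exact_shift)
        groups[n] = groups.get(n, 0.0) + s.probability
    return sorted(groups.items())
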