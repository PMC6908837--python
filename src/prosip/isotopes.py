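"""Enrichment-parameterized isotopologue envelopes.

The core quantity of proteomic SIP: the distribution of a molecule's
isotopologues grouped by nucleon-number offset from the all-light species,
as a function of the :sup:`13`\\ C atom fraction of its carbon.  Under an
enrichment hypothesis ``p``, every carbon atom is :sup:`13`\\ C with
probability ``p`` independently; all other elements keep natural isotope
abundances.  Isotopologues are aggregated by nucleon offset — at the 0.03 /
0.01 Da tolerances used downstream, isotopic fine structure is unresolvable —
with an abundance-weighted centroid mass per offset class.

Envelopes are computed by per-element convolution: the carbon marginal is a
closed-form binomial, the remaining elements are iterated polynomial products
of their per-atom natural distributions, truncated at a configurable
cumulative abundance per step and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special

from .chem import ElementalFormula
from .constants import C13_DELTA, ELEMENTS, NATURAL_C13, NATURAL_ISOTOPES

#: Default cumulative-abundance cutoff for truncating envelopes.
DEFAULT_CUTOFF = 0.999


@dataclass(frozen=True)
class EnrichmentSpec:
    """Heavy-isotope atom fraction for one element (carbon supported)."""

    element: str = "C"
    atom_fraction: float = NATURAL_C13

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        if not 0.0 <= self.atom_fraction <= 1.0:
            raise ValueError("atom_fraction must lie in [0, 1]")

    @property
    def atom_percent(self) -> float:
        return 100.0 * self.atom_fraction


NATURAL = EnrichmentSpec()


@dataclass(frozen=True)
class Envelope:
    """Isotopologue distribution aggregated by nucleon offset.

    ``offsets`` are contiguous integer nucleon shifts relative to the
    all-light isotopologue, ``abundances`` the probability per offset class
    (summing to 1 after truncation renormalization), ``centroid_masses`` the
    abundance-weighted centroid mass per class in Da.
    """

    offsets: np.ndarray
    abundances: np.ndarray
    centroid_masses: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.offsets, self.abundances, self.centroid_masses):
            arr.setflags(write=False)
        if np.any(self.abundances < -1e-12):
            raise ValueError("negative abundance in envelope")
        total = float(self.abundances.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"envelope abundances sum to {total}, not 1")
        if np.any(np.diff(self.centroid_masses) <= 0):
            raise ValueError("centroid masses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def mean_mass(self) -> float:
        return float(np.dot(self.abundances, self.centroid_masses))


def element_distribution(
    element: str, spec: EnrichmentSpec | None = None
) -> list[tuple[float, float]]:
    """Per-atom (mass, abundance) isotope list for one element.

    Carbon under an enrichment spec uses {12C: 1-p, 13C: p}; every other
    element (and carbon without a spec) uses natural abundances.
    """
    if element not in ELEMENTS:
        raise ValueError(f"unsupported element {element!r}")
    natural = NATURAL_ISOTOPES[element]
    if spec is not None and spec.element == element:
        if element != "C":
            raise ValueError("enrichment is supported for carbon only")
        p = spec.atom_fraction
        masses = {off: m for off, m, _ab in natural}
        return [(masses[0], 1.0 - p), (masses[1], p)]
    return [(m, ab) for _off, m, ab in natural]


def _truncate(
    abund: np.ndarray, moment: np.ndarray, lo: int, cutoff: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Keep the smallest offset window of top-abundance classes reaching
    ``cutoff`` cumulative abundance; renormalize."""
    if cutoff >= 1.0:
        total = abund.sum()
        return abund / total, moment / total, lo
    order = np.argsort(abund)[::-1]
    cum = np.cumsum(abund[order])
    n_keep = int(np.searchsorted(cum, cutoff * abund.sum())) + 1
    kept = np.sort(order[:n_keep])
    i, j = kept[0], kept[-1]
    abund = abund[i: j + 1]
    moment = moment[i: j + 1]
    total = abund.sum()
    return abund / total, moment / total, lo + int(i)


def _convolve(
    a1: np.ndarray, m1: np.ndarray, lo1: int,
    a2: np.ndarray, m2: np.ndarray, lo2: int,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Convolve two (abundance, mass-moment) envelopes.

    ``m`` arrays hold first mass moments per class (abundance x centroid);
    the moment of a sum of independent parts is additive under convolution.
    """
    abund = np.convolve(a1, a2)
    moment = np.convolve(m1, a2) + np.convolve(a1, m2)
    return _truncate(abund, moment, lo1 + lo2, cutoff)


def _element_arrays(
    element: str, spec: EnrichmentSpec | None
) -> tuple[np.ndarray, np.ndarray, int]:
    dist = element_distribution(element, spec)
    if spec is not None and spec.element == element:
        offsets = [0, 1]
    else:
        offsets = [off for off, _m, ab in NATURAL_ISOTOPES[element] if ab > 0]
        dist = [(m, ab) for m, ab in dist if ab > 0]
    hi = max(offsets)
    abund = np.zeros(hi + 1)
    moment = np.zeros(hi + 1)
    for off, (mass, ab) in zip(offsets, dist):
        abund[off] = ab
        moment[off] = ab * mass
    return abund, moment, 0


def _n_atoms(
    element: str, n: int, spec: EnrichmentSpec | None, cutoff: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Envelope of ``n`` atoms of one element, by squaring convolution."""
    base = _element_arrays(element, spec)
    result = None
    power = base
    k = n
    while k:
        if k & 1:
            result = power if result is None else _convolve(*result, *power, cutoff)
        k >>= 1
        if k:
            power = _convolve(*power, *power, cutoff)
    assert result is not None
    return result


def _carbon_binomial(
    n: int, p: float, cutoff: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Closed-form carbon marginal: k of n atoms heavy ~ Binomial(n, p)."""
    m12 = NATURAL_ISOTOPES["C"][0][1]
    m13 = NATURAL_ISOTOPES["C"][1][1]
    k = np.arange(n + 1)
    if p <= 0.0:
        abund = np.zeros(n + 1)
        abund[0] = 1.0
    elif p >= 1.0:
        abund = np.zeros(n + 1)
        abund[-1] = 1.0
    else:
        log_pmf = (
            special.gammaln(n + 1)
            - special.gammaln(k + 1)
            - special.gammaln(n - k + 1)
            + k * np.log(p)
            + (n - k) * np.log1p(-p)
        )
        abund = np.exp(log_pmf)
    masses = (n - k) * m12 + k * m13
    return _truncate(abund, abund * masses, 0, cutoff)


@lru_cache(maxsize=50_000)
def _natural_residual(
    counts: tuple[int, int, int, int, int], per_step: float
) -> tuple[np.ndarray, np.ndarray, int] | None:
    """Envelope of the non-carbon (natural-abundance) part of a formula;
    independent of the enrichment hypothesis, so cached separately."""
    parts = []
    for element, n in zip(ELEMENTS, counts):
        if n == 0 or element == "C":
            continue
        parts.append(_n_atoms(element, n, None, per_step))
    if not parts:
        return None
    result = parts[0]
    for part in parts[1:]:
        result = _convolve(*result, *part, per_step)
    return result


@lru_cache(maxsize=200_000)
def _formula_envelope_cached(
    counts: tuple[int, int, int, int, int],
    p: float | None,
    truncate: float,
    per_step: float,
) -> Envelope:
    residual = _natural_residual(counts, per_step)
    n_carbon = counts[0]
    if n_carbon:
        carbon = _carbon_binomial(n_carbon, p, per_step)
        result = (
            carbon if residual is None else _convolve(*carbon, *residual, per_step)
        )
    else:
        result = residual
    if result is None:
        raise ValueError("empty formula")
    abund, moment, lo = _truncate(result[0], result[1], result[2], truncate)
    offsets = np.arange(lo, lo + len(abund))
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = moment / abund
    if np.any(abund <= 0):
        # zero-abundance interior classes (e.g. the missing 35S) get a
        # nominal centroid so masses stay monotone; they carry no weight.
        anchor = np.flatnonzero(abund > 0)[0]
        holes = abund <= 0
        centroid[holes] = centroid[anchor] + (
            offsets[holes] - offsets[anchor]
        ) * C13_DELTA
    return Envelope(offsets=offsets, abundances=abund, centroid_masses=centroid)


def formula_envelope(
    formula: ElementalFormula,
    spec: EnrichmentSpec | None = None,
    truncate: float = DEFAULT_CUTOFF,
    per_step_truncate: float = DEFAULT_CUTOFF,
) -> Envelope:
    """Isotopologue envelope of a formula under a carbon-enrichment spec.

    ``truncate`` is the final cumulative-abundance cutoff in (0.99, 1];
    ``per_step_truncate`` bounds intermediate convolution products.  Results
    are cached; treat returned arrays as read-only.
    """
    if not 0.99 < truncate <= 1.0:
        raise ValueError("truncate cutoff must lie in (0.99, 1]")
    if spec is None:
        spec = NATURAL
    return _formula_envelope_cached(
        formula.as_tuple(), spec.atom_fraction, truncate, per_step_truncate
    )


def most_abundant_offset(envelope: Envelope) -> int:
    """Nucleon offset of the maximal envelope peak; ties go to the lower
    offset."""
    return int(envelope.offsets[int(np.argmax(envelope.abundances))])


def clear_envelope_cache() -> None:
    _formula_envelope_cached.cache_clear()
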