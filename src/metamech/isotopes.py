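"""Natural-abundance correction and mass-isotopologue-distribution algebra.

In stable-isotope tracing, the raw mass-shift spectrum of a metabolite mixes
tracer-derived labeling with two nuisance processes: naturally occurring heavy
isotopes of the tracer element (each unlabeled atom carries a heavy isotope
with probability ``p``), and incomplete isotopic purity of the tracer itself
(each nominally labeled position retains its label with probability ``pi``).
This module builds the forward matrix that maps a true mass isotopologue
distribution (MID) onto the observed spectrum and inverts it by non-negative
least squares, plus the small MID algebra (convolution, fractional enrichment)
used by downstream tracing readouts.

Only the tracer element is corrected (13C: p = 0.0107; 2H: p = 0.000115);
heavy isotopes of other elements in the formula are assumed resolved away by
high-resolution MS and are not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

#: Natural abundance of the heavy isotope, by tracer element.
NATURAL_ABUNDANCE = {"C": 0.0107, "H": 0.000115}

#: Default isotopic purity of commercial tracers (fraction of nominally
#: labeled positions actually carrying the heavy isotope).
DEFAULT_TRACER_PURITY = 0.99

# Negative raw intensities no larger (in magnitude) than this fraction of the
# spectrum maximum are treated as baseline-subtraction artifacts and clamped.
NEGATIVE_CLAMP_FRACTION = 0.01

__all__ = [
    "NATURAL_ABUNDANCE",
    "DEFAULT_TRACER_PURITY",
    "CorrectionMatrix",
    "CorrectedMID",
    "as_mid",
    "build_correction_matrix",
    "naturalize_mid",
    "correct_spectrum",
    "fractional_enrichment",
    "labeled_fraction",
    "convolve_mids",
]


def as_mid(fractions, *, atol: float = 1e-9) -> np.ndarray:
    """Validate and return a mass isotopologue distribution.

    A MID is a vector ``f_0 .. f_n`` of molecule fractions carrying 0..n heavy
    atoms; entries must lie in [0, 1] and sum to 1 within ``atol``.
    """
    mid = np.asarray(fractions, dtype=float)
    if mid.ndim != 1 or mid.size < 1:
        raise ValueError("MID must be a one-dimensional vector")
    if not np.all(np.isfinite(mid)):
        raise ValueError("MID contains non-finite entries")
    if np.any(mid < -atol) or np.any(mid > 1 + atol):
        raise ValueError("MID entries must lie in [0, 1]")
    total = mid.sum()
    if abs(total - 1.0) > max(atol, 1e-9):
        raise ValueError(f"MID must sum to 1 (got {total!r})")
    return np.clip(mid, 0.0, 1.0)


@dataclass(frozen=True)
class CorrectionMatrix:
    """Forward model mapping a true MID to the observed mass-shift spectrum.

    Column ``i`` is the probability distribution of the observed mass shift
    for a molecule with ``i`` tracer-derived labels: binomial label loss with
    probability ``1 - tracer_purity`` over the ``i`` labeled positions,
    convolved with binomial natural-abundance gain with probability
    ``p_natural`` over the ``n_atoms - i`` unlabeled positions.
    """

    n_atoms: int
    p_natural: float
    tracer_purity: float
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = self.entries
        if m.shape != (self.n_atoms + 1, self.n_atoms + 1):
            raise ValueError("correction matrix has wrong shape")
        colsums = m.sum(axis=0)
        if np.any(colsums > 1 + 1e-9) or np.any(m < -1e-12):
            raise ValueError("each column must be a probability distribution")

    def forward(self, mid: np.ndarray) -> np.ndarray:
        """Observed spectrum for a true MID (matrix-vector product)."""
        mid = as_mid(mid)
        if mid.size != self.n_atoms + 1:
            raise ValueError("MID length does not match matrix size")
        return self.entries @ mid


def build_correction_matrix(
    n_atoms: int,
    p_natural: float,
    tracer_purity: float = 1.0,
) -> CorrectionMatrix:
    """Build the (n+1)x(n+1) natural-abundance / tracer-purity matrix.

    Parameters
    ----------
    n_atoms
        Number of correctable atoms of the tracer element.
    p_natural
        Natural abundance of the heavy isotope (must be < 0.5 so that the
        true distribution stays identifiable).
    tracer_purity
        Probability that a nominally labeled position carries the label
        (must exceed 0.5).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if not 0.0 <= p_natural < 0.5:
        raise ValueError("p_natural must satisfy 0 <= p < 0.5")
    if not 0.5 < tracer_purity <= 1.0:
        raise ValueError("tracer_purity must satisfy 0.5 < purity <= 1")

    n = n_atoms
    entries = np.zeros((n + 1, n + 1))
    shifts = np.arange(n + 1)
    for i in range(n + 1):
        # labels retained out of i nominally labeled positions
        retained = stats.binom.pmf(np.arange(i + 1), i, tracer_purity)
        # natural-abundance gains over the n - i unlabeled positions
        gained = stats.binom.pmf(np.arange(n - i + 1), n - i, p_natural)
        col = np.convolve(retained, gained)
        entries[shifts, i] = col
    return CorrectionMatrix(n_atoms=n, p_natural=p_natural,
                            tracer_purity=tracer_purity, entries=entries)


def naturalize_mid(mid: np.ndarray, p_natural: float,
                   tracer_purity: float = 1.0) -> np.ndarray:
    """Forward-convolve a true MID with natural abundance (and purity loss).

    This is the noise-free forward model that :func:`correct_spectrum`
    inverts; the synthetic generator uses it to emit raw spectra.
    """
    mid = as_mid(mid)
    matrix = build_correction_matrix(mid.size - 1, p_natural, tracer_purity)
    return matrix.forward(mid)


@dataclass(frozen=True)
class CorrectedMID:
    """Result of natural-abundance correction.

    ``mid`` sums to 1 and is non-negative; ``residual`` is the relative L2
    misfit ``||M x - raw|| / ||raw||`` of the non-negative solution;
    ``flagged`` marks spectra whose residual exceeded the threshold, which
    usually indicates a wrong atom count or a co-eluting contaminant.
    """

    mid: np.ndarray
    residual: float
    flagged: bool
    n_clamped: int = 0


def correct_spectrum(
    raw,
    matrix: CorrectionMatrix,
    *,
    residual_threshold: float = 0.05,
) -> CorrectedMID:
    """Recover the tracer-derived MID from a raw mass-shift spectrum.

    Solves ``raw ~ matrix @ x`` for ``x >= 0`` by non-negative least squares
    and renormalizes the solution to sum 1. NNLS (rather than a direct
    triangular solve) keeps fractions non-negative under measurement noise;
    the two coincide whenever the unconstrained solution is feasible.

    Small negative raw intensities (|x| <= 1% of the spectrum maximum) are
    clamped to zero with a warning; larger negatives are rejected as corrupt.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size != matrix.n_atoms + 1:
        raise ValueError("raw spectrum length does not match matrix size")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw spectrum contains non-finite entries")

    n_clamped = 0
    if np.any(raw < 0):
        limit = NEGATIVE_CLAMP_FRACTION * raw.max(initial=0.0)
        worst = -raw.min()
        if raw.max(initial=0.0) <= 0 or worst > limit:
            raise ValueError(
                "raw spectrum has negative intensities beyond the "
                f"{NEGATIVE_CLAMP_FRACTION:.0%} clamp threshold"
            )
        n_clamped = int((raw < 0).sum())
        warnings.warn(
            f"clamped {n_clamped} small negative intensities to zero",
            stacklevel=2,
        )
        raw = np.clip(raw, 0.0, None)

    total = raw.sum()
    if total <= 0:
        raise ValueError("raw spectrum has no positive intensity")

    scale = np.linalg.norm(raw)
    x, rnorm = optimize.nnls(matrix.entries, raw)
    residual = float(rnorm / scale)
    if x.sum() <= 0:
        raise ValueError("correction produced an all-zero solution")
    mid = x / x.sum()
    return CorrectedMID(mid=mid, residual=residual,
                        flagged=residual > residual_threshold,
                        n_clamped=n_clamped)


def fractional_enrichment(mid) -> float:
    """Atom-level labeled fraction, sum(i * f_i) / n."""
    mid = as_mid(mid)
    n = mid.size - 1
    if n == 0:
        return 0.0
    return float(np.dot(np.arange(n + 1), mid) / n)


def labeled_fraction(mid) -> float:
    """Fraction of molecules carrying at least one label, 1 - f0."""
    mid = as_mid(mid)
    return float(1.0 - mid[0])


def convolve_mids(a, b) -> np.ndarray:
    """MID of a condensation product: discrete convolution of the part MIDs.

    A molecule assembled from a part with MID ``a`` (n_a atoms) and an
    independent part with MID ``b`` (n_b atoms) has an (n_a + n_b)-atom MID
    equal to the convolution of the two.
    """
    a = as_mid(a)
    b = as_mid(b)
    out = np.convolve(a, b)
    # renormalize away accumulated floating-point drift
    return out / out.sum()
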