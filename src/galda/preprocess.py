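"""Spectral preprocessing chain: track selection -> baseline correction ->
vector (L2) normalization -> mean centering.

The order is fixed and matters: normalizing before baseline correction would
break the unit-norm postcondition, and centering must come last so the
training-set column means can be reused for test spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solveh_banded

from .dataset import LabeledSpectraSet, ProcessedSpectraSet


@dataclass
class PreprocessConfig:
    track_lo: float = 0.0
    track_hi: float = 10.0
    #: boundary precision in decimals for track selection; the axis is
    #: compared to the window after rounding to this many decimals (the
    #: conventional 0.001-ppm display precision).  None compares raw values.
    track_decimals: int | None = 3
    baseline_method: str = "asymmetric_least_squares"
    baseline_params: dict = field(default_factory=dict)
    center: bool = True
    # individual step toggles, for ablation experiments
    apply_track: bool = True
    apply_baseline: bool = True
    apply_normalize: bool = True

    def __post_init__(self) -> None:
        if not self.track_lo < self.track_hi:
            raise ValueError("track_lo must be < track_hi")
        if self.baseline_method not in ("asymmetric_least_squares", "polynomial"):
            raise ValueError(f"unknown baseline_method {self.baseline_method!r}")


def select_track(
    spectra: LabeledSpectraSet,
    lo: float = 0.0,
    hi: float = 10.0,
    decimals: int | None = 3,
) -> LabeledSpectraSet:
    """Keep the columns whose chemical shift lies in the closed [lo, hi] window.

    With ``decimals`` set, the axis is rounded to that precision before the
    comparison, i.e. window edges are applied at display precision (half a
    unit in the last decimal of tolerance at each edge).
    """
    axis = np.round(spectra.ppm, decimals) if decimals is not None else spectra.ppm
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(f"track [{lo}, {hi}] does not overlap the ppm axis")
    return replace(spectra, ppm=spectra.ppm[mask].copy(), X=spectra.X[:, mask].copy())


def asls_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.01, n_iter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline of one spectrum (Whittaker smoother
    with asymmetric weights): points above the baseline get weight ``p``,
    points below ``1 - p``; ``lam`` penalizes second differences."""
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 points for baseline estimation")
    # banded upper form of lam * D2'D2 (symmetric pentadiagonal)
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.ones(n - 2)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * off2
    ab[1, 1:] = lam * off1
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab[2] = lam * main + w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, p, 1.0 - p)
    return z


def polynomial_baseline(
    y: np.ndarray, x: np.ndarray, degree: int = 3, n_iter: int = 20
) -> np.ndarray:
    """Iterative polynomial baseline: refit after clipping the signal to the
    current fit so peaks stop pulling the polynomial upward."""
    if y.size < max(8, degree + 1):
        raise ValueError("too few points for polynomial baseline")
    xs = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    work = y.copy()
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(xs, work, degree)
        fit = np.polynomial.polynomial.polyval(xs, coeffs)
        work = np.minimum(work, fit)
    return fit


def baseline_correct(
    spectra: LabeledSpectraSet, config: PreprocessConfig | None = None
) -> LabeledSpectraSet:
    """Subtract a per-spectrum slowly varying baseline estimate."""
    cfg = config if config is not None else PreprocessConfig()
    if not np.isfinite(spectra.X).all():
        raise ValueError("spectra contain non-finite values")
    X = spectra.X
    Z = np.empty_like(X)
    if cfg.baseline_method == "asymmetric_least_squares":
        params = {"lam": 1e5, "p": 0.01, "n_iter": 10, **cfg.baseline_params}
        for i in range(X.shape[0]):
            Z[i] = asls_baseline(X[i], **params)
    else:
        params = {"degree": 3, "n_iter": 20, **cfg.baseline_params}
        for i in range(X.shape[0]):
            Z[i] = polynomial_baseline(X[i], spectra.ppm, **params)
    return replace(spectra, X=X - Z)


def vector_normalize(spectra: LabeledSpectraSet) -> LabeledSpectraSet:
    """Scale each spectrum to unit Euclidean norm (removes dilution effects)."""
    norms = np.linalg.norm(spectra.X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        bad = ", ".join(str(spectra.patient_ids[i]) for i in zero)
        raise ValueError(f"cannot normalize all-zero spectra: {bad}")
    return replace(spectra, X=spectra.X / norms[:, None])


def mean_center(
    spectra: LabeledSpectraSet, means: np.ndarray | None = None
) -> ProcessedSpectraSet:
    """Subtract column means.

    With ``means=None`` (training contract) the set's own column means are
    computed, applied and stored; otherwise the supplied training means are
    applied (test-set contract).
    """
    if means is None:
        means = spectra.X.mean(axis=0)
    else:
        means = np.asarray(means, dtype=float)
        if means.size != spectra.n_points:
            raise ValueError(
                f"means length {means.size} != {spectra.n_points} columns"
            )
    prov = list(getattr(spectra, "provenance", [])) + ["mean_centering"]
    return ProcessedSpectraSet(
        ppm=spectra.ppm.copy(),
        X=spectra.X - means[None, :],
        labels=spectra.labels.copy(),
        patient_ids=spectra.patient_ids.copy(),
        column_means=means.copy(),
        provenance=prov,
    )


def run_preprocessing(
    raw: LabeledSpectraSet,
    config: PreprocessConfig | None = None,
    means: np.ndarray | None = None,
) -> ProcessedSpectraSet:
    """Apply the full chain in fixed order, recording provenance.

    ``means`` (optional) centers with externally supplied training means.
    """
    cfg = config if config is not None else PreprocessConfig()
    out = raw
    prov = []
    if cfg.apply_track:
        out = select_track(out, cfg.track_lo, cfg.track_hi, cfg.track_decimals)
        prov.append("track_selection")
    if cfg.apply_baseline:
        out = baseline_correct(out, cfg)
        prov.append("baseline_correction")
    if cfg.apply_normalize:
        out = vector_normalize(out)
        prov.append("vector_normalization")
    if cfg.center:
        centered = mean_center(out, means)
        centered.provenance = prov + ["mean_centering"]
        return centered
    return ProcessedSpectraSet(
        ppm=out.ppm, X=out.X, labels=out.labels, patient_ids=out.patient_ids,
        column_means=None, provenance=prov,
    )
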