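"""Synthetic urine-like 1H NMR cohort generator.

Generates labeled spectral cohorts with the group structure of a three-arm
glycemic case-control design (control C, prediabetes PD, type 2 diabetes
T2D): 21 metabolite multiplets at group-specific chemical shifts, a
dominant creatinine resonance, glucose only in the diabetic group, glycine
absent there, a strictly decreasing urea signal C > PD > T2D, per-sample
dilution, smooth baseline drift, a residual-water hump and additive noise.

Spectra are generated "post-phase": pure absorption-mode Lorentzian lines on
an evenly spaced ppm grid.  No free-induction decay, phasing or solvent
suppression physics is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .dataset import GROUPS, AcquisitionGrid, LabeledSpectraSet

MULTIPLICITIES = ("singlet", "broad_singlet", "doublet", "multiplet")

#: Broad singlets (exchange-broadened lines such as urea NH2) render with
#: this factor on the linewidth.
BROAD_FACTOR = 5.0


@dataclass(frozen=True)
class PeakComponent:
    """One resonance of a metabolite: a line center or a multiplet envelope."""

    multiplicity: str
    center: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if self.center is None and (self.lo is None or self.hi is None):
            raise ValueError("component needs a center or a lo/hi range")

    @property
    def midpoint(self) -> float:
        if self.center is not None:
            return float(self.center)
        return 0.5 * (self.lo + self.hi)

    @property
    def span(self) -> tuple[float, float] | None:
        if self.lo is not None and self.hi is not None:
            return (float(self.lo), float(self.hi))
        return None


@dataclass
class MetabolitePeak:
    """One library record: per-group shifts and relative group intensities."""

    code: int
    name: str
    group_shifts: dict
    group_intensity: dict
    multiplicity: str
    j_spacing: float = 0.024  # ~7 Hz doublet splitting at 300 MHz
    linewidth: float = 0.006  # FWHM, ppm
    pathway: str = ""

    def components(self, group: str) -> list[PeakComponent]:
        return list(self.group_shifts.get(group, []))

    def centers(self, group: str) -> list[float]:
        """Component midpoints for one group (empty if absent)."""
        return [c.midpoint for c in self.components(group)]

    def line_positions(self, group: str) -> list[tuple[float, float, float]]:
        """Rendered Lorentzian lines for ``group``.

        Returns (center_ppm, relative_amplitude, fwhm) triples; amplitudes of
        a component's lines sum to the metabolite's group intensity.
        """
        amp = float(self.group_intensity.get(group, 0.0))
        if amp <= 0.0:
            return []
        lines: list[tuple[float, float, float]] = []
        for comp in self.components(group):
            mult = comp.multiplicity
            if mult == "singlet":
                lines.append((comp.midpoint, amp, self.linewidth))
            elif mult == "broad_singlet":
                lines.append((comp.midpoint, amp, BROAD_FACTOR * self.linewidth))
            elif mult == "doublet":
                span = comp.span
                j = (span[1] - span[0]) if span else self.j_spacing
                mid = comp.midpoint
                lines.append((mid - j / 2.0, amp / 2.0, self.linewidth))
                lines.append((mid + j / 2.0, amp / 2.0, self.linewidth))
            else:  # multiplet: 3-5 evenly spaced lines across the envelope
                span = comp.span or (comp.midpoint - 0.03, comp.midpoint + 0.03)
                n_lines = 5 if (span[1] - span[0]) > 0.2 else 3
                pos = np.linspace(span[0], span[1], n_lines)
                for x0 in pos:
                    lines.append((float(x0), amp / n_lines, self.linewidth))
        return lines


@dataclass(frozen=True)
class WaterBand:
    """Residual solvent hump left by imperfect water suppression."""

    center: float = 4.73
    width: float = 0.4  # FWHM, ppm
    amplitude: float = 2.0


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults reproduce the 39-sample three-group design (11 C / 12 PD /
    16 T2D).  ``dilution_sd`` is the log-scale SD of the per-sample global
    amplitude factor; ``intensity_variation_sd`` the log-scale SD of the
    per-sample, per-metabolite biological variability; ``noise_sd`` the
    additive Gaussian noise SD in the units of the relative peak amplitudes
    (creatinine peak height = 10).
    """

    n_per_group: dict = field(
        default_factory=lambda: {"C": 11, "PD": 12, "T2D": 16}
    )
    dilution_sd: float = 0.2
    intensity_variation_sd: float = 0.25
    noise_sd: float = 0.02
    baseline_amplitude: float = 0.5
    water_band: WaterBand | None = field(default_factory=WaterBand)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")
        for name in ("dilution_sd", "intensity_variation_sd", "noise_sd",
                     "baseline_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _parse_component(rec: dict, default_mult: str) -> PeakComponent:
    return PeakComponent(
        multiplicity=rec.get("multiplicity", default_mult),
        center=rec.get("center"),
        lo=rec.get("lo"),
        hi=rec.get("hi"),
    )


def build_default_library() -> list[MetabolitePeak]:
    """Load the 21-metabolite default peak library shipped with the package."""
    text = resources.files("galda.data").joinpath("peak_library.yaml").read_text()
    records = yaml.safe_load(text)
    library = []
    for rec in records:
        mult = rec["multiplicity"]
        shifts = {
            g: [_parse_component(c, mult) for c in rec["shifts"].get(g, [])]
            for g in GROUPS
        }
        library.append(
            MetabolitePeak(
                code=int(rec["code"]),
                name=rec["name"],
                group_shifts=shifts,
                group_intensity={g: float(v) for g, v in rec["intensity"].items()},
                multiplicity=mult,
                pathway=rec.get("pathway", ""),
            )
        )
    if len(library) != 21:
        raise RuntimeError("default peak library must contain 21 metabolites")
    return library


def _lorentzian(ppm: np.ndarray, center: float, height: float, fwhm: float
                ) -> np.ndarray:
    hw = fwhm / 2.0
    return height * hw * hw / ((ppm - center) ** 2 + hw * hw)


def _baseline_drift(ppm: np.ndarray, amplitude: float, rng: np.random.Generator
                    ) -> np.ndarray:
    # cubic drift on a [-1, 1]-scaled axis; coefficients ~U(-1, 1)
    x = 2.0 * (ppm - ppm[0]) / (ppm[-1] - ppm[0]) - 1.0
    coeffs = rng.uniform(-1.0, 1.0, size=4)
    return amplitude * (coeffs[0] + coeffs[1] * x + coeffs[2] * x**2
                        + coeffs[3] * x**3)


def simulate_spectrum(
    group: str,
    library: list[MetabolitePeak],
    grid: AcquisitionGrid,
    cohort_cfg: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one spectrum of ``group`` on ``grid``.

    Sum of Lorentzian multiplets scaled by group intensity, per-metabolite
    biological variability and a per-sample log-normal dilution factor, plus
    baseline drift, residual water and additive Gaussian noise.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; valid groups: {GROUPS}")
    ppm = grid.ppm()
    signal = np.zeros_like(ppm)
    dilution = float(np.exp(rng.normal(0.0, cohort_cfg.dilution_sd)))
    for peak in library:
        # draw per-metabolite variability unconditionally so the RNG stream
        # is aligned across groups
        factor = float(np.exp(rng.normal(0.0, cohort_cfg.intensity_variation_sd)))
        for center, amp, fwhm in peak.line_positions(group):
            signal += _lorentzian(ppm, center, amp * factor, fwhm)
    out = dilution * signal
    if cohort_cfg.baseline_amplitude > 0:
        out = out + _baseline_drift(ppm, cohort_cfg.baseline_amplitude, rng)
    else:
        rng.uniform(-1.0, 1.0, size=4)  # keep stream aligned
    wb = cohort_cfg.water_band
    if wb is not None and wb.amplitude > 0:
        out = out + _lorentzian(ppm, wb.center, wb.amplitude
                                * float(rng.uniform(0.7, 1.3)), wb.width)
    if cohort_cfg.noise_sd > 0:
        out = out + rng.normal(0.0, cohort_cfg.noise_sd, size=ppm.size)
    return out


def simulate_cohort(
    cohort_cfg: CohortConfig | None = None,
    library: list[MetabolitePeak] | None = None,
    grid: AcquisitionGrid | None = None,
) -> LabeledSpectraSet:
    """Generate a full labeled cohort, reproducible from ``cohort_cfg.seed``."""
    cfg = cohort_cfg if cohort_cfg is not None else CohortConfig()
    lib = library if library is not None else build_default_library()
    g = grid if grid is not None else AcquisitionGrid()
    rng = np.random.default_rng(cfg.seed)
    rows, labels, ids = [], [], []
    for group in GROUPS:
        n = int(cfg.n_per_group.get(group, 0))
        for i in range(n):
            rows.append(simulate_spectrum(group, lib, g, cfg, rng))
            labels.append(group)
            ids.append(f"{group}{i + 1:02d}")
    return LabeledSpectraSet(
        ppm=g.ppm(), X=np.vstack(rows), labels=np.array(labels, dtype=object),
        patient_ids=np.array(ids, dtype=object),
    )
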