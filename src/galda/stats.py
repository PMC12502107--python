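"""Univariate statistics on selected chemical shifts and ppm annotation.

One-way ANOVA (optionally Kruskal-Wallis) per selected variable, plus
nearest-neighbour annotation of a chemical shift against the metabolite
peak library (multiplet envelopes match by containment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .dataset import GROUPS, LabeledSpectraSet
from .synthetic import MetabolitePeak, build_default_library


@dataclass
class VariableReport:
    ppm: float
    per_group: dict            # label -> {"mean": ..., "sd": ..., "n": ...}
    p_value: float
    significant: bool
    annotation: str
    kruskal_p: float | None = None


def anova_oneway(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def anova_from_summary(means, sds, ns) -> tuple[float, float]:
    """One-way ANOVA reconstructed from per-group means, SDs and sizes.

    Identical to ``anova_oneway`` on any raw data with those summaries:
    SS_between from means/sizes, SS_within = sum (n_i - 1) SD_i^2.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not means.size == sds.size == ns.size:
        raise ValueError("means, sds and ns must have equal length")
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    k, N = means.size, ns.sum()
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    if ss_within == 0:
        return (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
    F = (ss_between / (k - 1)) / (ss_within / (N - k))
    return float(F), float(sps.f.sf(F, k - 1, N - k))


def kruskal_oneway(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis rank test behind the same interface; returns (H, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    res = sps.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def _component_distance(ppm: float, comp) -> float:
    span = comp.span
    if span is not None:
        if span[0] <= ppm <= span[1]:
            return 0.0
        return min(abs(ppm - span[0]), abs(ppm - span[1]))
    return abs(ppm - comp.center)


def annotate_ppm(
    ppm: float,
    library: list[MetabolitePeak] | None = None,
    tolerance: float = 0.03,
) -> str:
    """Name of the nearest library resonance within ``tolerance`` ppm, over
    all groups' line centers and multiplet envelopes (containment matches at
    distance 0); ``"unassigned"`` if nothing is close enough.  Deterministic
    and independent of library record order (ties break by distance to the
    component midpoint, then alphabetically)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lib = library if library is not None else build_default_library()
    candidates = []
    for peak in lib:
        for group in GROUPS:
            for comp in peak.components(group):
                d = _component_distance(ppm, comp)
                if d <= tolerance:
                    candidates.append((d, abs(ppm - comp.midpoint), peak.name))
    if not candidates:
        return "unassigned"
    return min(candidates)[2]


def report_selected_variables(
    model,
    spectra: LabeledSpectraSet,
    library: list[MetabolitePeak] | None = None,
    tolerance: float = 0.03,
    alpha: float = 0.05,
    include_kruskal: bool = False,
) -> list[VariableReport]:
    """Per-variable report for a fitted GA-LDA model: per-group mean/SD of
    the preprocessed intensity, one-way ANOVA p, significance flag at
    ``alpha`` and metabolite annotation."""
    if model.selected_ppm is None:
        raise ValueError("model carries no selected ppm values")
    labels = np.asarray(spectra.labels, dtype=object)
    groups_present = [g for g in GROUPS if (labels == g).any()]
    if len(groups_present) < 2:
        raise ValueError("spectra must carry labels for at least 2 groups")
    lib = library if library is not None else build_default_library()
    from .ga import design_matrix
    genes = design_matrix(spectra.X, getattr(model, "bin_starts", None))
    reports = []
    for idx, ppm in zip(model.selected_indices, model.selected_ppm):
        col = genes[:, int(idx)]
        per_group, samples = {}, []
        for g in groups_present:
            vals = col[labels == g]
            per_group[g] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
            samples.append(vals)
        _, p = anova_oneway(samples)
        kp = kruskal_oneway(samples)[1] if include_kruskal else None
        reports.append(
            VariableReport(
                ppm=float(ppm), per_group=per_group, p_value=p,
                significant=bool(p < alpha),
                annotation=annotate_ppm(float(ppm), lib, tolerance),
                kruskal_p=kp,
            )
        )
    return reports
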