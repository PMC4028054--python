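"""qPCR analysis mathematics: SDR efficiencies, ΔΔCq fold changes, ANOVA.

The quantification cycle Cq of a real-time PCR falls by one for every
doubling of starting template when amplification is perfectly efficient.
A standard dose-response (SDR) dilution series gives the actual per-assay
efficiency from the least-squares slope of Cq against log10 template:

    E = 10^(-1 / slope)          (E = 2 for a perfect doubler)

Relative quantification normalizes a target gene to a reference
(housekeeping) gene between a test and a control group.  With per-assay
efficiencies (the efficiency-corrected, relative-standard-curve form):

    ΔCq   = mean Cq(test) - mean Cq(control)          (per gene)
    fold  = E_target^(-ΔCq_target) / E_ref^(-ΔCq_ref)
    ΔΔCq  = ΔCq_target - ΔCq_ref

When both efficiencies are exactly 2 this reduces to the textbook
``2^(-ΔΔCq)`` identity.  Group means are arithmetic means of Cq, i.e.
geometric means of template quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyEstimate",
    "FoldChange",
    "fit_efficiency",
    "fold_change",
    "one_way_anova",
]


@dataclass(frozen=True)
class DilutionSeries:
    """(log10 relative template, Cq) pairs for one gene's SDR curve."""

    gene_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        amounts = [a for a, _ in self.points]
        if any(b >= a for a, b in zip(amounts, amounts[1:])):
            raise ValueError("template amounts must be strictly decreasing")


@dataclass(frozen=True)
class EfficiencyEstimate:
    gene_id: str
    slope: float
    efficiency: float
    r_squared: float

    @property
    def within_assay_range(self) -> bool:
        """Typical valid assays have 1 < E <= 2.2."""
        return 1.0 < self.efficiency <= 2.2


def fit_efficiency(series: DilutionSeries) -> EfficiencyEstimate:
    """Least-squares Cq ~ log10(amount); E = 10^(-1/slope).

    Fewer than 3 points or a non-negative slope (no amplification response)
    is an assay failure.
    """
    if len(series.points) < 3:
        raise ValueError(
            f"{series.gene_id}: need >= 3 dilution points, got {len(series.points)}"
        )
    x = np.array([a for a, _ in series.points], dtype=float)
    y = np.array([c for _, c in series.points], dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"{series.gene_id}: non-negative SDR slope {fit.slope:.4g}; assay failed"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope)
    return EfficiencyEstimate(
        gene_id=series.gene_id,
        slope=float(fit.slope),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


@dataclass(frozen=True)
class FoldChange:
    target_gene: str
    reference_gene: str
    test_group: str
    control_group: str
    dcq_target: float
    dcq_reference: float
    ddcq: float
    fold: float


def fold_change(
    target_cq: Mapping[str, Sequence[float]],
    reference_cq: Mapping[str, Sequence[float]],
    e_target: float = 2.0,
    e_reference: float = 2.0,
    test_group: str = "test",
    control_group: str = "control",
    target_gene: str = "target",
    reference_gene: str = "reference",
    efficiency_corrected: bool = True,
) -> FoldChange:
    """Efficiency-corrected relative quantification between two groups.

    ``target_cq`` and ``reference_cq`` map group labels to replicate Cq
    values; both genes must be measured in both groups.  With
    ``efficiency_corrected=False`` both efficiencies are forced to 2
    (plain ``2^(-ΔΔCq)``).
    """
    for name, table in (("target", target_cq), ("reference", reference_cq)):
        for group in (test_group, control_group):
            if group not in table or len(table[group]) == 0:
                raise ValueError(f"{name} gene has no Cq values for group {group!r}")
    if not efficiency_corrected:
        e_target = e_reference = 2.0
    if e_target <= 1 or e_reference <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    dcq_t = float(np.mean(target_cq[test_group]) - np.mean(target_cq[control_group]))
    dcq_r = float(
        np.mean(reference_cq[test_group]) - np.mean(reference_cq[control_group])
    )
    fold = float(e_target ** (-dcq_t) / e_reference ** (-dcq_r))
    return FoldChange(
        target_gene=target_gene,
        reference_gene=reference_gene,
        test_group=test_group,
        control_group=control_group,
        dcq_target=dcq_t,
        dcq_reference=dcq_r,
        ddcq=dcq_t - dcq_r,
        fold=fold,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Requires >= 2 groups with >= 2 replicates each.  When every value is
    identical (zero between- and within-group variance) the comparison is
    vacuous and (F, p) = (0, 1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise ValueError(f"group {i} has fewer than 2 replicates")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f_stat, p_val = stats.f_oneway(*arrays)
    return float(f_stat), float(p_val)
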