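"""Flow-cytometry gating statistics and ChIP-qPCR relative enrichment.

The FACS rules quantify reporter silencing: the GFP-negative gate is drawn
on an enhancer-less (noE) control such that at least 99.9% of control cells
fall below it, percent-positive is counted against that threshold, and
expression under knockdown is reported as relative fluorescence after
subtracting the noE background from both knockdown and control medians.

ChIP-qPCR enrichment uses the standard percent-of-input model with
amplification efficiency 2, normalized to a known bound reference site so
that per-batch offsets cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "FACSSample",
    "QPCRMeasurement",
    "negative_gate",
    "percent_positive",
    "relative_fluorescence",
    "percent_input",
    "chip_relative_enrichment",
]


@dataclass
class FACSSample:
    """Per-cell fluorescence intensities (arbitrary units) for one sample."""

    intensities: np.ndarray
    label: str = ""
    channel: Literal["GFP", "dsRed", "BFP"] = "GFP"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 1:
            raise ValueError(f"FACS sample {self.label!r} is empty")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"FACS sample {self.label!r} contains non-finite intensities")

    @property
    def median(self) -> float:
        return float(np.median(self.intensities))

    def __len__(self) -> int:
        return self.intensities.size


@dataclass(frozen=True)
class QPCRMeasurement:
    """One qPCR site: IP and input cycle thresholds plus input dilution."""

    site_label: str
    ct_ip: float
    ct_input: float
    input_dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name, ct in (("ct_ip", self.ct_ip), ("ct_input", self.ct_input)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.site_label!r}: {name} must be positive and finite")
        if self.input_dilution_factor < 1:
            raise ValueError(f"{self.site_label!r}: input dilution factor must be >= 1")


def negative_gate(control: FACSSample, quantile: float = 0.999) -> float:
    """Threshold FI such that at least the given fraction of the control
    (noE) sample is gate-negative (at or below the threshold).

    The threshold is the upper ``quantile`` of the control intensities with
    linear interpolation between order statistics — a deterministic stand-in
    for a manually drawn gate.  For sample sizes where the interpolated
    quantile would leave more than the allowed fraction of control cells
    above the gate, the threshold is raised to the next order statistic so
    the guarantee holds for every n.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"gate quantile must lie in (0, 1), got {quantile}")
    thr = float(np.quantile(control.intensities, quantile, method="linear"))
    if np.mean(control.intensities <= thr) < quantile:
        thr = float(np.quantile(control.intensities, quantile, method="higher"))
    return thr


def percent_positive(sample: FACSSample, threshold: float) -> float:
    """Percentage of cells with FI strictly above the gate threshold."""
    return 100.0 * float(np.mean(sample.intensities > threshold))


def relative_fluorescence(median_kd: float, median_ctrl: float, median_noe: float) -> float:
    """Knockdown expression relative to control after background subtraction:
    (median_kd - median_noE) / (median_ctrl - median_noE)."""
    denom = median_ctrl - median_noe
    if denom <= 0:
        raise ValueError(
            "control median must exceed the noE background "
            f"(ctrl={median_ctrl}, noE={median_noe})"
        )
    return (median_kd - median_noe) / denom


def percent_input(m: QPCRMeasurement, efficiency: float = 2.0) -> float:
    """Recovered fraction of input chromatin, in percent.

    The input Ct is first adjusted for its dilution
    (``ct_input - log_eff(dilution)``); with amplification efficiency
    ``efficiency`` per cycle, percent input = 100 * eff^(adjusted_input - ct_ip).
    """
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    adjusted_input = m.ct_input - math.log(m.input_dilution_factor, efficiency)
    return 100.0 * efficiency ** (adjusted_input - m.ct_ip)


def chip_relative_enrichment(
    target: QPCRMeasurement, reference: QPCRMeasurement, efficiency: float = 2.0
) -> float:
    """Enrichment at a target site relative to a known bound reference site
    from the same immunoprecipitation: ratio of percent-input values."""
    return percent_input(target, efficiency) / percent_input(reference, efficiency)
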