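"""Adaptation and scale-invariance metrics for step-response experiments.

Precision error E and sensitivity S follow the convention of minimal-network
adaptation screens: both relative output changes are normalized by the
relative input change, so a circuit adapts when E <= 0.1 (output returns to
within 10% of the relative input change) while still detecting the signal
(S >= 1).  Approximate scale invariance (ASI) compares the output transients
of a baseline step and a scaled-background step of the same fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PRECISION_THRESHOLD = 0.1
SENSITIVITY_THRESHOLD = 1.0
ASI_THRESHOLD = 0.1

#: Baseline outputs below this are treated as zero: the relative metrics are
#: then undefined and the circuit is classified non-adapting.
OUTPUT_FLOOR = 1e-6


class UndefinedMetric(ValueError):
    """Raised when a relative metric has a vanishing normalizer."""


@dataclass
class StepResponseSummary:
    """Amplitude summary of one step experiment.

    ``O1`` is the pre-step steady output, ``Opeak`` the extremal transient
    output (the post-step value farthest from O1, either sign), and ``O2``
    the re-settled post-step output.
    """

    O1: float
    Opeak: float
    O2: float
    u1: float
    u2: float
    settled: bool = True

    @property
    def input_fold(self) -> float:
        return self.u2 / self.u1


def _relative_input_change(u1: float, u2: float) -> float:
    if u1 == 0 or u2 == u1:
        raise UndefinedMetric("step must change the input from a nonzero level")
    return abs(u2 - u1) / abs(u1)


def precision_error(s: StepResponseSummary) -> float:
    """E = |(O2 - O1)/O1| / |(u2 - u1)/u1|; adaptation requires E <= 0.1."""
    if abs(s.O1) < OUTPUT_FLOOR:
        raise UndefinedMetric("pre-step output is (numerically) zero")
    return abs((s.O2 - s.O1) / s.O1) / _relative_input_change(s.u1, s.u2)


def sensitivity(s: StepResponseSummary) -> float:
    """S = |(Opeak - O1)/O1| / |(u2 - u1)/u1|; signal detection requires S >= 1."""
    if abs(s.O1) < OUTPUT_FLOOR:
        raise UndefinedMetric("pre-step output is (numerically) zero")
    return abs((s.Opeak - s.O1) / s.O1) / _relative_input_change(s.u1, s.u2)


def asi_error(y_ref, y_scaled, y_ref_baseline=None) -> float:
    """Relative difference between a baseline and a scaled step response.

    rho = max_t |y_scaled(t) - y_ref(t)| / max_t |y_ref(t) - y_ref(0-)|.

    Both series must share the post-step time grid.  The normalizer is the
    reference transient amplitude (not the baseline output), so circuits with
    a weak transient cannot pass trivially; ASI requires rho <= 0.1.
    ``y_ref_baseline`` defaults to the first sample of ``y_ref`` (the
    pre-adapted output at the step instant).
    """
    y_ref = np.asarray(y_ref, dtype=float)
    y_scaled = np.asarray(y_scaled, dtype=float)
    if y_ref.shape != y_scaled.shape:
        raise ValueError("series must share a common time grid")
    base = y_ref[0] if y_ref_baseline is None else float(y_ref_baseline)
    amplitude = np.max(np.abs(y_ref - base))
    if amplitude <= 0:
        raise UndefinedMetric("reference transient has zero amplitude")
    return float(np.max(np.abs(y_scaled - y_ref)) / amplitude)


def summarize_step(t, y, O1: float, u1: float, u2: float,
                   settled: bool) -> StepResponseSummary:
    """Build a :class:`StepResponseSummary` from a post-step output series."""
    y = np.asarray(y, dtype=float)
    ipeak = int(np.argmax(np.abs(y - O1)))
    return StepResponseSummary(O1=float(O1), Opeak=float(y[ipeak]),
                               O2=float(y[-1]), u1=u1, u2=u2, settled=settled)
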