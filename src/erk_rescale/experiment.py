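"""Experiment timeline shared by every stage of the analysis.

All times are minutes on a common clock starting at ``t_start``.  The
timeline mirrors a typical live-cell ERK imaging run: a growth-factor-free
baseline period of at least two hours, a stimulus addition at ``t_stim``,
and a terminal MEK-inhibitor treatment at ``t_meki`` that provides the
per-cell zero-activity reference used for normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .errors import ValidationError

#: Width of the pre-stimulus window averaged for the baseline, minutes.
BASELINE_WINDOW_MIN = 120.0
#: Width of the MEK-inhibitor window used for normalization, minutes.
MEKI_WINDOW_MIN = 60.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Timing and treatment annotations for one experiment.

    Parameters
    ----------
    sampling_interval
        Acquisition period in minutes.
    t_start, t_stim, t_meki, t_end
        Minutes on a common clock: experiment start, stimulus addition,
        MEK-inhibitor addition, experiment end.
    stimulus_label, stimulus_dose
        Stimulus identity and dose (ng/ml).
    meki_dose
        MEK inhibitor dose (nM).
    """

    sampling_interval: float = 3.0
    t_start: float = 0.0
    t_stim: float = 120.0
    t_meki: float = 270.0
    t_end: float = 330.0
    stimulus_label: str = "EGF"
    stimulus_dose: float = 10.0
    meki_dose: float = 100.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0")
        if not (self.t_start < self.t_stim < self.t_meki < self.t_end):
            raise ValidationError(
                "timeline must satisfy t_start < t_stim < t_meki < t_end"
            )
        if self.t_stim - self.t_start < BASELINE_WINDOW_MIN:
            raise ValidationError(
                "t_stim - t_start must be >= 120 min to cover the baseline window"
            )
        if self.t_end - self.t_meki < MEKI_WINDOW_MIN:
            raise ValidationError(
                "t_end - t_meki must be >= 60 min to cover the MEKi window"
            )

    def times(self) -> np.ndarray:
        """Sampling grid in minutes, inclusive of ``t_end`` when it falls on grid."""
        n = int(np.floor((self.t_end - self.t_start) / self.sampling_interval + 1e-9))
        return self.t_start + self.sampling_interval * np.arange(n + 1)

    # -- canonical analysis windows (start, stop), half-open on the right ----
    @property
    def baseline_window(self) -> tuple[float, float]:
        return (self.t_stim - BASELINE_WINDOW_MIN, self.t_stim)

    @property
    def meki_window(self) -> tuple[float, float]:
        return (self.t_meki, self.t_meki + MEKI_WINDOW_MIN)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
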