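"""Trial-by-neuron spike count tables.

The central in-memory container for both passive-fixation and
free-viewing analyses: an integer count matrix (trials x neurons)
with per-trial condition and stimulus labels plus the analysis
window the counts were taken in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

UNADAPT = "unadapt"
ADAPT = "adapt"


@dataclass
class TrialTable:
    """Spike counts for a set of trials.

    Parameters
    ----------
    counts : (n_trials, n_neurons) non-negative integer array.
    condition : per-trial condition label, 'unadapt' or 'adapt'.
    stimulus_angle : per-trial stimulus angle in degrees.
    period : stimulus space period in degrees (360 for color, 180 for
        orientation).
    window_ms : (start, end) of the count window relative to stimulus
        onset; rates in spikes/s are counts / window length.
    feature : 'color' or 'orientation'.
    seed : seed of the generator that produced the table, if synthetic.
    """

    counts: np.ndarray
    condition: np.ndarray
    stimulus_angle: np.ndarray
    period: int
    window_ms: tuple[float, float] = (0.0, 200.0)
    feature: str = "color"
    seed: int | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.condition = np.asarray(self.condition, dtype=object)
        self.stimulus_angle = np.asarray(self.stimulus_angle, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (trials x neurons)")
        n = self.counts.shape[0]
        if len(self.condition) != n or len(self.stimulus_angle) != n:
            raise ValueError("per-trial labels must match trial count")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.period not in (180, 360):
            raise ValueError("period must be 180 or 360 degrees")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def window_s(self) -> float:
        return (self.window_ms[1] - self.window_ms[0]) / 1000.0

    @property
    def angles(self) -> np.ndarray:
        """Sorted unique stimulus angles present in the table."""
        return np.unique(self.stimulus_angle)

    def rates(self) -> np.ndarray:
        """Counts converted to firing rates in spikes/s."""
        return self.counts / self.window_s

    def select(self, condition: str | None = None,
               stimuli=None) -> "TrialTable":
        """Subset of trials by condition and/or stimulus angles."""
        mask = np.ones(self.n_trials, dtype=bool)
        if condition is not None:
            mask &= self.condition == condition
        if stimuli is not None:
            mask &= np.isin(self.stimulus_angle, np.asarray(stimuli, float))
        return TrialTable(self.counts[mask], self.condition[mask],
                          self.stimulus_angle[mask], self.period,
                          self.window_ms, self.feature, self.seed)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "trial_id": np.arange(self.n_trials),
            "condition": self.condition,
            "stimulus_angle_deg": self.stimulus_angle,
        })
        for k in range(self.n_neurons):
            df[f"neuron_{k}"] = self.counts[:, k]
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write counts as CSV with a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "window_ms": list(self.window_ms),
            "feature": self.feature,
            "period": self.period,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        neuron_cols = [c for c in df.columns if c.startswith("neuron_")]
        neuron_cols.sort(key=lambda c: int(c.split("_")[1]))
        return cls(
            counts=df[neuron_cols].to_numpy(),
            condition=df["condition"].to_numpy(dtype=object),
            stimulus_angle=df["stimulus_angle_deg"].to_numpy(dtype=float),
            period=int(meta["period"]),
            window_ms=tuple(meta["window_ms"]),
            feature=meta["feature"],
            seed=meta["seed"],
        )
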