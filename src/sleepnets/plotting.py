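"""Hypnogram and parameter-panel figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io import Hypnogram
from .stages import CANONICAL_STAGES

# conventional hypnogram y-axis: deep sleep at the bottom, wake on top
_PLOT_LEVEL = {"SWS": 0, "S2": 1, "S1": 2, "REM": 3, "WASO": 4}


def plot_hypnogram(hyp: Hypnogram, ax=None):
    """Step plot of the stage sequence across the night."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    levels = [_PLOT_LEVEL[s] for s in hyp.stages]
    t = np.arange(hyp.n_epochs) * hyp.epoch_minutes / 60.0
    ax.step(t, levels, where="post", lw=0.8)
    ax.set_yticks(sorted(_PLOT_LEVEL.values()))
    ax.set_yticklabels([s for s, _ in sorted(_PLOT_LEVEL.items(), key=lambda kv: kv[1])])
    ax.set_xlabel("hours since record start")
    ax.set_title(f"{hyp.subject_id} night {hyp.night_index}")
    return ax


def plot_night_parameters(phases: dict[str, "object"], ax_pair=None):
    """Transition probabilities and expected durations across night phases.

    ``phases`` maps a phase label (start/middle/end) to a
    ``ConditionalParameters``; one line per stage in each panel.
    """
    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 3.2))
    ax_t, ax_d = ax_pair
    labels = list(phases)
    x = np.arange(len(labels))
    for i, stage in enumerate(CANONICAL_STAGES):
        ax_t.plot(x, [phases[k].transition[i] for k in labels], "o-", label=stage)
        ax_d.plot(x, [phases[k].expected_durations[stage] for k in labels], "o-")
    for ax, ylab in ((ax_t, "P(stage)"), (ax_d, "expected duration (min)")):
        ax.set_xticks(x)
        ax.set_xticklabels(labels)
        ax.set_ylabel(ylab)
    ax_t.legend(fontsize=7)
    return ax_pair
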