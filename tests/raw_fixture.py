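"""Shared noiseless fixture for subspace-recovery checks.

Simulates the feed-forward model with planted exactly-orthogonal readout
planes and a go-to-movement delay long enough for preparatory activity to
decay before the movement epoch, so each epoch's raw (cross-condition
centered, unscaled) activity lies exactly in its own planted plane.
"""

import numpy as np

from orthospace.generator import GeneratorParams, Timeline, make_scenario
from orthospace.population import MOVEMENT_EPOCH, PREPARATORY_EPOCH, EpochMatrix

DECAYED_TIMELINE = Timeline(
    target_onset_ms=0.0, go_cue_ms=500.0, move_onset_ms=1150.0, end_ms=1450.0
)


def raw_planted_epochs(seed: int):
    resp, truth = make_scenario(
        "orthogonal_linked", GeneratorParams(seed=seed), timeline=DECAYED_TIMELINE
    )
    t = resp.time_ms

    def window(epoch):
        anchor = resp.events[epoch.anchor_event]
        lo = anchor + epoch.start_offset_ms
        idx = (t >= lo) & (t < lo + epoch.duration_ms)
        block = resp.rates[:, :, idx]
        n, c, tw = block.shape
        return EpochMatrix(block.reshape(n, c * tw), epoch, c, tw)

    return window(PREPARATORY_EPOCH), window(MOVEMENT_EPOCH), truth
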