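"""Shared end-to-end simulation helper for recognition tests."""

from __future__ import annotations

import numpy as np

import proteospike as ps


def simulate_and_classify(
    table: ps.ProfileTable,
    seed: int,
    n_events: int = 40,
    dt: float = 5.0,
    collapse: bool = False,
):
    """Simulate one recording per character, profile it, classify vs the table.

    With ``collapse=True`` every character is generated from the same
    (letter-A) parameters, removing all between-character separation.
    Returns (true_labels, predicted_labels).
    """
    clf = ps.NearestProfileClassifier().fit(table)
    true_labels, estimated = [], []
    for k, profile in enumerate(table):
        source = table["A"] if collapse else profile
        cfg = ps.GeneratorConfig.from_profile(
            source,
            label=profile.label,
            duration=10.0 * source.period.mean,
            sampling_interval=dt,
            noise_sd=0.05,
            seed=(seed * 997 + k) % (2**31),
        )
        rec, _ = ps.simulate_recording(cfg, n_events=n_events)
        estimated.append(ps.profile_character(rec, label=profile.label))
        true_labels.append(profile.label)
    return true_labels, list(clf.predict(estimated))
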