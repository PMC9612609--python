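"""Published per-subject trial counts for the WAY-EEG-GAL grasp-and-lift study.

The public WAY-EEG-GAL collection provides 32-channel EEG + 5-channel
bipolar EMG during grasp-and-lift trials whose objects vary in surface
friction (sandpaper vs silk, the "SS" problem) and weight (light vs heavy,
the "LH" problem).  These manifests record, per subject, how many usable
segments each class contributes; they are inputs for balancing arithmetic
and sanity checks, not a substitute for the signals themselves.
"""

from __future__ import annotations

#: subject id -> (class-1 count, class-2 count); SS: sandpaper vs silk
SS_COUNTS = {
    "P1": (51, 220),
    "P4": (39, 210),
    "P7": (51, 221),
    "P11": (50, 221),
    "P2": (50, 221),
    "P3": (51, 220),
    "P5": (50, 221),
    "P9": (51, 220),
}

#: subject id -> (class-1 count, class-2 count); LH: light vs heavy
LH_COUNTS = {
    "P1": (84, 57),
    "P4": (84, 57),
    "P7": (84, 57),
    "P11": (84, 57),
    "P2": (84, 57),
    "P3": (84, 84),
    "P5": (84, 30),
    "P9": (84, 57),
}


def class_totals(counts: dict) -> tuple[int, int]:
    """Dataset-wide (class-1, class-2) totals of a per-subject manifest."""
    c1 = sum(v[0] for v in counts.values())
    c2 = sum(v[1] for v in counts.values())
    return c1, c2


def balanced_total_per_class(counts: dict) -> int:
    """Per-class total after exact per-subject balancing to the majority count."""
    return sum(max(v) for v in counts.values())
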