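"""Mapping stable features back to sensors/bands and aggregating into ROIs.

Every MSC feature is an (EMG muscle, EEG channel, frequency band) triple,
so a selected column maps back to physiology through the inverse feature
index.  Triples are then aggregated, independently per domain, into regions
of interest: frequency bands into {low, SMR, full}, EEG channels of a
10-20 montage into {Frontal, Centro-parietal, Occipital}, and muscles into
{Arm, Forearm, Hand}.  The per-domain ROI percentages summarize where an
algorithm's stable features live.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

from .coherence import FeatureMatrix

#: Frequency-band ROIs: slow rhythms, sensorimotor rhythms (8-80 Hz), and
#: the whole-spectrum band kept as its own region.
DEFAULT_FREQUENCY_ROIS = {
    "delta": "low", "theta": "low",
    "alpha": "SMR", "beta1": "SMR", "beta2": "SMR", "beta": "SMR",
    "gamma1": "SMR", "gamma2": "SMR", "gamma3": "SMR", "gamma": "SMR",
    "full": "full",
}

#: 32-channel 10-20 montage grouped into three scalp regions; temporal,
#: central and parietal sites are merged into one centro-parietal region
#: because they jointly cover the motor-related cortices.
DEFAULT_EEG_ROIS = {
    **{ch: "Frontal" for ch in
       ("Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8")},
    **{ch: "Centro-parietal" for ch in
       ("FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
        "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8")},
    **{ch: "Occipital" for ch in ("PO3", "PO4", "O1", "Oz", "O2")},
}

#: Upper-limb muscles: anterior deltoid (AD) and brachioradialis (BR) on the
#: arm, common extensor digitorum (CED) and flexor digitorum (FD) on the
#: forearm, first dorsal interosseous (FDI) on the hand.
DEFAULT_EMG_ROIS = {
    "AD": "Arm", "BR": "Arm",
    "CED": "Forearm", "FD": "Forearm",
    "FDI": "Hand",
}

DOMAINS = ("frequency", "eeg", "emg")


@dataclass(frozen=True)
class RoiScheme:
    """Per-domain maps from band/channel/muscle name to its ROI."""

    frequency_rois: dict = field(default_factory=lambda: dict(DEFAULT_FREQUENCY_ROIS))
    eeg_rois: dict = field(default_factory=lambda: dict(DEFAULT_EEG_ROIS))
    emg_rois: dict = field(default_factory=lambda: dict(DEFAULT_EMG_ROIS))

    def roi_names(self, domain: str) -> tuple[str, ...]:
        table = self._table(domain)
        seen = []
        for v in table.values():
            if v not in seen:
                seen.append(v)
        return tuple(seen)

    def _table(self, domain: str) -> dict:
        if domain == "frequency":
            return self.frequency_rois
        if domain == "eeg":
            return self.eeg_rois
        if domain == "emg":
            return self.emg_rois
        raise KeyError(f"unknown domain {domain!r}")

    @classmethod
    def from_file(cls, path) -> "RoiScheme":
        """Load a scheme from YAML or JSON with keys frequency/eeg/emg."""
        text = open(path).read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(
            frequency_rois=dict(data.get("frequency", DEFAULT_FREQUENCY_ROIS)),
            eeg_rois=dict(data.get("eeg", DEFAULT_EEG_ROIS)),
            emg_rois=dict(data.get("emg", DEFAULT_EMG_ROIS)),
        )

    def to_file(self, path) -> None:
        data = {"frequency": self.frequency_rois, "eeg": self.eeg_rois,
                "emg": self.emg_rois}
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(data, fh, indent=2, sort_keys=True)
            else:
                yaml.safe_dump(data, fh)


def map_features_to_domains(columns, fm: FeatureMatrix) -> list[tuple[str, str, str]]:
    """Columns -> (muscle code, EEG channel, band name) triples, order preserved."""
    return [fm.column_triple(int(c)) for c in columns]


def aggregate_to_rois(triples, scheme: RoiScheme | None = None) -> dict:
    """Percentage of triples falling in each ROI, per domain independently.

    Overlapping bands each count once (a triple in beta1 and one in beta are
    two SMR counts).  Returns ``{domain: {roi: percent}}``; each domain's
    percentages sum to 100 up to rounding.  An unmapped name is an error.
    """
    triples = list(triples)
    if not triples:
        raise ValueError("no feature triples to aggregate")
    scheme = scheme or RoiScheme()

    out: dict = {}
    for domain, pos in (("emg", 0), ("eeg", 1), ("frequency", 2)):
        table = scheme._table(domain)
        counts: dict[str, int] = {roi: 0 for roi in scheme.roi_names(domain)}
        for t in triples:
            name = t[pos]
            if name not in table:
                raise KeyError(f"{domain} name {name!r} has no ROI assignment")
            counts[table[name]] += 1
        out[domain] = {roi: 100.0 * n / len(triples) for roi, n in counts.items()}
    return out
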