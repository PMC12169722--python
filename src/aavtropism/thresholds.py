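"""Control-calibrated positivity thresholds and per-nucleus classification.

GFP positivity is calibrated per patient from untransduced (PBS-only)
control sections: the cutoff is the maximum per-nucleus mean GFP observed in
the patient's controls, and a nucleus is GFP+ only if its mean GFP is
*strictly greater* than that maximum. By construction, re-classifying the
control nuclei with their own threshold yields exactly zero positives.

Marker (NeuN / GFAP / Iba1) thresholds are set per image, by default at the
mean of the channel's per-nucleus means, which for a bimodal
positive/negative population sits between the modes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from .nuclei import ROLE_COLUMNS

MARKER_ROLES = ("marker_a", "marker_b")

#: Default biological names of the marker-defined classes in the two-marker
#: staining scheme used throughout (GFAP on the 633 channel, NeuN on 546).
DEFAULT_CLASS_NAMES = {"marker_a": "GFAP", "marker_b": "NeuN"}


@dataclass
class ThresholdSet:
    """Per-patient positivity cutoffs.

    ``gfp_cutoff`` is the maximum control-nucleus mean GFP for this patient;
    ``gfp_rule`` is always "strictly_greater". ``marker_cutoffs`` maps the
    marker role to its intensity cutoff.
    """

    patient_id: str
    gfp_cutoff: float
    marker_cutoffs: dict[str, float] = field(default_factory=dict)
    gfp_rule: str = "strictly_greater"
    control_image_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def calibrate_gfp_threshold(control_tables: list[pd.DataFrame],
                            patient_id: str) -> ThresholdSet:
    """GFP cutoff = max mean-GFP over all control nuclei of this patient.

    All control images of a patient are pooled; the contributing image ids
    are recorded for provenance.
    """
    if not control_tables:
        raise ValueError("at least one control table is required")
    col = ROLE_COLUMNS["gfp"]
    maxima = []
    image_ids: list[str] = []
    for tab in control_tables:
        if len(tab) == 0:
            raise ValueError("control table is empty; cannot calibrate")
        maxima.append(float(tab[col].max()))
        if "image_id" in tab:
            image_ids.extend(sorted(set(map(str, tab["image_id"]))))
    return ThresholdSet(patient_id=patient_id, gfp_cutoff=max(maxima),
                        control_image_ids=image_ids)


def set_marker_threshold(table: pd.DataFrame, role: str,
                         method="channel_mean") -> float:
    """Cutoff for a marker channel: the mean of per-nucleus means, or fixed.

    ``method`` is either the string "channel_mean" or a fixed numeric value
    passed through unchanged.
    """
    if role not in MARKER_ROLES:
        raise ValueError(f"unknown marker role {role!r}; expected one of {MARKER_ROLES}")
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method != "channel_mean":
        raise ValueError(f"unknown method {method!r}")
    if len(table) == 0:
        raise ValueError("cannot take channel mean of an empty table")
    return float(table[ROLE_COLUMNS[role]].mean())


def classify_nuclei(table: pd.DataFrame, thresholds: ThresholdSet,
                    class_names: dict[str, str] | None = None,
                    exclude_double: bool = False) -> pd.DataFrame:
    """Flag every nucleus positive/negative per channel and assign a class.

    GFP positivity uses a strict ``>`` against the control-calibrated
    cutoff (a nucleus exactly at the cutoff is negative). Marker positivity
    uses ``>`` against the marker cutoff. Nuclei positive for both markers
    are assigned the class "double" (and, unless ``exclude_double``, still
    count in both marker denominators downstream); nuclei positive for
    neither are "unclassified".
    """
    class_names = dict(DEFAULT_CLASS_NAMES if class_names is None else class_names)
    missing = [r for r in MARKER_ROLES if r not in thresholds.marker_cutoffs]
    if missing:
        raise ValueError(f"marker cutoffs missing for roles: {missing}")
    out = table.copy()
    out["gfp_pos"] = out[ROLE_COLUMNS["gfp"]] > thresholds.gfp_cutoff
    for role in MARKER_ROLES:
        out[f"{role}_pos"] = out[ROLE_COLUMNS[role]] > thresholds.marker_cutoffs[role]
    a, b = (out["marker_a_pos"], out["marker_b_pos"])
    out["cell_class"] = "unclassified"
    out.loc[a & ~b, "cell_class"] = class_names["marker_a"]
    out.loc[b & ~a, "cell_class"] = class_names["marker_b"]
    out.loc[a & b, "cell_class"] = "double"
    if exclude_double:
        out.loc[a & b, ["marker_a_pos", "marker_b_pos"]] = False
    out["patient_id"] = thresholds.patient_id
    return out
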