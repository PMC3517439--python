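"""Bundled published inputs: the Mariner divergence survey and its calibrations.

These are the printed per-family divergence statistics and the
phylogenetic calibration priors for the mammal/insect Mariner
horizontal-transfer analysis. They are *inputs* — the package recomputes
all age estimates and verdicts from them at run time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .dating import CalibrationWindow

__all__ = ["load_divergence_survey", "load_calibrations"]


def _data_path(name: str):
    return resources.files("tehop.data").joinpath(name)


def load_divergence_survey() -> pd.DataFrame:
    """Published Mariner family divergences (percent, with SD and n) per genome."""
    with resources.as_file(_data_path("mariner_divergence_survey.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_calibrations() -> tuple[dict[str, CalibrationWindow], dict[str, float], dict[frozenset, float]]:
    """Calibration windows per genome, family caps (MYA), and split ages.

    Returns ``(calibrations, caps, splits)`` where ``splits`` maps a
    frozenset of two genome labels to their divergence time in MYA.
    """
    with resources.as_file(_data_path("mariner_calibrations.yaml")) as p:
        raw = yaml.safe_load(p.read_text())
    calibrations = {
        c["genome"]: CalibrationWindow(
            family=c["family"],
            genome=c["genome"],
            age_min=float(c["age_min"]),
            age_max=float(c["age_max"]),
            rationale=str(c.get("rationale", "")).strip(),
            divergence_genome=c.get("divergence_genome", ""),
        )
        for c in raw["calibrations"]
    }
    caps = {k: float(v) for k, v in raw.get("caps", {}).items()}
    splits = {frozenset((a, b)): float(age) for a, b, age in raw.get("splits", [])}
    return calibrations, caps, splits
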