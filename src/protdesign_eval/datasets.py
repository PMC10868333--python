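"""Packaged reference data.

Ships transcriptions of the published benchmark indicator tables (the
eleven-method *de novo* table and the six-method single-chain table),
their subjective weight rows, the default orientation map, natural
amino-acid background frequencies and the per-residue maximal-SASA
reference.

The single-chain transcription carries the per-method design times that
are consistent across both tables; the published single-chain table's
time column contains a row-offset typesetting error (each time is shifted
one method down), which the transcription corrects.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .io import AMINO_ACIDS, IndicatorTable, read_indicator_table

_DATA = resources.files(__package__) / "data"


def _path(name: str):
    return _DATA / name


def load_benchmark_config() -> dict:
    """Orientation map, subjective weight rows and pipeline defaults."""
    with resources.as_file(_path("benchmark_config.json")) as p:
        return json.loads(p.read_text())


def load_denovo_table() -> IndicatorTable:
    """11 methods × 6 indicators; the noise baseline's time is missing."""
    config = load_benchmark_config()
    with resources.as_file(_path("denovo_indicators.csv")) as p:
        return read_indicator_table(p, config["orientations"])


def load_singlechain_table() -> IndicatorTable:
    """6 methods × 7 indicators (qualified-RMSD split)."""
    config = load_benchmark_config()
    with resources.as_file(_path("singlechain_indicators.csv")) as p:
        return read_indicator_table(p, config["orientations"])


def _aa_reference() -> dict:
    with resources.as_file(_path("amino_acid_reference.json")) as p:
        return json.loads(p.read_text())


def natural_background() -> dict[str, float]:
    """Natural amino-acid frequencies (normalized to sum exactly 1)."""
    bg = _aa_reference()["background"]
    total = sum(bg.values())
    return {aa: bg[aa] / total for aa in AMINO_ACIDS}


def natural_background_vector() -> np.ndarray:
    """The background as a 20-vector in :data:`AMINO_ACIDS` order."""
    bg = natural_background()
    return np.array([bg[aa] for aa in AMINO_ACIDS])


def max_sasa_reference() -> dict[str, float]:
    """Theoretical maximal SASA (Å²) per residue type."""
    return dict(_aa_reference()["max_sasa"])


def default_nonpolar_set() -> frozenset[str]:
    return frozenset(_aa_reference()["nonpolar"])
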