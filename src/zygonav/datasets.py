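"""Bundled reference measurements.

Two small tables ship with the package, taken from a six-reduction zygoma
model-surgery study performed with FNRP guidance and prefabricated bone
plates: the per-hole drilling deviations (6 fracture sites x 12 screw holes)
and the per-case global reduction errors (geometric-center displacement and
per-axis rotation).  They serve as worked-example inputs and as regression
fixtures for the summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import DeviationTable

__all__ = ["load_drilling_deviations", "load_reduction_errors"]


def _data_path(name: str):
    return resources.files("zygonav").joinpath("data", name)


def load_drilling_deviations() -> DeviationTable:
    """The 72 measured drilling deviations (mm), 6 sites x 12 holes."""
    from .io import read_deviation_table

    with resources.as_file(_data_path("drilling_deviations.tsv")) as p:
        return DeviationTable(read_deviation_table(p))


def load_reduction_errors() -> pd.DataFrame:
    """Per-case global reduction errors: displacement (mm) and signed
    rotations about x, y, z (degrees) for six reductions."""
    with resources.as_file(_data_path("reduction_errors.tsv")) as p:
        return pd.read_csv(p, sep="\t")
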