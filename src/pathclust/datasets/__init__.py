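"""Bundled reference tables."""

from importlib.resources import files

import pandas as pd

from ..distances import DistanceMatrix

__all__ = ["load_reference_subtype_distances"]


def load_reference_subtype_distances() -> DistanceMatrix:
    """Cohort-level distance-score matrix between the five receptor-defined
    breast cancer subtypes, as reported for the original plasma cohort
    (distance-score metric, sum mode)."""
    path = files(__package__).joinpath("cohort_subtype_distances.tsv")
    with path.open() as fh:
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    frame.index.name = None
    frame.columns = frame.columns.astype(str)
    return DistanceMatrix(values=frame.astype(float), metric="distance_score", mode="sum")
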