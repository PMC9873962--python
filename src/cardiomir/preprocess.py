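"""Array preprocessing: replicate averaging, floor filtering, median scaling.

The pipeline order is: average the technical reads, drop miRNAs that fail
the detection floor in any sample, then scale each sample column so all
column medians agree (the standard single-channel median normalization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PreprocessParams",
    "average_replicates",
    "filter_floor",
    "median_normalize",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Settings of the preprocessing stage.

    intensity_floor is inclusive: a row whose minimum across all samples is
    exactly the floor survives. normalization_target of ``None`` means the
    global median of the pre-normalization column medians.
    """

    replicate_count: int = 10
    intensity_floor: float = 50.0
    normalization_target: float | None = None

    def __post_init__(self) -> None:
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def average_replicates(stack: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise arithmetic mean of a stack of technical reads.

    All matrices must share identical row and column labels in the same
    order; a mismatch raises naming the offending axis.
    """
    if not stack:
        raise ValueError("empty replicate stack")
    first = stack[0]
    for i, m in enumerate(stack[1:], start=2):
        if not m.index.equals(first.index):
            raise ValueError(f"replicate {i}: row labels differ from replicate 1")
        if not m.columns.equals(first.columns):
            raise ValueError(f"replicate {i}: column labels differ from replicate 1")
    out = first.copy()
    for m in stack[1:]:
        out = out + m
    return out / len(stack)


def filter_floor(m: pd.DataFrame, params: PreprocessParams | None = None) -> pd.DataFrame:
    """Retain rows detected in every sample.

    A row survives iff its minimum across all samples is at or above the
    intensity floor ("50 or higher" is inclusive). Row order is preserved;
    an empty result is a warning, not an error.
    """
    params = params or PreprocessParams()
    keep = m.min(axis=1) >= params.intensity_floor
    out = m.loc[keep]
    log.info("floor filter at %g: %d of %d rows retained",
             params.intensity_floor, len(out), len(m))
    if out.empty:
        warnings.warn("intensity filter removed every row", stacklevel=2)
    return out


def median_normalize(m: pd.DataFrame, params: PreprocessParams | None = None) -> pd.DataFrame:
    """Scale each sample column so its median hits a common target.

    The target defaults to the global median of the pre-normalization
    column medians. Scaling is multiplicative, so intensities stay
    non-negative and within-column ranks are untouched. A column with
    median 0 cannot be scaled and raises.
    """
    if m.empty:
        raise ValueError("cannot normalize an empty matrix")
    params = params or PreprocessParams()
    medians = m.median(axis=0)
    if (medians == 0).any():
        bad = medians.index[medians == 0][0]
        raise ValueError(f"column {bad!r} has median 0; cannot scale")
    target = params.normalization_target
    if target is None:
        target = float(medians.median())
    return m * (target / medians)


def preprocess(m: pd.DataFrame, params: PreprocessParams | None = None) -> pd.DataFrame:
    """Floor-filter then median-normalize one averaged matrix."""
    params = params or PreprocessParams()
    return median_normalize(filter_floor(m, params), params)
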