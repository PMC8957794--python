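"""Intersection/union combination of selected feature subsets.

Different wrapper methods select different subsets of the same feature
space.  Combining them by set intersection yields consensus features
(those every method agrees on), while union pools all evidence.  From
three input masks M1, M2, M3 this produces eight combination subsets:
the four intersections M1∩M2, M1∩M3, M2∩M3, M1∩M2∩M3 and the four
unions M1∪M2, M1∪M3, M2∪M3, M1∪M2∪M3; two inputs produce one of each.

Selection rates (selected features as a percentage of the feature space)
obey inclusion–exclusion exactly: rate(A∪B) = rate(A) + rate(B) − rate(A∩B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ValidationError


@dataclass
class CombinationSet:
    """Named input masks and their intersection/union combinations."""

    inputs: dict[str, np.ndarray]
    combos: dict[str, np.ndarray]

    @property
    def empty_combos(self) -> list[str]:
        """Names of combinations that select no feature at all."""
        return [name for name, mask in self.combos.items() if not mask.any()]


def combine(masks: Mapping[str, np.ndarray]) -> CombinationSet:
    """All pairwise and (for three inputs) triple intersections and unions.

    Accepts two or three equal-length boolean masks keyed by method name.
    Empty intersections are retained (flagged via ``empty_combos``) rather
    than dropped: an empty consensus is itself a result.
    """
    names = list(masks)
    if not 2 <= len(names) <= 3:
        raise ValidationError("combine requires 2 or 3 input masks")
    arrays = {k: np.asarray(v, dtype=bool) for k, v in masks.items()}
    lengths = {v.size for v in arrays.values()}
    if len(lengths) != 1:
        raise ValidationError(f"mask lengths differ: {sorted(lengths)}")

    combos: dict[str, np.ndarray] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            combos[f"{a}&{b}"] = arrays[a] & arrays[b]
    if len(names) == 3:
        combos["&".join(names)] = (
            arrays[names[0]] & arrays[names[1]] & arrays[names[2]]
        )
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            combos[f"{a}|{b}"] = arrays[a] | arrays[b]
    if len(names) == 3:
        combos["|".join(names)] = (
            arrays[names[0]] | arrays[names[1]] | arrays[names[2]]
        )
    return CombinationSet(inputs=arrays, combos=combos)


def selection_rate(mask: np.ndarray) -> float:
    """Selected features as a percentage of the feature space."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size < 1:
        raise ValidationError("mask must have length >= 1")
    return 100.0 * float(mask.sum()) / mask.size


def implied_union_rate(rate_a: float, rate_b: float, rate_ab: float) -> float:
    """Union rate from solo and intersection rates by inclusion–exclusion."""
    return rate_a + rate_b - rate_ab


def rate_table(
    runs: Mapping[str, Mapping[str, np.ndarray]], decimals: int = 4
) -> pd.DataFrame:
    """Per-dataset selection rates of solo methods and their combinations.

    ``runs`` maps dataset name -> method name -> mask (2 or 3 methods per
    dataset, same feature space within a dataset).  The result has one row
    per dataset plus an ``Average`` row; combinations that select nothing
    are rendered as ``—`` and excluded from the column average.
    """
    rows: dict[str, dict[str, object]] = {}
    columns: list[str] = []
    for dataset, method_masks in runs.items():
        cs = combine(method_masks)
        row: dict[str, object] = {}
        for name, mask in cs.inputs.items():
            row[name] = round(selection_rate(mask), decimals)
        for name, mask in cs.combos.items():
            if mask.any():
                row[name] = round(selection_rate(mask), decimals)
            else:
                row[name] = "—"
        rows[dataset] = row
        if not columns:
            columns = list(row)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)

    avg: dict[str, object] = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce").dropna()
        avg[col] = round(float(numeric.mean()), decimals) if len(numeric) else "—"
    df.loc["Average"] = avg
    return df
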