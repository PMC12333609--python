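"""Presence/background feature tables extracted from a predictor stack."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import InvalidInputError, PredictorStack

__all__ = ["SdmDesign", "extract_design"]


@dataclass
class SdmDesign:
    """Rows of labelled (presence=1 / background=0) predictor values.

    ``table`` holds columns ``label``, ``weight`` and one column per
    predictor; no missing predictor values are allowed.
    """

    table: pd.DataFrame
    predictor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).reset_index(drop=True)
        if "label" not in df:
            raise InvalidInputError("design needs a 'label' column")
        if "weight" not in df:
            df["weight"] = 1.0
        if not self.predictor_names:
            self.predictor_names = [c for c in df.columns if c not in ("label", "weight")]
        if df[self.predictor_names].isna().any().any():
            raise InvalidInputError("design has missing predictor values")
        if (df["weight"] < 0).any():
            raise InvalidInputError("weights must be non-negative")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(int)

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    def X(self, names: list[str] | None = None) -> np.ndarray:
        return self.table[names or self.predictor_names].to_numpy(float)

    def subset_rows(self, mask: np.ndarray) -> "SdmDesign":
        return SdmDesign(self.table[np.asarray(mask, bool)], list(self.predictor_names))

    def subset_predictors(self, names: list[str]) -> "SdmDesign":
        cols = ["label", "weight"] + list(names)
        return SdmDesign(self.table[cols], list(names))

    def presences(self) -> "SdmDesign":
        return self.subset_rows(self.labels == 1)

    def background(self) -> "SdmDesign":
        return self.subset_rows(self.labels == 0)


def extract_design(
    stack: PredictorStack,
    pres_xy: tuple[np.ndarray, np.ndarray],
    bg_xy: tuple[np.ndarray, np.ndarray] | None = None,
    drop_invalid: bool = True,
) -> SdmDesign:
    """Sample the stack at presence (label 1) and background (label 0) points.

    Points falling on nodata cells (any layer) are dropped when
    ``drop_invalid`` is set, otherwise they raise.
    """
    frames = []
    for label, xy in ((1, pres_xy), (0, bg_xy)):
        if xy is None:
            continue
        x, y = np.asarray(xy[0], float), np.asarray(xy[1], float)
        df = stack.sample(x, y)
        df.insert(0, "label", label)
        df.insert(1, "weight", 1.0)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    bad = out[stack.names].isna().any(axis=1)
    if bad.any():
        if not drop_invalid:
            raise InvalidInputError(f"{int(bad.sum())} points fall on nodata cells")
        out = out[~bad]
    return SdmDesign(out, list(stack.names))
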