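"""Point-annotation container shared by the generator, the counting model and
the evaluation code.

A :class:`PointSet` is one image's worth of seed points: ground-truth
annotations carry no scores, model predictions carry a confidence per point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PointSet:
    """Per-image seed point annotations or predictions.

    Attributes
    ----------
    xy : (N, 2) float array
        Point coordinates in pixels, x rightward, y downward.
    scores : (N,) float array or None
        Confidence in [0, 1]; present iff the points are predictions.
    image_id : str or None
        Identifier of the image the points belong to.
    """

    xy: np.ndarray
    scores: np.ndarray | None = None
    image_id: str | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
            if len(self.scores) != len(self.xy):
                raise ValueError("scores length must match number of points")

    def __len__(self) -> int:
        return len(self.xy)

    @classmethod
    def empty(cls, image_id: str | None = None) -> "PointSet":
        return cls(xy=np.empty((0, 2)), image_id=image_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"image_id": self.image_id, "x": self.xy[:, 0],
                           "y": self.xy[:, 1]})
        if self.scores is not None:
            df["score"] = self.scores
        return df


def write_points_csv(path, pointsets: list[PointSet]) -> None:
    """Write point annotations as a flat CSV (image_id, x, y[, score])."""
    frames = [ps.to_frame() for ps in pointsets if len(ps) or True]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_points_csv(path) -> dict[str, PointSet]:
    """Read a point-annotation CSV back into per-image PointSets."""
    df = pd.read_csv(path)
    out: dict[str, PointSet] = {}
    for image_id, grp in df.groupby("image_id", sort=False):
        scores = grp["score"].to_numpy() if "score" in grp.columns else None
        out[str(image_id)] = PointSet(
            xy=grp[["x", "y"]].to_numpy(), scores=scores, image_id=str(image_id)
        )
    return out
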