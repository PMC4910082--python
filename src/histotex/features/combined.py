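"""Feature-set registry: pure descriptor families and their combinations.

The six pure families, ranked by their multiclass classification
accuracy, are histogram-lower > LBP > histogram-higher > GLCM >
perceptual > Gabor.  Combined sets concatenate families in that order:

======== ==================================================== ======
set id   contents                                             length
======== ==================================================== ======
best2    histogram-lower + LBP                                43
best3    best2 + histogram-higher minus duplicates            49
best4    best3 + GLCM                                         69
best5    best4 + perceptual                                   74
all6     best5 + Gabor                                        80
======== ==================================================== ======

The best3 deduplication drops the central moments mu2..mu5 from
histogram-higher, since histogram-lower already carries variance,
skewness, kurtosis and the 5th moment (the same information up to
normalisation).  This is the only reading under which best5 comes out
at 5 + 38 + 6 + 20 + 5 = 74 dimensions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gabor import GABOR_NAMES, gabor_features
from .glcm import GLCM_NAMES, glcm_features
from .histogram import (
    HISTOGRAM_HIGHER_NAMES,
    HISTOGRAM_LOWER_NAMES,
    histogram_higher,
    histogram_lower,
)
from .lbp import LBP_HF_NAMES, lbp_hf
from .perceptual import PERCEPTUAL_NAMES, perceptual_features

# histogram-higher columns kept in combined sets (mu6..mu11)
_HH_KEEP = [i for i, n in enumerate(HISTOGRAM_HIGHER_NAMES)
            if int(n.rsplit("moment", 1)[1]) >= 6]

PURE_SETS = {
    "histogram_lower": (histogram_lower, HISTOGRAM_LOWER_NAMES),
    "histogram_higher": (histogram_higher, HISTOGRAM_HIGHER_NAMES),
    "lbp": (lbp_hf, LBP_HF_NAMES),
    "glcm": (glcm_features, GLCM_NAMES),
    "gabor": (gabor_features, GABOR_NAMES),
    "perceptual": (perceptual_features, PERCEPTUAL_NAMES),
}

#: accuracy-rank order used when concatenating
RANKED_PURE = [
    "histogram_lower", "lbp", "histogram_higher", "glcm", "perceptual",
    "gabor",
]

COMBINED_SETS = {
    "best2": RANKED_PURE[:2],
    "best3": RANKED_PURE[:3],
    "best4": RANKED_PURE[:4],
    "best5": RANKED_PURE[:5],
    "all6": RANKED_PURE[:6],
}

FEATURE_SET_LENGTHS = {
    "histogram_lower": 5,
    "histogram_higher": 10,
    "lbp": 38,
    "glcm": 20,
    "gabor": 6,
    "perceptual": 5,
    "best2": 43,
    "best3": 49,
    "best4": 69,
    "best5": 74,
    "all6": 80,
}

FEATURE_SET_IDS = list(FEATURE_SET_LENGTHS)


def feature_names(set_id: str) -> list:
    """Ordered feature names for a pure or combined set id."""
    if set_id in PURE_SETS:
        return list(PURE_SETS[set_id][1])
    if set_id in COMBINED_SETS:
        names = []
        for member in COMBINED_SETS[set_id]:
            member_names = PURE_SETS[member][1]
            if member == "histogram_higher":
                member_names = [member_names[i] for i in _HH_KEEP]
            names.extend(member_names)
        return names
    raise ValueError(f"unknown feature set id: {set_id!r}")


def combined_features(img: np.ndarray, set_id: str) -> np.ndarray:
    """Feature vector of a greyscale image for any registered set id."""
    if set_id in PURE_SETS:
        return PURE_SETS[set_id][0](img)
    if set_id not in COMBINED_SETS:
        raise ValueError(f"unknown feature set id: {set_id!r}")
    parts = []
    for member in COMBINED_SETS[set_id]:
        vec = PURE_SETS[member][0](img)
        if member == "histogram_higher":
            vec = vec[_HH_KEEP]
        parts.append(vec)
    return np.concatenate(parts)


def extract_matrix(tileset, set_id: str, to_gray=None) -> pd.DataFrame:
    """Feature matrix of a labelled tile set.

    Returns a DataFrame with one named feature column per feature and a
    final integer ``label`` column; rows align with ``tileset.tiles``.
    """
    from ..image_io import to_grayscale

    if to_gray is None:
        to_gray = to_grayscale
    if len(tileset) == 0:
        raise ValueError("empty tile set")
    names = feature_names(set_id)
    rows = np.empty((len(tileset), len(names)))
    for i, tile in enumerate(tileset.tiles):
        try:
            rows[i] = combined_features(to_gray(tile), set_id)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed on tile {i}: {exc}"
                               ) from exc
    df = pd.DataFrame(rows, columns=names)
    df["label"] = np.asarray(tileset.labels, dtype=int)
    return df
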