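"""End-to-end glue: corpus -> segmented ROIs -> feature/chemistry tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemistry import strength_profile
from .features import extract_features
from .segmentation import segment
from .spectral import extract_spectral_features
from .synth import Corpus


def extract_feature_table(corpus: Corpus, min_area: int = 25) -> pd.DataFrame:
    """Segment every image and extract the 21-feature vector.

    Returns a frame with columns id, class and the 21 feature names.
    """
    rows = []
    for item in corpus.items:
        mask = segment(item.image, min_area=min_area)
        feats = extract_features(item.image, mask)
        rows.append({"id": item.item_id, "class": item.label.value,
                     **feats.to_dict()})
    return pd.DataFrame(rows)


def extract_spectral_table(corpus: Corpus) -> pd.DataFrame:
    """Calibrate and extract the 6-element spectral vector per item."""
    rows = []
    for item in corpus.items:
        if item.spectral is None:
            raise ValueError(f"item {item.item_id} has no spectral frames")
        feats = extract_spectral_features(item.spectral)
        rows.append({"id": item.item_id, "class": item.label.value,
                     **feats.to_dict()})
    return pd.DataFrame(rows)


def chemistry_table(corpus: Corpus) -> pd.DataFrame:
    """ISO strengths and genuineness flags for every generated assay."""
    rows = []
    for item in corpus.items:
        profile = strength_profile(item.assay)
        rows.append({
            "id": item.item_id, "class": item.label.value,
            "crocin": profile.crocin, "picrocrocin": profile.picrocrocin,
            "safranal": profile.safranal,
            "crocin_genuine": profile.crocin_genuine,
            "picrocrocin_genuine": profile.picrocrocin_genuine,
            "safranal_genuine": profile.safranal_genuine,
        })
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame,
                   columns) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) from a feature table with an id/class layout."""
    X = table.loc[:, list(columns)].to_numpy(dtype=np.float64)
    y = table["class"].to_numpy()
    return X, y
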