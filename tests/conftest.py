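import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenoscreen.image_features import OBJECT_MEASURES, WellObjectTable

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_object_table(
    records: list[dict],
    image_area: int = 65536,
    background_mean: float = 100.0,
    background_sd: float = 5.0,
    n_fields: int = 1,
) -> WellObjectTable:
    """Build a WellObjectTable directly from per-object measure dicts.

    Unspecified measures default to 1.0; centroids default to a grid so
    nearest-neighbour distances are well defined.
    """
    rows = []
    for i, rec in enumerate(records):
        row = {"label": i + 1, "field": rec.get("field", 0)}
        for m in OBJECT_MEASURES:
            row[m] = float(rec.get(m, 1.0))
        row["centroid_r"] = float(rec.get("centroid_r", 10.0 * i))
        row["centroid_c"] = float(rec.get("centroid_c", 10.0 * i))
        rows.append(row)
    objects = pd.DataFrame(
        rows, columns=["label", "field", *OBJECT_MEASURES, "centroid_r", "centroid_c"]
    )
    return WellObjectTable(
        well=None,
        objects=objects,
        n_fields=n_fields,
        image_area=image_area,
        background_mean=background_mean,
        background_sd=background_sd,
        background_n=image_area - int(objects["area"].sum()) if rows else image_area,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
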