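import numpy as np
import pandas as pd
import pytest

from lumiscreen.io import ScreenDataset


def make_toy_screen() -> ScreenDataset:
    """Two plates, 6 wells each: 3 test genes + 3 controls per plate, 1 replicate."""
    pm = pd.DataFrame(
        [
            ("P01", "A1", "test", "TLN1", ""),
            ("P01", "A2", "test", "RAP1B", ""),
            ("P01", "A3", "test", "VEGFB", ""),
            ("P01", "B1", "negative_control", "", "GFP"),
            ("P01", "B2", "negative_control", "", "Scrambled"),
            ("P01", "B3", "negative_control", "", "AllStars"),
            ("P02", "A1", "test", "PJA2", ""),
            ("P02", "A2", "test", "RHOJ", ""),
            ("P02", "A3", "test", "TNS3", ""),
            ("P02", "B1", "negative_control", "", "GFP"),
            ("P02", "B2", "negative_control", "", "Scrambled"),
            ("P02", "B3", "negative_control", "", "AllStars"),
        ],
        columns=["plate_id", "well", "role", "gene_id", "control_type"],
    )
    rows = []
    rng = np.random.default_rng(42)
    for plate in ("P01", "P02"):
        for well in ("A1", "A2", "A3", "B1", "B2", "B3"):
            rows.append((plate, well, 1, float(rng.uniform(80, 120))))
    ms = pd.DataFrame(rows, columns=["plate_id", "well", "replicate", "rlu"])
    return ScreenDataset(platemap=pm, measurements=ms)


@pytest.fixture
def toy_screen() -> ScreenDataset:
    return make_toy_screen()


@pytest.fixture
def phospho_intensity_cols():
    stim = [f"stimulated_{i}" for i in range(1, 5)]
    ctl = [f"control_{i}" for i in range(1, 5)]
    return stim, ctl
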