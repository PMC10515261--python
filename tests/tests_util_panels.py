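"""Shared helper: random panels with missing cells for merge checks."""

import numpy as np
import pandas as pd

from riskcast import Panel


def random_panel(rng, max_regions=6, max_years=12, missing_frac=0.3):
    n_regions = int(rng.integers(1, max_regions))
    n_years = int(rng.integers(1, max_years))
    values = rng.uniform(0, 1, size=(n_years, n_regions))
    values[rng.uniform(size=values.shape) < missing_frac] = np.nan
    data = pd.DataFrame(
        values,
        index=pd.Index(range(1990, 1990 + n_years), name="year"),
        columns=[f"R{i}" for i in range(n_regions)],
    )
    return Panel(data=data), values
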