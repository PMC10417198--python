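import dataclasses

import numpy as np
import pandas as pd
import pytest

from sepkit.io import err_col, ppm_col
from sepkit.simulate import default_config, generate_profile_table


@pytest.fixture
def config():
    return default_config(seed=123)


@pytest.fixture
def profile(config):
    return generate_profile_table(config)


def null_config(seed=0, **overrides):
    """Default design with every effect flattened to 1 (null generator)."""
    cfg = default_config(seed=seed)
    changes = dict(
        site_effects={g.site: {} for g in cfg.group_defs},
        cooking_effects={},
        production_effects={},
        planted_nonzero={},
    )
    changes.update(overrides)
    return dataclasses.replace(cfg, **changes)


def strong_site_config(seed=0):
    """Design with large, distinct per-group fingerprints: trivially separable."""
    cfg = default_config(seed=seed)
    els = list(cfg.element_roster)
    minors = [e for e in els if e not in ("As", "Zr", "Th")]
    effects = {}
    for i, g in enumerate(cfg.group_defs):
        up = minors[i % len(minors)]
        down = minors[(i + 4) % len(minors)]
        effects[g.site] = {up: 3.0, down: 0.3}
    return dataclasses.replace(
        cfg,
        site_effects=effects,
        noise_cv=0.03,
        planted_nonzero={},
    )


def make_profile(values: dict[str, np.ndarray], err_scale: float = 0.01,
                 groups: int = 8) -> pd.DataFrame:
    """Hand-built profile table from raw per-element value arrays."""
    n = len(next(iter(values.values())))
    per = n // groups
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i:02d}" for i in range(n)],
            "site": [f"g{i // per}" for i in range(n)],
            "production": ["farmed"] * n,
            "preparation": ["raw"] * n,
        }
    )
    for el, vals in values.items():
        vals = np.asarray(vals, dtype=float)
        table[ppm_col(el)] = vals
        table[err_col(el)] = err_scale * np.abs(vals)
    return table
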