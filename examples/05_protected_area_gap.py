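"""Gap analysis: how well do existing protected areas cover priorities?

Overlays the simulated protected-area mask on a BrCE prioritization,
splits the landscape into the five protection/selection classes, and
reports per-species range protection now versus under the top-17%
solution.
"""

import numpy as np
import pandas as pd

from endemap import (
    NullModelConfig,
    SyntheticConfig,
    build_features,
    core_area_rank,
    plant_endemism,
    run_canape,
    top_fraction,
)
from endemap.evaluate import (
    ProtectedMask,
    protection_classes,
    species_protection,
)

land = plant_endemism(SyntheticConfig(seed=11))
classes = run_canape(land.presence, land.tree,
                     NullModelConfig(n_rand=199, seed=110))["class"].to_numpy()
ranking = core_area_rank(
    build_features("BrCE", land.presence, land.tree, classes), seed=1)

mask = ProtectedMask(land.protected)
pcls = protection_classes(ranking, mask, lower=0.17, upper=0.30)
print("protection/selection classes (cells):")
print(pd.Series(pcls).value_counts().to_string())
print()

current = species_protection(land.presence, mask.cells)
future = species_protection(land.presence, top_fraction(ranking, 0.17))
print(f"mean range protection now:           "
      f"{current.attrs['mean_percent']:.1f}%")
print(f"mean range protection in top 17%:    "
      f"{future.attrs['mean_percent']:.1f}%")
print(f"species with <50% of range protected: "
      f"{current.attrs['n_below_50']} now, {future.attrs['n_below_50']} "
      "under the solution")
print(f"species with <10%:                    "
      f"{current.attrs['n_below_10']} now, {future.attrs['n_below_10']} "
      "under the solution")
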