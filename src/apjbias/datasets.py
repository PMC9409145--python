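"""Published reference values used as inputs and regression baselines.

These are the printed summary numbers for (-)-epicatechin (EC) and the
G-protein-biased comparator CMF-019 at the apelin receptor: the
Tyr221/Tyr309 distance table sampled every 10 ns from 100 ns active-state
simulations, the beta-arrestin recruitment Bmax values (relative
luminescence units), and the operational-model / binding / inhibition
parameters.  They serve as pipeline inputs (the raw curves and
trajectories are not deposited) and as ground-truth settings for the
synthetic generators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import DistanceSeries

__all__ = [
    "tyr_pair_distance_table", "tyr_pair_series", "BMAX_RLU",
    "BMAX_REFERENCE_LABEL", "OPERATIONAL_PARAMS", "BINDING_PARAMS",
    "INHIBITION_IC50_M", "INHIBITION_MAX_PERCENT",
]

_TIMES_NS = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0]

# Distances in Angstrom between the TM5 Tyr221 and TM7 Tyr309 residues,
# one column per ligand and donor direction ("Tyr309O-HTyr221" = acceptor
# oxygen on Tyr309, donor hydrogen on Tyr221).
_TYR_TABLE = {
    "time_ns": _TIMES_NS,
    "ec_Tyr309O-HTyr221": [3.04, 3.41, 3.08, 4.25, 2.70, 2.18, 2.15, 3.49, 3.30, 2.12],
    "ec_Tyr221O-HTyr309": [2.22, 2.31, 2.11, 3.41, 2.94, 2.80, 3.07, 4.34, 3.29, 2.92],
    "cmf_Tyr309O-HTyr221": [4.15, 3.85, 3.42, 4.66, 4.85, 5.52, 10.31, 6.42, 9.31, 8.67],
    "cmf_Tyr221O-HTyr309": [3.96, 3.57, 3.38, 3.99, 4.06, 4.68, 11.13, 5.72, 9.95, 9.82],
}


def tyr_pair_distance_table() -> pd.DataFrame:
    """The Tyr221/Tyr309 distance table as a tidy DataFrame."""
    return pd.DataFrame(_TYR_TABLE)


def tyr_pair_series(ligand: str, donor: str) -> DistanceSeries:
    """One column of the distance table as a :class:`DistanceSeries`.

    ``ligand`` is ``"ec"`` or ``"cmf"``; ``donor`` is ``"Tyr221"`` or
    ``"Tyr309"`` (the residue donating the hydrogen).
    """
    acceptor = {"Tyr221": "Tyr309", "Tyr309": "Tyr221"}.get(donor)
    if acceptor is None:
        raise ValueError("donor must be 'Tyr221' or 'Tyr309'")
    key = f"{ligand.lower()}_{acceptor}O-H{donor}"
    if key not in _TYR_TABLE:
        raise ValueError(f"no column for ligand {ligand!r}")
    return DistanceSeries(
        pair_label=key.split("_", 1)[1],
        times_ns=np.array(_TIMES_NS),
        distances_A=np.array(_TYR_TABLE[key]),
    )


# Maximal specific binding of the recruitment assay, RLU.
BMAX_RLU = {
    "apelin-13": 801_286.0,
    "EC": 810_100.0,
    "EC+ML221": 733_981.0,
}
BMAX_REFERENCE_LABEL = "apelin-13"

# Operational-model efficacy/affinity (dimensionless model scale) per ligand.
OPERATIONAL_PARAMS = {
    "EC": {"tau": 21.8, "KA": 20.8},
    "EC+ML221": {"tau": 1.53, "KA": 0.53},
}

# Saturation-binding parameters: Bmax (RLU), Kd (M), Hill slope h.
BINDING_PARAMS = {
    "apelin-13": {"Bmax": 801_286.0, "Kd": 2.508e-11, "h": 0.2202},
    "EC": {"Bmax": 810_100.0, "Kd": 1.755e-12, "h": 0.3432},
    "EC+ML221": {"Bmax": 733_981.0, "Kd": 1.012e-9, "h": 0.2134},
}

# Antagonist-displacement curve of EC in the presence of ML221.
INHIBITION_IC50_M = 6.93e-11
INHIBITION_MAX_PERCENT = 71.57
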