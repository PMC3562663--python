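"""Published benchmark counts for five topology predictors and their fusion.

Residue-level confusion counts and TM-region counts reported for five
individual transmembrane-topology predictors (OCTOPUS, PRO-TMHMM,
PRODIV-TMHMM, SCAMPI-msa, SCAMPI-seq) and their evidential-fusion
ensemble, evaluated by tenfold cross-validation on a homology-reduced
set of 125 membrane proteins of known topology (29 902 residues, 515
observed TM helices).  These counts are inputs for recomputing the
benchmark's residue- and region-level scores; the raw predictor
outputs and the underlying protein set are not redistributed here.
"""

from __future__ import annotations

import numpy as np

from topper.bpa import ConfusionMatrix
from topper.evaluation import RegionScore

__all__ = ["PREDICTOR_IDS", "ENSEMBLE_ID", "confusion_matrices", "region_counts"]

PREDICTOR_IDS = ("OCTOPUS", "PRO", "PRODIV", "SCAMPI-msa", "SCAMPI-seq")
ENSEMBLE_ID = "TOPPER"

# rows = true class (i, M, o), columns = predicted class (i, M, o)
_CONFUSION = {
    "OCTOPUS": [[7655, 389, 839], [1877, 9785, 1458], [1230, 578, 6091]],
    "PRO": [[7574, 450, 859], [1922, 9588, 1610], [1051, 714, 6134]],
    "PRODIV": [[7323, 442, 1118], [1819, 9884, 1417], [1117, 775, 6007]],
    "SCAMPI-msa": [[7655, 389, 839], [1877, 9785, 1458], [1230, 578, 6091]],
    "SCAMPI-seq": [[7359, 455, 1069], [1907, 9628, 1585], [1101, 564, 6234]],
    "TOPPER": [[7636, 358, 889], [1799, 9817, 1504], [916, 518, 6465]],
}

# (N_obs, N_prd, N_cor) TM-region counts under the >= 9-residue overlap rule
_REGIONS = {
    "OCTOPUS": (515, 512, 500),
    "PRO": (515, 512, 498),
    "PRODIV": (515, 524, 503),
    "SCAMPI-msa": (515, 512, 500),
    "SCAMPI-seq": (515, 507, 494),
    "TOPPER": (515, 507, 500),
}


def confusion_matrices() -> dict[str, ConfusionMatrix]:
    """The benchmark residue confusion matrices, individual predictors plus ensemble."""
    return {
        pid: ConfusionMatrix(counts=np.array(cells, dtype=np.int64), predictor_id=pid)
        for pid, cells in _CONFUSION.items()
    }


def region_counts() -> dict[str, RegionScore]:
    """The benchmark TM-region counts as :class:`RegionScore` inputs."""
    return {pid: RegionScore(*counts) for pid, counts in _REGIONS.items()}
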