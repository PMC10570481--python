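"""Shared constants, seed derivation, and logging setup.

Feature order is fixed package-wide: (DWI, FA, S0, MD, AD, RD).  Every
6-vector, archetype mean, codebook row, centroid and component plane uses
this order.
"""

from __future__ import annotations

import hashlib
import logging

FEATURES: tuple[str, ...] = ("dwi", "fa", "s0", "md", "ad", "rd")
N_FEATURES: int = len(FEATURES)

# column indices into any 6-feature array
DWI, FA, S0, MD, AD, RD = range(6)

#: acquisition voxel size (mm) used for synthetic grids
VOXEL_SIZE_MM: float = 1.7

#: observed tumor-ROI voxel-count range; outside it we warn, never fail
ROI_VOXEL_RANGE: tuple[int, int] = (100, 17463)

logger = logging.getLogger("dtci")
if not logger.handlers:  # library default: warnings to stderr
    logging.basicConfig(format="%(levelname)s dtci: %(message)s")


def derive_seed(master_seed: int, *tags: object) -> int:
    """Derive a child seed from a master seed and a label path.

    One master seed fans out to every stochastic component (SOM init, KM++
    restarts, per-repetition reseeds, bootstraps) through this function, so
    an end-to-end run is reproducible and each component's stream is
    documented by its tag path, e.g. ``derive_seed(s, "km", K, rep)``.
    Returns an integer in [0, 2**31).
    """
    key = str(int(master_seed)) + "/" + "/".join(str(t) for t in tags)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
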